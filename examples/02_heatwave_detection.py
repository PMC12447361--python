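"""Detect heatwaves under the six canonical definitions and match exposure.

Computes location-specific percentile thresholds, flags runs of consecutive
exceedance days, and builds the lag 0-14 exposure vector for one interview
date (lag 0 = the recall day, i.e. the day before the interview).
"""

import pandas as pd

from heatfeed import (
    CANONICAL_DEFINITIONS,
    GeneratorConfig,
    HeatwaveDefinition,
    compute_threshold,
    detect_heatwaves,
    generate_climate,
)
from heatfeed.climate import lag_vector

climate = generate_climate(GeneratorConfig(
    seed=2, n_countries=1, clusters_per_country=1, children_per_cluster=1))
series = next(iter(climate.values()))

print(f"cluster {series.cluster_id}: {len(series)} days of daily mean temperature")
for pct, dur in CANONICAL_DEFINITIONS:
    definition = HeatwaveDefinition(pct, dur)
    thr = compute_threshold(series, pct)
    cal = detect_heatwaves(series, definition, thr)
    print(f"  p{pct:>4}, >= {dur} days: threshold {thr:5.2f} C, "
          f"{cal.n_events:4d} events, {cal.is_heatwave_day.mean():.3f} of days flagged")

definition = HeatwaveDefinition(95.0, 2)
cal = detect_heatwaves(series, definition, compute_threshold(series, 95.0))
interview = pd.Timestamp("2015-08-20")
h = lag_vector(cal, interview, max_lag=14)
print(f"\nexposure vector for interview {interview.date()} (lag 0 = recall day):")
print("  " + " ".join(str(int(v)) for v in h))
print(f"  {h.sum()} heatwave day(s) in the 15-day window")
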