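import numpy as np
import pandas as pd
import pytest

from heatfeed.climate import DailySeries
from heatfeed.synthetic import GeneratorConfig, generate_climate, generate_records_mode_b


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_cohort():
    """A small mode-B cohort reused by indicator/model/pipeline tests."""
    cfg = GeneratorConfig(
        seed=42, mode="B", n_countries=3, clusters_per_country=2,
        children_per_cluster=120, interview_range=("2010-01-01", "2011-12-31"),
    )
    climate = generate_climate(cfg)
    return generate_records_mode_b(cfg, climate)


@pytest.fixture()
def flat_series():
    dates = pd.date_range("2000-01-01", periods=400, freq="D")
    return DailySeries("flat", dates, np.full(400, 25.0))


def make_series(tmean, start="2000-01-01", cluster_id="X", **kw):
    dates = pd.date_range(start, periods=len(tmean), freq="D")
    return DailySeries(cluster_id, dates, np.asarray(tmean, dtype=float), **kw)
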