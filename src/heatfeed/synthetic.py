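"""Synthetic cluster climates and survey-style child records with planted truth.

Stands in for the two real inputs of the analysis — reanalysis daily
temperature per survey cluster and household-survey recall records — so that
every downstream stage (exposure, indicators, distributed-lag model,
inference) can be exercised and validated against a known exposure-outcome
structure without any data download.

Climate: per-cluster daily mean temperature 2000-2020 with a sinusoidal
seasonal cycle, a linear warming trend and stationary AR(1) noise.

Records, two modes:

* Mode A ("direct outcome"): the binary outcome (not meeting an indicator)
  is drawn from a logistic model whose linear predictor contains a planted
  lag-distributed heatwave effect, covariate effects, and Gaussian country
  intercepts.  Used for parameter-recovery and coverage studies.
* Mode B ("recall items"): the 24-h recall items themselves (8 food-group
  flags, meal and milk-feed counts, breastfeeding status) are drawn with
  group-specific base rates and heat sensitivities; indicators are NOT
  stored and must be derived downstream.  Heat sensitivity ordering mirrors
  the qualitative food-group ranking of the motivating analysis
  (vegetables/legumes most affected, breastfeeding least).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit, logit

from .basis import LagBasisSpec, natural_cubic_basis
from .climate import (
    DailySeries,
    HeatwaveDefinition,
    build_lag_matrix,
    compute_threshold,
    detect_heatwaves,
)

logger = logging.getLogger(__name__)

#: Cumulative log-OR of the planted lag curve: the headline cumulative odds
#: ratio for not meeting minimum dietary diversity (6.19).
DEFAULT_CUMULATIVE_OR = 6.19

#: Default marginal covariate effects (log-odds of NOT meeting the standard).
DEFAULT_COVARIATE_EFFECTS = {
    "female": 0.02,          # near-null sex difference
    "age_months": -0.05,     # per month above 6; older children fare better
    "laz": -0.05,            # per Z
    "maternal_age": -0.01,   # per year above 25
    "education_primary": -0.15,
    "education_secondary": -0.40,
    "urban": -0.35,
    "wealth_quintile": -0.12,  # per quintile above the 1st
}

#: Mode-B base consumption rates per food group on non-heatwave days.
DEFAULT_BASE_RATES = {
    "fg_grains": 0.60,
    "fg_legumes_nuts": 0.25,
    "fg_dairy": 0.30,
    "fg_flesh": 0.25,
    "fg_eggs": 0.15,
    "fg_vita_fruit_veg": 0.35,
    "fg_other_fruit_veg": 0.30,
}

#: Mode-B cumulative heat sensitivities (log-OR of NOT consuming the group),
#: ordered like the observed food-group ranking: vegetables most sensitive,
#: breastfeeding least.
DEFAULT_HEAT_SENSITIVITY = {
    "fg_vita_fruit_veg": float(np.log(5.82)),
    "fg_legumes_nuts": float(np.log(5.36)),
    "fg_grains": float(np.log(4.96)),
    "fg_eggs": float(np.log(4.42)),
    "fg_other_fruit_veg": float(np.log(4.00)),
    "fg_flesh": float(np.log(3.46)),
    "fg_dairy": float(np.log(2.13)),
    "breastfeeding": float(np.log(1.93)),
}


def default_planted_curve(max_lag: int = 14, cumulative_log_or: float | None = None,
                          decay: float = 0.7) -> np.ndarray:
    """Smooth declining lag curve summing exactly to the cumulative log-OR.

    A geometric decay (effects immediate, fading over two weeks) projected
    into the natural-spline lag family used by the analysis, then rescaled so
    the lag sum equals ``cumulative_log_or`` exactly.
    """
    if cumulative_log_or is None:
        cumulative_log_or = float(np.log(DEFAULT_CUMULATIVE_OR))
    b = natural_cubic_basis(LagBasisSpec(max_lag=max_lag)).b
    target = decay ** np.arange(max_lag + 1)
    coef, *_ = np.linalg.lstsq(b, target, rcond=None)
    curve = b @ coef
    return curve * (cumulative_log_or / curve.sum())


@dataclass
class GeneratorConfig:
    """Truth record of one synthetic cohort."""

    n_countries: int = 6
    clusters_per_country: int = 8
    children_per_cluster: int = 100
    date_range: tuple[str, str] = ("2000-01-01", "2020-12-31")
    interview_range: tuple[str, str] = ("2000-02-01", "2019-12-31")
    # climate
    mean_temp_range: tuple[float, float] = (22.0, 30.0)  # deg C, per-cluster draw
    seasonal_amplitude: float = 4.0  # deg C
    ar1_coefficient: float = 0.7
    noise_sd: float = 1.8  # deg C
    warming_trend: float = 0.2  # deg C per decade
    # outcome model
    baseline_logit: float = 1.5  # log-odds of NOT meeting the standard
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    country_intercept_sd: float = 0.3
    planted_lag_curve: np.ndarray | None = None  # lags 0..14, log-OR each
    planted_cumulative_logor: float | None = None
    heatwave_definition: HeatwaveDefinition = HeatwaveDefinition(95.0, 2)
    mode: str = "A"  # "A" direct outcome | "B" recall items
    # mode-B knobs
    base_rates: dict = field(default_factory=lambda: dict(DEFAULT_BASE_RATES))
    heat_sensitivity: dict = field(
        default_factory=lambda: dict(DEFAULT_HEAT_SENSITIVITY))
    meal_count_mean: float = 3.0
    meal_count_heat_shift: float = -0.15  # log-mean shift under full exposure
    milk_feed_mean_bf: float = 0.8
    milk_feed_mean_nonbf: float = 2.0
    # breastfeeding logit: intercept + slope * (age_months - 6)
    breastfed_logit_intercept: float = 3.5
    breastfed_logit_age_slope: float = -0.18
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar1_coefficient < 1.0):
            raise ValueError("ar1_coefficient must be in [0, 1)")
        start, end = (pd.Timestamp(d) for d in self.date_range)
        if end <= start:
            raise ValueError(
                f"date_range must span at least one day, got {self.date_range}"
            )
        if self.mode not in ("A", "B"):
            raise ValueError("mode must be 'A' or 'B'")
        if self.planted_lag_curve is None:
            self.planted_lag_curve = default_planted_curve(
                cumulative_log_or=self.planted_cumulative_logor
            )
        self.planted_lag_curve = np.asarray(self.planted_lag_curve, dtype=float)
        if len(self.planted_lag_curve) != 15:
            raise ValueError("planted_lag_curve must have length 15 (lags 0..14)")
        if self.planted_cumulative_logor is None:
            self.planted_cumulative_logor = float(self.planted_lag_curve.sum())
        if self.mode == "A" and abs(
            self.planted_lag_curve.sum() - self.planted_cumulative_logor
        ) > 1e-12:
            raise ValueError(
                "planted_lag_curve must sum to planted_cumulative_logor in mode A"
            )

    @property
    def n_clusters(self) -> int:
        return self.n_countries * self.clusters_per_country

    @property
    def n_children(self) -> int:
        return self.n_clusters * self.children_per_cluster

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_lag_curve"] = [float(v) for v in self.planted_lag_curve]
        d["heatwave_definition"] = {
            "percentile": self.heatwave_definition.percentile,
            "min_duration": self.heatwave_definition.min_duration,
        }
        return d


@dataclass
class SyntheticCohort:
    climate: dict[str, DailySeries]
    records: pd.DataFrame
    truth: GeneratorConfig
    country_intercepts: pd.Series | None = None


def _cluster_ids(config: GeneratorConfig) -> list[tuple[str, str]]:
    out = []
    for c in range(config.n_countries):
        for k in range(config.clusters_per_country):
            out.append((f"C{c:02d}", f"C{c:02d}_K{k:02d}"))
    return out


def generate_climate(config: GeneratorConfig) -> dict[str, DailySeries]:
    """Seasonal AR(1) daily temperature series per cluster.

    T(d) = mean + A sin(2 pi (doy - phase)/365.25) + trend * years + e(d)
    with e(d) = ar1 * e(d-1) + N(0, noise_sd^2), initialised at the
    stationary distribution.  Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    dates = pd.date_range(config.date_range[0], config.date_range[1], freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    years_elapsed = (dates - dates[0]).days.to_numpy() / 365.25

    phi = config.ar1_coefficient
    stat_sd = config.noise_sd / np.sqrt(1.0 - phi**2) if config.noise_sd > 0 else 0.0

    out: dict[str, DailySeries] = {}
    for _country, cid in _cluster_ids(config):
        mean = rng.uniform(*config.mean_temp_range)
        phase = rng.uniform(0.0, 365.25)
        seasonal = config.seasonal_amplitude * np.sin(
            2.0 * np.pi * (doy - phase) / 365.25
        )
        trend = config.warming_trend * (years_elapsed / 10.0)
        if config.noise_sd > 0:
            innov = rng.normal(0.0, config.noise_sd, size=n)
            e0 = rng.normal(0.0, stat_sd)
            e = lfilter([1.0], [1.0, -phi], innov, zi=np.array([phi * e0]))[0]
        else:
            e = np.zeros(n)
        tmean = mean + seasonal + trend + e
        # dewpoint a few degrees below air temperature with mild noise;
        # precipitation as occasional exponential amounts
        tdew = tmean - rng.gamma(shape=4.0, scale=1.0, size=n)
        precip = rng.exponential(4.0, size=n) * (rng.random(n) < 0.3)
        out[cid] = DailySeries(cluster_id=cid, dates=dates, tmean=tmean,
                               tdew=tdew, precip=precip)
    return out


def _draw_covariates(rng, n, config: GeneratorConfig) -> pd.DataFrame:
    """Simple documented covariate distributions; enough to exercise adjustment."""
    education = rng.choice(["none", "primary", "secondary"], size=n)
    return pd.DataFrame({
        "sex": np.where(rng.random(n) < 0.5, "male", "female"),
        "age_months": rng.integers(6, 24, size=n),
        "laz": rng.normal(-1.0, 1.0, size=n),
        "maternal_age": np.clip(np.round(rng.normal(27.0, 6.0, size=n)), 15, 49),
        "education": education,
        "living_with_partner": (rng.random(n) < 0.8).astype(int),
        "wealth_quintile": rng.integers(1, 6, size=n),
        "urban": (rng.random(n) < 0.3).astype(int),
        "housing_usual": (rng.random(n) < 0.95).astype(int),
        "n_under5": 1 + rng.poisson(1.0, size=n),
        "refrigerator": (rng.random(n) < 0.3).astype(int),
        "air_conditioning": (rng.random(n) < 0.1).astype(int),
    })


def _linear_predictor_covariates(cov: pd.DataFrame, effects: dict) -> np.ndarray:
    """Planted covariate contribution, centred at documented references."""
    lp = np.zeros(len(cov))
    g = effects.get
    lp += g("female", 0.0) * (cov["sex"].to_numpy() == "female")
    lp += g("age_months", 0.0) * (cov["age_months"].to_numpy() - 6)
    lp += g("laz", 0.0) * cov["laz"].to_numpy()
    lp += g("maternal_age", 0.0) * (cov["maternal_age"].to_numpy() - 25.0)
    lp += g("education_primary", 0.0) * (cov["education"].to_numpy() == "primary")
    lp += g("education_secondary", 0.0) * (cov["education"].to_numpy() == "secondary")
    lp += g("urban", 0.0) * cov["urban"].to_numpy()
    lp += g("wealth_quintile", 0.0) * (cov["wealth_quintile"].to_numpy() - 1)
    return lp


def _frame_skeleton(config: GeneratorConfig, rng) -> pd.DataFrame:
    pairs = _cluster_ids(config)
    country = np.repeat([p[0] for p in pairs], config.children_per_cluster)
    cluster = np.repeat([p[1] for p in pairs], config.children_per_cluster)
    n = len(cluster)
    lo, hi = (pd.Timestamp(d) for d in config.interview_range)
    clim_start = pd.Timestamp(config.date_range[0])
    if (lo - clim_start).days < 21:
        raise ValueError("interview_range must leave >= 21 days of prior climate")
    offsets = rng.integers(0, (hi - lo).days + 1, size=n)
    dates = lo + pd.to_timedelta(offsets, unit="D")
    df = pd.DataFrame({
        "record_id": [f"R{i:06d}" for i in range(n)],
        "country_id": country,
        "cluster_id": cluster,
        "interview_date": dates,
    })
    df["year"] = df["interview_date"].dt.year
    df["month"] = df["interview_date"].dt.month
    return df


def _exposure_matrix(config: GeneratorConfig, climate, records) -> np.ndarray:
    definition = config.heatwave_definition
    calendars = {}
    for cid, series in climate.items():
        thr = compute_threshold(series, definition.percentile)
        calendars[cid] = detect_heatwaves(series, definition, thr)
    lag = build_lag_matrix(records, calendars, max_lag=14)
    if len(lag) != len(records):
        raise ValueError("synthetic records lack climate coverage (generator bug)")
    return lag.to_numpy(dtype=float)


def generate_records(config: GeneratorConfig,
                     climate: dict[str, DailySeries]) -> SyntheticCohort:
    """Dispatch to the configured generation mode."""
    if config.mode == "A":
        return generate_records_mode_a(config, climate)
    return generate_records_mode_b(config, climate)


def generate_records_mode_a(config: GeneratorConfig,
                            climate: dict[str, DailySeries]) -> SyntheticCohort:
    """Direct-outcome cohort: Bernoulli outcome from the planted logistic model."""
    if config.mode != "A":
        raise ValueError("config.mode must be 'A'")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    records = _frame_skeleton(config, rng)
    cov = _draw_covariates(rng, len(records), config)
    records = pd.concat([records, cov], axis=1)

    u = rng.normal(0.0, config.country_intercept_sd, size=config.n_countries)
    countries = sorted(records["country_id"].unique())
    u_by_country = pd.Series(u[: len(countries)], index=countries)

    h = _exposure_matrix(config, climate, records)
    lp = (
        config.baseline_logit
        + _linear_predictor_covariates(cov, config.covariate_effects)
        + u_by_country[records["country_id"]].to_numpy()
        + h @ config.planted_lag_curve
    )
    records["not_meeting"] = rng.binomial(1, expit(lp))
    records["is_breastfed"] = (rng.random(len(records)) < 0.7).astype(int)
    return SyntheticCohort(climate=climate, records=records, truth=config,
                           country_intercepts=u_by_country)


def generate_records_mode_b(config: GeneratorConfig,
                            climate: dict[str, DailySeries]) -> SyntheticCohort:
    """Recall-item cohort: food groups, feed counts and breastfeeding drawn
    with group-specific base rates and lag-distributed heat sensitivities."""
    if config.mode != "B":
        raise ValueError("config.mode must be 'B'")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    records = _frame_skeleton(config, rng)
    cov = _draw_covariates(rng, len(records), config)
    records = pd.concat([records, cov], axis=1)
    n = len(records)

    h = _exposure_matrix(config, climate, records)
    # shared lag-weight shape, normalised to sum 1; per-group cumulative
    # sensitivity scales it
    shape = config.planted_lag_curve / config.planted_lag_curve.sum()
    expo = h @ shape  # in [0, 1] roughly; 1 under sustained exposure

    age = records["age_months"].to_numpy()
    bf_logit = (config.breastfed_logit_intercept
                + config.breastfed_logit_age_slope * (age - 6))
    s_bf = config.heat_sensitivity.get("breastfeeding", 0.0)
    is_bf = rng.random(n) < expit(bf_logit - s_bf * expo)
    records["is_breastfed"] = is_bf.astype(int)
    records["fg_breastmilk"] = is_bf.astype(int)

    for grp, base in config.base_rates.items():
        s = config.heat_sensitivity.get(grp, 0.0)
        p_not = expit(logit(1.0 - base) + s * expo)
        records[grp] = (rng.random(n) >= p_not).astype(int)

    log_mu = np.log(config.meal_count_mean) + config.meal_count_heat_shift * expo
    records["meal_count"] = rng.poisson(np.exp(log_mu))
    milk_mu = np.where(is_bf, config.milk_feed_mean_bf, config.milk_feed_mean_nonbf)
    records["milk_feed_count"] = rng.poisson(milk_mu)
    return SyntheticCohort(climate=climate, records=records, truth=config)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Climate plus records in one call."""
    return generate_records(config, generate_climate(config))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_climate_csv(climate: dict[str, DailySeries], path) -> None:
    """Long-format climate CSV: cluster_id, date (ISO-8601), tmean_c[, ...]."""
    frames = []
    for cid, s in climate.items():
        d = {"cluster_id": cid, "date": s.dates.strftime("%Y-%m-%d"),
             "tmean_c": s.tmean}
        if s.tdew is not None:
            d["tdew_c"] = s.tdew
        if s.precip is not None:
            d["precip_mm"] = s.precip
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.4f")


def write_records_csv(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["interview_date"] = pd.to_datetime(out["interview_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_config_yaml(config: GeneratorConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
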