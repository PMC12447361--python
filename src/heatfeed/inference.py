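"""Cumulative and lag-specific odds ratios, stratum comparisons, sensitivity suite.

The cumulative effect is the summed lag-specific log-odds contribution over
the whole lag window — the contrast between sustained heatwave exposure on
all 15 lag days and no exposure.  Standard errors come from the delta method
(a linear contrast c'beta has variance c'Vc); 95% CIs use the normal
multiplier 1.959964.  Between-stratum effect modification is tested with a
multivariate Wald statistic on the cross-basis coefficient difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .basis import BasisMatrix

logger = logging.getLogger(__name__)

Z95 = 1.959964


@dataclass(frozen=True)
class CumulativeEffect:
    log_or: float
    se: float
    outcome: str = ""
    definition: str = ""

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.log_or))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.log_or - Z95 * self.se)),
            float(np.exp(self.log_or + Z95 * self.se)),
        )


@dataclass
class LagCurve:
    lags: np.ndarray
    log_or: np.ndarray
    se: np.ndarray

    @property
    def odds_ratio(self) -> np.ndarray:
        return np.exp(self.log_or)

    @property
    def ci95_low(self) -> np.ndarray:
        return np.exp(self.log_or - Z95 * self.se)

    @property
    def ci95_high(self) -> np.ndarray:
        return np.exp(self.log_or + Z95 * self.se)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag": self.lags, "log_or": self.log_or, "se": self.se,
             "or": self.odds_ratio, "ci_low": self.ci95_low,
             "ci_high": self.ci95_high}
        )


@dataclass
class StrataComparison:
    labels: tuple
    effects: tuple  # per-stratum CumulativeEffect
    wald_stat: float
    df: int
    p_value: float
    z_cumulative: float
    p_cumulative: float


def _crossbasis_blocks(fit, basis: BasisMatrix):
    beta = fit.beta_crossbasis
    vcov = fit.vcov_crossbasis
    if beta.shape[0] != basis.df or vcov.shape != (basis.df, basis.df):
        raise ValueError("cross-basis coefficient block does not match basis df")
    if not np.all(np.isfinite(vcov)):
        raise ValueError("missing/invalid covariance block for cross-basis")
    return beta, vcov


def cumulative_or(fit, basis: BasisMatrix, outcome: str = "",
                  definition: str = "") -> CumulativeEffect:
    """Cumulative (all-lag) odds ratio with delta-method 95% CI.

    The contrast vector is the column sum of the basis over lags 0..max_lag,
    i.e. exposure on every day of the lag window versus none.
    """
    beta, vcov = _crossbasis_blocks(fit, basis)
    c = basis.cumulative_contrast()
    log_or = float(c @ beta)
    se = float(np.sqrt(c @ vcov @ c))
    return CumulativeEffect(
        log_or=log_or, se=se,
        outcome=outcome or getattr(fit, "outcome", ""),
        definition=definition,
    )


def lag_curve(fit, basis: BasisMatrix) -> LagCurve:
    """Per-lag log-OR, SE and CI: contrast rows of the basis matrix."""
    beta, vcov = _crossbasis_blocks(fit, basis)
    log_or = basis.b @ beta
    se = np.sqrt(np.einsum("kj,jl,kl->k", basis.b, vcov, basis.b))
    return LagCurve(lags=np.arange(basis.b.shape[0]), log_or=log_or, se=se)


def wald_compare(fit_a, fit_b, basis: BasisMatrix,
                 labels: tuple = ("a", "b")) -> StrataComparison:
    """Multivariate Wald test for effect modification between two strata.

    The strata are fitted independently (disjoint samples, same basis), so
    the covariance of the coefficient difference is the sum of the two
    blocks.  Also reports the scalar z-test on the cumulative log-ORs.
    """
    ba, va = _crossbasis_blocks(fit_a, basis)
    bb, vb = _crossbasis_blocks(fit_b, basis)
    d = ba - bb
    pooled = va + vb
    df = len(d)
    try:
        w = float(d @ np.linalg.solve(pooled, d))
    except np.linalg.LinAlgError:
        logger.warning("wald_compare: singular pooled covariance, using pseudo-inverse")
        pinv = np.linalg.pinv(pooled)
        w = float(d @ pinv @ d)
        df = int(np.linalg.matrix_rank(pooled))
    w = max(w, 0.0)
    p = float(stats.chi2.sf(w, df))

    ea = cumulative_or(fit_a, basis)
    eb = cumulative_or(fit_b, basis)
    z = (ea.log_or - eb.log_or) / np.sqrt(ea.se**2 + eb.se**2)
    return StrataComparison(
        labels=labels, effects=(ea, eb), wald_stat=w, df=df, p_value=p,
        z_cumulative=float(z), p_cumulative=float(2 * stats.norm.sf(abs(z))),
    )


def stratified_effects(fits_by_level: dict, basis: BasisMatrix) -> pd.DataFrame:
    """Forest-plot-ready table of cumulative ORs per stratum level."""
    rows = []
    for level, fit in fits_by_level.items():
        e = cumulative_or(fit, basis)
        lo, hi = e.ci95
        rows.append({"stratum": level, "or": e.odds_ratio, "ci_low": lo,
                     "ci_high": hi, "log_or": e.log_or, "se": e.se,
                     "n": fit.n_used})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sensitivity suite
# ---------------------------------------------------------------------------

def sensitivity_suite(records, series_by_cluster, base_spec, indicators=None,
                      variants: list[str] | None = None) -> pd.DataFrame:
    """Re-run the primary model under the prespecified robustness variants.

    Variants: "identity" (no change), "precip_24m" (add 24-month cumulative
    precipitation), "drop_<covariate>" for each adjustable covariate,
    "lag20" (extend the lag window to 20 days), "lag_df5" (one more spline
    df), "humidity" (add recall-day relative humidity).  Failures are
    recorded and the suite continues.
    """
    from .pipeline import run_analysis  # local import to avoid a cycle

    if variants is None:
        variants = ["identity", "precip_24m"]
        variants += [f"drop_{c}" for c in base_spec.covariates
                     if c not in ("year", "month")]
        variants += ["drop_year_month", "lag20", "lag_df5", "humidity"]

    rows = []
    for name in variants:
        try:
            spec, extra = _variant_spec(name, base_spec, records, series_by_cluster)
            result = run_analysis(records, series_by_cluster, spec,
                                  indicators=indicators, extra_covariates=extra)
            eff = cumulative_or(result.fit, result.basis,
                                definition=spec.definition.label)
            lo, hi = eff.ci95
            rows.append({"variant": name, "or": eff.odds_ratio, "ci_low": lo,
                         "ci_high": hi, "log_or": eff.log_or, "se": eff.se,
                         "n": result.fit.n_used, "status": "ok"})
        except Exception as exc:
            logger.warning("sensitivity variant %s failed: %s", name, exc)
            rows.append({"variant": name, "or": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "log_or": np.nan, "se": np.nan,
                         "n": 0, "status": f"failed: {exc}"})
    return pd.DataFrame(rows)


def _variant_spec(name, base_spec, records, series_by_cluster):
    from dataclasses import replace

    from .basis import LagBasisSpec

    if name == "identity":
        return base_spec, None
    if name == "precip_24m":
        return base_spec, cumulative_precipitation(records, series_by_cluster,
                                                   months=24)
    if name.startswith("drop_"):
        target = name[5:]
        drop = ("year", "month") if target == "year_month" else (target,)
        missing = [c for c in drop if c not in base_spec.covariates]
        if missing:
            raise ValueError(f"cannot drop absent covariate(s) {missing}")
        covs = tuple(c for c in base_spec.covariates if c not in drop)
        return replace(base_spec, covariates=covs), None
    if name == "lag20":
        ls = base_spec.lag_spec
        return replace(base_spec, lag_spec=LagBasisSpec(
            max_lag=20, df=ls.df,
            include_intercept_column=ls.include_intercept_column)), None
    if name == "lag_df5":
        ls = base_spec.lag_spec
        return replace(base_spec, lag_spec=LagBasisSpec(
            max_lag=ls.max_lag, df=ls.df + 1,
            include_intercept_column=ls.include_intercept_column)), None
    if name == "humidity":
        return base_spec, recall_day_relative_humidity(records, series_by_cluster)
    raise ValueError(f"unknown sensitivity variant {name!r}")


def cumulative_precipitation(records, series_by_cluster, months: int = 24) -> pd.DataFrame:
    """Total precipitation over the ``months``*30.44 days before interview."""
    window = int(round(months * 30.44))
    out = np.full(len(records), np.nan)
    dates = pd.to_datetime(records["interview_date"])
    for pos, (cid, date) in enumerate(zip(records["cluster_id"], dates)):
        s = series_by_cluster.get(cid)
        if s is None or s.precip is None:
            continue
        i0 = s.day_index(date)
        if i0 - window >= 0 and i0 - 1 < len(s):
            out[pos] = s.precip[i0 - window:i0].sum()
    idx = records["record_id"] if "record_id" in records else records.index
    return pd.DataFrame({f"precip_{months}m": out}, index=pd.Index(idx))


def recall_day_relative_humidity(records, series_by_cluster) -> pd.DataFrame:
    """Relative humidity on the recall day (interview date minus one)."""
    from .climate import relative_humidity

    out = np.full(len(records), np.nan)
    dates = pd.to_datetime(records["interview_date"])
    for pos, (cid, date) in enumerate(zip(records["cluster_id"], dates)):
        s = series_by_cluster.get(cid)
        if s is None or s.tdew is None:
            continue
        i = s.day_index(date) - 1
        if 0 <= i < len(s):
            out[pos] = relative_humidity(s.tmean[i], s.tdew[i])
    idx = records["record_id"] if "record_id" in records else records.index
    return pd.DataFrame({"rh_recall_day": out}, index=pd.Index(idx))
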