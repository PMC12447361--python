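"""End-to-end orchestration: exposure -> indicators -> basis -> fit -> inference.

``run_analysis`` is the library-level entry point used by tests, the
sensitivity suite and the CLI; ``run_pipeline`` adds on-disk artefacts and a
provenance manifest (input hashes, config echo, versions) for reproducible
shell runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .basis import BasisMatrix, cross_basis, natural_cubic_basis
from .climate import (
    DailySeries,
    HeatwaveCalendar,
    annual_mean_for_records,
    build_lag_matrix,
    compute_threshold,
    detect_heatwaves,
    read_climate_csv,
    write_calendar_csv,
)
from .indicators import classify_frame, descriptive_table
from .inference import cumulative_or, lag_curve, sensitivity_suite, wald_compare
from .model import FitResult, ModelSpec, build_design, fit_random_intercept_logit

logger = logging.getLogger(__name__)

#: Default stratification factors (column, split rule) for effect modification.
DEFAULT_STRATA = (
    ("urban", "binary"),
    ("wealth_quintile", "le2"),       # low (quintile <= 2) vs higher wealth
    ("n_under5", "gt3"),              # more than three under-5s vs not
    ("refrigerator", "binary"),
    ("air_conditioning", "binary"),
    ("maternal_age", "lt20_20_35_gt35"),
    ("education", "levels"),
    ("living_with_partner", "binary"),
    ("housing_usual", "binary"),
)


@dataclass
class AnalysisResult:
    fit: FitResult
    basis: BasisMatrix
    calendars: dict[str, HeatwaveCalendar]
    crossbasis: pd.DataFrame
    indicators: pd.DataFrame | None = None
    lag_exposure: pd.DataFrame | None = field(default=None, repr=False)


def compute_calendars(series_by_cluster: dict[str, DailySeries], definition,
                      climatology=None) -> dict[str, HeatwaveCalendar]:
    out = {}
    for cid, series in series_by_cluster.items():
        thr = compute_threshold(series, definition.percentile, climatology)
        out[cid] = detect_heatwaves(series, definition, thr)
    return out


def run_analysis(
    records: pd.DataFrame,
    series_by_cluster: dict[str, DailySeries],
    spec: ModelSpec,
    indicators: pd.DataFrame | None = None,
    extra_covariates: pd.DataFrame | None = None,
) -> AnalysisResult:
    """Run the full modelling chain for one outcome and one heatwave definition."""
    calendars = compute_calendars(series_by_cluster, spec.definition)
    max_lag = spec.lag_spec.max_lag
    lag = build_lag_matrix(records, calendars, max_lag=max_lag)
    kept = records[records["record_id"].isin(lag.index)].copy() \
        if "record_id" in records else records.loc[lag.index].copy()

    basis = natural_cubic_basis(spec.lag_spec)
    z = cross_basis(basis, lag.to_numpy())
    zdf = pd.DataFrame(z, index=lag.index,
                       columns=[f"cb{j}" for j in range(z.shape[1])])

    if "annual_mean_temp" in spec.covariates and "annual_mean_temp" not in kept:
        kept["annual_mean_temp"] = annual_mean_for_records(
            kept, series_by_cluster
        ).to_numpy()

    if indicators is None and spec.outcome.startswith("not_") and \
            spec.outcome[4:] in ("mdd", "mmf", "mad"):
        indicators = classify_frame(kept)

    design = build_design(kept, indicators, zdf, spec,
                          extra_covariates=extra_covariates)
    fit = fit_random_intercept_logit(design, spec)
    return AnalysisResult(fit=fit, basis=basis, calendars=calendars,
                          crossbasis=zdf, indicators=indicators,
                          lag_exposure=lag)


def stratified_analysis(records, series_by_cluster, spec, strata=DEFAULT_STRATA):
    """Independent per-stratum fits plus Wald effect-modification tests."""
    results = []
    for column, rule in strata:
        if column not in records:
            continue
        masks = _stratum_masks(records, column, rule)
        fits = {}
        basis = None
        for label, mask in masks.items():
            sub = records.loc[mask]
            if len(sub) == 0:
                continue
            try:
                res = run_analysis(sub, series_by_cluster, spec)
            except Exception as exc:
                logger.warning("stratum %s=%s failed: %s", column, label, exc)
                continue
            fits[label] = res.fit
            basis = res.basis
        if len(fits) == 2 and basis is not None:
            (la, fa), (lb, fb) = fits.items()
            comp = wald_compare(fa, fb, basis, labels=(la, lb))
            for lab, eff in zip(comp.labels, comp.effects):
                lo, hi = eff.ci95
                results.append({
                    "factor": column, "stratum": lab, "or": eff.odds_ratio,
                    "ci_low": lo, "ci_high": hi, "wald_stat": comp.wald_stat,
                    "wald_df": comp.df, "p_value": comp.p_value,
                })
    return pd.DataFrame(results)


def _stratum_masks(records, column, rule):
    col = records[column]
    if rule == "binary":
        b = col.astype(bool)
        return {"yes": b.to_numpy(), "no": (~b).to_numpy()}
    if rule == "le2":
        return {"low": (col <= 2).to_numpy(), "high": (col > 2).to_numpy()}
    if rule == "gt3":
        return {"gt3": (col > 3).to_numpy(), "le3": (col <= 3).to_numpy()}
    if rule == "lt20_20_35_gt35":
        return {"20-35": ((col >= 20) & (col <= 35)).to_numpy(),
                "other": ((col < 20) | (col > 35)).to_numpy()}
    if rule == "levels":
        levels = sorted(col.unique())
        return {str(l): (col == l).to_numpy() for l in levels}
    raise ValueError(f"unknown stratum rule {rule!r}")


# ---------------------------------------------------------------------------
# On-disk pipeline with manifest
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a reproducible shell run (YAML-loadable)."""

    climate_path: str
    records_path: str
    output_dir: str
    outcome: str = "not_mdd"
    percentile: float = 95.0
    min_duration: int = 2
    max_lag: int = 14
    lag_df: int = 4
    random_intercept: str = "country"
    run_strata: bool = False
    run_sensitivity: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def model_spec(self) -> ModelSpec:
        from .basis import LagBasisSpec
        from .climate import HeatwaveDefinition

        return ModelSpec(
            outcome=self.outcome,
            random_intercept=self.random_intercept,
            definition=HeatwaveDefinition(self.percentile, self.min_duration),
            lag_spec=LagBasisSpec(max_lag=self.max_lag, df=self.lag_df),
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, writing artefacts and a provenance manifest.

    Stage failure retains partial artefacts; the manifest records the failure
    point.  Reruns with identical config and inputs are bit-identical for the
    deterministic stages.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "inputs": {
            "climate": _sha256(config.climate_path),
            "records": _sha256(config.records_path),
        },
        "config": dict(config.__dict__),
        "versions": {"heatfeed": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": {},
    }

    def _finish(status: str):
        manifest["status"] = status
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest

    try:
        series = read_climate_csv(config.climate_path)
        records = pd.read_csv(config.records_path, parse_dates=["interview_date"])
        if "year" not in records:
            records["year"] = records["interview_date"].dt.year
        if "month" not in records:
            records["month"] = records["interview_date"].dt.month
        manifest["stages"]["load"] = "ok"

        spec = config.model_spec()
        calendars = compute_calendars(series, spec.definition)
        write_calendar_csv(calendars, out / "heatwave_calendar.csv")
        manifest["stages"]["exposure"] = "ok"

        from .indicators import FOOD_GROUP_COLUMNS

        indicators = None
        if all(c in records for c in FOOD_GROUP_COLUMNS):
            indicators = classify_frame(records)
            indicators.astype(int).to_csv(out / "indicators.csv")
            descriptive_table(records, indicators).to_csv(
                out / "descriptive_table.csv", index=False
            )
        manifest["stages"]["indicators"] = "ok"

        result = run_analysis(records, series, spec, indicators=indicators)
        result.lag_exposure.to_csv(out / "lag_exposure.csv")
        result.fit.to_json(out / "fit.json")
        manifest["stages"]["fit"] = "ok"

        eff = cumulative_or(result.fit, result.basis,
                            definition=spec.definition.label)
        lo, hi = eff.ci95
        pd.DataFrame([{
            "outcome": spec.outcome, "definition": spec.definition.label,
            "stratum": "all", "or": eff.odds_ratio, "ci_low": lo, "ci_high": hi,
            "p": float(2 * stats.norm.sf(abs(eff.log_or / eff.se)))
            if eff.se > 0 else float("nan"),
        }]).to_csv(out / "effects.csv", index=False)
        lag_curve(result.fit, result.basis).to_frame().to_csv(
            out / "lag_curve.csv", index=False
        )
        manifest["stages"]["effects"] = "ok"

        if config.run_strata:
            stratified_analysis(records, series, spec).to_csv(
                out / "stratified_effects.csv", index=False
            )
            manifest["stages"]["strata"] = "ok"
        if config.run_sensitivity:
            sensitivity_suite(records, series, spec, indicators=indicators).to_csv(
                out / "sensitivity.csv", index=False
            )
            manifest["stages"]["sensitivity"] = "ok"
    except Exception as exc:
        stage = next((s for s in ("load", "exposure", "indicators", "fit",
                                  "effects", "strata", "sensitivity")
                      if s not in manifest["stages"]), "unknown")
        manifest["stages"][stage] = f"failed: {exc}"
        _finish("failed")
        raise
    return _finish("ok")
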