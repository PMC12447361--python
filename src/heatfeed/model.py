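"""Design-matrix assembly and random-intercept logistic regression.

The outcome is coded 1 when the child did NOT meet the feeding standard (or
did not consume a food group), so coefficients are log-odds of inadequate
feeding.  Fixed effects: child covariates (sex, age in months, length-for-age
Z), maternal covariates (age, education), residence, household wealth,
categorical survey year and month, the cluster's annual mean temperature
over the preceding 12 months, and the distributed-lag cross-basis columns.
A Gaussian random intercept per country absorbs unobserved between-country
heterogeneity.

Estimation maximises the Laplace-approximated marginal likelihood: for a
candidate intercept standard deviation the joint penalised log-likelihood is
maximised over (beta, u) by penalised iteratively reweighted least squares,
and the profile criterion over log(sd) is optimised by bounded scalar
search.  With fewer than ``min_groups`` countries (default 5), or when
configured, the model falls back to plain logistic regression with fixed
country dummies, fitted through statsmodels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import expit

from .basis import BasisMatrix, LagBasisSpec
from .climate import HeatwaveDefinition

logger = logging.getLogger(__name__)

#: Default covariate set of the main model (column names in the records frame).
DEFAULT_COVARIATES = (
    "sex", "age_months", "laz", "maternal_age", "education",
    "urban", "wealth_quintile", "year", "month", "annual_mean_temp",
)

#: Columns treated as unordered categoricals (dummy-coded, first level reference).
CATEGORICAL_COVARIATES = ("sex", "education", "wealth_quintile", "year", "month")


class SeparationError(RuntimeError):
    """Raised when quasi-complete separation makes a coefficient diverge."""


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what."""

    outcome: str = "not_mdd"
    covariates: tuple = DEFAULT_COVARIATES
    random_intercept: str = "country"  # "country" | "region" | "none"
    definition: HeatwaveDefinition = HeatwaveDefinition(95.0, 2)
    lag_spec: LagBasisSpec = LagBasisSpec()
    min_groups: int = 5

    def __post_init__(self) -> None:
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("duplicated covariates in ModelSpec")
        if self.random_intercept not in ("country", "region", "none"):
            raise ValueError(f"unknown random_intercept {self.random_intercept!r}")


@dataclass
class DesignMatrix:
    y: np.ndarray  # 1 = NOT meeting the standard
    X: pd.DataFrame  # fixed-effect columns, cross-basis columns last
    group: np.ndarray  # integer codes of the grouping factor
    group_labels: list
    crossbasis_cols: list
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)


@dataclass
class FitResult:
    beta: pd.Series
    vcov: pd.DataFrame
    crossbasis_cols: list
    random_intercept_sd: float
    converged: bool
    n_used: int
    loglik: float
    method: str  # "laplace" | "fixed_dummies" | "plain"
    n_dropped: int = 0
    outcome: str = ""
    random_effects: pd.Series | None = field(default=None, repr=False)

    @property
    def beta_crossbasis(self) -> np.ndarray:
        return self.beta[self.crossbasis_cols].to_numpy()

    @property
    def vcov_crossbasis(self) -> np.ndarray:
        return self.vcov.loc[self.crossbasis_cols, self.crossbasis_cols].to_numpy()

    def to_json(self, path) -> None:
        payload = {
            "beta": self.beta.to_dict(),
            "vcov": {"columns": list(self.vcov.columns),
                     "values": self.vcov.to_numpy().tolist()},
            "crossbasis_cols": self.crossbasis_cols,
            "random_intercept_sd": self.random_intercept_sd,
            "converged": self.converged,
            "n_used": self.n_used,
            "loglik": self.loglik,
            "method": self.method,
            "n_dropped": self.n_dropped,
            "outcome": self.outcome,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            d = json.load(fh)
        cols = d["vcov"]["columns"]
        return cls(
            beta=pd.Series(d["beta"]),
            vcov=pd.DataFrame(np.asarray(d["vcov"]["values"]), index=cols, columns=cols),
            crossbasis_cols=d["crossbasis_cols"],
            random_intercept_sd=d["random_intercept_sd"],
            converged=d["converged"],
            n_used=d["n_used"],
            loglik=d["loglik"],
            method=d["method"],
            n_dropped=d.get("n_dropped", 0),
            outcome=d.get("outcome", ""),
        )


# ---------------------------------------------------------------------------
# Design assembly
# ---------------------------------------------------------------------------

def _outcome_vector(spec: ModelSpec, records: pd.DataFrame,
                    indicators: pd.DataFrame | None) -> pd.Series:
    """y = 1 iff the standard was NOT met / the food group was NOT consumed."""
    name = spec.outcome
    if name.startswith("not_") and name[4:] in ("mdd", "mmf", "mad"):
        if indicators is None:
            raise ValueError(f"outcome {name} needs classified indicators")
        met = indicators[name[4:]]
        return (~met.astype(bool)).astype(float)
    if name.startswith("not_fg_"):
        col = name[4:]
        if col not in records:
            raise ValueError(f"food-group column {col} missing from records")
        s = records.set_index("record_id")[col] if "record_id" in records else records[col]
        return (~s.astype(bool)).astype(float)
    if name == "not_meeting":  # direct-outcome synthetic mode
        s = records.set_index("record_id")["not_meeting"] if "record_id" in records \
            else records["not_meeting"]
        return s.astype(float)
    raise ValueError(f"unknown outcome {name!r}")


def build_design(
    records: pd.DataFrame,
    indicators: pd.DataFrame | None,
    crossbasis: pd.DataFrame,
    spec: ModelSpec,
    extra_covariates: pd.DataFrame | None = None,
) -> DesignMatrix:
    """Assemble y, X and the grouping factor for one model.

    Complete cases only: records with a missing covariate, outcome or
    cross-basis row are dropped and the count logged.  Categorical
    covariates are dummy-coded against their first (sorted) level; the
    cross-basis columns are appended last and tagged.
    """
    rec = records.set_index("record_id") if "record_id" in records else records.copy()
    y = _outcome_vector(spec, records, indicators)
    y.index = rec.index if y.index.name is None else y.index

    for cov in spec.covariates:
        if cov not in rec:
            raise ValueError(f"covariate {cov!r} missing from records")
    categorical = [c for c in spec.covariates
                   if c in CATEGORICAL_COVARIATES or rec[c].dtype == object]
    numeric = [c for c in spec.covariates if c not in categorical]

    # complete cases first: dummy coding uses the levels present in the
    # analysed sample, so no reference level can silently vanish
    raw = rec[list(spec.covariates)]
    keep = raw.notna().all(axis=1) & y.notna() & \
        crossbasis.reindex(rec.index).notna().all(axis=1).to_numpy()
    if extra_covariates is not None:
        keep &= extra_covariates.reindex(rec.index).notna().all(axis=1).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("build_design: dropped %d incomplete record(s)", n_dropped)
    rec, y = rec.loc[keep], y.loc[keep]

    parts = [pd.Series(1.0, index=rec.index, name="intercept")]
    for cov in spec.covariates:
        col = rec[cov]
        if cov in categorical:
            levels = sorted(pd.unique(col))
            dummies = pd.get_dummies(
                pd.Categorical(col, categories=levels), prefix=cov, dtype=float
            ).iloc[:, 1:]  # first (sorted) level is the reference
            dummies.index = rec.index
            parts.append(dummies)
        else:
            parts.append(col.astype(float))
    if extra_covariates is not None:
        parts.append(extra_covariates.reindex(rec.index).astype(float))

    cb = crossbasis.reindex(rec.index)
    cb_cols = [f"cb{j}" for j in range(cb.shape[1])]
    cb.columns = cb_cols
    parts.append(cb)
    X = pd.concat(parts, axis=1)

    if spec.random_intercept == "none":
        group = np.zeros(len(X), dtype=int)
        labels = ["all"]
    else:
        col = "country_id" if spec.random_intercept == "country" else "region"
        codes, uniques = pd.factorize(rec.loc[keep, col], sort=True)
        group, labels = codes, list(uniques)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"design matrix rank deficient; offending columns: {bad}")

    return DesignMatrix(
        y=y.to_numpy(), X=X, group=group, group_labels=labels,
        crossbasis_cols=cb_cols, n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically safe sum(y*eta - log(1+exp(eta)))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _pirls(X, y, group, n_groups, sigma2, beta, u, max_iter=100, tol=1e-9):
    """Joint penalised Newton (IRLS) for (beta, u) at fixed intercept variance."""
    p = X.shape[1]

    def pen_ll(beta, u):
        eta = X @ beta + u[group]
        return _bernoulli_loglik(y, eta) - 0.5 * np.sum(u**2) / sigma2

    current = pen_ll(beta, u)
    for _ in range(max_iter):
        eta = X @ beta + u[group]
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        r = y - mu
        g_beta = X.T @ r
        g_u = np.bincount(group, weights=r, minlength=n_groups) - u / sigma2
        Xw = X * w[:, None]
        A = Xw.T @ X
        ZtWX = np.zeros((n_groups, p))
        np.add.at(ZtWX, group, Xw)
        d = np.bincount(group, weights=w, minlength=n_groups) + 1.0 / sigma2
        # Schur-complement solve of the blocked Newton system
        S = A - ZtWX.T @ (ZtWX / d[:, None])
        rhs = g_beta - ZtWX.T @ (g_u / d)
        try:
            db = np.linalg.solve(S, rhs)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular Newton system: {exc}") from exc
        du = (g_u - ZtWX @ db) / d
        step = 1.0
        for _half in range(30):
            cand = pen_ll(beta + step * db, u + step * du)
            if cand >= current - 1e-12:
                break
            step *= 0.5
        beta = beta + step * db
        u = u + step * du
        if abs(cand - current) < tol * (abs(current) + 1.0):
            current = cand
            break
        current = cand
    w_raw = np.clip(expit(X @ beta + u[group]) * (1 - expit(X @ beta + u[group])),
                    1e-10, None)
    d_raw = np.bincount(group, weights=w_raw, minlength=n_groups)
    return beta, u, current, d_raw


def _laplace_fit(X, y, group, n_groups, colnames):
    """Profile the Laplace marginal likelihood over log(sd)."""
    p = X.shape[1]
    state = {"beta": np.zeros(p), "u": np.zeros(n_groups)}

    def neg_marginal(log_sd):
        sigma2 = float(np.exp(2.0 * log_sd))
        beta, u, pll, d_raw = _pirls(
            X, y, group, n_groups, sigma2, state["beta"].copy(), state["u"].copy()
        )
        state["beta"], state["u"] = beta, u
        ll = pll - 0.5 * np.sum(np.log1p(sigma2 * d_raw))
        return -ll

    res = minimize_scalar(
        neg_marginal, bounds=(np.log(1e-3), np.log(5.0)), method="bounded",
        options={"xatol": 1e-3},
    )
    log_sd = float(res.x)
    sigma2 = float(np.exp(2.0 * log_sd))
    beta, u, pll, d_raw = _pirls(
        X, y, group, n_groups, sigma2, state["beta"], state["u"],
    )
    if np.any(np.abs(beta) > 15.0):
        bad = [colnames[j] for j in np.flatnonzero(np.abs(beta) > 15.0)]
        raise SeparationError(
            f"coefficient(s) diverging (|beta| > 15): {bad}; "
            "likely quasi-complete separation"
        )
    # beta block of the inverse joint penalised Hessian
    eta = X @ beta + u[group]
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    Xw = X * w[:, None]
    A = Xw.T @ X
    ZtWX = np.zeros((n_groups, p))
    np.add.at(ZtWX, group, Xw)
    d = np.bincount(group, weights=w, minlength=n_groups) + 1.0 / sigma2
    S = A - ZtWX.T @ (ZtWX / d[:, None])
    vcov = np.linalg.inv(S)
    ll = pll - 0.5 * np.sum(np.log1p(sigma2 * d_raw))
    return beta, vcov, float(np.exp(log_sd)), ll, u, bool(res.success)


def fit_random_intercept_logit(design: DesignMatrix, spec: ModelSpec | None = None,
                               force_method: str | None = None) -> FitResult:
    """Fit the mixed-effects (random-intercept) logistic regression.

    Deterministic: fixed zero starting values and a bounded deterministic
    scalar search over log(sd).  Falls back to fixed country dummies when
    there are fewer than ``spec.min_groups`` groups (recorded in
    ``FitResult.method``).
    """
    spec = spec or ModelSpec()
    X = design.X.to_numpy(dtype=float)
    cols = list(design.X.columns)
    y = design.y.astype(float)

    use_random = (
        force_method == "laplace"
        or (force_method is None
            and spec.random_intercept != "none"
            and design.n_groups >= spec.min_groups)
    )
    if use_random:
        beta, vcov, sd, ll, u, ok = _laplace_fit(
            X, y, design.group, design.n_groups, cols
        )
        return FitResult(
            beta=pd.Series(beta, index=cols),
            vcov=pd.DataFrame(vcov, index=cols, columns=cols),
            crossbasis_cols=design.crossbasis_cols,
            random_intercept_sd=sd, converged=ok, n_used=design.n,
            loglik=ll, method="laplace", n_dropped=design.n_dropped,
            outcome=spec.outcome,
            random_effects=pd.Series(u, index=design.group_labels),
        )

    # fixed-dummies fallback (or no grouping): plain logistic via statsmodels
    Xf = design.X.copy()
    method = "plain"
    if spec.random_intercept != "none" and design.n_groups > 1:
        method = "fixed_dummies"
        if design.n_groups >= spec.min_groups:
            logger.info("fit: fixed-dummy fallback forced with %d groups",
                        design.n_groups)
        dummies = pd.get_dummies(
            pd.Categorical(design.group), prefix="group", dtype=float
        ).iloc[:, 1:]
        dummies.index = Xf.index
        Xf = pd.concat([Xf, dummies], axis=1)
    model = sm.GLM(y, Xf.to_numpy(dtype=float), family=sm.families.Binomial())
    try:
        fit = model.fit(maxiter=200, tol=1e-10)
    except Exception as exc:  # pragma: no cover - defensive
        raise SeparationError(f"plain logistic fit failed: {exc}") from exc
    beta = np.asarray(fit.params)
    if np.any(np.abs(beta) > 15.0):
        bad = [Xf.columns[j] for j in np.flatnonzero(np.abs(beta) > 15.0)]
        raise SeparationError(
            f"coefficient(s) diverging (|beta| > 15): {bad}; "
            "likely quasi-complete separation"
        )
    all_cols = list(Xf.columns)
    return FitResult(
        beta=pd.Series(beta, index=all_cols),
        vcov=pd.DataFrame(np.asarray(fit.cov_params()), index=all_cols,
                          columns=all_cols),
        crossbasis_cols=design.crossbasis_cols,
        random_intercept_sd=0.0, converged=bool(fit.converged),
        n_used=design.n, loglik=float(fit.llf), method=method,
        n_dropped=design.n_dropped, outcome=spec.outcome,
    )


def fit_for_breastfed_subset(
    records: pd.DataFrame,
    indicators: pd.DataFrame | None,
    crossbasis: pd.DataFrame,
    spec: ModelSpec,
) -> FitResult:
    """Fit restricted to currently breastfed children (food-group outcomes).

    Avoids confounding by voluntary weaning when the outcome is the
    breastmilk food group.
    """
    mask = records["is_breastfed"].astype(bool)
    if not mask.any():
        raise ValueError("breastfed subset is empty")
    sub = records.loc[mask.to_numpy()]
    logger.info("breastfed subset: %d of %d records", len(sub), len(records))
    ind = None
    if indicators is not None:
        key = sub["record_id"] if "record_id" in sub else sub.index
        ind = indicators.reindex(key)
    design = build_design(sub, ind, crossbasis, spec)
    return fit_random_intercept_logit(design, spec)
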