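"""Natural cubic spline lag-response basis and cross-basis construction.

The distributed-lag model represents the lag-specific log-odds contribution
of heatwave exposure as a smooth function of lag, parameterised by a natural
cubic spline over lags 0..max_lag with internal knots equally spaced on the
log-lag scale.  With the default 2 internal knots and an intercept column the
basis has 4 degrees of freedom.

The basis follows the standard natural-spline construction: a cubic B-spline
basis on boundary knots [0, max_lag], projected onto the null space of the
second-derivative constraints at both boundaries, so the spanned functions
extrapolate linearly beyond the boundary knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import qr


def log_knots(max_lag: int, n_knots: int = 2) -> np.ndarray:
    """Internal knot positions equally spaced on the log-lag scale.

    knots_j = exp(j / (n_knots+1) * log(max_lag)), j = 1..n_knots: the points
    splitting [0, log(max_lag)] into n_knots+1 equal parts, endpoints
    excluded.
    """
    if max_lag < 2:
        raise ValueError("max_lag must be >= 2")
    if n_knots < 1:
        raise ValueError("n_knots must be >= 1")
    j = np.arange(1, n_knots + 1)
    return np.exp(j / (n_knots + 1) * np.log(max_lag))


@dataclass(frozen=True)
class LagBasisSpec:
    """Specification of the lag-response spline basis."""

    max_lag: int = 14
    df: int = 4
    include_intercept_column: bool = True

    def __post_init__(self) -> None:
        if self.max_lag < 2:
            raise ValueError("max_lag must be >= 2")
        if self.n_internal_knots < 1:
            raise ValueError(
                f"df={self.df} with intercept={self.include_intercept_column} "
                "leaves no internal knots; increase df"
            )

    @property
    def n_internal_knots(self) -> int:
        # natural spline dimension: K + 1, plus 1 when the intercept column
        # is included -> df = K + 2 (intercept) or K + 1 (no intercept)
        return self.df - 2 if self.include_intercept_column else self.df - 1

    @property
    def internal_knots(self) -> np.ndarray:
        return log_knots(self.max_lag, self.n_internal_knots)


@dataclass
class BasisMatrix:
    """Natural-spline basis evaluated at integer lags 0..max_lag."""

    b: np.ndarray  # (max_lag + 1, df)
    knots: np.ndarray
    boundary: tuple[float, float]
    spec: LagBasisSpec
    _aug_knots: np.ndarray = field(repr=False, default=None)
    _null_space: np.ndarray = field(repr=False, default=None)
    _drop_first: bool = field(repr=False, default=False)

    @property
    def max_lag(self) -> int:
        return self.b.shape[0] - 1

    @property
    def df(self) -> int:
        return self.b.shape[1]

    def evaluate(self, x) -> np.ndarray:
        """Evaluate the basis at arbitrary lag values.

        Beyond the boundary knots the natural-spline columns continue
        linearly (first-order continuation from the boundary value and
        slope).
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.boundary
        out = np.empty((len(x), self.df))
        inside = (x >= lo) & (x <= hi)
        if inside.any():
            out[inside] = self._raw(x[inside])
        for is_low, b in ((True, lo), (False, hi)):
            mask = (x < b) if is_low else (x > b)
            if mask.any():
                val = self._raw(np.array([b]))
                slope = self._raw(np.array([b]), der=1)
                out[mask] = val + (x[mask, None] - b) * slope
        return out

    def _raw(self, x: np.ndarray, der: int = 0) -> np.ndarray:
        t = self._aug_knots
        n_b = len(t) - 4
        cols = np.empty((len(x), n_b))
        for j in range(n_b):
            c = np.zeros(n_b)
            c[j] = 1.0
            sp = BSpline(t, c, 3, extrapolate=True)
            if der:
                sp = sp.derivative(der)
            cols[:, j] = sp(x)
        if self._drop_first:
            cols = cols[:, 1:]
        return cols @ self._null_space

    def cumulative_contrast(self) -> np.ndarray:
        """Contrast vector for the cumulative (all-lags) effect: column sums."""
        return self.b.sum(axis=0)


def natural_cubic_basis(spec: LagBasisSpec) -> BasisMatrix:
    """Build the natural cubic spline basis at integer lags 0..max_lag."""
    knots = spec.internal_knots
    lo, hi = 0.0, float(spec.max_lag)
    if np.any(knots <= lo) or np.any(knots >= hi):
        raise ValueError("internal knots must lie strictly inside (0, max_lag)")
    t = np.concatenate(([lo] * 4, knots, [hi] * 4))
    n_b = len(t) - 4  # number of cubic B-splines

    # second derivative of each B-spline at both boundaries
    constraints = np.empty((2, n_b))
    for j in range(n_b):
        c = np.zeros(n_b)
        c[j] = 1.0
        d2 = BSpline(t, c, 3, extrapolate=True).derivative(2)
        constraints[0, j] = d2(lo)
        constraints[1, j] = d2(hi)

    drop_first = not spec.include_intercept_column
    if drop_first:
        constraints = constraints[:, 1:]
    # null space of the constraints: Q columns beyond the constraint rank
    q, _ = qr(constraints.T, mode="full")
    null = q[:, 2:]

    bm = BasisMatrix(
        b=np.empty((spec.max_lag + 1, null.shape[1])),
        knots=knots,
        boundary=(lo, hi),
        spec=spec,
        _aug_knots=t,
        _null_space=null,
        _drop_first=drop_first,
    )
    bm.b = bm.evaluate(np.arange(spec.max_lag + 1))
    if np.linalg.matrix_rank(bm.b) != bm.df:
        raise ValueError("basis matrix is rank deficient")
    if bm.df != spec.df:
        raise ValueError(
            f"constructed basis has {bm.df} columns, spec demands df={spec.df}"
        )
    return bm


def cross_basis(basis: BasisMatrix, exposures) -> np.ndarray:
    """Project lagged exposure vectors onto the lag basis: z_i = B^T h_i.

    exposures is an (n, max_lag+1) array (or a frame of lag0..lagL columns);
    returns the (n, df) cross-basis design block.
    """
    h = np.asarray(exposures, dtype=float)
    if h.ndim == 1:
        h = h[None, :]
    if h.shape[1] != basis.b.shape[0]:
        raise ValueError(
            f"exposure length {h.shape[1]} != basis rows {basis.b.shape[0]}"
        )
    return h @ basis.b
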