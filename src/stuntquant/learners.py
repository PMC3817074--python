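"""Penalized base learners for the additive predictor.

Four families, one per term type of the model:

* categorical-linear — dummy coding against a reference level, ridge-penalized
  only when the level count exceeds the degrees-of-freedom budget;
* P-spline — a cubic B-spline basis with a second-order difference penalty,
  decomposed into an unpenalized linear part and a centered smooth deviation
  orthogonal to {1, z}, so component-wise selection decides linearity
  data-drivenly;
* varying-coefficient — the P-spline basis in a continuous modifier (child
  age), gated by the 0/1 indicator of one non-reference group level;
* spatial — region indicators penalized by the neighbourhood-graph Laplacian
  (Gaussian Markov random field).

Every penalized learner is calibrated so that the trace of its hat matrix
S(lambda) = X (X'X + lambda K)^{-1} X' equals a common effective-df target,
which keeps the base-learner selection inside boosting unbiased.
"""

from __future__ import annotations

from collections.abc import Callable
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.interpolate import BSpline
from scipy.optimize import brentq

from .scenario import RegionGraph

__all__ = [
    "CovariateSpec",
    "BaseLearner",
    "PreparedLearner",
    "bspline_design",
    "difference_penalty",
    "hat_trace",
    "calibrate_df",
    "build_intercept_learner",
    "build_categorical_learner",
    "build_pspline_learner",
    "build_varying_learner",
    "build_spatial_learner",
]

DEFAULT_KNOTS = 20       # interior knots of every P-spline basis
DEFAULT_DF = 4.0         # shared effective-df target
SPLINE_DEGREE = 3
DF_TOL = 1e-4            # calibration solves well inside the 0.01 contract
_JITTER = 1e-10


@dataclass(frozen=True)
class CovariateSpec:
    """Role of one covariate in the model."""

    name: str
    kind: str  # categorical | continuous | spatial | varying
    levels: tuple[str, ...] | None = None
    reference_level: str | None = None
    knots: int = DEFAULT_KNOTS
    range: tuple[float, float] | None = None
    center: float | None = None  # centering constant for the linear part

    def validate(self) -> None:
        if self.kind not in ("categorical", "continuous", "spatial", "varying"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind in ("categorical", "varying"):
            if not self.levels or len(self.levels) < 2:
                raise ValueError(f"{self.name}: needs >= 2 levels")
            ref = self.reference_level if self.reference_level is not None else self.levels[0]
            if ref not in self.levels:
                raise ValueError(f"{self.name}: reference level {ref!r} not declared")
        if self.kind == "continuous":
            if self.range is None or not self.range[0] < self.range[1]:
                raise ValueError(f"{self.name}: needs range with min < max")
            if self.knots < 4:
                raise ValueError(f"{self.name}: spline terms need >= 4 knots")

    @property
    def reference(self) -> str:
        assert self.levels is not None
        return self.reference_level if self.reference_level is not None else self.levels[0]


def bspline_design(x: np.ndarray, low: float, high: float,
                   n_knots: int = DEFAULT_KNOTS, degree: int = SPLINE_DEGREE) -> np.ndarray:
    """B-spline basis on equally spaced interior knots over [low, high];
    values outside the range are clamped to the boundary."""
    x = np.clip(np.asarray(x, dtype=float), low, high)
    inner = np.linspace(low, high, n_knots + 2)
    knots = np.concatenate([np.full(degree, low), inner, np.full(degree, high)])
    # design_matrix is strict about the half-open last interval
    x = np.minimum(x, high - 1e-12 * max(1.0, abs(high)))
    return BSpline.design_matrix(x, knots, degree).toarray()


def difference_penalty(p: int, order: int = 2) -> np.ndarray:
    """K = D'D for the order-th difference matrix on p coefficients."""
    d = np.diff(np.eye(p), n=order, axis=0)
    return d.T @ d


def _chol_with_jitter(a: np.ndarray) -> tuple[np.ndarray, bool]:
    try:
        return linalg.cho_factor(a, lower=True), True
    except linalg.LinAlgError:
        jitter = _JITTER * np.mean(np.diag(a)) if np.mean(np.diag(a)) > 0 else _JITTER
        return linalg.cho_factor(a + jitter * np.eye(a.shape[0]), lower=True), True


def _df_spectrum(X: np.ndarray, K: np.ndarray) -> tuple[float, np.ndarray]:
    """Spectrum behind the hat-matrix trace.

    Splitting the coefficient space into the penalty's null space (never
    shrunk; contributes its rank to the df at every lambda) and the
    penalty-whitened complement projected off the null-space fit,
    trace S(lambda) = base + sum_i d_i / (d_i + lambda), with d_i >= 0 the
    eigenvalues of the whitened, projected Gram matrix.  This form stays
    stable when the design has empty or nearly empty columns (data-sparse
    spline tails), which make X'X itself singular.
    """
    w, U = linalg.eigh((K + K.T) / 2.0)
    w = np.clip(w, 0.0, None)
    null = w < 1e-10 * max(float(w.max()), 1.0)
    base = 0.0
    B = X @ (U[:, ~null] / np.sqrt(w[~null])) if (~null).any() else np.zeros((X.shape[0], 0))
    if null.any():
        A = X @ U[:, null]
        ua, sa, _ = np.linalg.svd(A, full_matrices=False)
        keep = sa > max(A.shape) * np.finfo(float).eps * (sa[0] if len(sa) else 0.0)
        base = float(keep.sum())
        if base and B.shape[1]:
            q = ua[:, keep]
            B = B - q @ (q.T @ B)
    d = np.clip(linalg.eigvalsh(B.T @ B), 0.0, None) if B.shape[1] else np.empty(0)
    return base, d


def hat_trace(X: np.ndarray, K: np.ndarray, lam: float) -> float:
    """trace of X (X'X + lam K)^{-1} X' (pseudo-inverse for rank-deficient
    unpenalized fits)."""
    base, d = _df_spectrum(X, K)
    if lam == 0.0:
        return base + float(np.sum(d > 1e-10 * max(float(d.max(initial=0.0)), 1.0)))
    return base + float(np.sum(d / (d + lam)))


def calibrate_df(X: np.ndarray, K: np.ndarray, df: float) -> float:
    """Solve trace S(lambda) = df by monotone root finding in log-lambda.

    The attainable range is (rank of the unpenalized null-space fit,
    rank(X)]; a df outside it raises with the interval reported.
    """
    base, d = _df_spectrum(X, K)
    d_pos = d[d > 1e-12 * max(float(d.max(initial=0.0)), 1.0)]
    rank = base + len(d_pos)
    if df >= rank - DF_TOL:
        if df > rank + 0.011:
            raise ValueError(f"df {df} not attainable; interval ({base}, {rank}]")
        return 0.0
    if df <= base:
        raise ValueError(f"df {df} not attainable; interval ({base}, {rank}]")

    def trace_minus_df(loglam: float) -> float:
        lam = 10.0 ** loglam
        return base + float(np.sum(d_pos / (d_pos + lam))) - df

    lo, hi = -12.0, 12.0
    while trace_minus_df(hi) > 0 and hi < 40:
        hi += 4.0
    while trace_minus_df(lo) < 0 and lo > -40:
        lo -= 4.0
    loglam = brentq(trace_minus_df, lo, hi, xtol=1e-10)
    return float(10.0 ** loglam)


class PreparedLearner:
    """A base learner bound to a dataset: design matrix built, lambda
    calibrated to the df target, normal-equations factor cached."""

    def __init__(self, learner: "BaseLearner", table: pd.DataFrame):
        self.learner = learner
        self.id = learner.id
        X, transform = learner.build_design(table)
        self.X = X
        self._transform = transform
        p = X.shape[1]
        K = learner.penalty
        if K is None or learner.df_target is None or learner.df_target >= p:
            # unpenalizable (p <= df budget): plain least squares
            self.lam = 0.0
            K = np.zeros((p, p)) if K is None else K
        else:
            self.lam = calibrate_df(X, K, learner.df_target)
        self.penalty = K
        self.hat_trace = hat_trace(X, K, self.lam)
        a = X.T @ X + self.lam * K
        self._factor, _ = _chol_with_jitter(a)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def fit_to_gradient(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        """Penalized least-squares fit of u: coefficients, fitted values, SSE."""
        u = np.asarray(u, dtype=float)
        coef = linalg.cho_solve(self._factor, self.X.T @ u)
        fitted = self.X @ coef
        resid = u - fitted
        return coef, fitted, float(resid @ resid)

    def design_for(self, table: pd.DataFrame) -> np.ndarray:
        """Design matrix on new data under the frozen training transform."""
        X, _ = self.learner.build_design(table, transform=self._transform)
        return X


@dataclass
class BaseLearner:
    """One term of the additive predictor: a design rule, a penalty, and a
    df target.  ``design_fn(table, transform)`` returns (X, transform);
    passing a previously returned transform must reproduce the training-time
    design rule on new rows."""

    id: str
    design_fn: Callable[[pd.DataFrame, object], tuple[np.ndarray, object]]
    penalty: np.ndarray | None
    df_target: float | None
    meta: dict = field(default_factory=dict)

    def build_design(self, table: pd.DataFrame, transform: object = None):
        return self.design_fn(table, transform)

    def prepare(self, table: pd.DataFrame) -> PreparedLearner:
        return PreparedLearner(self, table)


# ---------------------------------------------------------------------------
# builders

def build_intercept_learner() -> BaseLearner:
    """Unpenalized constant column; used when boosting must be able to move
    the intercept away from the offset initialisation."""

    def design(table: pd.DataFrame, transform=None):
        return np.ones((len(table), 1)), None

    return BaseLearner("intercept", design, None, None, {"kind": "intercept"})


def build_categorical_learner(spec: CovariateSpec, df: float = DEFAULT_DF) -> BaseLearner:
    """Dummy coding against the reference level; ridge-calibrated to df only
    when the number of non-reference levels exceeds df."""
    spec.validate()
    if spec.kind != "categorical":
        raise ValueError(f"{spec.name}: not categorical")
    ref = spec.reference
    others = tuple(l for l in spec.levels if l != ref)

    def design(table: pd.DataFrame, transform=None):
        col = table[spec.name]
        X = np.column_stack([(col == l).to_numpy(dtype=float) for l in others])
        return X, None

    p = len(others)
    penalty = np.eye(p) if p > df else None
    return BaseLearner(
        f"cat({spec.name})", design, penalty, df if p > df else None,
        {"kind": "categorical", "covariate": spec.name, "levels": others, "reference": ref},
    )


def _pspline_raw(spec: CovariateSpec, x: np.ndarray) -> np.ndarray:
    lo, hi = spec.range
    return bspline_design(x, lo, hi, spec.knots)


def build_pspline_learner(spec: CovariateSpec, df: float = DEFAULT_DF) -> tuple[BaseLearner, BaseLearner]:
    """Linear/smooth decomposition of a P-spline term.

    Returns (linear_part, smooth_deviation).  The linear part is the centered
    covariate with 1 df and no penalty.  The smooth deviation maps the
    difference-penalized B-spline basis through the spectral reparameterisation
    of its penalty (identity penalty on p−2 columns) and residualizes the
    result against span{1, z} on the training rows, so its fits are orthogonal
    to anything the linear part can produce; boosting's choice between the two
    is the data-driven linear/non-linear determination.
    """
    spec.validate()
    if spec.kind != "continuous":
        raise ValueError(f"{spec.name}: not continuous")
    lo, hi = spec.range
    center = spec.center if spec.center is not None else 0.5 * (lo + hi)

    def linear_design(table: pd.DataFrame, transform=None):
        x = table[spec.name].to_numpy(dtype=float)
        return (x - center)[:, None], None

    linear = BaseLearner(
        f"lin({spec.name})", linear_design, None, None,
        {"kind": "linear", "covariate": spec.name, "center": center},
    )

    p = spec.knots + SPLINE_DEGREE + 1
    K = difference_penalty(p)
    w, u = linalg.eigh(K)
    pos = w > 1e-9
    reparam = u[:, pos] / np.sqrt(w[pos])  # basis coef -> penalized coords

    def smooth_design(table: pd.DataFrame, transform=None):
        x = table[spec.name].to_numpy(dtype=float)
        B = _pspline_raw(spec, x) @ reparam
        C = np.column_stack([np.ones_like(x), x - center])
        if transform is None:
            A, *_ = np.linalg.lstsq(C, B, rcond=None)
            transform = A
        return B - C @ transform, transform

    n_pen = int(pos.sum())
    smooth = BaseLearner(
        f"smooth({spec.name})", smooth_design, np.eye(n_pen), df,
        {"kind": "smooth", "covariate": spec.name, "center": center},
    )
    return linear, smooth


def build_varying_learner(modifier_spec: CovariateSpec, group_spec: CovariateSpec,
                          level: str, df: float = DEFAULT_DF) -> BaseLearner:
    """Age-varying group effect: P-spline basis in the continuous modifier,
    rows gated by the indicator of one non-reference group level.  Records in
    any other level — including the reference — get exactly 0."""
    modifier_spec.validate()
    group_spec.validate()
    if modifier_spec.kind != "continuous":
        raise ValueError("modifier must be continuous")
    if group_spec.kind not in ("categorical", "varying"):
        raise ValueError("group must be categorical")
    if level == group_spec.reference:
        raise ValueError("varying term not defined for the reference level")
    if level not in group_spec.levels:
        raise ValueError(f"level {level!r} not declared for {group_spec.name!r}")

    p = modifier_spec.knots + SPLINE_DEGREE + 1

    def design(table: pd.DataFrame, transform=None):
        x = table[modifier_spec.name].to_numpy(dtype=float)
        B = _pspline_raw(modifier_spec, x)
        ind = (table[group_spec.name] == level).to_numpy(dtype=float)
        return B * ind[:, None], None

    return BaseLearner(
        f"varying({group_spec.name}={level}|{modifier_spec.name})",
        design, difference_penalty(p), df,
        {"kind": "varying", "covariate": group_spec.name, "level": level,
         "modifier": modifier_spec.name},
    )


def build_spatial_learner(graph: RegionGraph, df: float = DEFAULT_DF,
                          column: str = "region") -> BaseLearner:
    """Region-indicator design penalized by the graph Laplacian; effects are
    shrunk toward the average of their neighbours (Markov-random-field
    smoothing)."""
    ids = list(graph.region_ids)
    index = {r: i for i, r in enumerate(ids)}

    def design(table: pd.DataFrame, transform=None):
        col = table[column]
        unknown = set(col.unique()) - set(index)
        if unknown:
            raise ValueError(f"records with unknown region(s): {sorted(unknown)!r}")
        X = np.zeros((len(table), len(ids)))
        X[np.arange(len(table)), col.map(index).to_numpy()] = 1.0
        return X, None

    return BaseLearner(
        f"spatial({column})", design, graph.laplacian.copy(), df,
        {"kind": "spatial", "covariate": column, "regions": tuple(ids)},
    )
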