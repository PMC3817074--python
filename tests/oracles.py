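"""Independent reference implementations used to cross-check the package.

Each oracle takes a different computational route than the code it checks:
exact linear programming for the check-loss minimiser, statsmodels' Newton
solver for the logistic MLE, dense penalized normal equations for base-learner
fits, and direct dense linear algebra for hat-matrix traces.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def lp_quantile_regression(X: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    """Exact check-loss minimiser via the standard LP formulation:
    min tau*1'u + (1-tau)*1'v  s.t.  X b + u - v = y, u, v >= 0."""
    n, p = X.shape
    A = np.hstack([X, np.eye(n), -np.eye(n)])
    c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau)])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A, b_eq=y, bounds=bounds, method="highs")
    assert res.success, res.message
    return res.x[:p]


def newton_logistic(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Logistic MLE via statsmodels' Newton-type solver."""
    import statsmodels.api as sm

    return np.asarray(sm.Logit(y, X).fit(disp=0).params)


def penalized_lstsq(X: np.ndarray, K: np.ndarray, lam: float, u: np.ndarray) -> np.ndarray:
    """Dense normal-equations solve (X'X + lam K)^{-1} X'u."""
    return np.linalg.solve(X.T @ X + lam * K, X.T @ u)


def dense_hat_trace(X: np.ndarray, K: np.ndarray, lam: float) -> float:
    """trace of X (X'X + lam K)^{-1} X' by direct dense inversion."""
    a = X.T @ X + lam * K
    return float(np.trace(np.linalg.solve(a, X.T @ X)))


def sorted_percentile(values: np.ndarray, q: float) -> float:
    """Weibull (type 6) percentile by explicit order statistics: the
    q-percentile sits at rank position q/100 * (n + 1)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    h = q / 100.0 * (n + 1)
    k = int(np.floor(h))
    if k < 1:
        return float(v[0])
    if k >= n:
        return float(v[-1])
    frac = h - k
    return float(v[k - 1] + frac * (v[k] - v[k - 1]))


def check_risk(y: np.ndarray, eta: np.ndarray, tau: float) -> float:
    """Term-by-term summation of the check loss."""
    total = 0.0
    for yi, ei in zip(y, eta):
        u = yi - ei
        total += u * tau if u >= 0 else u * (tau - 1.0)
    return total / len(y)
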