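"""Component-wise functional gradient descent boosting.

At each iteration the negative gradient of the loss (check loss for a
conditional quantile, binomial deviance for a log-odds model) is computed at
the current additive predictor; every base learner is fit to it by penalized
least squares; only the best-fitting learner is updated, by a small step
length nu.  The iteration count mstop is the regularization parameter and is
chosen by k-fold cross-validation.  Learners that are never selected keep
identically zero coefficients — boosting does variable selection and
estimation in one pass.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .learners import BaseLearner, PreparedLearner

__all__ = [
    "LossSpec",
    "BoostedModel",
    "CVResult",
    "negative_gradient",
    "empirical_risk",
    "offset_init",
    "boost",
    "cross_validate_mstop",
    "predict",
    "predict_term",
    "default_cv_grid",
]

PAPER_TAUS = (0.05, 0.15, 0.35, 0.50)
DEFAULT_NU = 0.2


def default_cv_grid(max_mstop: int = 2500, step: int = 25) -> tuple[int, ...]:
    """Checkpoints every `step` iterations, starting at 0 (offset-only)."""
    return tuple(range(0, max_mstop + 1, step))


@dataclass(frozen=True)
class LossSpec:
    family: str  # "quantile" | "binomial"
    tau: float | None = None

    def __post_init__(self):
        if self.family not in ("quantile", "binomial"):
            raise ValueError(f"unknown loss family {self.family!r}")
        if self.family == "quantile":
            if self.tau is None or not 0.0 < self.tau < 1.0:
                raise ValueError("quantile loss needs tau in (0, 1)")
        elif self.tau is not None:
            raise ValueError("binomial loss takes no tau")

    @property
    def label(self) -> str:
        return f"tau={self.tau:g}" if self.family == "quantile" else "binomial"


def _check_binomial(y: np.ndarray) -> None:
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial outcome must be 0/1")


def negative_gradient(loss: LossSpec, y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Check loss: u = tau where y − eta > 0, else tau − 1 (exact ties take
    the tau − 1 branch, the subgradient choice that keeps the risk monotone
    under descent).  Binomial: u = y − logistic(eta)."""
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if y.shape != eta.shape:
        raise ValueError("y and eta differ in length")
    if loss.family == "quantile":
        return np.where(y - eta > 0, loss.tau, loss.tau - 1.0)
    _check_binomial(y)
    return y - expit(eta)


def empirical_risk(loss: LossSpec, y: np.ndarray, eta: np.ndarray) -> float:
    """Mean check loss rho_tau(y − eta), or mean binomial negative
    log-likelihood on the log-odds scale."""
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if loss.family == "quantile":
        u = y - eta
        return float(np.mean(u * (loss.tau - (u < 0))))
    _check_binomial(y)
    # -[y*eta - log(1+exp(eta))], numerically stable
    return float(np.mean(np.logaddexp(0.0, eta) - y * eta))


def offset_init(loss: LossSpec, y: np.ndarray) -> float:
    """Quantile: the empirical tau-quantile of y (linear interpolation of
    order statistics).  Binomial: the log-odds of the outcome mean."""
    y = np.asarray(y, dtype=float)
    if len(y) < 1:
        raise ValueError("empty outcome")
    if loss.family == "quantile":
        return float(np.quantile(y, loss.tau, method="linear"))
    _check_binomial(y)
    p = float(np.mean(y))
    if p in (0.0, 1.0):
        raise ValueError("degenerate binomial outcome: all identical")
    return float(np.log(p / (1.0 - p)))


class BoostedModel:
    """Offset + accumulated per-learner coefficient contributions.

    The additive predictor of a record is exactly
    offset + sum over learners of design(record) . contributions[learner].
    """

    def __init__(self, loss: LossSpec, offset: float,
                 prepared: list[PreparedLearner], nu: float):
        self.loss = loss
        self.offset = offset
        self.prepared = prepared
        self.nu = nu
        self.contributions: dict[str, np.ndarray] = {
            pl.id: np.zeros(pl.p) for pl in prepared
        }
        self.selection_path: list[str] = []
        self.train_risk_path: list[float] = []

    @property
    def mstop(self) -> int:
        return len(self.selection_path)

    def learner(self, learner_id: str) -> PreparedLearner:
        for pl in self.prepared:
            if pl.id == learner_id:
                return pl
        raise KeyError(learner_id)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(table), self.offset)
        for pl in self.prepared:
            coef = self.contributions[pl.id]
            if np.any(coef):
                eta += pl.design_for(table) @ coef
        return eta

    def predict_term(self, learner_id: str, table: pd.DataFrame) -> np.ndarray:
        pl = self.learner(learner_id)
        coef = self.contributions[learner_id]
        if not np.any(coef):
            return np.zeros(len(table))
        return pl.design_for(table) @ coef

    def selection_counts(self) -> dict[str, int]:
        counts = {pl.id: 0 for pl in self.prepared}
        for lid in self.selection_path:
            counts[lid] += 1
        return counts

    def to_json(self) -> str:
        digest = hashlib.sha256(
            json.dumps([pl.id for pl in self.prepared]).encode()
        ).hexdigest()[:16]
        return json.dumps({
            "loss": {"family": self.loss.family, "tau": self.loss.tau},
            "offset": self.offset,
            "nu": self.nu,
            "mstop": self.mstop,
            "selection_path": self.selection_path,
            "contributions": {k: v.tolist() for k, v in self.contributions.items()},
            "config_digest": digest,
        })

    @classmethod
    def from_json(cls, payload: str, learners: list[BaseLearner],
                  table: pd.DataFrame) -> "BoostedModel":
        """Reload a serialized model; learners are re-prepared on the table
        the model was fitted to (the config digest pins the learner set)."""
        doc = json.loads(payload)
        loss = LossSpec(doc["loss"]["family"], doc["loss"]["tau"])
        prepared = [bl.prepare(table) for bl in learners]
        model = cls(loss, doc["offset"], prepared, doc["nu"])
        model.selection_path = list(doc["selection_path"])
        for k, v in doc["contributions"].items():
            model.contributions[k] = np.asarray(v, dtype=float)
        return model


def boost(
    table: pd.DataFrame,
    y: np.ndarray,
    learners: list[BaseLearner],
    loss: LossSpec,
    mstop: int,
    nu: float = DEFAULT_NU,
    *,
    track_risk: bool = False,
    eval_table: pd.DataFrame | None = None,
    eval_y: np.ndarray | None = None,
    checkpoints: tuple[int, ...] | None = None,
) -> BoostedModel:
    """Run component-wise boosting for mstop iterations.

    Ties in the SSE selection go to the lowest learner index (the configured
    learner order), which makes runs reproducible.  With mstop = 0 the model
    is offset-only.  If an eval set and checkpoints are given, the held-out
    empirical risk at each checkpoint is stored on ``model.eval_risks``.
    """
    if mstop < 0:
        raise ValueError("mstop must be >= 0")
    if not 0.0 < nu <= 1.0:
        raise ValueError("nu must be in (0, 1]")
    y = np.asarray(y, dtype=float)
    prepared = [bl.prepare(table) for bl in learners]
    if not prepared:
        raise ValueError("no base learners")
    offset = offset_init(loss, y)
    model = BoostedModel(loss, offset, prepared, nu)
    eta = np.full(len(y), offset)

    eval_mode = eval_table is not None
    if eval_mode:
        eval_y = np.asarray(eval_y, dtype=float)
        eval_designs = [pl.design_for(eval_table) for pl in prepared]
        eta_eval = np.full(len(eval_y), offset)
        ckpts = sorted(set(checkpoints or ()))
        model.eval_risks = {}
        if 0 in ckpts:
            model.eval_risks[0] = empirical_risk(loss, eval_y, eta_eval)

    if track_risk:
        model.train_risk_path.append(empirical_risk(loss, y, eta))

    for it in range(1, mstop + 1):
        u = negative_gradient(loss, y, eta)
        best = None
        for idx, pl in enumerate(prepared):
            try:
                coef, fitted, sse = pl.fit_to_gradient(u)
            except Exception as exc:  # singular after jitter: unusable this round
                warnings.warn(f"learner {pl.id} unusable at iteration {it}: {exc}",
                              stacklevel=2)
                continue
            if best is None or sse < best[0] - 1e-12:
                best = (sse, idx, coef, fitted)
        if best is None:
            raise RuntimeError("all base learners unusable")
        _, idx, coef, fitted = best
        pl = prepared[idx]
        model.contributions[pl.id] += nu * coef
        eta += nu * fitted
        model.selection_path.append(pl.id)
        if track_risk:
            model.train_risk_path.append(empirical_risk(loss, y, eta))
        if eval_mode:
            eta_eval = eta_eval + nu * (eval_designs[idx] @ coef)
            if it in ckpts:
                model.eval_risks[it] = empirical_risk(loss, eval_y, eta_eval)
    return model


@dataclass
class CVResult:
    mstop: int
    grid: tuple[int, ...]
    mean_risk: np.ndarray
    fold_risk: np.ndarray = field(repr=False, default=None)


def cross_validate_mstop(
    table: pd.DataFrame,
    y: np.ndarray,
    learners: list[BaseLearner],
    loss: LossSpec,
    folds: int = 5,
    grid: tuple[int, ...] | None = None,
    seed: int = 0,
    nu: float = DEFAULT_NU,
) -> CVResult:
    """Five-fold (by default) cross-validated choice of the stopping
    iteration: records are partitioned by a seeded permutation, each fold's
    held-out risk is evaluated at every checkpoint of the grid, and the
    checkpoint minimizing the mean held-out risk wins (ties go to the
    smallest checkpoint)."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    grid = tuple(sorted(set(grid if grid is not None else default_cv_grid())))
    y = np.asarray(y, dtype=float)
    n = len(y)
    perm = np.random.default_rng(seed).permutation(n)
    fold_ids = np.empty(n, dtype=int)
    fold_ids[perm] = np.arange(n) % folds
    risks = np.empty((folds, len(grid)))
    for f in range(folds):
        test = fold_ids == f
        if test.sum() < 2 or (~test).sum() < 2:
            raise ValueError("fold with fewer than 2 records")
        model = boost(
            table.loc[~test], y[~test], learners, loss, mstop=max(grid), nu=nu,
            eval_table=table.loc[test], eval_y=y[test], checkpoints=grid,
        )
        risks[f] = [model.eval_risks[g] for g in grid]
    mean_risk = risks.mean(axis=0)
    best = int(np.argmin(mean_risk))  # first minimum = smallest checkpoint
    return CVResult(mstop=grid[best], grid=grid, mean_risk=mean_risk, fold_risk=risks)


def predict(model: BoostedModel, table: pd.DataFrame) -> np.ndarray:
    return model.predict(table)


def predict_term(model: BoostedModel, learner_id: str, table: pd.DataFrame) -> np.ndarray:
    return model.predict_term(learner_id, table)
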