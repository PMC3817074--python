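"""Bootstrap inference and effect summaries.

Boosting provides no analytic standard errors, so uncertainty comes from
refitting the model on bootstrap resamples.  Significance follows the
resampling rules of the survey analysis this package reproduces:

* a categorical level is significant when the 95% percentile bootstrap CI of
  its coefficient excludes zero;
* a smooth (or age-varying) effect is significant when all replicate curves
  are strictly positive — or all strictly negative — on at least one common
  interval of the covariate range (operationalized as two consecutive points
  of a shared evaluation grid; a per-replicate-interval reading is available
  behind ``common_interval=False``).

Percentiles use the Weibull (type 6) interpolation of order statistics, so
with B = 100 replicates the 2.5% bound interpolates between the 2nd and 3rd
smallest values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boosting import BoostedModel, LossSpec, boost
from .learners import BaseLearner

__all__ = [
    "BootstrapEnsemble",
    "EffectSummary",
    "bootstrap_fit",
    "ci_categorical",
    "effect_curve",
    "significance_continuous",
    "curves_significant",
    "classify_shape",
    "spatial_effects",
]

DEFAULT_B = 100
CI_LEVEL = (2.5, 97.5)
GRID_SIZE = 100

SHAPE_LABELS = (
    "constant", "linear+", "linear-",
    "nonlinear-inverse-U", "nonlinear-U",
    "nonlinear-monotone+", "nonlinear-monotone-",
)


@dataclass
class BootstrapEnsemble:
    """B boosted models refitted on seeded with-replacement resamples under a
    shared configuration (same learners, loss, nu and a fixed mstop)."""

    models: list[BoostedModel]
    seeds: list[int]
    loss: LossSpec
    mstop: int
    nu: float

    @property
    def B(self) -> int:
        return len(self.models)


@dataclass
class EffectSummary:
    covariate: str
    level: str | None
    grid: np.ndarray | None
    point: np.ndarray | float
    ci_lower: np.ndarray | float
    ci_upper: np.ndarray | float
    significant: bool
    shape_label: str | None = None


def _percentile(values: np.ndarray, q: float) -> float:
    return float(np.quantile(np.asarray(values, dtype=float), q / 100.0,
                             method="weibull"))


def bootstrap_fit(
    table: pd.DataFrame,
    y_column: str,
    learners: list[BaseLearner],
    loss: LossSpec,
    mstop: int,
    nu: float,
    B: int = DEFAULT_B,
    seed: int = 0,
) -> BootstrapEnsemble:
    """Refit the model on B with-replacement resamples of size n; replicate b
    draws its indices from a generator seeded at seed + b.  Replicates whose
    fit fails are dropped with a warning; more than 10% dropped is an error."""
    if B < 2:
        raise ValueError("B must be >= 2")
    n = len(table)
    models, seeds, failures = [], [], 0
    for b in range(B):
        rep_seed = seed + b
        idx = np.random.default_rng(rep_seed).integers(0, n, size=n)
        sample = table.iloc[idx].reset_index(drop=True)
        try:
            model = boost(sample, sample[y_column].to_numpy(dtype=float),
                          learners, loss, mstop=mstop, nu=nu)
        except Exception as exc:
            failures += 1
            warnings.warn(f"bootstrap replicate {b} failed: {exc}", stacklevel=2)
            continue
        models.append(model)
        seeds.append(rep_seed)
    if failures > 0.1 * B:
        raise RuntimeError(f"{failures}/{B} bootstrap replicates failed")
    return BootstrapEnsemble(models, seeds, loss, mstop, nu)


def _categorical_learner(model: BoostedModel, covariate: str):
    for pl in model.prepared:
        if pl.learner.meta.get("kind") == "categorical" \
                and pl.learner.meta.get("covariate") == covariate:
            return pl
    raise KeyError(f"no categorical learner for {covariate!r}")


def _level_coef(model: BoostedModel, covariate: str, level: str) -> float:
    pl = _categorical_learner(model, covariate)
    levels = pl.learner.meta["levels"]
    if level not in levels:
        raise ValueError(f"unknown level {level!r} for {covariate!r} "
                         f"(reference is {pl.learner.meta['reference']!r})")
    return float(model.contributions[pl.id][levels.index(level)])


def ci_categorical(ensemble: BootstrapEnsemble, full_model: BoostedModel,
                   covariate: str, level: str) -> EffectSummary:
    """Percentile bootstrap CI for one non-reference level's coefficient;
    significant iff the CI excludes zero."""
    reps = np.array([_level_coef(m, covariate, level) for m in ensemble.models])
    lo, hi = _percentile(reps, CI_LEVEL[0]), _percentile(reps, CI_LEVEL[1])
    point = _level_coef(full_model, covariate, level)
    return EffectSummary(
        covariate=covariate, level=level, grid=None, point=point,
        ci_lower=lo, ci_upper=hi, significant=not (lo <= 0.0 <= hi),
    )


def effect_curve(model: BoostedModel, covariate: str, grid: np.ndarray,
                 level: str | None = None) -> np.ndarray:
    """Evaluate one covariate's fitted effect on a grid.

    Continuous covariates sum their linear and smooth-deviation terms;
    age-varying terms need the group level and are evaluated along the
    modifier (child-age) grid within that level.
    """
    grid = np.asarray(grid, dtype=float)
    total = np.zeros(len(grid))
    found = False
    for pl in model.prepared:
        meta = pl.learner.meta
        if meta.get("covariate") != covariate:
            continue
        kind = meta.get("kind")
        if kind in ("linear", "smooth") and level is None:
            frame = pd.DataFrame({covariate: grid})
            total += model.predict_term(pl.id, frame)
            found = True
        elif kind == "varying" and level is not None and meta.get("level") == level:
            frame = pd.DataFrame({meta["modifier"]: grid, covariate: level})
            total += model.predict_term(pl.id, frame)
            found = True
    if not found:
        raise ValueError(f"no smooth or varying term for {covariate!r}"
                         + (f" level {level!r}" if level else ""))
    return total


def significance_continuous(
    ensemble: BootstrapEnsemble,
    full_model: BoostedModel,
    covariate: str,
    value_range: tuple[float, float],
    grid_size: int = GRID_SIZE,
    level: str | None = None,
    common_interval: bool = True,
) -> EffectSummary:
    """Significance of a smooth or age-varying effect from the replicate
    curves; see the module docstring for the interval rule."""
    if grid_size < 10:
        raise ValueError("grid_size must be >= 10")
    grid = np.linspace(value_range[0], value_range[1], grid_size)
    curves = np.array([effect_curve(m, covariate, grid, level=level)
                       for m in ensemble.models])
    significant = curves_significant(curves, common_interval=common_interval)
    point = effect_curve(full_model, covariate, grid, level=level)
    lo = np.array([_percentile(curves[:, j], CI_LEVEL[0]) for j in range(grid_size)])
    hi = np.array([_percentile(curves[:, j], CI_LEVEL[1]) for j in range(grid_size)])
    return EffectSummary(
        covariate=covariate, level=level, grid=grid, point=point,
        ci_lower=lo, ci_upper=hi, significant=significant,
        shape_label=classify_shape(point),
    )


def curves_significant(curves: np.ndarray, common_interval: bool = True,
                       run_length: int = 2) -> bool:
    """The resampling significance rule for effect curves: curves is a
    (B, grid) array of replicate evaluations; significant iff all B curves
    are strictly positive (or all strictly negative) on at least one interval
    — ``run_length`` consecutive grid points, shared across replicates under
    the default reading, anywhere per replicate otherwise."""
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    if common_interval:
        return bool(_has_run((curves > 0).all(axis=0), run_length)
                    or _has_run((curves < 0).all(axis=0), run_length))
    pos_each = all(_has_run(c > 0, run_length) for c in curves)
    neg_each = all(_has_run(c < 0, run_length) for c in curves)
    return bool(pos_each or neg_each)


def _has_run(mask: np.ndarray, length: int) -> bool:
    run = 0
    for m in mask:
        run = run + 1 if m else 0
        if run >= length:
            return True
    return False


def classify_shape(curve: np.ndarray, *, flat_tol: float = 1e-6,
                   linear_r2: float = 0.95) -> str:
    """Descriptive label for a fitted effect curve on a grid.

    Rules: a near-zero range is ``constant``; a straight-line fit with
    R^2 >= 0.95 is ``linear`` with its slope sign; otherwise the sign pattern
    of the first differences decides — one + to − change is an inverse U, one
    − to + change a U, no change a (nonlinear) monotone trend.  Labels are
    descriptive only and never feed back into estimation.
    """
    curve = np.asarray(curve, dtype=float)
    if len(curve) < 10:
        raise ValueError("curve needs >= 10 grid points")
    if not np.all(np.isfinite(curve)):
        raise ValueError("non-finite curve values")
    rng = float(curve.max() - curve.min())
    if rng < flat_tol:
        return "constant"
    x = np.arange(len(curve), dtype=float)
    slope, intercept = np.polyfit(x, curve, 1)
    resid = curve - (slope * x + intercept)
    r2 = 1.0 - float(resid @ resid) / float(((curve - curve.mean()) ** 2).sum())
    if r2 >= linear_r2:
        return "linear+" if slope > 0 else "linear-"
    d = np.diff(curve)
    signs = np.sign(d[np.abs(d) > 0.01 * np.abs(d).max()])
    if len(signs) == 0:
        return "constant"
    first, last = signs[0], signs[-1]
    changed = np.any(signs[:-1] != signs[1:])
    if not changed:
        return "nonlinear-monotone+" if first > 0 else "nonlinear-monotone-"
    if first > 0 and last < 0:
        return "nonlinear-inverse-U"
    if first < 0 and last > 0:
        return "nonlinear-U"
    # wiggly but with a net monotone sign pattern
    return "nonlinear-monotone+" if last > 0 else "nonlinear-monotone-"


def spatial_effects(model: BoostedModel, centered: bool = True) -> pd.DataFrame:
    """Per-region fitted effect of the spatial term; centered to mean zero
    across regions by default (the level is absorbed by the offset)."""
    for pl in model.prepared:
        if pl.learner.meta.get("kind") == "spatial":
            vals = model.contributions[pl.id].copy()
            if centered:
                vals = vals - vals.mean()
            return pd.DataFrame({
                "region": list(pl.learner.meta["regions"]),
                "effect": vals,
            })
    raise KeyError("model has no spatial learner")
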