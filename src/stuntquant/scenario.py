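"""Synthetic survey-cohort generation with known additive quantile structure.

The generator emulates a child-level undernutrition survey: a continuous
height-for-age Z-score (HAZ) outcome, a mix of categorical and continuous
covariates, a region identifier living on a neighbourhood graph, and a
planted additive predictor

    eta_i = intercept + sum_j f_j(covariate_ij)

so that under iid noise the true conditional tau-quantile of the outcome is
``eta + F^{-1}(tau)`` for every tau — every downstream estimator can be
validated by parameter recovery without access to the original survey data.

All randomness flows from ``ScenarioSpec.seed``; covariates, outcome noise
and missingness draw from generators seeded at fixed offsets from it.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CovariateDef",
    "NoiseSpec",
    "VaryingEffect",
    "ScenarioSpec",
    "RegionGraph",
    "make_region_graph",
    "generate_covariates",
    "true_predictor",
    "generate_outcome",
    "simulate_cohort",
    "nfhs_like_scenario",
    "recovery_scenario",
    "shape_scenario",
    "spatial_scenario",
    "grid_surface_effect",
]

_FREQ_TOL = 1e-9

# seed offsets for the named generation stages
_COVARIATE_STAGE = 0
_OUTCOME_STAGE = 1
_MISSING_STAGE = 2


@dataclass(frozen=True)
class CovariateDef:
    """Definition of one covariate column.

    kind:
        ``categorical`` — drawn from ``categories`` with ``frequencies``;
        ``continuous``  — drawn from ``distribution`` (``uniform`` with
        ``low``/``high`` or ``truncnorm`` with ``mean``/``sd``/``low``/``high``);
        ``spatial``     — region labels drawn from the region graph
        (uniformly unless ``frequencies`` is given).
    """

    name: str
    kind: str
    categories: tuple[str, ...] | None = None
    frequencies: tuple[float, ...] | None = None
    distribution: str | None = None
    params: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.kind not in ("categorical", "continuous", "spatial"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.categories or self.frequencies is None:
                raise ValueError(f"{self.name}: categorical needs categories+frequencies")
            if len(self.categories) != len(self.frequencies):
                raise ValueError(f"{self.name}: categories/frequencies length mismatch")
            if abs(sum(self.frequencies) - 1.0) > _FREQ_TOL:
                raise ValueError(f"{self.name}: frequencies sum to {sum(self.frequencies)}, not 1")
            if any(f < 0 for f in self.frequencies):
                raise ValueError(f"{self.name}: negative frequency")
        elif self.kind == "continuous":
            if self.distribution not in ("uniform", "truncnorm"):
                raise ValueError(f"{self.name}: unknown distribution {self.distribution!r}")
        elif self.kind == "spatial" and self.frequencies is not None:
            if abs(sum(self.frequencies) - 1.0) > _FREQ_TOL:
                raise ValueError(f"{self.name}: region frequencies do not sum to 1")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise on the latent Z-score.

    ``model="iid"`` draws eps ~ sigma * F with F a symmetric standard family
    (``gaussian`` or ``logistic``); every conditional quantile curve then
    shares the shape of eta.  ``model="heteroscedastic"`` multiplies sigma by
    ``scale_function(table)`` record-wise, creating genuinely differential
    quantile effects.
    """

    model: str = "iid"
    distribution: str = "gaussian"
    sigma: float = 1.0
    scale_function: Callable[[pd.DataFrame], np.ndarray] | None = None

    def validate(self) -> None:
        if self.model not in ("iid", "heteroscedastic"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.distribution not in ("gaussian", "logistic"):
            raise ValueError(f"unknown noise distribution {self.distribution!r}")
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0 (0 = noise-free limit)")
        if self.model == "heteroscedastic" and self.scale_function is None:
            raise ValueError("heteroscedastic noise needs a scale_function")


@dataclass(frozen=True)
class VaryingEffect:
    """An age-varying group effect: curve(modifier) applied within each
    non-reference level of a categorical covariate; reference level
    contributes exactly 0."""

    modifier: str
    curves: Mapping[str, Callable[[np.ndarray], np.ndarray]]


# a categorical effect is a {level: coefficient} map (reference level absent
# or 0); a continuous effect is a vectorised callable; a spatial effect is a
# {region_id: value} map.
Effect = Mapping[str, float] | Callable[[np.ndarray], np.ndarray] | VaryingEffect


@dataclass(frozen=True)
class ScenarioSpec:
    """The synthetic truth: covariate laws, planted effects, noise model."""

    n: int
    seed: int
    covariate_specs: tuple[CovariateDef, ...]
    effect_functions: Mapping[str, Effect] = field(default_factory=dict)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    intercept: float = 0.0
    missingness: Mapping[str, float] = field(default_factory=dict)
    # survey-style plausibility bounds on the Z-score; values are clamped
    # (growth-standard pipelines flag |Z| > 6 as implausible)
    z_range: tuple[float, float] | None = None

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        names = [c.name for c in self.covariate_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariate names")
        for c in self.covariate_specs:
            c.validate()
        for key in self.effect_functions:
            if key not in names:
                raise ValueError(f"effect function references undeclared covariate {key!r}")
        for key, eff in self.effect_functions.items():
            if isinstance(eff, VaryingEffect) and eff.modifier not in names:
                raise ValueError(f"varying effect on {key!r} references missing modifier")
        self.noise.validate()
        for col, p in self.missingness.items():
            if not 0 <= p < 1:
                raise ValueError(f"missingness probability for {col!r} outside [0, 1)")

    def covariate(self, name: str) -> CovariateDef:
        for c in self.covariate_specs:
            if c.name == name:
                return c
        raise KeyError(name)


class RegionGraph:
    """Region adjacency structure backing the spatial Markov-random-field
    penalty: Laplacian = degree on the diagonal, −1 between neighbours."""

    def __init__(
        self,
        region_ids: Sequence[str],
        edges: Sequence[tuple[str, str]],
        positions: Mapping[str, tuple[float, float]] | None = None,
    ):
        self.region_ids = list(region_ids)
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("duplicate region ids")
        index = {r: i for i, r in enumerate(self.region_ids)}
        self.edges = []
        seen = set()
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop on region {a!r}")
            if a not in index or b not in index:
                raise ValueError(f"edge ({a!r}, {b!r}) references undeclared region")
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            self.edges.append((a, b))
        k = len(self.region_ids)
        lap = np.zeros((k, k))
        for a, b in self.edges:
            i, j = index[a], index[b]
            lap[i, i] += 1
            lap[j, j] += 1
            lap[i, j] -= 1
            lap[j, i] -= 1
        self.laplacian = lap
        self.positions = dict(positions) if positions else None
        g = nx.Graph()
        g.add_nodes_from(self.region_ids)
        g.add_edges_from(self.edges)
        if k > 1 and not nx.is_connected(g):
            warnings.warn("region graph is disconnected; GMRF penalty remains valid",
                          stacklevel=2)

    def __len__(self) -> int:
        return len(self.region_ids)

    def to_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            for a, b in self.edges:
                fh.write(f"{a} {b}\n")

    @classmethod
    def from_edge_list(cls, path) -> "RegionGraph":
        edges, ids = [], []
        seen = set()
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                a, b = parts[:2]
                edges.append((a, b))
                for r in (a, b):
                    if r not in seen:
                        seen.add(r)
                        ids.append(r)
        return cls(ids, edges)


def make_region_graph(layout: str | Sequence[tuple[str, str]], k: int | None = None) -> RegionGraph:
    """Build a region graph: ``"grid"`` (near-square lattice trimmed to k
    regions), ``"path"``, or an explicit edge list."""
    if not isinstance(layout, str):
        ids, seen = [], set()
        for a, b in layout:
            for r in (a, b):
                if r not in seen:
                    seen.add(r)
                    ids.append(r)
        return RegionGraph(ids, list(layout))
    if k is None or k < 1:
        raise ValueError("k must be >= 1")
    if layout == "path":
        ids = [f"R{i:02d}" for i in range(k)]
        edges = [(ids[i], ids[i + 1]) for i in range(k - 1)]
        pos = {r: (float(i), 0.0) for i, r in enumerate(ids)}
        return RegionGraph(ids, edges, pos)
    if layout == "grid":
        ncol = int(np.ceil(np.sqrt(k)))
        nrow = int(np.ceil(k / ncol))
        cells = [(r, c) for r in range(nrow) for c in range(ncol)][:k]
        cellset = set(cells)
        label = {cell: f"R{i:02d}" for i, cell in enumerate(cells)}
        edges = []
        for (r, c) in cells:
            for nb in ((r + 1, c), (r, c + 1)):
                if nb in cellset:
                    edges.append((label[(r, c)], label[nb]))
        pos = {label[(r, c)]: (float(c), float(r)) for (r, c) in cells}
        return RegionGraph(list(label.values()), edges, pos)
    raise ValueError(f"unknown layout {layout!r}")


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def generate_covariates(spec: ScenarioSpec, graph: RegionGraph | None = None) -> pd.DataFrame:
    """Draw the covariate columns (outcome absent). Deterministic given
    ``spec.seed``; columns appear in declaration order."""
    spec.validate()
    rng = _rng(spec.seed, _COVARIATE_STAGE)
    n = spec.n
    cols: dict[str, object] = {"record_id": np.arange(n)}
    for cov in spec.covariate_specs:
        if cov.kind == "categorical":
            cols[cov.name] = rng.choice(cov.categories, size=n, p=cov.frequencies)
        elif cov.kind == "spatial":
            if graph is None:
                raise ValueError(f"{cov.name}: spatial covariate needs a region graph")
            p = cov.frequencies
            cols[cov.name] = rng.choice(graph.region_ids, size=n, p=p)
        else:
            p = cov.params
            if cov.distribution == "uniform":
                cols[cov.name] = rng.uniform(p["low"], p["high"], size=n)
            else:  # truncnorm
                a = (p["low"] - p["mean"]) / p["sd"]
                b = (p["high"] - p["mean"]) / p["sd"]
                cols[cov.name] = stats.truncnorm.rvs(
                    a, b, loc=p["mean"], scale=p["sd"], size=n, random_state=rng
                )
    return pd.DataFrame(cols)


def true_predictor(table: pd.DataFrame, spec: ScenarioSpec) -> np.ndarray:
    """Evaluate the planted additive predictor eta on a covariate table."""
    eta = np.full(len(table), float(spec.intercept))
    for name, eff in spec.effect_functions.items():
        if name not in table.columns:
            raise ValueError(f"effect function references missing column {name!r}")
        col = table[name]
        if isinstance(eff, VaryingEffect):
            age = table[eff.modifier].to_numpy(dtype=float)
            for level, curve in eff.curves.items():
                mask = (col == level).to_numpy()
                if mask.any():
                    eta[mask] += np.asarray(curve(age[mask]), dtype=float)
        elif callable(eff):
            eta += np.asarray(eff(col.to_numpy(dtype=float)), dtype=float)
        else:  # {level/region: value}; unmapped (reference) levels contribute 0
            eta += col.map(lambda v: float(eff.get(v, 0.0))).to_numpy(dtype=float)
    return eta


def generate_outcome(
    eta: np.ndarray, spec: ScenarioSpec, table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Z = eta + eps; stunting indicators use the non-strict thresholds
    Z <= −2 (stunted) and Z <= −3 (severely stunted)."""
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite values in eta")
    rng = _rng(spec.seed, _OUTCOME_STAGE)
    noise = spec.noise
    if noise.distribution == "gaussian":
        eps = rng.standard_normal(len(eta))
    else:
        eps = rng.logistic(size=len(eta))
    scale = np.full(len(eta), noise.sigma)
    if noise.model == "heteroscedastic":
        if table is None:
            raise ValueError("heteroscedastic noise needs the covariate table")
        scale = scale * np.asarray(noise.scale_function(table), dtype=float)
        if np.any(scale <= 0):
            raise ValueError("scale_function produced non-positive scales")
    z = eta + scale * eps
    if spec.z_range is not None:
        z = np.clip(z, spec.z_range[0], spec.z_range[1])
    return pd.DataFrame({
        "haz": z,
        "stunted": (z <= -2.0).astype(int),
        "severely_stunted": (z <= -3.0).astype(int),
    })


def simulate_cohort(spec: ScenarioSpec, graph: RegionGraph | None = None) -> pd.DataFrame:
    """Covariates + planted predictor + outcome (+ optional missingness)."""
    table = generate_covariates(spec, graph)
    eta = true_predictor(table, spec)
    out = generate_outcome(eta, spec, table)
    table = pd.concat([table, out], axis=1)
    if spec.missingness:
        rng = _rng(spec.seed, _MISSING_STAGE)
        for col, p in spec.missingness.items():
            mask = rng.random(len(table)) < p
            if mask.any():
                table[col] = table[col].astype(object)
                table.loc[mask, col] = np.nan
    return table


# ---------------------------------------------------------------------------
# canonical scenarios

def grid_surface_effect(graph: RegionGraph, amplitude: float = 0.4) -> dict[str, float]:
    """A smooth, centered surface over the graph's lattice positions, used as
    the planted regional truth for spatial recovery."""
    if graph.positions is None:
        raise ValueError("graph has no layout positions")
    xs = np.array([graph.positions[r][0] for r in graph.region_ids])
    ys = np.array([graph.positions[r][1] for r in graph.region_ids])
    sx = xs / max(xs.max(), 1.0)
    sy = ys / max(ys.max(), 1.0)
    vals = amplitude * (np.sin(np.pi * sx) * np.cos(np.pi * sy) + 0.5 * sx)
    vals = vals - vals.mean()
    return dict(zip(graph.region_ids, vals))


def _maternal_age_curve(scale: float = 0.02) -> Callable[[np.ndarray], np.ndarray]:
    """Rises linearly to 30 y, plateaus, declines from 45 y (inverse-U)."""
    def f(a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        return scale * (np.minimum(a, 30.0) - 30.0) - 2.0 * scale * np.maximum(a - 45.0, 0.0)
    return f


def nfhs_like_scenario(n: int = 12176, seed: int = 0, *, heteroscedastic: bool = False,
                       missingness: Mapping[str, float] | None = None) -> tuple[ScenarioSpec, RegionGraph]:
    """The default survey-like cohort.

    Marginals follow the published survey's variable table: ~52/48 sex split,
    five wealth quintiles, 1.1% twins, three breastfeeding categories,
    29 regions, maternal age/BMI with the stated moments.  Planted effects
    use the published magnitudes (girl +0.166, richest +0.224, twin −0.866,
    HAZ falling by 2 units over months 0–24, an inverse-U maternal-age
    curve, a sign-switching age-varying breastfeeding curve, a smooth
    regional surface).  Noise sigma 1.68 makes the marginal Z-score sd about
    1.79 and the stunting prevalence about 37% (severe about 17%).
    """
    graph = make_region_graph("grid", 29)
    covs = (
        CovariateDef("child_age", "continuous", distribution="uniform",
                     params={"low": 0.0, "high": 24.0}),
        CovariateDef("sex", "categorical", ("male", "female"), (0.519, 0.481)),
        CovariateDef("mother_age", "continuous", distribution="truncnorm",
                     params={"mean": 25.66, "sd": 5.21, "low": 15.0, "high": 49.0}),
        CovariateDef("mother_bmi", "continuous", distribution="truncnorm",
                     params={"mean": 20.10, "sd": 3.26, "low": 12.04, "high": 40.34}),
        CovariateDef("wealth", "categorical",
                     ("poorest", "poorer", "middle", "richer", "richest"),
                     (0.179, 0.183, 0.202, 0.224, 0.212)),
        CovariateDef("twin", "categorical", ("no", "yes"), (0.989, 0.011)),
        CovariateDef("breastfeeding", "categorical",
                     ("none", "bf_complementary", "exclusive"), (0.130, 0.776, 0.094)),
        CovariateDef("food_diversity", "categorical",
                     ("low", "medium", "high"), (0.588, 0.285, 0.127)),
        CovariateDef("region", "spatial"),
    )
    mat = _maternal_age_curve(0.02)
    bmi_eff = lambda b: 0.04 * (np.minimum(b, 25.0) - 20.1) + 0.01 * (np.maximum(b, 25.0) - 25.0)
    effects: dict[str, Effect] = {
        "child_age": lambda a: -(a - 12.0) / 12.0,
        "sex": {"female": 0.166},
        "mother_age": lambda a: mat(a) - np.mean(mat(np.array([25.66]))),
        "mother_bmi": bmi_eff,
        "wealth": {"poorer": 0.025, "middle": 0.058, "richer": 0.089, "richest": 0.224},
        "twin": {"yes": -0.866},
        "breastfeeding": VaryingEffect("child_age", {
            "bf_complementary": lambda a: 0.25 * (1.0 - a / 10.5),
            "exclusive": lambda a: 0.35 * (1.0 - a / 10.5),
        }),
        "food_diversity": {"medium": 0.05, "high": 0.1},
        "region": grid_surface_effect(graph, 0.3),
    }
    noise = NoiseSpec(sigma=1.68)
    if heteroscedastic:
        noise = NoiseSpec(
            model="heteroscedastic", sigma=1.68,
            scale_function=lambda t: np.where(t["sex"] == "female", 1.4, 1.0),
        )
    # intercept = target marginal HAZ mean (-1.37) minus the analytic mean of
    # the planted effects under the covariate laws (~ +0.14), so the cohort
    # reproduces the survey's marginal moments and ~37% stunting
    spec = ScenarioSpec(
        n=n, seed=seed, covariate_specs=covs, effect_functions=effects,
        noise=noise, intercept=-1.51, missingness=missingness or {},
        z_range=(-6.0, 6.0),
    )
    spec.validate()
    return spec, graph


def recovery_scenario(n: int = 2000, seed: int = 0) -> tuple[ScenarioSpec, RegionGraph]:
    """Parameter-recovery cohort: the three published categorical effect
    magnitudes (girl +0.166, richest +0.224, twin −0.866), one null
    categorical covariate, a linear age trend and a regional surface.

    Noise sigma 0.5: the power computation behind this choice must account
    for boosting shrinkage — at the cross-validated stopping iteration the
    fitted categorical coefficients sit at roughly half to two-thirds of
    their planted magnitudes, so the normal-theory detection calculation is
    run at an effective effect size of half the planted one.  For the
    weakest effect (richest-vs-poorest +0.224 with ~18%/21% quintile shares)
    that calculation requires sigma <= 0.55 for >= 0.9 detection at
    n = 2000; sigma = 0.5 is the round value inside that bound.
    """
    graph = make_region_graph("grid", 29)
    covs = (
        CovariateDef("child_age", "continuous", distribution="uniform",
                     params={"low": 0.0, "high": 24.0}),
        CovariateDef("sex", "categorical", ("male", "female"), (0.519, 0.481)),
        CovariateDef("wealth", "categorical",
                     ("poorest", "poorer", "middle", "richer", "richest"),
                     (0.179, 0.183, 0.202, 0.224, 0.212)),
        CovariateDef("twin", "categorical", ("no", "yes"), (0.989, 0.011)),
        CovariateDef("null_cat", "categorical", ("a", "b"), (0.5, 0.5)),
        CovariateDef("region", "spatial"),
    )
    effects: dict[str, Effect] = {
        "child_age": lambda a: -(a - 12.0) / 12.0,
        "sex": {"female": 0.166},
        "wealth": {"poorer": 0.025, "middle": 0.058, "richer": 0.089, "richest": 0.224},
        "twin": {"yes": -0.866},
        "region": grid_surface_effect(graph, 0.25),
    }
    spec = ScenarioSpec(n=n, seed=seed, covariate_specs=covs,
                        effect_functions=effects, noise=NoiseSpec(sigma=0.5),
                        intercept=-1.37)
    spec.validate()
    return spec, graph


def shape_scenario(n: int = 2000, seed: int = 0, *, curve_scale: float = 0.12,
                   n_nuisance: int = 6) -> tuple[ScenarioSpec, RegionGraph | None]:
    """Shape-recovery cohort: an inverse-U maternal-age curve, a purely
    linear education effect, and several null continuous covariates.

    The curve slope (0.12 Z-units per year up to age 30) puts the curve's
    spread on the order of the noise sd (0.5) — the regime where the shape
    of an effect, rather than its mere detection, is the estimation
    question.  The null covariates make the candidate set realistically
    crowded, so selection behaviour can be read off the fitted path.
    """
    covs = [
        CovariateDef("mother_age", "continuous", distribution="truncnorm",
                     params={"mean": 25.66, "sd": 5.21, "low": 15.0, "high": 49.0}),
        CovariateDef("education", "continuous", distribution="uniform",
                     params={"low": 0.0, "high": 20.0}),
    ]
    covs += [CovariateDef(f"noise{j}", "continuous", distribution="uniform",
                          params={"low": 0.0, "high": 1.0})
             for j in range(n_nuisance)]
    mat = _maternal_age_curve(curve_scale)
    effects: dict[str, Effect] = {
        "mother_age": mat,
        "education": lambda e: 0.05 * (e - 10.0),
    }
    spec = ScenarioSpec(n=n, seed=seed, covariate_specs=tuple(covs),
                        effect_functions=effects, noise=NoiseSpec(sigma=0.5))
    spec.validate()
    return spec, None


def spatial_scenario(n: int = 2000, seed: int = 0, k: int = 29) -> tuple[ScenarioSpec, RegionGraph]:
    """Spatial-recovery cohort: a smooth planted surface over a k-region
    lattice plus one linear nuisance covariate."""
    graph = make_region_graph("grid", k)
    covs = (
        CovariateDef("child_age", "continuous", distribution="uniform",
                     params={"low": 0.0, "high": 24.0}),
        CovariateDef("region", "spatial"),
    )
    effects: dict[str, Effect] = {
        "child_age": lambda a: -(a - 12.0) / 12.0,
        "region": grid_surface_effect(graph, 0.4),
    }
    spec = ScenarioSpec(n=n, seed=seed, covariate_specs=covs,
                        effect_functions=effects, noise=NoiseSpec(sigma=0.8))
    spec.validate()
    return spec, graph
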