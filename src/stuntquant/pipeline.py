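"""End-to-end analysis pipeline.

Stages: load the child-level table, apply the exclusion cascade (records with
a missing outcome first, then listwise deletion on the declared covariates),
derive the binary stunting indicators, fit the six boosted models (quantile
regression at tau in {0.05, 0.15, 0.35, 0.50} plus logistic models for
stunting and severe stunting, all with the same flexible additive predictor),
run bootstrap inference, and emit effect tables, per-region spatial effects,
per-term curves and a cross-model concordance report.

A single integer seed fixes everything downstream: CV fold assignment,
selection tie-breaks (deterministic by learner order) and bootstrap resamples
all derive their seeds from it at fixed stage offsets.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import learners as L
from .boosting import (PAPER_TAUS, BoostedModel, CVResult, LossSpec, boost,
                       cross_validate_mstop, default_cv_grid)
from .inference import (BootstrapEnsemble, EffectSummary, bootstrap_fit,
                        ci_categorical, significance_continuous, spatial_effects)
from .scenario import RegionGraph

__all__ = [
    "ModelConfig",
    "ExclusionReport",
    "ResultBundle",
    "load_table",
    "apply_exclusions",
    "binarize",
    "build_learners",
    "run_full_analysis",
    "report",
    "paper_preset",
]

log = logging.getLogger("stuntquant")

Z_RANGE = (-6.0, 6.0)
STUNTED_CUT = -2.0
SEVERE_CUT = -3.0

# seed stage offsets
_CV_OFFSET = 101
_BOOT_OFFSET = 10_000


@dataclass
class ModelConfig:
    """Covariate roles and estimation settings for the full analysis."""

    covariates: dict[str, dict]          # name -> {kind, reference?, modifier?}
    outcome: str = "haz"
    region_column: str = "region"
    quantiles: tuple[float, ...] = PAPER_TAUS
    fit_logistic: bool = True
    nu: float = 0.2
    df: float = L.DEFAULT_DF
    knots: int = L.DEFAULT_KNOTS
    B: int = 100
    folds: int = 5
    cv_grid: tuple[int, ...] = field(default_factory=default_cv_grid)
    seed: int = 1
    age_column: str | None = None
    age_range: tuple[float, float] = (0.0, 24.0)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        # YAML 1.1 reads bare yes/no as booleans; survey category labels
        # are strings, so map them back
        def unbool(v):
            if isinstance(v, bool):
                return "yes" if v else "no"
            return v
        for role in doc.get("covariates", {}).values():
            if "reference" in role:
                role["reference"] = unbool(role["reference"])
            if "levels" in role:
                role["levels"] = [unbool(l) for l in role["levels"]]
        grid = doc.pop("cv_grid", None)
        if isinstance(grid, dict):
            doc["cv_grid"] = default_cv_grid(grid.get("max", 2500), grid.get("step", 25))
        elif grid is not None:
            doc["cv_grid"] = tuple(int(g) for g in grid)
        for key in ("quantiles", "age_range"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def declared_columns(self) -> list[str]:
        return [self.outcome] + list(self.covariates)

    def continuous_columns(self) -> list[str]:
        cols = [self.outcome]
        for name, role in self.covariates.items():
            if role.get("kind") == "continuous":
                cols.append(name)
        return cols


def paper_preset(covariates: dict[str, dict], **overrides) -> ModelConfig:
    """The replication settings: tau in {0.05, 0.15, 0.35, 0.50}, nu = 0.2,
    B = 100 bootstrap samples, 5-fold CV."""
    cfg = dict(covariates=covariates, quantiles=PAPER_TAUS, nu=0.2, B=100, folds=5)
    cfg.update(overrides)
    return ModelConfig(**cfg)


def load_table(path, config: ModelConfig) -> tuple[pd.DataFrame, dict]:
    """Read the child-level CSV.  Declared columns must exist; unparseable
    numeric cells become missing (counted); outcome values outside [−6, 6]
    reject the record (counted)."""
    table = pd.read_csv(path)
    missing_cols = [c for c in config.declared_columns() if c not in table.columns]
    if missing_cols:
        raise ValueError(f"declared columns absent from {path}: {missing_cols}")
    if "weight" in table.columns:
        warnings.warn("survey weight column present; weights are not used",
                      stacklevel=2)
    report: dict = {"n_read": len(table), "unparseable_cells": 0}
    for col in config.continuous_columns():
        raw = table[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        report["unparseable_cells"] += int((coerced.isna() & raw.notna()).sum())
        table[col] = coerced
    z = table[config.outcome]
    out_of_range = z.notna() & ((z < Z_RANGE[0]) | (z > Z_RANGE[1]))
    report["n_rejected_outcome_range"] = int(out_of_range.sum())
    table = table.loc[~out_of_range].reset_index(drop=True)
    if config.age_column:
        age = table[config.age_column].dropna()
        lo, hi = config.age_range
        if len(age) and (age.min() < lo or age.max() > hi):
            raise ValueError(f"{config.age_column} outside [{lo}, {hi}]")
    report["n_loaded"] = len(table)
    log.info("load_table: read %d, rejected %d out-of-range outcomes",
             report["n_read"], report["n_rejected_outcome_range"])
    return table, report


@dataclass(frozen=True)
class ExclusionReport:
    n_start: int
    n_missing_outcome: int
    n_missing_covariates: int
    n_final: int

    @property
    def missing_proportion(self) -> float:
        return (self.n_missing_outcome + self.n_missing_covariates) / self.n_start


def apply_exclusions(table: pd.DataFrame, config: ModelConfig) -> tuple[pd.DataFrame, ExclusionReport]:
    """Exclusion cascade in the fixed order: first drop records with a
    missing outcome, then listwise-delete on the declared covariates."""
    n_start = len(table)
    has_outcome = table[config.outcome].notna()
    step1 = table.loc[has_outcome]
    n_missing_outcome = n_start - len(step1)
    covs = list(config.covariates)
    complete = step1[covs].notna().all(axis=1) if covs else pd.Series(True, index=step1.index)
    final = step1.loc[complete].reset_index(drop=True)
    n_missing_cov = len(step1) - len(final)
    rep = ExclusionReport(n_start, n_missing_outcome, n_missing_cov, len(final))
    if rep.n_final == 0:
        warnings.warn("exclusion cascade removed every record", stacklevel=2)
    log.info("exclusions: %d -> %d (missing outcome %d, missing covariates %d)",
             n_start, rep.n_final, n_missing_outcome, n_missing_cov)
    return final, rep


def binarize(table: pd.DataFrame, config: ModelConfig | None = None) -> pd.DataFrame:
    """Derive stunted (Z <= −2) and severely stunted (Z <= −3) indicators;
    the thresholds are non-strict."""
    outcome = config.outcome if config else "haz"
    z = table[outcome]
    table = table.copy()
    table["stunted"] = (z <= STUNTED_CUT).astype(int)
    table["severely_stunted"] = (z <= SEVERE_CUT).astype(int)
    return table


def build_learners(config: ModelConfig, table: pd.DataFrame,
                   graph: RegionGraph | None = None) -> list[L.BaseLearner]:
    """Translate covariate roles into base learners: categorical dummies,
    linear + smooth-deviation P-spline pairs, per-level age-varying terms,
    and the Laplacian-penalized spatial term.  Learner order is the config
    order; ties in boosting break toward earlier entries."""
    built: list[L.BaseLearner] = []
    cont_specs: dict[str, L.CovariateSpec] = {}
    for name, role in config.covariates.items():
        if role.get("kind") == "continuous":
            x = table[name].astype(float)
            cont_specs[name] = L.CovariateSpec(
                name, "continuous", knots=config.knots,
                range=(float(x.min()), float(x.max())), center=float(x.mean()),
            )
    for name, role in config.covariates.items():
        kind = role.get("kind")
        if kind == "categorical":
            levels = tuple(role.get("levels") or sorted(table[name].dropna().unique()))
            spec = L.CovariateSpec(name, "categorical", levels=levels,
                                   reference_level=role.get("reference"))
            built.append(L.build_categorical_learner(spec, config.df))
        elif kind == "continuous":
            lin, smooth = L.build_pspline_learner(cont_specs[name], config.df)
            built.extend([lin, smooth])
        elif kind == "varying":
            modifier = role["modifier"]
            if modifier not in cont_specs:
                x = table[modifier].astype(float)
                cont_specs[modifier] = L.CovariateSpec(
                    modifier, "continuous", knots=config.knots,
                    range=(float(x.min()), float(x.max())), center=float(x.mean()))
            levels = tuple(role.get("levels") or sorted(table[name].dropna().unique()))
            group = L.CovariateSpec(name, "varying", levels=levels,
                                    reference_level=role.get("reference"))
            for level in levels:
                if level != group.reference:
                    built.append(L.build_varying_learner(
                        cont_specs[modifier], group, level, config.df))
        elif kind == "spatial":
            if graph is None:
                raise ValueError(f"{name}: spatial covariate needs a region graph")
            built.append(L.build_spatial_learner(graph, config.df, column=name))
        else:
            raise ValueError(f"{name}: unknown covariate kind {kind!r}")
    return built


@dataclass
class ModelResult:
    name: str
    loss: LossSpec
    mstop: int
    cv: CVResult
    model: BoostedModel
    ensemble: BootstrapEnsemble
    summaries: list[EffectSummary]
    spatial: pd.DataFrame | None


@dataclass
class ResultBundle:
    config: ModelConfig
    models: dict[str, ModelResult]
    concordance: pd.DataFrame
    failures: dict[str, str]
    manifest: dict


def _model_plan(config: ModelConfig) -> list[tuple[str, LossSpec, str]]:
    plan = [(f"quantile_{tau:g}", LossSpec("quantile", tau), config.outcome)
            for tau in config.quantiles]
    if config.fit_logistic:
        plan.append(("logistic_stunted", LossSpec("binomial"), "stunted"))
        plan.append(("logistic_severely_stunted", LossSpec("binomial"), "severely_stunted"))
    return plan


def _summarize_model(config: ModelConfig, table: pd.DataFrame,
                     model: BoostedModel, ensemble: BootstrapEnsemble) -> list[EffectSummary]:
    out: list[EffectSummary] = []
    for name, role in config.covariates.items():
        kind = role.get("kind")
        if kind == "categorical":
            levels = tuple(role.get("levels") or sorted(table[name].dropna().unique()))
            ref = role.get("reference") or levels[0]
            for level in levels:
                if level != ref:
                    out.append(ci_categorical(ensemble, model, name, level))
        elif kind == "continuous":
            x = table[name].astype(float)
            out.append(significance_continuous(
                ensemble, model, name, (float(x.min()), float(x.max()))))
        elif kind == "varying":
            modifier = role["modifier"]
            a = table[modifier].astype(float)
            levels = tuple(role.get("levels") or sorted(table[name].dropna().unique()))
            ref = role.get("reference") or levels[0]
            for level in levels:
                if level != ref:
                    out.append(significance_continuous(
                        ensemble, model, name,
                        (float(a.min()), float(a.max())), level=level))
    return out


def run_full_analysis(table: pd.DataFrame, config: ModelConfig,
                      graph: RegionGraph | None = None) -> ResultBundle:
    """CV-select mstop, fit, and bootstrap every model of the plan, then
    build per-model effect summaries and the cross-model concordance table.
    Models that fail are recorded in the bundle's failure manifest; the rest
    are still returned."""
    learners = build_learners(config, table, graph)
    results: dict[str, ModelResult] = {}
    failures: dict[str, str] = {}
    for i, (name, loss, ycol) in enumerate(_model_plan(config)):
        t0 = time.time()
        try:
            y = table[ycol].to_numpy(dtype=float)
            cv = cross_validate_mstop(table, y, learners, loss,
                                      folds=config.folds, grid=config.cv_grid,
                                      seed=config.seed + _CV_OFFSET + i,
                                      nu=config.nu)
            model = boost(table, y, learners, loss, mstop=cv.mstop, nu=config.nu)
            ensemble = bootstrap_fit(table, ycol, learners, loss,
                                     mstop=cv.mstop, nu=config.nu, B=config.B,
                                     seed=config.seed + _BOOT_OFFSET * (i + 1))
            summaries = _summarize_model(config, table, model, ensemble)
            spatial = None
            if any(r.get("kind") == "spatial" for r in config.covariates.values()):
                spatial = spatial_effects(model)
            results[name] = ModelResult(name, loss, cv.mstop, cv, model,
                                        ensemble, summaries, spatial)
            log.info("model %s: mstop*=%d, fitted in %.1fs",
                     name, cv.mstop, time.time() - t0)
        except Exception as exc:
            failures[name] = str(exc)
            log.warning("model %s failed: %s", name, exc)
    concordance = _concordance(results)
    manifest = {
        "seed": config.seed,
        "n": len(table),
        "models": {k: {"mstop": v.mstop, "loss": v.loss.label, "B": v.ensemble.B}
                   for k, v in results.items()},
        "failures": failures,
    }
    return ResultBundle(config, results, concordance, failures, manifest)


def _concordance(results: dict[str, ModelResult]) -> pd.DataFrame:
    """Compare the tau = 0.35 quantile model with the stunting logistic
    model: concordant findings have opposite signs (a higher Z-score quantile
    means lower stunting odds)."""
    qname, lname = "quantile_0.35", "logistic_stunted"
    if qname not in results or lname not in results:
        return pd.DataFrame()
    rows = []
    qsum = {(s.covariate, s.level): s for s in results[qname].summaries}
    lsum = {(s.covariate, s.level): s for s in results[lname].summaries}
    for key, qs in qsum.items():
        ls = lsum.get(key)
        if ls is None or qs.grid is not None:
            continue
        rows.append({
            "covariate": key[0], "level": key[1],
            "estimate_q35": qs.point, "significant_q35": qs.significant,
            "estimate_logit": ls.point, "significant_logit": ls.significant,
            "signs_opposite": bool(qs.point * ls.point < 0),
            "significance_agrees": qs.significant == ls.significant,
        })
    return pd.DataFrame(rows)


def _summary_frame(summaries: list[EffectSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        if s.grid is None:
            rows.append({"covariate": s.covariate, "level": s.level,
                         "estimate": s.point, "ci_lower": s.ci_lower,
                         "ci_upper": s.ci_upper, "significant": s.significant,
                         "shape_label": ""})
        else:
            rows.append({"covariate": s.covariate, "level": s.level or "",
                         "estimate": float(np.ptp(s.point)),
                         "ci_lower": np.nan, "ci_upper": np.nan,
                         "significant": s.significant,
                         "shape_label": s.shape_label})
    return pd.DataFrame(rows)


def report(bundle: ResultBundle, outdir) -> list[Path]:
    """Write per-model effect tables, per-region spatial effects, per-term
    curves, the concordance table and the JSON run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit_csv(frame: pd.DataFrame, name: str) -> None:
        path = outdir / name
        frame.to_csv(path, index=False)
        written.append(path)

    for name, res in bundle.models.items():
        emit_csv(_summary_frame(res.summaries), f"effects_{name}.csv")
        if res.spatial is not None:
            emit_csv(res.spatial, f"spatial_{name}.csv")
        curve_rows = []
        for s in res.summaries:
            if s.grid is not None:
                for g, pt, lo, hi in zip(s.grid, s.point, s.ci_lower, s.ci_upper):
                    curve_rows.append({"covariate": s.covariate,
                                       "level": s.level or "", "x": g,
                                       "effect": pt, "ci_lower": lo, "ci_upper": hi})
        if curve_rows:
            emit_csv(pd.DataFrame(curve_rows), f"curves_{name}.csv")
    if len(bundle.concordance):
        emit_csv(bundle.concordance, "concordance.csv")
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True))
    written.append(manifest_path)
    return written
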