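# stuntquant

Boosted additive quantile regression for the determinants of child stunting,
with a synthetic survey-cohort generator for validating the whole pipeline by
parameter recovery.

## The problem

Child stunting (height-for-age Z-score, HAZ, at or below −2; severe stunting
at or below −3) is the canonical marker of chronic undernutrition. Survey
analyses of its determinants usually dichotomize the Z-score and fit a
logistic regression, discarding information and any hope of seeing whether a
risk factor acts differently in the lower tail of the growth distribution.
This package implements the alternative: **additive quantile regression
estimated by component-wise gradient boosting**, which models

```
Q_Y(τ | x, z, s) = η_τ(x, z, s)
η_τ = β_0 + Σ_j β_j x_j + Σ_k f_k(z_k) + Σ_l f_age,l(age)·1[feed = l] + f_spat(s)
```

for quantile levels τ ∈ {0.05, 0.15, 0.35, 0.50} — categorical covariates
enter linearly against a reference level, continuous covariates as penalized
splines (P-splines) decomposed into a linear part and a smooth deviation so
the linear/non-linear decision is data-driven, feeding variables as
age-varying coefficient curves, and the region `s` as a Gaussian Markov
random field smoothed over the neighbourhood graph. Matched logistic models
(same predictor, binomial loss) are fitted for stunting and severe stunting.

Estimation is component-wise functional gradient descent: at each iteration
every base learner is fitted by penalized least squares to the negative
gradient of the check loss ρ_τ (or the binomial deviance), and only the best
one is updated with step length ν = 0.2. The iteration count `mstop` is the
regularization knob, chosen by five-fold cross-validation. Because boosting
yields no standard errors, 95% confidence intervals come from refitting on
bootstrap resamples, and significance follows resampling rules: a CI
excluding zero (categorical), or all replicate curves sharing a sign on some
interval (smooth terms).

The intended users are biostatisticians and epidemiologists who want this
model class as a tested library — or who want to study its behaviour
(selection bias, shrinkage, coverage, spatial smoothing) on cohorts with
known planted truth before trusting it on survey data.

## Worked example

```python
import numpy as np
import stuntquant as sq
from stuntquant.boosting import LossSpec
from stuntquant.inference import bootstrap_fit, ci_categorical

spec, graph = sq.recovery_scenario(n=3000, seed=1)   # planted truth known
table = sq.simulate_cohort(spec, graph)

roles = {
    "child_age": {"kind": "continuous"},
    "sex":    {"kind": "categorical", "reference": "male",
               "levels": ["male", "female"]},
    "wealth": {"kind": "categorical", "reference": "poorest",
               "levels": ["poorest", "poorer", "middle", "richer", "richest"]},
    "twin":   {"kind": "categorical", "reference": "no", "levels": ["no", "yes"]},
    "region": {"kind": "spatial"},
}
config = sq.ModelConfig(covariates=roles, seed=1)
learners = sq.build_learners(config, table, graph)

y = table["haz"].to_numpy()
loss = LossSpec("quantile", 0.35)
cv = sq.cross_validate_mstop(table, y, learners, loss, folds=5,
                             grid=tuple(range(0, 1501, 25)), seed=11)
model = sq.boost(table, y, learners, loss, mstop=cv.mstop, nu=0.2)
ens = bootstrap_fit(table, "haz", learners, loss, mstop=cv.mstop,
                    nu=0.2, B=40, seed=900)
print(ci_categorical(ens, model, "sex", "female"))
```

Running the bundled driver `python analysis/04_bootstrap_inference.py`
prints exactly this analysis (with one extra null covariate):

```
mstop* = 200, B = 40
covariate level       planted     est            95% CI  sig
sex       female        0.166   0.162  [ 0.108,  0.218]  True
wealth    richest       0.224   0.136  [ 0.037,  0.187]  True
twin      yes          -0.866  -0.741  [-0.839, -0.372]  True
null_cat  b             0.000   0.000  [-0.015,  0.019]  False
child_age curve: linear-, significant=True, span 1.94 Z-units
```

Reading it: the planted girl-vs-boy shift of +0.166 Z-units on the 35%
quantile is estimated at +0.162 with a CI excluding zero; the twin effect is
recovered with the boosting shrinkage typical of CV-stopped fits (−0.74 vs
−0.87 planted) but is unambiguously significant; the null covariate is left
alone; and the fitted child-age curve is classified as a declining
near-linear trend spanning about 2 Z-units over months 0–24, as planted.

The numbered scripts under `analysis/` tell the full story in order:
cohort generation (`01`), the exclusion cascade and prevalence arithmetic
(`02`), the four quantile fits (`03`), bootstrap inference (`04`) and the
quantile-vs-logistic comparison (`05`); outputs land under `results/`.

A CLI wraps the same library: `stuntquant simulate | fit | run | report`
(see `stuntquant --help`).

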