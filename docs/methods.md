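# Methods

## Model

For a child-level table with continuous HAZ outcome Y, categorical
covariates x, continuous covariates z, feeding categories interacting with
child age, and a region label s, the conditional τ-quantile is modelled as

    Q_Y(τ | ·) = β_0τ + Σ_j β_jτ x_j + Σ_k f_kτ(z_k)
               + Σ_l f_age,lτ(age) · 1[feed = l] + f_spat,τ(s).

Each τ is fitted independently (no crossing correction: crossing on new data
is possible and is reported, not repaired). The matched binary models use
the same predictor with the binomial deviance; their coefficients live on
the log-odds scale, so a risk factor that raises a Z-score quantile should
lower the stunting log-odds — concordance between model families means
*opposite* signs.

## Base learners

Every term of the predictor is one penalized least-squares base learner: a
design rule X, a penalty K, and a weight λ.

* **Categorical**: dummy coding against a declared reference level. Ridge
  penalty (K = I) only when the number of non-reference levels exceeds the
  effective-df budget; otherwise unpenalized.
* **P-spline, decomposed**: cubic B-splines on 20 equally spaced interior
  knots over the observed range (basis dimension 24), second-order
  difference penalty — the standard P-spline configuration. The term is
  split into (i) an unpenalized *linear part*, the mean-centered covariate
  (1 df), and (ii) a *smooth deviation*: the basis is mapped through the
  spectral reparameterization of the difference penalty (the 22 penalized
  eigendirections, identity penalty) and then residualized against
  span{1, z} on the fitted rows, so its fits are exactly orthogonal to
  anything the linear part can produce. Component-wise selection between
  the two parts is the data-driven linear/non-linear decision. The
  residualization matrix is frozen at fit time so prediction on new data is
  well-defined.
* **Varying coefficient**: the same B-spline basis in child age, rows gated
  by the 0/1 indicator of one non-reference feeding level (one learner per
  level); difference penalty on the spline coefficients. Records outside
  the level contribute exactly zero; the basis spans constants, so a pure
  level shift is representable.
* **Spatial**: region indicator columns penalized by the neighbourhood-graph
  Laplacian (the intrinsic Gaussian-Markov-random-field penalty); fitted
  regional effects are shrunk toward their neighbours' average, and the
  constant direction (the Laplacian null space) is unpenalized. Reported
  regional effects are centered to mean zero; the level belongs to the
  offset.

### Effective-df calibration

To keep base-learner selection unbiased, each penalizable learner's λ is
calibrated so that trace S(λ) = df with S(λ) = X(XᵀX + λK)⁻¹Xᵀ. The trace is
computed in a numerically safe dual form: splitting coefficients into the
penalty's null space (contributing its rank at every λ) and the
penalty-whitened complement projected off the null-space fit, the trace is
`base + Σ d_i/(d_i + λ)` with d_i ≥ 0 the eigenvalues of the whitened,
projected Gram matrix. This stays finite and monotone even when the design
itself is rank-deficient (B-spline columns with no data in a sparse tail).
λ is solved by bisection in log λ to a trace tolerance of 1e-4, well inside
the 0.01 contract; calibration is re-run on every dataset a learner is
prepared on (full data, CV folds, bootstrap resamples), so the df contract
holds per fit. The default common budget is **df = 4**; decomposition linear
parts carry 1 df — exact equality across all learners is impossible once
1-df linear parts exist, a known compromise of this design (see the shape
experiment below for where it matters).

## Boosting

Offset: the empirical τ-quantile of y (linear interpolation of order
statistics) or the outcome log-odds. Per iteration: negative gradient u of
the loss at the current predictor (check loss: u_i = τ if y_i − η_i > 0 else
τ − 1, with exact ties taking the τ − 1 branch — a declared convention;
ties have probability zero for continuous outcomes); every learner fitted
to u; the learner with minimal SSE updated by ν = 0.2 times its fitted
coefficients; ties in SSE break toward the earlier learner in config order,
making runs reproducible. `mstop` is selected by five-fold CV on a
checkpoint grid (default every 25 iterations from 0 — the offset-only
model — to 2500), minimizing mean held-out risk with ties to the smallest
checkpoint. One integer seed fixes fold assignment, bootstrap resamples and
everything downstream.

### What the boosting path does and does not guarantee

For the smooth binomial loss, the damped functional gradient descent
converges to the logistic MLE (agreement with an independent Newton solver
to ~1e-6 in the tests). For the non-differentiable check loss, *greedy
per-coordinate* selection can come to rest at coordinate-wise stationary
points that are not the joint minimizer: risk within ~1e-4 of the optimum
but individual coefficients off by up to several hundredths, because no
single-coordinate move improves a piecewise-linear objective along a flat
valley. This is the classical failure mode of coordinate descent on
non-smooth, non-separable functions, not an implementation artifact. The
oracle-equivalence check against the exact LP minimizer therefore uses a
single joint linear base learner (all covariates plus intercept in one
term), under which the engine performs full-gradient descent and matches the
LP solution to well under 0.01 per coefficient; the component-wise
configuration is pinned to what it actually guarantees — risk-level
optimality. A practical consequence: extreme-tail fits (τ = 0.05) converge
slowly and need mstop in the thousands when flexible learners compete.

## Bootstrap inference

B resamples with replacement of size n (default B = 100; replicate b seeds
its resampling generator at seed + b), each refitted with `mstop` **fixed**
at the full-data CV choice — re-running CV inside every replicate would be
five times costlier for little gain, and the fixed-mstop ensemble is the
design the CIs describe. Percentile CIs use the Weibull (type 6) order-
statistic interpolation, under which the 2.5% bound with B = 100
interpolates between the 2nd and 3rd smallest replicate values. Significance
rules: a categorical level is significant when its 95% CI excludes zero; a
smooth or age-varying effect when **all** replicate curves are strictly
positive (or all strictly negative) on at least two consecutive points of a
shared 100-point grid. The "shared interval" reading is the default; a
per-replicate-interval reading is available behind `common_interval=False`.
Shape labels (linear±, inverse-U, U, monotone±, constant) are assigned by
declared rules — straight-line R² ≥ 0.95 ⇒ linear; otherwise the sign
pattern of first differences — and are descriptive only.

## The synthetic generator

`ScenarioSpec` declares covariate laws (categorical frequencies, truncated
normal or uniform continuous laws, region labels on a lattice graph),
planted effect functions (per-level coefficients, tabulated or callable
curves, age-varying curves per feeding level, per-region surfaces), a noise
model, and optional MCAR missingness. Under iid noise, Z = η + σε with ε
symmetric, so the true conditional τ-quantile is η + σF⁻¹(τ) for every τ —
all quantile curves share one shape, the regime in which quantile and
logistic results must agree up to sign. The heteroscedastic variant
multiplies σ by a covariate function, creating genuinely differential
quantile effects for testing that machinery. Stunting indicators use the
non-strict thresholds Z ≤ −2 and Z ≤ −3.

Canonical scenarios (each a one-call constructor, all parameters fixed
here):

* **Survey-like cohort** (`nfhs_like_scenario`, n = 12 176): marginals match
  the published variable table (51.9/48.1 sex split, five wealth quintiles
  at their observed shares, 1.1% twins, three breastfeeding categories,
  29 regions, maternal age/BMI moments), planted effects at the published
  magnitudes (girl +0.166, richest +0.224, twin −0.866, a 2-Z-unit age
  decline over months 0–24, an inverse-U maternal-age curve, a
  sign-switching age-varying breastfeeding curve, a smooth regional
  surface), σ = 1.68 and intercept −1.51 so the marginal HAZ has mean ≈
  −1.37, sd ≈ 1.8, stunting ≈ 37% and severe stunting ≈ 18%. Z-scores are
  clamped to the plausibility range [−6, 6], as growth-standard pipelines
  do.
* **Recovery cohort** (`recovery_scenario`, n = 2000, σ = 0.5): the three
  headline categorical magnitudes plus a null covariate, a linear age
  trend and a regional surface. σ was set by a power computation that
  models boosting shrinkage: at the CV-selected mstop the categorical
  coefficients sit at roughly half their planted size, and requiring ≥ 90%
  CI-detection of the weakest effect (+0.224 between ~18% and ~21% shares)
  at n = 2000 then needs σ ≤ 0.55.
* **Shape cohort** (`shape_scenario`, n = 2000, σ = 0.5): an inverse-U
  maternal-age curve (slope 0.12 Z/y to age 30, plateau, decline from 45 —
  curve sd on the order of the noise sd, the regime where shape rather than
  detection is the question), a purely linear education effect, six null
  continuous covariates.
* **Spatial cohort** (`spatial_scenario`, n = 2000): a smooth planted
  surface over the 29-region lattice plus a linear age nuisance term.

What the generator does **not** emulate: the survey's multi-stage cluster
design, weights and non-response; informative (non-MCAR) missingness;
measurement error in anthropometry; more than ~10 of the 30+ survey
variables. Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the declared data-generating process, not
robustness to survey-design artifacts.

## Validation experiment designs

* **Coverage**: in-sample fraction below the fitted τ-curve within 0.02 of
  τ for all four τ on the survey-like cohort at n = 2000.
* **Detection**: 20 recovery cohorts, B = 40 (scaled from B = 100), mstop
  CV-selected once and shared; each headline effect must be significant in
  ≥ 80% of replicates, the null covariate in ≤ 10%.
* **Shape and data-driven linearity**: five shape cohorts, median
  regression, **common df = 1 across all learners** — with the default
  df = 4 the smooth deviation holds a selection advantage over the 1-df
  linear part and collects noise-phase selections by construction; the
  equal-df configuration is the unbiased-selection setting the boosting
  model-selection literature prescribes, and the linearity-routing question
  is only well-posed there. Summaries are medians over the five cohorts:
  per-cohort routing is bimodal (usually zero, occasionally large when a
  sample's empirical quantile curve genuinely wiggles — CV cannot resolve
  the O(df/n) held-out cost of wiggle-fitting against its O(1/√n) noise
  floor, at any n). Criteria: every cohort classified inverse-U, median
  curve RMSE ≤ 10% of the curve sd (curves compared after centering both to
  sample mean zero, since the level is absorbed by the offset), median
  routing share ≤ 5%.
* **Spatial**: centered fitted regional effects correlate ≥ 0.9 with the
  planted surface at n = 2000 over 29 regions.
* **Concordance**: on five recovery cohorts, the τ = 0.35 and
  logistic-stunting models must give opposite-signed, same-significance
  calls for ≥ 80% of the headline effect-replicate pairs. Effects planted
  at ≤ 0.06 Z-units are excluded from the sign comparison: no n = 2000
  experiment identifies their sign reliably.

Problem sizes throughout (n = 2000–3000, B = 20–40, grids to 1500–2500) are
the package's desk-scale study conditions; the full replication preset
(τ set, ν = 0.2, B = 100, 5 folds) is `paper_preset()` / `--paper-preset`.

## Numerical choices and degenerate inputs

Normal equations are solved by Cholesky with one retry adding
1e-10 × mean-diagonal jitter; a learner whose system stays singular is
skipped for that iteration with a warning. Spline evaluations clamp values
to the knot range. `mstop = 0` yields the offset-only model. A constant
outcome gives offset = that constant and, when an intercept learner is
present to absorb the tie-convention subgradient, zero effects everywhere.
Bootstrap replicates that fail to fit are dropped with a warning; more than
10% dropped is an error. Empty exclusion results warn rather than raise.
Region graphs may be disconnected (warning; the Laplacian penalty remains
valid, with one null dimension per component).

## Known limitations

Greedy component-wise stalls on the check loss (above); slow extreme-tail
convergence; no analytic standard errors by construction; no survey weights
(a `weight` column is accepted and ignored with a warning); no
multiple-testing adjustment, matching the analysis this package reproduces;
tensor-product interactions and monotonicity constraints are out of scope;
the shape classifier approximates what was originally a visual judgement.
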