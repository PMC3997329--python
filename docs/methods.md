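# Methods

## Model

A closed population of `N` animals is trapped on `m` occasions. `Y_ij ∈ {0,1}`
indicates capture of animal `i` on occasion `j`; `T_i = Σ_j Y_ij` is its
capture count and `t_i` its first-capture occasion. Capture probability is
constant over occasions and modelled on individual covariates `x_i` through
the logistic link,

    p_i = h(x_i'β),    h(u) = 1 / (1 + e^{-u}),

an individual-heterogeneity (M_h-type) model; the intercept-only special case
is the equal-catchability model M_0. The probability that animal `i` is
caught at least once is `π_i = 1 − (1 − p_i)^m`. Because covariates are
unknown for animals never caught, all estimation conditions on the `n`
observed animals, and abundance is estimated by the Horvitz–Thompson sum

    N̂ = Σ_{i=1}^{n} 1 / π̂_i .

Its variance combines a binomial term `Σ (1 − π̂_i)/π̂_i²` with a delta-method
term `g' V(β̂) g`, `g = −Σ_i η_i x_i`, where

    η_i = π_i^{-2} · m · p_i · (1 − π_i)

is the sensitivity of `1/π_i` to the linear predictor (`eta_sensitivity`).
The default interval is the nominal-95% Wald interval `N̂ ± 1.96·SE`; a
lognormal interval bounded below by `n` is available (`ci_method="lognormal"`).
The interval form matters only for coverage studies and is reported with every
estimate.

## Estimators

### Quasi-likelihood GEE (`QuasiLikelihoodGEE`)

Capture histories are repeated binary measurements, so β solves estimating
equations over individuals with a working correlation across occasions. Two
occasion-mean formulations are provided:

* **conditional** (default): `μ_ij = p_i/π_i`, the occasion mean given the
  animal was observed at least once — the correct conditioning for
  captured-only data;
* **marginal**: `μ_ij = p_i`, appropriate when the capture/no-capture process
  itself is modelled without the selection step.

With the logistic link and working independence the occasion-level
quasi-score collapses to the simplified form

    U(β) = Σ_i x_i (T_i − m μ_i) = 0,

which for the marginal form is exactly the Bernoulli-GLM score on the
individual×occasion expansion, and for the conditional form is exactly the
score of the conditional (captured-individuals) likelihood. The solver is
Fisher scoring with step-halving on the score norm, starting from β = 0,
converging when the step or score norm falls below `tol` (default 1e-8),
with at most `max_iter = 100` iterations. The model-based covariance is the
inverse conditional information `Σ_i m (∂μ_i/∂u) x_i x_i'`; a sandwich
covariance from the individual score contributions is computed whenever full
histories are available.

Because `μ_ij` is constant within an individual, an exchangeable working
correlation leaves the root unchanged and rescales the model-based covariance
by `1 + (m−1)α̂`; `α̂` is the moment estimator built from within-individual
cross-products of Pearson residuals. Misspecifying the working correlation
therefore affects reported precision, never consistency.

Fits with any fitted `|logit p̂_i| > 10` are flagged as boundary solutions
(effectively p̂ → 0 or 1, e.g. every animal caught on every occasion); the
Monte-Carlo harness excludes and tallies such replicates.

The estimator can be fitted from grouped published totals (`fit_grouped`):
representing each group member by its group-mean capture count leaves `U`
unchanged when the design is a saturated categorical factor, which is how the
chipmunk example (published only as per-sex counts and capture totals) is
analysed. Closed forms used as cross-checks: marginal intercept-only
`p̂_0 = ΣT_i/(nm)`; conditional per-group root of `m p/π(p) = mean captures`
(unique in (0,1) because the left side increases strictly from 1 to m).

### Partial-likelihood GLM (`PartialLikelihoodGLM`)

Conditioning on `t_i`, the number of recaptures after first capture is
binomial, `(T_i − 1) | t_i ~ Bin(m − t_i, p_i)`, giving a likelihood free of
`N` and of the first-capture selection step. The binomial-logit fit is
performed by statsmodels GLM; its inverse observed information is the
coefficient covariance. Animals first caught on the last occasion contribute
zero trials: they are retained (their fitted `π̂` enters N̂) but carry no
likelihood information. The partial likelihood discards the first captures,
so this estimator is less efficient than the GEE above — visibly so at low
capture probabilities.

### Partial-likelihood GLMM (`PartialLikelihoodGLMM`)

Unexplained heterogeneity is modelled by an individual Gaussian random
intercept, `p_i = h(x_i'β + σ_b z_i)`, `z_i ~ N(0,1)`. The default fit is
penalized quasi-likelihood: iterate (1) working response
`ζ_i = η_i + (y_i − n_i p_i)/w_i`, weights `w_i = n_i p_i(1−p_i)`; (2) REML
update of `σ_b²` in the working linear mixed model (one-dimensional bounded
optimisation on log σ²); (3) GLS for β with marginal variance `1/w_i + σ_b²`
and shrinkage BLUP `b̂_i = σ²w_i/(1+σ²w_i)·(ζ_i − x_i'β)`. Convergence is
`1e-6` on all of (β, b, σ_b), at most 200 outer iterations. `σ̂_b = 0`
reduces the fit to the GLM exactly.

The random-intercept variance is equivalent to a ridge penalty with smoothing
parameter `λ = 1/σ_b²`. Alternatives to the REML update:

* `method="gcv"`: λ chosen on a 25-point log grid in [1e-4, 1e4] by
  generalized cross-validation, `GCV(λ) = n·D_λ/(n − edf_λ)²`, where `D_λ` is
  the weighted working-response residual sum of squares (the quadratic
  approximation of the binomial deviance — the raw deviance vanishes together
  with `(n − edf)` as λ → 0 for per-individual intercepts and would make the
  score degenerate) and `edf` is the trace of the working hat matrix. Flat
  score profiles resolve to the smallest λ.
* `method="gh"`: exact marginal maximum likelihood with 20-node Gauss–Hermite
  quadrature. PQL is known to shrink variance components for small binomial
  denominators (we measure σ̂_b ≈ 0.86 at σ_b = 1 with 5–9 trials); the GH
  route has no such approximation bias and serves as the exact-likelihood
  cross-check in the test suite.

Coefficient covariance is the β block of the inverse penalized joint
information over (β, b); the abundance delta-method term propagates both
blocks through gradients `−η_i x_i` and `−η_i`. Predicted effects enter
`π̂_i` at the predicted `ẑ_i` by default (`pi_form="conditional"`); a
Gauss–Hermite marginal option integrates `z` out. Zero-trial individuals get
`ẑ_i = 0` — there is no recapture information to estimate them.

**Caveat — selection on the latent effect.** Among animals observed at least
once, the latent effect is size-biased (catchable animals are
over-represented), and this tilt is not part of the partial-likelihood
conditioning. With the small σ_b = 0.1 of the default generator the effect is
negligible; at σ_b = 1 even exact ML on observed animals recovers σ̂_b ≈ 0.92.
Parameter-recovery tests therefore use binomial random-intercept data
generated without the selection step; the capture-data behaviour of the GLMM
(systematic overestimation of N when capture probabilities are low) is tested
as a qualitative property. The intuition for the overestimation: the fitted
heterogeneity pushes some π̂_i toward small values, and 1/π̂_i is convex, so
extra (partly spurious) heterogeneity inflates N̂ and its spread.

## Synthetic-data generator

`Scenario` defaults encode the study design the package is built around:
sex ~ Bernoulli(0.5); weight ~ Normal(mean 15 g, variance 4); logistic
capture model with sex effect 0.1, weight effect 0.2 g⁻¹ and intercept −3.5 /
−4.0 / −4.5 for the high / medium / low presets (average capture probability
≈ 0.4 / 0.3 / 0.2 at the 15 g reference weight); latent heterogeneity
σ_b = 0.1, drawn once per animal and held constant across occasions.
Captures are independent Bernoulli(p_i) across occasions given p_i:
within-animal dependence enters only through the shared p_i, there are no
occasion (time) effects, no behavioural response to capture, no
misidentification, and the population is closed. Passing tests therefore say
nothing about trap-happy/shy animals, time-varying effort, or open
populations. `analytic_mean_p`/`analytic_pi` are reference-weight quantities;
averaging over the weight distribution lowers π, increasingly so for larger
`m`.

Seeding: one master `SeedSequence`; per-cell and per-replicate streams are
spawned deterministically, so any replicate is reproducible in isolation.

## Monte-Carlo harness

`run_study` simulates each replicate once and fits every requested estimator
on the same observed subset (sex + weight design). Metrics per cell: mean
captured `n̄` (and its SD), mean estimate AVE, Monte-Carlo SD (sample SD,
denominator r−1; at r = 1000 indistinguishable from the r denominator at two
decimals), percentage relative bias PRB = 100(AVE−N)/N, CV = 100·SE/AVE,
RMSE = √(mean (N̂−N)²), and COV, the percentage of nominal-95% Wald intervals
covering the true N, so coverage discrepancies trace to the interval form.
The identity `RMSE² = SE²(r−1)/r + (AVE−N)²` holds exactly for the harness
output and is asserted in the tests. Replicates where an estimator fails
(non-convergence, boundary, singular design) are excluded from that
estimator's metrics and reported in an `excluded` column; with a single
replicate the SD is reported as missing, not zero.

Problem sizes used by the shipped tests and the acceptance script: 1000
replicates per cell for the headline Monte-Carlo means (N ∈ {100, 500},
m ∈ {6, 10}); 400 replicates for the six-cell GEE/GLM RMSE comparison; 300
for the GLMM behaviour check; 100 populations of N = 2000 for GEE coefficient
recovery and 30 datasets of 1500 individuals for GLMM recovery. These sizes
put Monte-Carlo error well below the effects being checked while keeping the
whole suite under a minute of compute.

## Numerical choices

* `π` is computed as `−expm1(m·log1p(−p))` to avoid cancellation at small p.
* Root-finding for the per-group conditional equation uses bracketed Brent on
  (0,1) with `xtol = 1e-14`; group means ≤ 1 or ≥ m return a boundary
  diagnostic instead of a root.
* Fisher scoring uses step-halving (up to 30 halvings) on the score norm.
* Singular information raises an error naming the collinear design terms.
* The λ grid tie-break is "smallest λ"; the GCV selector is exposed
  separately (`gcv_path`) so the selection rule is testable in isolation.
* All reported human-readable numbers are rounded to two decimals; machine
  output keeps full precision.

## Known limitations

* Published grouped summaries support only GEE-type fits; partial-likelihood
  estimators need individual first-capture times and refuse grouped input
  explicitly.
* The sandwich covariance is unavailable for grouped (pseudo-count) fits.
* No time-varying covariates, behavioural-response terms, model averaging, or
  open-population extensions.
* PQL variance components are biased downward for few trials per individual;
  use `method="gh"` when σ_b itself is the quantity of interest.
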