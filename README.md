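# geecr

Closed-population capture–recapture estimation of capture probabilities and
population size, for studies where animals are trapped repeatedly over `m`
occasions and differ in catchability. Heterogeneity is modelled on individual
covariates (sex, weight, …) through a logistic model

    p_i = h(x_i'β),    π_i = 1 − (1 − p_i)^m,

and abundance is estimated from the `n` distinct animals ever caught by the
Horvitz–Thompson estimator `N̂ = Σ 1/π̂_i`, with a delta-method standard
error. Three estimators of β are provided, as scikit-learn-style classes:

| class | idea |
|---|---|
| `QuasiLikelihoodGEE` | estimating equations over individuals treating the `m` occasion indicators as repeated binary measurements, with conditional (`μ = p/π`, default) or marginal (`μ = p`) occasion means and independence or exchangeable working correlation |
| `PartialLikelihoodGLM` | binomial-logit fit of the recaptures after first capture, `(T_i−1) \| t_i ~ Bin(m−t_i, p_i)` |
| `PartialLikelihoodGLMM` | adds a Gaussian individual random intercept `σ_b z_i`, fitted by penalized quasi-likelihood (GCV or exact Gauss–Hermite likelihood optional) |

The package also ships the matching synthetic-data generator (`Scenario`,
`simulate_population`), a Monte-Carlo performance harness (`run_study`:
bias, RMSE, CV, coverage), file I/O for capture-history CSV and MARK-style
`.INP` files, and a `geecr` command-line tool (`fit`, `simulate`, `study`).
See `docs/methods.md` for the statistical details.

## Worked example: least chipmunk livetrapping data

45 distinct chipmunks were caught 88 times over 6 occasions (22 males with 41
captures, 23 females with 47). The dataset is published only as these
sufficient statistics, which the GEE estimator can fit directly:

```sh
$ geecr fit --input chipmunk --mean-form marginal
method: ql-gee  (mean form: marginal)
  (intercept)     -0.73 (0.13)
  N_hat           49.66 (2.62)
  95% CI       [44.53, 54.79] (wald)

$ geecr fit --input chipmunk --terms sex --mean-form conditional
method: ql-gee  (mean form: conditional)
  (intercept)     -0.84 (0.21)
  sex             -0.21 (0.32)
  N_hat           52.39 (3.76)
  95% CI       [45.02, 59.77] (wald)
```

The first fit is the equal-catchability model: the pooled per-occasion
capture proportion is 88/270 = 0.326 (logit −0.73), so each animal had
probability π̂ = 1 − (1−0.326)⁶ = 0.906 of being seen at all, giving
N̂ = 45/0.906 ≈ 49.7 animals — about five more than were ever caught. The
second fit lets catchability differ by sex (males slightly less catchable,
sex coefficient −0.21, not significant) and raises the estimate to ≈ 52.4.
Partial-likelihood fits require individual first-capture times, which were
never published for these data; the CLI says so explicitly.

The same analysis in Python:

```python
from geecr import chipmunk_summary, fit_grouped

fit = fit_grouped(chipmunk_summary(), covariate=False, mean_form="marginal")
print(fit.coef_)                 # [-0.7267]
print(fit.abundance().n_hat)     # 49.658
```

## Simulation studies

```python
from geecr import run_study, scenario

table = run_study(
    [scenario("low", N=100, m=6)], ["ql-gee", "pl-glm", "pl-glmm"],
    reps=1000, seed=0,
)
print(table[["estimator", "n_bar", "AVE", "SE", "PRB", "RMSE", "COV"]])
```

Under the low-capture scenario (average capture probability ≈ 0.2, so only
≈ 70 of 100 animals are ever seen) the GEE estimator is the most stable; the
mixed model systematically overestimates N. The `geecr study` subcommand runs
the same harness from a YAML configuration.

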