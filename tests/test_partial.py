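"""Partial-likelihood GLM and mixed-model (PQL) estimation."""

import warnings

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import binom

from geecr import (
    PartialLikelihoodGLM,
    PartialLikelihoodGLMM,
    PLData,
    Scenario,
    build_pl_data,
    select_lambda_gcv,
    simulate_population,
    summarize,
)
from geecr.partial import (
    DEFAULT_LAMBDA_GRID,
    _select_min,
    penalized_joint_vcov,
)


class TestBuildPLData:
    def test_enumeration(self, small_history):
        # histories: caught once at occ 1 / occs 1,2 / occs 2,3 (m = 3)
        pl = build_pl_data(summarize(small_history))
        assert pl.successes.tolist() == [0, 1, 1]
        assert pl.trials.tolist() == [2, 2, 1]

    def test_last_occasion_first_capture_inert(self):
        import geecr

        y = np.array([[0, 0, 0, 0, 0, 1], [0, 1, 0, 1, 1, 0]])
        pl = build_pl_data(summarize(geecr.CaptureHistory(y=y)))
        assert pl.successes.tolist() == [0, 2]
        assert pl.trials.tolist() == [0, 4]
        assert pl.active.tolist() == [False, True]

    def test_conservation(self, medium_population):
        s = summarize(medium_population.observed)
        pl = build_pl_data(s)
        assert pl.successes.sum() == (s.T - 1).sum()


def grid_mle_intercept(successes, trials, lo=-6, hi=6):
    """Independent 1-parameter likelihood maximizer by iterated grid refinement."""
    for _ in range(8):
        grid = np.linspace(lo, hi, 201)
        ll = np.array(
            [
                binom.logpmf(successes, trials, expit(b)).sum()
                for b in grid
            ]
        )
        k = int(np.argmax(ll))
        lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, 200)]
    return (lo + hi) / 2


class TestPartialLikelihoodGLM:
    def test_matches_grid_search_oracle(self):
        successes = np.array([0, 1, 2, 1, 0, 3])
        trials = np.array([2, 3, 4, 5, 1, 5])
        pl = PLData(successes, trials, np.ones((6, 1)), m=6)
        fit = PartialLikelihoodGLM().fit_pl(pl)
        oracle = grid_mle_intercept(successes, trials)
        assert fit.coef_[0] == pytest.approx(oracle, abs=1e-6)

    def test_all_last_occasion_unidentifiable(self):
        pl = PLData(np.zeros(3, int), np.zeros(3, int), np.ones((3, 1)), m=4)
        with pytest.raises(ValueError, match="last occasion"):
            PartialLikelihoodGLM().fit_pl(pl)

    def test_saturated_successes_flag_boundary(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pl = PLData(np.array([3, 2, 4]), np.array([3, 2, 4]), np.ones((3, 1)), m=5)
            fit = PartialLikelihoodGLM().fit_pl(pl)
        assert fit.boundary_

    def test_equal_group_rates_zero_slope(self):
        # identical recapture profiles in both covariate groups
        successes = np.array([1, 2, 1, 2])
        trials = np.array([4, 4, 4, 4])
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        fit = PartialLikelihoodGLM().fit_pl(PLData(successes, trials, X, m=5))
        assert fit.coef_[1] == pytest.approx(0.0, abs=1e-8)

    def test_abundance_on_simulated_data(self, medium_population):
        ch = medium_population.observed
        fit = PartialLikelihoodGLM().fit(ch.covariates[["sex", "weight"]], ch.y)
        ab = fit.abundance()
        assert ab.n_hat >= ch.n
        assert ab.ci_low <= ab.n_hat <= ab.ci_high


class TestPartialLikelihoodGLMM:
    def test_sigma_zero_reduces_to_glm(self, medium_population):
        ch = medium_population.observed
        X = ch.covariates[["sex", "weight"]]
        glm = PartialLikelihoodGLM().fit(X, ch.y)
        glmm = PartialLikelihoodGLMM(sigma_b=0.0).fit(X, ch.y)
        assert np.allclose(glm.coef_, glmm.coef_, atol=1e-6)
        assert glmm.deviance() == pytest.approx(glm.deviance_, abs=1e-6)
        assert np.allclose(glmm.random_effects_, 0.0)

    def test_homogeneous_data_estimates_near_zero_sigma(self):
        sc = Scenario(N=1000, m=8, beta0=-3.5, sigma_b=0.0)
        pop = simulate_population(sc, np.random.default_rng(0))
        ch = pop.observed
        X = ch.covariates[["sex", "weight"]]
        fit = PartialLikelihoodGLMM().fit(X, ch.y)
        glm = PartialLikelihoodGLM().fit(X, ch.y)
        assert fit.sigma_b_ < 0.05
        assert np.allclose(fit.coef_, glm.coef_, atol=1e-3)

    def test_inert_individuals_have_zero_predicted_effect(self):
        import geecr

        y = np.array(
            [[0, 0, 0, 0, 0, 1]] + [[1, 0, 1, 0, 1, 0]] * 5 + [[0, 1, 0, 0, 0, 1]] * 5
        )
        ch = geecr.CaptureHistory(y=y)
        fit = PartialLikelihoodGLMM(sigma_b=0.8).fit(None, ch.y)
        assert fit.random_effects_[0] == 0.0

    def test_gh_marginal_pi_option_runs(self, medium_population):
        ch = medium_population.observed
        X = ch.covariates[["sex", "weight"]]
        fit = PartialLikelihoodGLMM(sigma_b=0.5, pi_form="marginal").fit(X, ch.y)
        assert ((fit.pi_hat_ > 0) & (fit.pi_hat_ <= 1)).all()


class TestPenalizedVariance:
    def test_large_lambda_kills_random_effect_block(self):
        rng = np.random.default_rng(6)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        w = rng.uniform(0.5, 2.0, 30)
        traces = []
        for lam in (0.1, 1.0, 10.0, 1e4, 1e8):
            K = penalized_joint_vcov(X, w, lam)
            traces.append(np.trace(K[2:, 2:]))
        assert all(a >= b for a, b in zip(traces, traces[1:]))  # monotone shrinkage
        assert traces[-1] < 1e-6
        # beta block tends to the unpenalized GLM covariance
        K_inf = penalized_joint_vcov(X, w, 1e10)
        glm_vcov = np.linalg.inv((X * w[:, None]).T @ X)
        assert np.allclose(K_inf[:2, :2], glm_vcov, rtol=1e-4)

    def test_abundance_variance_exceeds_binomial_term(self, medium_population):
        ch = medium_population.observed
        fit = PartialLikelihoodGLMM(sigma_b=0.3).fit(ch.covariates[["sex", "weight"]], ch.y)
        ab = fit.abundance()
        assert ab.se**2 >= ab.var_binomial


class TestGCVSelection:
    def test_interior_minimizer_selected(self):
        grid = np.array([0.01, 0.1, 1.0, 10.0])
        assert _select_min(grid, np.array([3.0, 1.0, 2.0, 4.0])) == 0.1

    def test_flat_score_ties_to_smallest(self):
        grid = np.array([0.01, 0.1, 1.0])
        assert _select_min(grid, np.ones(3)) == 0.01

    def test_selected_lambda_finite_positive(self):
        sc = Scenario(N=300, m=8, beta0=-3.5, sigma_b=0.5)
        pop = simulate_population(sc, np.random.default_rng(104))
        pl = build_pl_data(summarize(pop.observed), pop.observed.covariates[["sex", "weight"]])
        lam = select_lambda_gcv(pl)
        assert np.isfinite(lam) and lam > 0
        assert lam in DEFAULT_LAMBDA_GRID
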