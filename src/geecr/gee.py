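"""Quasi-likelihood GEE estimation of capture probabilities.

Capture histories are repeated binary measurements on the same animal, so the
coefficients of the logistic capture model are estimated by solving
generalized estimating equations

    sum_i D_i' V_i^{-1} (Y_i - mu_i) = 0

over the n captured individuals, where ``mu_ij`` is the occasion mean under a
working correlation structure R(alpha).  Two mean formulations are supported:

* ``conditional`` (default): ``mu_ij = p_i / pi_i``, the occasion capture
  probability given the animal was caught at least once (the estimating
  equations condition on the observed set, as in Huggins-style inference).
  With a saturated categorical design this reduces per group to the moment
  equation ``m p / pi = mean capture count``.
* ``marginal``: ``mu_ij = p_i``; for an intercept-only model the root is the
  pooled per-occasion capture proportion ``p0 = sum T_i / (n m)``.

Because the occasion means are constant within an individual, an exchangeable
working correlation leaves the root of the equations unchanged relative to
working independence; it only rescales the model-based covariance by
``1 + (m-1) alpha``.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from .core import horvitz_thompson, prob_ever_captured
from .data import CaptureHistory, GroupedSummary

__all__ = [
    "QuasiLikelihoodGEE",
    "solve_m0_marginal",
    "solve_conditional_group",
    "estimate_alpha_exchangeable",
    "fit_grouped",
]


def _mean_and_deriv(p, m, mean_form):
    """Occasion mean mu and its derivative d mu / d(linear predictor)."""
    dp = p * (1.0 - p)
    if mean_form == "marginal":
        return p, dp
    if mean_form == "conditional":
        pi = prob_ever_captured(p, m)
        mu = p / pi
        # d(p/pi)/du = p(1-p) [1/pi - m p (1-p)^{m-1} / pi^2]
        dmu = dp * (1.0 / pi - m * p * (1.0 - p) ** (m - 1) / pi**2)
        return mu, dmu
    raise ValueError(f"unknown mean_form {mean_form!r}")


class NonConvergenceError(RuntimeError):
    """GEE solver failed to reach the requested tolerance."""


class QuasiLikelihoodGEE(BaseEstimator):
    """Quasi-likelihood GEE estimator of logistic capture probabilities.

    Parameters
    ----------
    mean_form : {"conditional", "marginal"}
        Occasion-mean formulation (see module docstring).
    working_correlation : {"independence", "exchangeable"}
        Working correlation among occasions.  The exchangeable alpha is
        estimated by moments from Pearson residuals when full histories are
        available.
    tol : float
        Convergence tolerance on both the coefficient step and the norm of
        the estimating function.
    max_iter : int
        Maximum Fisher-scoring iterations.
    boundary_logit : float
        Fitted linear predictors exceeding this magnitude mark the fit as a
        boundary solution (effectively p -> 0 or 1), flagged non-estimable.

    Attributes
    ----------
    coef_ : ndarray, (p,) — intercept first.
    vcov_ : ndarray — model-based coefficient covariance.
    vcov_robust_ : ndarray or None — sandwich covariance.
    p_hat_, pi_hat_ : ndarray, (n,)
    alpha_ : float — estimated exchangeable correlation (0 under independence).
    converged_, boundary_ : bool;  n_iter_ : int;  score_ : ndarray.
    """

    method = "ql-gee"

    def __init__(
        self,
        mean_form: str = "conditional",
        working_correlation: str = "independence",
        tol: float = 1e-8,
        max_iter: int = 100,
        boundary_logit: float = 10.0,
    ):
        self.mean_form = mean_form
        self.working_correlation = working_correlation
        self.tol = tol
        self.max_iter = max_iter
        self.boundary_logit = boundary_logit

    # -- fitting ---------------------------------------------------------

    def fit(self, X, Y):
        """Fit from covariates ``X`` (n, p0; may be None) and capture matrix ``Y`` (n, m)."""
        Y = np.asarray(Y)
        design, names = _build_design(X, Y.shape[0])
        self.feature_names_in_ = names
        T = Y.sum(axis=1).astype(float)
        self._solve(design, T, Y.shape[1], y_full=Y)
        return self

    def fit_counts(self, X, T, m):
        """Fit from per-individual capture counts ``T`` (sufficient under independence).

        ``T`` may be fractional, which supports fitting from grouped published
        totals; the sandwich covariance is then not meaningful and is set to
        None.
        """
        T = np.asarray(T, dtype=float)
        design, names = _build_design(X, T.shape[0])
        self.feature_names_in_ = names
        self._solve(design, T, int(m), y_full=None)
        return self

    def fit_capture_history(self, ch: CaptureHistory, terms=()):
        """Fit on a :class:`CaptureHistory` using the named covariate ``terms``."""
        X = ch.covariate_matrix(tuple(terms))
        self.feature_names_in_ = ["(intercept)", *terms]
        self.fit(X if X.shape[1] else None, ch.y)
        self.feature_names_in_ = ["(intercept)", *terms]
        return self

    def _solve(self, X, T, m, y_full=None):
        n, p = X.shape
        if np.any(T < 0) or np.any(T > m):
            raise ValueError("capture counts must lie in [0, m]")
        beta = np.zeros(p)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            U, J = self._score_info(X, T, m, beta)
            try:
                step = np.linalg.solve(J, U)
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError(
                    "singular information matrix; collinear terms among "
                    f"{list(self.feature_names_in_)}"
                )
            # step-halving on the estimating-function norm
            norm0 = np.linalg.norm(U)
            lam = 1.0
            for _ in range(30):
                cand = beta + lam * step
                U1, _ = self._score_info(X, T, m, cand)
                if np.linalg.norm(U1) <= norm0 or np.max(np.abs(lam * step)) < self.tol:
                    break
                lam /= 2.0
            beta = beta + lam * step
            if np.max(np.abs(lam * step)) < self.tol or np.linalg.norm(U1) < self.tol:
                converged = True
                break
        U, J = self._score_info(X, T, m, beta)
        eta_lin = X @ beta
        p_hat = expit(eta_lin)
        alpha = 0.0
        scale = 1.0
        if self.working_correlation == "exchangeable" and y_full is not None:
            mu, _ = _mean_and_deriv(p_hat, m, self.mean_form)
            alpha = estimate_alpha_exchangeable(
                (y_full - mu[:, None]) / np.sqrt(np.clip(mu * (1 - mu), 1e-12, None))[:, None]
            )
            scale = 1.0 + (m - 1) * alpha
        elif self.working_correlation not in ("independence", "exchangeable"):
            raise ValueError(f"unknown working_correlation {self.working_correlation!r}")
        vcov = np.linalg.inv(J) * scale
        self.coef_ = beta
        self.score_ = U
        self.n_iter_ = it
        self.converged_ = bool(converged)
        self.boundary_ = bool(np.max(np.abs(eta_lin)) > self.boundary_logit)
        self.p_hat_ = p_hat
        self.pi_hat_ = prob_ever_captured(p_hat, m)
        self.m_ = m
        self.X_design_ = X
        self.vcov_ = vcov
        self.alpha_ = float(alpha)
        self.vcov_robust_ = self._sandwich(X, T, m, beta) if y_full is not None else None
        return self

    def _score_info(self, X, T, m, beta):
        # Simplified estimating function under working independence with the
        # logistic link: the occasion-level quasi-score collapses to
        # U = sum_i x_i (T_i - m mu_i).  For the marginal form this is the
        # Bernoulli-GLM score; for the conditional form it is the conditional
        # (captured-individuals) likelihood score.  J is the sensitivity
        # sum_i m dmu_i x_i x_i' (the conditional information matrix).
        p = expit(X @ beta)
        mu, dmu = _mean_and_deriv(p, m, self.mean_form)
        U = X.T @ (T - m * mu)
        J = (X * (m * dmu)[:, None]).T @ X
        return U, J

    def _sandwich(self, X, T, m, beta):
        p = expit(X @ beta)
        mu, _ = _mean_and_deriv(p, m, self.mean_form)
        u_i = X * (T - m * mu)[:, None]
        _, J = self._score_info(X, T, m, beta)
        Jinv = np.linalg.inv(J)
        return Jinv @ (u_i.T @ u_i) @ Jinv

    # -- prediction / abundance ------------------------------------------

    def predict_proba(self, X):
        """Per-occasion capture probability for new covariate rows."""
        design, _ = _build_design(X, np.asarray(X).shape[0] if X is not None else None)
        return expit(design @ self.coef_)

    def abundance(self, ci_method="wald"):
        """Horvitz-Thompson abundance estimate from the fitted pi."""
        return horvitz_thompson(
            self.pi_hat_,
            p_hat=self.p_hat_,
            m=self.m_,
            X=self.X_design_,
            vcov=self.vcov_,
            ci_method=ci_method,
        )


def _build_design(X, n):
    """Prepend an intercept column; X may be None (intercept-only)."""
    if X is None:
        if n is None:
            raise ValueError("need number of rows for an intercept-only design")
        return np.ones((n, 1)), ["(intercept)"]
    names = ["(intercept)"]
    if hasattr(X, "columns"):
        names += [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names += [f"x{k + 1}" for k in range(X.shape[1])]
    return np.column_stack([np.ones(X.shape[0]), X]), names


# --- closed forms -----------------------------------------------------------


def solve_m0_marginal(n, m, total_captures):
    """Closed-form marginal M0 solution ``p0 = total_captures / (n m)``.

    Returns ``(p_hat, boundary)`` where boundary flags p at 0 or 1.
    """
    p = total_captures / (n * m)
    return p, not (0.0 < p < 1.0)


def solve_conditional_group(count, m, total_captures):
    """Solve the conditional moment equation ``m p / pi(p) = mean captures`` for one group.

    The left side increases strictly from 1 (p -> 0) to m (p = 1), so the root
    is unique when the group mean capture count lies in (1, m).  Returns
    ``(p_hat, boundary)``; outside that range the nearest boundary (0 or 1) is
    returned with the flag set.
    """
    target = total_captures / count
    if target <= 1.0:
        return 0.0, True
    if target >= m:
        return 1.0, True

    def g(p):
        return m * p / prob_ever_captured(p, m) - target

    return brentq(g, 1e-12, 1.0 - 1e-12, xtol=1e-14), False


def estimate_alpha_exchangeable(resid):
    """Moment estimator of the exchangeable correlation from Pearson residuals.

    ``resid`` is the n x m matrix of within-individual Pearson residuals;
    alpha is the mean within-individual cross-product over occasion pairs,
    scaled by the residual dispersion.
    """
    e = np.asarray(resid, dtype=float)
    n, m = e.shape
    if m < 2:
        raise ValueError("need at least two occasions")
    phi = np.mean(e**2)
    row = e.sum(axis=1)
    cross = (row**2 - (e**2).sum(axis=1)).sum() / (n * m * (m - 1))
    return float(cross / phi)


# --- grouped published data --------------------------------------------------


def fit_grouped(
    gs: GroupedSummary,
    covariate: bool = True,
    mean_form: str = "conditional",
    **kwargs,
) -> QuasiLikelihoodGEE:
    """Fit the QL-GEE from grouped sufficient statistics (count, total captures).

    Each group member is represented by its group-mean capture count, which
    leaves the estimating equations unchanged (they involve the data only
    through group totals when the design is a saturated categorical factor).
    With ``covariate=False`` an intercept-only (M0) model is fitted.
    """
    counts, totals, codes = [], [], []
    for label, (count, total) in gs.groups.items():
        counts.append(count)
        totals.append(total)
        codes.append(gs.codes.get(label, 0.0))
    T = np.concatenate([np.full(c, t / c) for c, t in zip(counts, totals)])
    if covariate:
        X = np.concatenate([np.full(c, z) for c, z in zip(counts, codes)])[:, None]
    else:
        X = None
    est = QuasiLikelihoodGEE(mean_form=mean_form, **kwargs)
    est.fit_counts(X, T, gs.m)
    return est


def logit_p(p):
    """Convenience logit used in reports."""
    return float(logit(p))
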