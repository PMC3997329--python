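"""Partial-likelihood GLM and GLMM estimation from recaptures after first capture.

Conditioning on the first-capture occasion t_i, the number of later recaptures
of individual i is binomial,

    (T_i - 1) | t_i  ~  Bin(m - t_i, p_i),

which yields a likelihood free of the unknown population size N.  The GLM
variant fits ``logit p_i = x_i' beta`` by binomial-logit maximum likelihood.
The GLMM variant adds a Gaussian individual random intercept,
``logit p_i = x_i' beta + sigma_b z_i`` with ``z_i ~ N(0,1)``, fitted by
penalized quasi-likelihood (PQL): iterate a working linear mixed-model solve
(GLS for beta, shrinkage BLUP for the random effects) with a variance-component
update, here the REML maximizer of the working model.  The random-intercept
variance maps to a ridge penalty with smoothing parameter ``lambda = 1/sigma_b^2``,
selectable by generalized cross-validation instead of REML.

Individuals first caught on the last occasion contribute zero trials: they are
retained (their fitted pi enters the abundance estimate, with predicted random
effect 0) but carry no partial-likelihood information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import binom
from sklearn.base import BaseEstimator

from .core import horvitz_thompson, eta_sensitivity, prob_ever_captured
from .data import CaptureSummary
from .gee import _build_design

__all__ = [
    "PLData",
    "build_pl_data",
    "PartialLikelihoodGLM",
    "PartialLikelihoodGLMM",
    "select_lambda_gcv",
    "gcv_path",
    "penalized_joint_vcov",
]

DEFAULT_LAMBDA_GRID = np.logspace(-4, 4, 25)


@dataclass(frozen=True)
class PLData:
    """Per-individual recapture records: successes = T_i - 1, trials = m - t_i."""

    successes: np.ndarray
    trials: np.ndarray
    X: np.ndarray  # design including intercept column
    m: int
    feature_names: tuple = ()

    @property
    def n(self) -> int:
        return self.successes.size

    @property
    def active(self) -> np.ndarray:
        """Mask of individuals with at least one post-first-capture trial."""
        return self.trials > 0


def build_pl_data(summary: CaptureSummary, X=None) -> PLData:
    """Build partial-likelihood records from a capture summary and covariates."""
    design, names = _build_design(X, summary.n)
    successes = summary.T.astype(int) - 1
    trials = summary.m - summary.t_first.astype(int)
    if np.any(successes < 0) or np.any(successes > trials):
        raise ValueError("inconsistent capture counts / first-capture times")
    return PLData(
        successes=successes,
        trials=trials,
        X=design,
        m=summary.m,
        feature_names=tuple(names),
    )


class PartialLikelihoodGLM(BaseEstimator):
    """Binomial-logit fit of recaptures after first capture (partial likelihood).

    Attributes after fit: ``coef_`` (intercept first), ``vcov_`` (inverse
    observed information), ``p_hat_``/``pi_hat_`` for all captured individuals,
    ``deviance_``, ``converged_``, ``boundary_``.
    """

    method = "pl-glm"

    def __init__(self, boundary_logit: float = 10.0):
        self.boundary_logit = boundary_logit

    def fit(self, X, Y):
        """Fit from covariates ``X`` (may be None) and capture matrix ``Y`` (n, m)."""
        Y = np.asarray(Y)
        T = Y.sum(axis=1).astype(int)
        t_first = Y.argmax(axis=1) + 1
        design, names = _build_design(X, Y.shape[0])
        pl = PLData(
            successes=T - 1,
            trials=Y.shape[1] - t_first,
            X=design,
            m=Y.shape[1],
            feature_names=tuple(names),
        )
        return self.fit_pl(pl)

    def fit_pl(self, pl: PLData):
        act = pl.active
        if not act.any():
            raise ValueError(
                "all individuals were first captured on the last occasion; "
                "the partial likelihood is unidentifiable"
            )
        endog = np.column_stack(
            [pl.successes[act], pl.trials[act] - pl.successes[act]]
        ).astype(float)
        model = sm.GLM(endog, pl.X[act], family=sm.families.Binomial())
        res = model.fit()
        self.feature_names_in_ = list(pl.feature_names)
        self.coef_ = np.asarray(res.params)
        self.vcov_ = np.asarray(res.cov_params())
        self.deviance_ = float(res.deviance)
        self.converged_ = bool(res.converged)
        eta_lin = pl.X @ self.coef_
        self.boundary_ = bool(np.max(np.abs(eta_lin)) > self.boundary_logit)
        self.p_hat_ = expit(eta_lin)
        self.pi_hat_ = prob_ever_captured(self.p_hat_, pl.m)
        self.m_ = pl.m
        self.X_design_ = pl.X
        return self

    def predict_proba(self, X):
        design, _ = _build_design(X, np.asarray(X).shape[0] if X is not None else None)
        return expit(design @ self.coef_)

    def abundance(self, ci_method="wald"):
        return horvitz_thompson(
            self.pi_hat_,
            p_hat=self.p_hat_,
            m=self.m_,
            X=self.X_design_,
            vcov=self.vcov_,
            ci_method=ci_method,
        )


# --- PQL machinery -----------------------------------------------------------


def _working_quantities(X, y, ntr, beta, b):
    eta = X @ beta + b
    p = expit(eta)
    w = np.clip(ntr * p * (1.0 - p), 1e-10, None)
    z = eta + (y - ntr * p) / w
    return p, w, z


def _reml_neg_loglik(log_s2, X, w, z):
    s2 = np.exp(log_s2)
    Sig = 1.0 / w + s2
    Xi = X / Sig[:, None]
    XtSX = X.T @ Xi
    beta = np.linalg.solve(XtSX, Xi.T @ z)
    r = z - X @ beta
    sign, logdet = np.linalg.slogdet(XtSX)
    return 0.5 * (np.sum(np.log(Sig)) + logdet + np.sum(r**2 / Sig))


def _gls_blup(X, w, z, s2):
    Sig = 1.0 / w + s2
    Xi = X / Sig[:, None]
    XtSX = X.T @ Xi
    beta = np.linalg.solve(XtSX, Xi.T @ z)
    resid = z - X @ beta
    shrink = s2 * w / (1.0 + s2 * w)
    b = shrink * resid
    return beta, b, XtSX, Sig, shrink


def _binomial_deviance(y, ntr, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / (ntr * p)), 0.0)
        t2 = np.where(ntr - y > 0, (ntr - y) * np.log((ntr - y) / (ntr - ntr * p)), 0.0)
    return float(2.0 * np.sum(t1 + t2))


def _pql_fixed_sigma(X, y, ntr, s2, tol, max_iter, start=None):
    """PQL inner loop at fixed random-intercept variance s2."""
    p_dim = X.shape[1]
    beta = np.zeros(p_dim) if start is None else start.copy()
    b = np.zeros(y.size)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        _, w, z = _working_quantities(X, y, ntr, beta, b)
        beta_new, b_new, XtSX, Sig, shrink = _gls_blup(X, w, z, s2)
        delta = max(np.max(np.abs(beta_new - beta)), np.max(np.abs(b_new - b), initial=0))
        beta, b = beta_new, b_new
        if delta < tol:
            converged = True
            break
    _, w, z = _working_quantities(X, y, ntr, beta, b)
    _, _, XtSX, Sig, shrink = _gls_blup(X, w, z, s2)
    return beta, b, w, z, XtSX, Sig, shrink, converged, it


def _gcv_score(X, y, ntr, beta, b, w, XtSX, Sig, shrink):
    """GCV = n * D / (n - edf)^2 for the working ridge fit.

    D is the weighted working-response residual sum of squares (the quadratic
    approximation of the binomial deviance); the raw deviance would vanish
    together with (n - edf) as lambda -> 0 and make the score degenerate.
    """
    n = y.size
    _, _, z = _working_quantities(X, y, ntr, beta, b)
    rss = float(np.sum(w * (z - X @ beta - b) ** 2))
    Xi = X / Sig[:, None]
    h_x = np.einsum("ij,jk,ik->i", X, np.linalg.inv(XtSX), Xi)
    edf = float(np.sum(shrink) + np.sum((1.0 - shrink) * h_x))
    edf = min(edf, n - 1e-6)
    return n * rss / (n - edf) ** 2


def gcv_path(pl: PLData, grid=None, tol=1e-6, max_iter=200):
    """GCV score at each grid value of lambda (sorted ascending)."""
    grid = DEFAULT_LAMBDA_GRID if grid is None else np.sort(np.asarray(grid, float))
    act = pl.active
    X, y, ntr = pl.X[act], pl.successes[act].astype(float), pl.trials[act].astype(float)
    scores = np.empty(grid.size)
    for k, lam in enumerate(grid):
        beta, b, w, z, XtSX, Sig, shrink, _, _ = _pql_fixed_sigma(
            X, y, ntr, 1.0 / lam, tol, max_iter
        )
        scores[k] = _gcv_score(X, y, ntr, beta, b, w, XtSX, Sig, shrink)
    return grid, scores


def _select_min(grid, scores, tie_tol=1e-12):
    """Smallest grid value attaining the minimum score (flat ties -> smallest)."""
    best = np.min(scores)
    return float(grid[np.flatnonzero(scores <= best + tie_tol)[0]])


def select_lambda_gcv(pl: PLData, grid=None, tol=1e-6, max_iter=200):
    """Grid-search GCV minimizer for the ridge parameter lambda = 1/sigma_b^2.

    Ties (flat score) resolve to the smallest lambda.
    """
    grid, scores = gcv_path(pl, grid, tol, max_iter)
    return _select_min(grid, scores)


def penalized_joint_vcov(X, w, lam):
    """Inverse penalized information for (beta, b) with ridge lam on the intercepts.

    ``[[X'WX, X'W], [WX, W + lam I]]^{-1}``; as lam -> infinity the
    random-effect block (the penalized directions) shrinks to zero and the
    beta block tends to the unpenalized GLM covariance.
    """
    X = np.asarray(X, float)
    w = np.asarray(w, float)
    n, p = X.shape
    K = np.empty((p + n, p + n))
    K[:p, :p] = (X * w[:, None]).T @ X
    K[:p, p:] = (X * w[:, None]).T
    K[p:, :p] = K[:p, p:].T
    K[p:, p:] = np.diag(w + lam)
    return np.linalg.inv(K)


class PartialLikelihoodGLMM(BaseEstimator):
    """Partial-likelihood logistic GLMM with an individual Gaussian random intercept.

    ``logit p_i = x_i' beta + sigma_b z_i``, z_i ~ N(0,1).  Default fitting is
    PQL with the variance component updated by REML of the working linear
    mixed model each outer iteration.

    Parameters
    ----------
    sigma_b : float or None
        Fix the random-intercept SD (0 reduces the fit to the GLM); None
        estimates it.
    method : {"pql", "gcv", "gh"}
        "pql": REML variance-component update (default).
        "gcv": choose lambda = 1/sigma_b^2 on a grid by generalized
        cross-validation.
        "gh": maximize the exact marginal likelihood with Gauss-Hermite
        quadrature (20 nodes); an exact-likelihood alternative to PQL.
    pi_form : {"conditional", "marginal"}
        Evaluate pi_i at the predicted random effect (conditional, default) or
        integrate the random effect out by Gauss-Hermite (marginal).

    Attributes after fit: ``coef_``, ``sigma_b_``, ``lambda_``,
    ``random_effects_`` (predicted z_i, 0 for zero-trial individuals),
    ``vcov_`` (beta block of the penalized information inverse), ``eta_``
    (sensitivity vector), ``converged_``, ``n_iter_``.
    """

    method_tag = "pl-glmm"

    def __init__(
        self,
        sigma_b: float | None = None,
        method: str = "pql",
        lambda_grid=None,
        pi_form: str = "conditional",
        tol: float = 1e-6,
        max_iter: int = 200,
        boundary_logit: float = 10.0,
        gh_nodes: int = 20,
    ):
        self.sigma_b = sigma_b
        self.method = method
        self.lambda_grid = lambda_grid
        self.pi_form = pi_form
        self.tol = tol
        self.max_iter = max_iter
        self.boundary_logit = boundary_logit
        self.gh_nodes = gh_nodes

    def fit(self, X, Y):
        Y = np.asarray(Y)
        T = Y.sum(axis=1).astype(int)
        t_first = Y.argmax(axis=1) + 1
        design, names = _build_design(X, Y.shape[0])
        pl = PLData(
            successes=T - 1,
            trials=Y.shape[1] - t_first,
            X=design,
            m=Y.shape[1],
            feature_names=tuple(names),
        )
        return self.fit_pl(pl)

    def fit_pl(self, pl: PLData):
        act = pl.active
        if not act.any():
            raise ValueError(
                "all individuals were first captured on the last occasion; "
                "the partial likelihood is unidentifiable"
            )
        X = pl.X[act]
        y = pl.successes[act].astype(float)
        ntr = pl.trials[act].astype(float)
        self._y_, self._ntr_ = y, ntr
        self.feature_names_in_ = list(pl.feature_names)

        if self.method == "gh" and self.sigma_b is None:
            beta, sigma, converged, it = self._fit_gh(X, y, ntr)
            s2 = sigma**2
            b = self._gh_blup(X, y, ntr, beta, sigma)
        elif self.sigma_b is not None:
            s2 = float(self.sigma_b) ** 2
            beta, b, w, z, XtSX, Sig, shrink, converged, it = _pql_fixed_sigma(
                X, y, ntr, s2, self.tol, self.max_iter
            )
        elif self.method == "gcv":
            lam = select_lambda_gcv(pl, self.lambda_grid, self.tol, self.max_iter)
            s2 = 1.0 / lam
            beta, b, w, z, XtSX, Sig, shrink, converged, it = _pql_fixed_sigma(
                X, y, ntr, s2, self.tol, self.max_iter
            )
        elif self.method == "pql":
            beta, b, s2, converged, it = self._fit_pql_reml(X, y, ntr)
        else:
            raise ValueError(f"unknown method {self.method!r}")

        sigma = float(np.sqrt(s2))
        lam = np.inf if s2 == 0 else 1.0 / s2
        _, w, _ = _working_quantities(X, y, ntr, beta, b if self.method != "gh" else b)
        K = penalized_joint_vcov(X, w, lam if np.isfinite(lam) else 1e12)
        p_dim = X.shape[1]

        self.coef_ = beta
        self.sigma_b_ = sigma
        self.lambda_ = float(lam)
        self.converged_ = bool(converged)
        self.n_iter_ = it
        self.vcov_ = K[:p_dim, :p_dim]
        self._joint_vcov_ = K
        self._active_mask_ = act

        # predicted standardized random effects; 0 where there is no recapture data
        z_all = np.zeros(pl.n)
        if sigma > 1e-8:
            z_all[act] = b / sigma
        self.random_effects_ = z_all
        eta_lin = pl.X @ beta + sigma * z_all
        self.boundary_ = bool(np.max(np.abs(eta_lin)) > self.boundary_logit)
        self.p_hat_ = expit(eta_lin)
        if self.pi_form == "conditional":
            self.pi_hat_ = prob_ever_captured(self.p_hat_, pl.m)
        else:
            self.pi_hat_ = self._marginal_pi(pl.X @ beta, sigma, pl.m)
        self.eta_ = eta_sensitivity(self.p_hat_, pl.m)
        self.m_ = pl.m
        self.X_design_ = pl.X
        return self

    # -- fitting backends -------------------------------------------------

    def _fit_pql_reml(self, X, y, ntr):
        beta = np.zeros(X.shape[1])
        b = np.zeros(y.size)
        s2 = 0.01
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            _, w, z = _working_quantities(X, y, ntr, beta, b)
            res = minimize_scalar(
                _reml_neg_loglik,
                bounds=(-20.0, 6.0),
                args=(X, w, z),
                method="bounded",
                options={"xatol": 1e-8},
            )
            s2_new = float(np.exp(res.x))
            if s2_new < 1e-8:
                s2_new = 0.0
            beta_new, b_new, *_ = _gls_blup(X, w, z, s2_new)
            delta = max(
                np.max(np.abs(beta_new - beta)),
                np.max(np.abs(b_new - b), initial=0.0),
                abs(np.sqrt(s2_new) - np.sqrt(s2)),
            )
            beta, b, s2 = beta_new, b_new, s2_new
            if delta < self.tol:
                converged = True
                break
        return beta, b, s2, converged, it

    def _gh_points(self):
        nodes, wts = np.polynomial.hermite_e.hermegauss(self.gh_nodes)
        return nodes, wts / np.sqrt(2 * np.pi) / np.sum(wts / np.sqrt(2 * np.pi))

    def _fit_gh(self, X, y, ntr):
        nodes, wts = self._gh_points()
        logw = np.log(wts)
        lbinom = gammaln(ntr + 1) - gammaln(y + 1) - gammaln(ntr - y + 1)

        def nll(theta):
            beta, sig = theta[:-1], np.exp(theta[-1])
            E = (X @ beta)[:, None] + sig * nodes[None, :]
            # log p = -log1p(exp(-E)), log(1-p) = -log1p(exp(E)), stably
            log_p = -np.logaddexp(0.0, -E)
            log_q = -np.logaddexp(0.0, E)
            ll = lbinom[:, None] + y[:, None] * log_p + (ntr - y)[:, None] * log_q
            return -float(np.sum(logsumexp(ll + logw[None, :], axis=1)))

        endog = np.column_stack([y, ntr - y])
        glm = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        x0 = np.append(np.asarray(glm.params), np.log(0.5))
        res = minimize(nll, x0, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-12})
        beta = res.x[:-1]
        sigma = float(np.exp(res.x[-1]))
        return beta, sigma, bool(res.success), int(res.nit)

    def _gh_blup(self, X, y, ntr, beta, sigma):
        """Posterior-mean random effects under the GH-fitted model."""
        nodes, wts = self._gh_points()
        eta = X @ beta
        num = np.zeros(y.size)
        den = np.zeros(y.size)
        for zk, wk in zip(nodes, wts):
            lk = wk * binom.pmf(y, ntr, expit(eta + sigma * zk))
            num += sigma * zk * lk
            den += lk
        return num / np.clip(den, 1e-300, None)

    def _marginal_pi(self, eta_fixed, sigma, m):
        nodes, wts = self._gh_points()
        pi = np.zeros(eta_fixed.size)
        for zk, wk in zip(nodes, wts):
            pi += wk * prob_ever_captured(expit(eta_fixed + sigma * zk), m)
        return pi

    # -- reporting ---------------------------------------------------------

    def deviance(self):
        """Binomial deviance of the fitted p over active individuals."""
        act = self._active_mask_
        return _binomial_deviance(self._y_, self._ntr_, self.p_hat_[act])

    def abundance(self, ci_method="wald"):
        """Horvitz-Thompson abundance with penalized delta-method variance.

        The coefficient-uncertainty term uses the joint penalized covariance of
        (beta, b) with gradient components -eta_i x_i (fixed effects) and
        -eta_i (each active random intercept).
        """
        pi = self.pi_hat_
        n_hat = float(np.sum(1.0 / pi))
        var_binom = float(np.sum((1.0 - pi) / pi**2))
        act = self._active_mask_
        p_dim = self.X_design_.shape[1]
        g = np.zeros(p_dim + int(act.sum()))
        g[:p_dim] = -(self.X_design_ * self.eta_[:, None]).sum(axis=0)
        g[p_dim:] = -self.eta_[act]
        var_coef = max(float(g @ self._joint_vcov_ @ g), 0.0)
        se = float(np.sqrt(var_binom + var_coef))
        z = 1.959963984540054
        if ci_method == "wald":
            lo, hi = n_hat - z * se, n_hat + z * se
        elif ci_method == "lognormal":
            f = max(n_hat - pi.size, 1e-12)
            c = np.exp(z * np.sqrt(np.log1p(se**2 / f**2)))
            lo, hi = pi.size + f / c, pi.size + f * c
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        from .core import AbundanceEstimate

        return AbundanceEstimate(
            n_hat=n_hat,
            se=se,
            ci_low=float(lo),
            ci_high=float(hi),
            ci_method=ci_method,
            var_binomial=var_binom,
            var_coef=var_coef,
        )
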