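"""Logistic capture-probability model and Horvitz-Thompson abundance estimation.

The capture probability of individual i on any occasion is modelled as
``p_i = h(x_i' beta)`` with logistic ``h(u) = 1/(1+exp(-u))``.  Under a closed
population with m occasions the probability of being caught at least once is
``pi_i = 1 - (1 - p_i)^m``, and abundance is estimated from the n captured
individuals by the Horvitz-Thompson estimator ``N_hat = sum_i 1/pi_i``.

The variance of N_hat combines a binomial term ``sum (1-pi)/pi^2`` (sampling of
individuals into the observed set) with a delta-method term propagating the
covariance of the coefficient estimates, as in Huggins-style conditional
inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "capture_prob",
    "prob_ever_captured",
    "eta_sensitivity",
    "AbundanceEstimate",
    "horvitz_thompson",
]


def capture_prob(beta, x):
    """Per-occasion capture probability ``h(x' beta)``.

    ``x`` may be a single design row or an (n, p) design matrix (including the
    intercept column).
    """
    beta = np.asarray(beta, dtype=float)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return expit(x @ beta)


def prob_ever_captured(p, m):
    """Probability of >= 1 capture in m occasions, ``1 - (1-p)^m``.

    Evaluated in log space, ``-expm1(m * log1p(-p))``, so small capture
    probabilities do not cancel catastrophically.  Strictly increasing in both
    ``p`` and ``m``.
    """
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        return -np.expm1(m * np.log1p(-p))


def eta_sensitivity(p, m):
    """Sensitivity ``eta = pi^-2 * m * p * (1 - pi)`` of ``1/pi`` to the linear predictor.

    This is |d(1/pi)/du| at u = logit(p); it propagates coefficient uncertainty
    into the Horvitz-Thompson estimator and appears in the penalized-variance
    formula for the mixed model.  Always nonnegative.
    """
    p = np.asarray(p, dtype=float)
    pi = prob_ever_captured(p, m)
    return m * p * (1.0 - pi) / pi**2


@dataclass(frozen=True)
class AbundanceEstimate:
    """Horvitz-Thompson abundance estimate with standard error and CI."""

    n_hat: float
    se: float
    ci_low: float
    ci_high: float
    ci_method: str = "wald"
    var_binomial: float = float("nan")
    var_coef: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "N_hat": self.n_hat,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_method": self.ci_method,
        }


def _wald_ci(n_hat, se, z):
    return n_hat - z * se, n_hat + z * se


def _lognormal_ci(n_hat, se, n, z):
    # Chao-style lognormal interval on N_hat - n, guaranteed >= n.
    f = max(n_hat - n, 1e-12)
    c = np.exp(z * np.sqrt(np.log1p(se**2 / f**2)))
    return n + f / c, n + f * c


def horvitz_thompson(
    pi_hat,
    p_hat=None,
    m=None,
    X=None,
    vcov=None,
    ci_method="wald",
    z=1.959963984540054,
) -> AbundanceEstimate:
    """Horvitz-Thompson abundance with Huggins-style delta-method variance.

    Parameters
    ----------
    pi_hat : array of shape (n,)
        Fitted capture-at-least-once probabilities for the captured individuals.
    p_hat, m, X, vcov : optional
        Per-occasion fitted probabilities, occasion count, design matrix
        (including intercept column) and coefficient covariance.  When all are
        supplied the coefficient-uncertainty term
        ``g' vcov g`` with ``g = -sum_i eta_i x_i`` is added to the binomial
        term ``sum_i (1-pi_i)/pi_i^2``.
    ci_method : {"wald", "lognormal"}
        95% interval form; Wald is the default used in coverage studies.
    """
    pi_hat = np.asarray(pi_hat, dtype=float)
    if pi_hat.ndim != 1 or pi_hat.size == 0:
        raise ValueError("pi_hat must be a non-empty 1-d array")
    if (pi_hat <= 0).any() or (pi_hat > 1).any():
        raise ValueError("fitted pi must lie in (0, 1]")
    n = pi_hat.size
    n_hat = float(np.sum(1.0 / pi_hat))
    var_binom = float(np.sum((1.0 - pi_hat) / pi_hat**2))
    var_coef = 0.0
    if vcov is not None:
        if p_hat is None or m is None or X is None:
            raise ValueError("delta-method term needs p_hat, m and X with vcov")
        eta = eta_sensitivity(np.asarray(p_hat, dtype=float), m)
        g = -(np.asarray(X, dtype=float) * eta[:, None]).sum(axis=0)
        var_coef = float(g @ np.asarray(vcov, dtype=float) @ g)
        var_coef = max(var_coef, 0.0)
    se = float(np.sqrt(var_binom + var_coef))
    if ci_method == "wald":
        lo, hi = _wald_ci(n_hat, se, z)
    elif ci_method == "lognormal":
        lo, hi = _lognormal_ci(n_hat, se, n, z)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
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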