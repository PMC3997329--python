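"""Monte-Carlo performance harness for abundance estimators.

For each (scenario, estimator) cell the harness simulates ``reps`` populations,
fits the estimator on each observed subset (sex + weight covariates), forms the
Horvitz-Thompson abundance estimate with a nominal-95% Wald interval, and
aggregates:

* n_bar — mean number of distinct individuals captured,
* AVE — mean abundance estimate,
* SE — Monte-Carlo SD of the estimates (sample SD, denominator r-1),
* PRB — percentage relative bias 100 (AVE - N)/N,
* CV — 100 SE / AVE,
* RMSE — sqrt(mean (N_hat - N)^2),
* COV — percentage of intervals containing the true N.

Replicates where an estimator fails to converge or hits a boundary
(|logit p| > 10, effectively p -> 0 or 1) are excluded from that estimator's
metrics and tallied in ``excluded``.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .gee import QuasiLikelihoodGEE
from .partial import PartialLikelihoodGLM, PartialLikelihoodGLMM
from .simulate import Scenario, simulate_population

__all__ = ["ESTIMATORS", "make_estimator", "performance_metrics", "run_study"]

logger = logging.getLogger(__name__)

ESTIMATORS = ("ql-gee", "pl-glm", "pl-glmm")


def make_estimator(name: str, **kwargs):
    """Estimator factory for the study harness and the CLI."""
    if name == "ql-gee":
        return QuasiLikelihoodGEE(**kwargs)
    if name == "pl-glm":
        return PartialLikelihoodGLM(**kwargs)
    if name == "pl-glmm":
        return PartialLikelihoodGLMM(**kwargs)
    raise ValueError(f"unknown estimator {name!r}; choose from {ESTIMATORS}")


def performance_metrics(N_true, estimates, ci_low=None, ci_high=None) -> dict:
    """Aggregate replicate-level estimates into the performance row.

    With a single replicate the Monte-Carlo SD (and CV) are undefined and
    reported as NaN, not zero.
    """
    est = np.asarray(estimates, dtype=float)
    r = est.size
    if r == 0:
        return {k: math.nan for k in ("AVE", "SE", "PRB", "CV", "RMSE", "COV")}
    ave = float(est.mean())
    se = float(est.std(ddof=1)) if r > 1 else math.nan
    prb = 100.0 * (ave - N_true) / N_true
    cv = 100.0 * se / ave if r > 1 else math.nan
    rmse = float(np.sqrt(np.mean((est - N_true) ** 2)))
    if ci_low is not None and ci_high is not None:
        lo = np.asarray(ci_low, dtype=float)
        hi = np.asarray(ci_high, dtype=float)
        cov = 100.0 * float(np.mean((lo <= N_true) & (N_true <= hi)))
    else:
        cov = math.nan
    return {"AVE": ave, "SE": se, "PRB": prb, "CV": cv, "RMSE": rmse, "COV": cov}


def _fit_one(name, pop):
    """Fit one estimator on one observed dataset; return (N_hat, lo, hi) or None."""
    ch = pop.observed
    est = make_estimator(name)
    X = ch.covariates[["sex", "weight"]]
    try:
        est.fit(X, ch.y)
    except Exception as exc:  # singular/separated replicate
        logger.debug("estimator %s failed: %s", name, exc)
        return None
    if not getattr(est, "converged_", True) or getattr(est, "boundary_", False):
        logger.debug("estimator %s non-estimable (boundary or non-convergence)", name)
        return None
    ab = est.abundance()
    if not np.isfinite(ab.n_hat):
        return None
    return ab.n_hat, ab.ci_low, ab.ci_high


def run_study(
    scenarios,
    estimators=("ql-gee", "pl-glm"),
    reps: int = 1000,
    seed: int = 0,
    return_raw: bool = False,
):
    """Run the Monte-Carlo study over every (scenario, estimator) cell.

    Parameters
    ----------
    scenarios : sequence of Scenario
    estimators : sequence of estimator names (see :data:`ESTIMATORS`)
    reps : number of Monte-Carlo replicates per scenario (>= 1)
    seed : master seed; per-replicate generators are spawned deterministically
        so each replicate is reproducible in isolation.
    return_raw : also return the per-replicate estimates as a tidy DataFrame.

    Returns
    -------
    DataFrame with one row per cell (plus the raw DataFrame when requested).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    scenarios = list(scenarios)
    for sc in scenarios:
        if not isinstance(sc, Scenario):
            raise TypeError("scenarios must be Scenario instances")
    master = np.random.SeedSequence(seed)
    cell_seeds = master.spawn(len(scenarios))
    rows = []
    raw_rows = []
    for sc, cell_ss in zip(scenarios, cell_seeds):
        rep_seeds = cell_ss.spawn(reps)
        n_obs = np.empty(reps)
        results = {name: [] for name in estimators}
        excluded = {name: 0 for name in estimators}
        for r, ss in enumerate(rep_seeds):
            pop = simulate_population(sc, np.random.default_rng(ss))
            n_obs[r] = pop.n_observed
            for name in estimators:
                out = _fit_one(name, pop)
                if out is None:
                    excluded[name] += 1
                else:
                    results[name].append(out)
                    if return_raw:
                        raw_rows.append(
                            {
                                "scenario": sc.name or f"beta0={sc.beta0}",
                                "N": sc.N,
                                "m": sc.m,
                                "estimator": name,
                                "rep": r,
                                "N_hat": out[0],
                                "ci_low": out[1],
                                "ci_high": out[2],
                            }
                        )
        for name in estimators:
            arr = np.array(results[name]).reshape(-1, 3)
            metrics = performance_metrics(sc.N, arr[:, 0], arr[:, 1], arr[:, 2])
            rows.append(
                {
                    "scenario": sc.name or f"beta0={sc.beta0}",
                    "N": sc.N,
                    "m": sc.m,
                    "estimator": name,
                    "n_bar": float(n_obs.mean()),
                    "n_sd": float(n_obs.std(ddof=1)) if reps > 1 else math.nan,
                    **metrics,
                    "reps_used": int(arr.shape[0]),
                    "excluded": excluded[name],
                }
            )
    table = pd.DataFrame(rows)
    if return_raw:
        return table, pd.DataFrame(raw_rows)
    return table
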