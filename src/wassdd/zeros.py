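"""Tests for differential proportions of zero expression (DPZ).

scRNA-seq expression distributions carry a point mass at zero whose weight
is itself biologically informative, so it is tested separately from the
non-zero part:

* single-replicate data (variant A): a Bayesian logistic regression of the
  per-cell zero indicator on condition, with the cellular detection rate
  (CDR — the fraction of genes detected in each cell) as a covariate to
  correct for differences in per-cell coverage.  Weakly-informative
  Cauchy priors (scale 2.5 on standardized predictors, 10 on the
  intercept) regularize the fit and resolve complete separation; inference
  is a Wald z-test on the condition coefficient at the posterior mode.
* replicated data (variant B, paired): the Cochran–Mantel–Haenszel (CMH)
  test over per-replicate 2x2 tables of (condition) x (zero, non-zero),
  the stratified generalization of the classical proportion test.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.contingency_tables import StratifiedTable

__all__ = ["detection_rate", "dpz_logistic", "cmh_test"]

PRIOR_SCALE_COEF = 2.5
PRIOR_SCALE_INTERCEPT = 10.0


def detection_rate(matrix) -> np.ndarray:
    """Per-cell fraction of genes with non-zero expression.

    ``matrix`` is genes x cells; computed on the full (pre-filtered) matrix
    because the CDR is a property of the cell, not of any one gene.
    """
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] == 0:
        raise ValueError("matrix must be 2-d with at least one gene")
    return np.asarray((m > 0).mean(axis=0), dtype=float)


def _neg_log_posterior(beta, x, y, scales):
    eta = x @ beta
    # log(1 + e^eta) - y*eta, computed stably
    nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta))
    return nll + float(np.sum(np.log1p((beta / scales) ** 2)))


def _grad(beta, x, y, scales):
    p = 1.0 / (1.0 + np.exp(-(x @ beta)))
    return x.T @ (p - y) + 2.0 * beta / (scales**2 + beta**2)


def dpz_logistic(zero_indicator, condition, cdr) -> float:
    """DPZ p-value from detection-rate-adjusted Bayesian logistic regression.

    Fits ``zero ~ intercept + condition + cdr`` by posterior-mode
    (Cauchy-penalized likelihood) and returns the two-sided Wald p-value
    for the condition coefficient.  Predictors follow the usual
    weakly-informative-prior preprocessing: the binary condition is
    centred, the CDR is centred and scaled to standard deviation 0.5.
    """
    y = np.asarray(zero_indicator, dtype=float).ravel()
    cond = np.asarray(condition).ravel()
    c = np.asarray(cdr, dtype=float).ravel()
    if not (y.size == cond.size == c.size):
        raise ValueError("zero_indicator, condition and cdr must align")
    if np.any((y != 0) & (y != 1)):
        raise ValueError("zero_indicator must be binary")
    levels = np.unique(cond)
    if levels.size != 2:
        raise ValueError("condition must have exactly two levels")
    g = (cond == levels[1]).astype(float)
    if min(g.sum(), (1 - g).sum()) < 2:
        raise ValueError("need at least 2 cells per condition")

    g_c = g - g.mean()
    sd = c.std()
    c_c = (c - c.mean()) / (2.0 * sd) if sd > 0 else np.zeros_like(c)
    x = np.column_stack([np.ones_like(y), g_c, c_c])
    scales = np.array([PRIOR_SCALE_INTERCEPT, PRIOR_SCALE_COEF, PRIOR_SCALE_COEF])

    res = optimize.minimize(
        _neg_log_posterior, np.zeros(3), args=(x, y, scales),
        jac=_grad, method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    beta = res.x

    # observed information at the mode; prior curvature can be negative in
    # the Cauchy tails, so fall back to the likelihood information if the
    # observed one is not invertible/positive
    p = 1.0 / (1.0 + np.exp(-(x @ beta)))
    w = p * (1.0 - p)
    info_lik = (x * w[:, None]).T @ x
    prior_curv = 2.0 * (scales**2 - beta**2) / (scales**2 + beta**2) ** 2
    for info in (info_lik + np.diag(prior_curv), info_lik + np.diag(2.0 / scales**2)):
        try:
            cov = np.linalg.inv(info)
            if cov[1, 1] > 0:
                break
        except np.linalg.LinAlgError:
            continue
    else:  # pragma: no cover - both fallbacks failed
        return 1.0
    z = beta[1] / np.sqrt(cov[1, 1])
    # floored away from zero so downstream Fisher combination stays defined
    return float(max(2.0 * stats.norm.sf(abs(z)), 1e-300))


def _stratum_ok(t: np.ndarray) -> bool:
    return bool(np.all(t.sum(axis=0) > 0) and np.all(t.sum(axis=1) > 0))


def cmh_test(tables) -> float:
    """Cochran-Mantel-Haenszel p-value over stratified 2x2 tables.

    Each table has rows = condition (A, B) and columns = (zero, non-zero).
    Strata with a zero row or column margin carry no information and are
    skipped; if all strata are degenerate the p-value is 1 with a warning.
    The chi-square statistic (1 df) is used without continuity correction.
    """
    arrs = [np.asarray(t, dtype=float) for t in tables]
    if len(arrs) < 2:
        raise ValueError("CMH test requires at least two strata")
    for t in arrs:
        if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
            raise ValueError("each stratum must be a 2x2 table of counts")
    kept = [t for t in arrs if _stratum_ok(t)]
    if not kept:
        warnings.warn("all strata degenerate; CMH test uninformative", stacklevel=2)
        return 1.0
    stacked = np.stack(kept, axis=-1)
    res = StratifiedTable(stacked).test_null_odds(correction=False)
    return float(max(res.pvalue, 1e-300))
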