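"""Mediator-wise effect estimation and joint-significance testing.

For each mediator surviving penalized selection, the exposure->mediator
effect alpha_k is estimated with the method's confounder adjustment, the
mediator->outcome effect beta_k comes from the penalized fit (SE from the
oracle refit), and both are tested by two-sided normal-approximation tests
with Benjamini-Hochberg correction across the candidate set. A mediator is
declared significant when max(P_BH,alpha, P_BH,beta) <= level: the joint
test rejects only if both pathways are individually significant.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "estimate_alpha",
    "raw_pvalue",
    "bh_adjust",
    "joint_decision",
    "percent_te",
]


def _ols_coef_se(y: np.ndarray, target: np.ndarray, covars: np.ndarray) -> tuple[float, float]:
    """OLS coefficient of ``target`` (plus SE) with ``covars`` partialled out."""
    n = len(y)
    W = np.column_stack([np.ones(n), covars]) if covars.size else np.ones((n, 1))
    # rank-tolerant projection: a redundant covariate column (e.g. a constant
    # score) does not invalidate the target coefficient
    cw, _, rank, _ = np.linalg.lstsq(W, np.column_stack([target, y]), rcond=None)
    tt = target - W @ cw[:, 0]
    yt = y - W @ cw[:, 1]
    denom = tt @ tt
    if denom <= 1e-12 * max(target @ target, 1.0):
        raise ValueError("design is rank-deficient: target collinear with covariates")
    coef = float((tt @ yt) / denom)
    dof = n - rank - 1
    if dof <= 0:
        raise ValueError("not enough observations")
    rss = max(yt @ yt - coef**2 * denom, 0.0)
    return coef, float(np.sqrt(rss / dof / denom))


def _wls_coef_se(y: np.ndarray, x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted OLS coefficient of x (plus SE) in y ~ 1 + x."""
    sw = w.sum()
    xbar = (w @ x) / sw
    ybar = (w @ y) / sw
    xc = x - xbar
    yc = y - ybar
    sxx = w @ (xc * xc)
    if sxx <= 1e-12 * max(float(w @ (x * x)), 1.0):
        raise ValueError("exposure is constant in the weighted sample")
    coef = float((w @ (xc * yc)) / sxx)
    resid = yc - coef * xc
    dof = len(y) - 2
    sigma2 = float(w @ (resid * resid)) / dof
    return coef, float(np.sqrt(sigma2 / sxx))


def estimate_alpha(
    Mk: np.ndarray, X: np.ndarray, adjuster: np.ndarray, method: str
) -> tuple[float, float]:
    """Exposure effect on one mediator under the method's adjustment.

    PSR/PSU: OLS coefficient of X in M_k ~ 1 + X + S (adjuster = scores S).
    PSW: weighted OLS coefficient of X in M_k ~ 1 + X (adjuster = weights).
    COV: OLS coefficient of X in M_k ~ 1 + X + Z (adjuster = confounders Z).
    """
    Mk = np.asarray(Mk, dtype=float).ravel()
    X = np.asarray(X, dtype=float).ravel()
    adjuster = np.asarray(adjuster, dtype=float)
    method = method.upper()
    if method in ("PSR", "PSU"):
        return _ols_coef_se(Mk, X, adjuster.reshape(-1, 1))
    if method == "PSW":
        w = adjuster.ravel()
        if (w <= 0).any():
            raise ValueError("weights must be strictly positive")
        return _wls_coef_se(Mk, X, w)
    if method == "COV":
        Z = adjuster if adjuster.ndim == 2 else adjuster.reshape(-1, 1)
        return _ols_coef_se(Mk, X, Z)
    raise ValueError(f"unknown method {method!r}")


def raw_pvalue(estimate: float, se: float) -> float:
    """Two-sided normal p-value 2*(1 - Phi(|estimate|/se))."""
    if se <= 0:
        raise ValueError(f"standard error must be positive, got {se}")
    return float(2.0 * stats.norm.sf(abs(estimate) / se))


def bh_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_raw, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def joint_decision(
    p_bh_alpha: float, p_bh_beta: float, level: float = 0.05
) -> tuple[float, bool]:
    """Joint-significance p-value (the max) and the decision at ``level``."""
    for p in (p_bh_alpha, p_bh_beta):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {p}")
    p_joint = max(p_bh_alpha, p_bh_beta)
    return p_joint, p_joint <= level


def percent_te(effect_k: float, gamma_hat: float, all_effects: np.ndarray) -> float:
    """Share (in %) of the total effect carried by one mediator.

    100 * alpha_k*beta_k / (gamma + sum of all candidate indirect effects);
    negative when the mediator's effect opposes the total. NaN when the
    denominator is zero.
    """
    denom = gamma_hat + float(np.sum(all_effects))
    if denom == 0:
        return float("nan")
    return 100.0 * effect_k / denom
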