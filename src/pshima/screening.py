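"""Sure independence screening (SIS) of mediators on the outcome side.

Each candidate mediator M_k receives a marginal outcome-model coefficient
``beta_k``; the ``d = ceil(2n / ln n)`` mediators with the largest
|beta_k| (computed on standardized mediators, so the ranking is
scale-free) survive to the penalized-selection stage.

Three marginal estimators implement the confounder adjustments:

* PS-as-covariate (PSR): OLS of Y on (1, X, M_k, S).
* Two-step weighting (PSW and the hybrid PSU): a weighted fit of
  Y ~ 1 + X + M_k yields the direct-effect estimate ``gamma_k,w``; the
  residual e_k = Y - gamma_k,w * X is then regressed on M_k without
  weights. The weighting removes confounding of the X coefficient, after
  which the M_k coefficient is estimated on the de-confounded residual.
* Covariate regression (COV): OLS of Y on (1, X, M_k, Z).

The scalar operations accept raw (unstandardized) inputs; :func:`screen`
standardizes internally and back-transforms reported coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .propensity import PropensityResult
from .simulate import MediationDataset

__all__ = [
    "ScreenResult",
    "sis_dimension",
    "marginal_beta_ps_covariate",
    "marginal_beta_two_step",
    "marginal_beta_cov",
    "screen",
    "METHODS",
]

METHODS = ("PSR", "PSW", "PSU", "COV")

_DEGENERATE_TOL = 1e-10


@dataclass
class ScreenResult:
    """Outcome of SIS for one dataset and method.

    ``kept`` holds 0-based mediator column indices ordered by decreasing
    |marginal beta| on the standardized scale (ties broken by ascending
    index); ``marginal_beta``/``marginal_se`` are on the original scale and
    aligned with ``kept``.
    """

    d: int
    kept: np.ndarray
    marginal_beta: np.ndarray
    marginal_se: np.ndarray
    method: str


def sis_dimension(n: int, p: Optional[int] = None) -> int:
    """Screening dimension d = ceil(2n / ln n), capped at p when given."""
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    d = int(np.ceil(2.0 * n / np.log(n)))
    if p is not None:
        d = min(d, p)
    return d


def _ols_partial(
    Y: np.ndarray, W: np.ndarray, M: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coefficient of each M column in OLS of Y on (W, M_k), via Frisch-Waugh.

    W must include the intercept column. Returns (beta, se, ok) with
    ``ok[k]`` False when M_k is collinear with W (those get beta 0, se inf).
    """
    n, q = W.shape
    if np.linalg.matrix_rank(W) < q:
        raise ValueError("fixed covariate block is rank-deficient")
    G = W.T @ W
    Mt = M - W @ np.linalg.solve(G, W.T @ M)
    Yt = Y - W @ np.linalg.solve(G, W.T @ Y)
    mm = np.einsum("ij,ij->j", Mt, Mt)
    scale = np.maximum(np.einsum("ij,ij->j", M, M), 1.0)
    ok = mm > _DEGENERATE_TOL * scale
    mm_safe = np.where(ok, mm, 1.0)
    beta = np.where(ok, (Mt.T @ Yt) / mm_safe, 0.0)
    dof = n - q - 1
    if dof <= 0:
        raise ValueError("not enough observations for the marginal regression")
    rss = np.maximum(Yt @ Yt - beta**2 * mm, 0.0)
    se = np.where(ok, np.sqrt(rss / dof / mm_safe), np.inf)
    return beta, se, ok


def _two_step_all(
    Y: np.ndarray, X: np.ndarray, M: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-step weighted estimator for every mediator column.

    Returns (beta, se, ok, gamma_w) where gamma_w[k] is the weighted
    direct-effect estimate from step 1.
    """
    n = len(Y)
    p = M.shape[1]
    sw = w.sum()
    swx = w @ X
    swx2 = w @ (X * X)
    swy = w @ Y
    swxy = (w * X) @ Y
    wM = w[:, None] * M
    swm = wM.sum(axis=0)
    swxm = (w * X) @ M
    swm2 = np.einsum("ij,ij->j", wM, M)
    swmy = (w * Y) @ M

    A = np.empty((p, 3, 3))
    A[:, 0, 0] = sw
    A[:, 0, 1] = A[:, 1, 0] = swx
    A[:, 0, 2] = A[:, 2, 0] = swm
    A[:, 1, 1] = swx2
    A[:, 1, 2] = A[:, 2, 1] = swxm
    A[:, 2, 2] = swm2
    b = np.empty((p, 3))
    b[:, 0] = swy
    b[:, 1] = swxy
    b[:, 2] = swmy

    dets = np.linalg.det(A)
    scale = max(float(sw) ** 3, 1.0)
    ok = np.abs(dets) > _DEGENERATE_TOL * scale
    A_safe = np.where(ok[:, None, None], A, np.eye(3)[None, :, :])
    sol = np.linalg.solve(A_safe, b[:, :, None])[:, :, 0]
    gamma_w = np.where(ok, sol[:, 1], 0.0)

    # step 2: residualize the weighted direct effect; step 3: plain OLS on M_k
    E = Y[:, None] - X[:, None] * gamma_w[None, :]
    Mbar = M.mean(axis=0)
    Mc = M - Mbar[None, :]
    sxx = np.einsum("ij,ij->j", Mc, Mc)
    ok = ok & (sxx > _DEGENERATE_TOL * np.maximum(np.einsum("ij,ij->j", M, M), 1.0))
    sxx_safe = np.where(ok, sxx, 1.0)
    sxy = np.einsum("ij,ij->j", Mc, E)
    beta = np.where(ok, sxy / sxx_safe, 0.0)
    ebar = E.mean(axis=0)
    syy = np.einsum("ij,ij->j", E, E) - n * ebar**2
    rss = np.maximum(syy - beta**2 * sxx, 0.0)
    se = np.where(ok, np.sqrt(rss / (n - 2) / sxx_safe), np.inf)
    return beta, se, ok, gamma_w


def marginal_beta_ps_covariate(
    Y: np.ndarray, X: np.ndarray, Mk: np.ndarray, S: np.ndarray
) -> tuple[float, float]:
    """Coefficient of M_k (and its SE) in OLS of Y ~ 1 + X + M_k + S."""
    Y, X, Mk, S = (np.asarray(v, dtype=float).ravel() for v in (Y, X, Mk, S))
    W = np.column_stack([np.ones_like(Y), X, S])
    beta, se, ok = _ols_partial(Y, W, Mk[:, None])
    if not ok[0]:
        return 0.0, float("inf")
    return float(beta[0]), float(se[0])


def marginal_beta_two_step(
    Y: np.ndarray, X: np.ndarray, Mk: np.ndarray, weights: np.ndarray
) -> tuple[float, float]:
    """Two-step weighted marginal estimate of the M_k outcome coefficient.

    Step 1: weighted least squares of Y ~ 1 + X + M_k gives gamma_k,w.
    Step 2: e_k = Y - gamma_k,w * X.
    Step 3: unweighted OLS of e_k ~ 1 + M_k gives (beta_k, SE).
    """
    Y, X, Mk, w = (np.asarray(v, dtype=float).ravel() for v in (Y, X, Mk, weights))
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    beta, se, ok, _ = _two_step_all(Y, X, Mk[:, None], w)
    if not ok[0]:
        return 0.0, float("inf")
    return float(beta[0]), float(se[0])


def marginal_beta_cov(
    Y: np.ndarray, X: np.ndarray, Mk: np.ndarray, Z: np.ndarray
) -> tuple[float, float]:
    """Coefficient of M_k (and its SE) in OLS of Y ~ 1 + X + M_k + Z."""
    Y, X, Mk = (np.asarray(v, dtype=float).ravel() for v in (Y, X, Mk))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z.reshape(-1, 1) if Z.size else Z.reshape(len(Y), 0)
    W = np.column_stack([np.ones_like(Y), X, Z])
    beta, se, ok = _ols_partial(Y, W, Mk[:, None])
    if not ok[0]:
        return 0.0, float("inf")
    return float(beta[0]), float(se[0])


def _marginal_betas(
    dataset: MediationDataset,
    method: str,
    propensity: Optional[PropensityResult],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized-scale marginal betas for every mediator column."""
    Y, X, M = dataset.Y, dataset.X, dataset.M
    sd = M.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Ms = (M - M.mean(axis=0)) / sd_safe
    if method in ("PSW", "PSU"):
        if propensity is None:
            raise ValueError(f"{method} screening requires a PropensityResult")
        beta, se, ok, _ = _two_step_all(Y, X, Ms, propensity.weights)
    elif method == "PSR":
        if propensity is None:
            raise ValueError("PSR screening requires a PropensityResult")
        W = np.column_stack([np.ones_like(Y), X, propensity.scores])
        beta, se, ok = _ols_partial(Y, W, Ms)
    elif method == "COV":
        W = np.column_stack([np.ones_like(Y), X, dataset.Z])
        beta, se, ok = _ols_partial(Y, W, Ms)
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    ok = ok & (sd > 0)
    return beta, se, ok


def screen(
    dataset: MediationDataset,
    method: str,
    propensity: Optional[PropensityResult] = None,
    d: Optional[int] = None,
) -> ScreenResult:
    """Keep the top-d mediators by |marginal beta| for the given method.

    ``d`` defaults to ``sis_dimension(n, p)``; degenerate mediator columns
    (constant, or collinear with the adjusters) are excluded from ranking.
    """
    if d is None:
        d = sis_dimension(dataset.n, dataset.p)
    d = min(d, dataset.p)
    beta_std, se_std, ok = _marginal_betas(dataset, method, propensity)
    candidates = np.flatnonzero(ok)
    # stable sort on ascending index, then stable sort by descending |beta|
    order = candidates[np.argsort(-np.abs(beta_std[candidates]), kind="stable")]
    kept = order[: min(d, len(order))]
    sd = dataset.M.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return ScreenResult(
        d=d,
        kept=kept,
        marginal_beta=beta_std[kept] / sd_safe[kept],
        marginal_se=se_std[kept] / sd_safe[kept],
        method=method,
    )
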