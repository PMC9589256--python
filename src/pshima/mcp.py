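"""Minimax concave penalty (MCP) regression for mediator selection.

The outcome model is fit on the screened mediators by minimizing

    (1/2n) * sum_i w_i (Y_i - c - gamma X_i - u'extra_i - sum_j beta_j M_ij)^2
        + sum_j p(beta_j; lambda, delta)

where only the mediator coefficients are penalized and

    p(b) = lambda (|b| - b^2 / (2 delta lambda))   for |b| <  delta*lambda
         = delta * lambda^2 / 2                     for |b| >= delta*lambda.

MCP applies soft-threshold-like shrinkage near zero but leaves large
coefficients unpenalized, which yields (near-)unbiased estimates of strong
effects and the oracle property that justifies post-selection least-squares
standard errors. Columns are standardized internally (the 1/2n loss scaling
and unit-variance columns follow the ncvreg convention, so lambda is on the
familiar scale); reported coefficients are back-transformed.

Solved by cyclic coordinate descent with warm starts along a decreasing
lambda path; each coordinate update is the closed-form firm threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

__all__ = [
    "McpFit",
    "mcp_penalty",
    "firm_threshold",
    "fit_mcp_path",
    "select_lambda",
    "oracle_se",
    "McpConvergenceError",
]

DEFAULT_DELTA = 3.0
DEFAULT_NLAMBDA = 50
LAMBDA_MIN_RATIO = 0.01
_TOL = 1e-7
_MAX_SWEEPS = 10_000


class McpConvergenceError(RuntimeError):
    pass


@dataclass
class McpFit:
    """One solution on the regularization path (original variable scale)."""

    beta: np.ndarray          # penalized mediator coefficients
    gamma_hat: float          # unpenalized coefficient of X
    extra_coef: np.ndarray    # unpenalized coefficients of extra covariates
    intercept: float
    support: np.ndarray       # indices j with beta[j] != 0
    lam: float
    delta: float
    rss: float                # (weighted) residual sum of squares
    n: int
    df: int                   # support size + number of unpenalized terms
    converged: bool
    n_sweeps: int
    se: Optional[np.ndarray] = None          # oracle SEs, aligned with support
    ic_path: Optional[list[tuple[float, float]]] = field(default=None, repr=False)


def mcp_penalty(b, lam: float, delta: float = DEFAULT_DELTA):
    """Evaluate the MCP penalty elementwise."""
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    b = np.asarray(b, dtype=float)
    ab = np.abs(b)
    if lam == 0:
        out = np.zeros_like(ab)
    else:
        out = np.where(
            ab < delta * lam,
            lam * (ab - ab**2 / (2.0 * delta * lam)),
            delta * lam**2 / 2.0,
        )
    return out if out.ndim else float(out)


def firm_threshold(z, lam: float, delta: float = DEFAULT_DELTA):
    """argmin_b 0.5*(b - z)^2 + mcp_penalty(b; lam, delta), elementwise.

    Zero inside |z| <= lam, inflated soft-threshold up to delta*lam, and the
    identity beyond (where the penalty is flat).
    """
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    if delta <= 1:
        raise ValueError(f"delta must exceed 1, got {delta}")
    z = np.asarray(z, dtype=float)
    az = np.abs(z)
    mid = np.sign(z) * (az - lam) / (1.0 - 1.0 / delta)
    out = np.where(az <= lam, 0.0, np.where(az <= delta * lam, mid, z))
    return out if out.ndim else float(out)


@njit(cache=True, inline="always")
def _update_coord(D, y, b, r, j, n, n_unpen, lam, dl, inv_factor):  # pragma: no cover
    bj = b[j]
    z = bj + np.dot(D[:, j], r) / n
    if j < n_unpen:
        new = z
    else:
        az = abs(z)
        if az <= lam:
            new = 0.0
        elif az <= dl:
            s = 1.0 if z > 0 else -1.0
            new = s * (az - lam) * inv_factor
        else:
            new = z
    diff = new - bj
    if diff != 0.0:
        r -= diff * D[:, j]
        b[j] = new
    return abs(diff)


@njit(cache=True)
def _cd_path(D, y, n_unpen, lambdas, delta, tol, max_sweeps):  # pragma: no cover
    """Warm-started coordinate descent over a decreasing lambda grid.

    D: n x m design, columns with mean-0 (in the working metric) and
    x'x/n == 1; the first ``n_unpen`` columns are unpenalized. Uses the
    usual active-set strategy: converge on the currently nonzero set, then
    make one full pass to admit violators, repeating until the full pass is
    itself stationary.
    """
    n, m = D.shape
    nl = len(lambdas)
    coefs = np.zeros((nl, m))
    sweeps = np.zeros(nl, dtype=np.int64)
    conv = np.zeros(nl, dtype=np.bool_)
    b = np.zeros(m)
    r = y.copy()
    active = np.zeros(m, dtype=np.int64)
    inv_factor = 1.0 / (1.0 - 1.0 / delta)
    for li in range(nl):
        lam = lambdas[li]
        dl = delta * lam
        it = 0
        converged = False
        while it < max_sweeps:
            # converge on the active (unpenalized or nonzero) coordinates
            n_act = 0
            for j in range(m):
                if j < n_unpen or b[j] != 0.0:
                    active[n_act] = j
                    n_act += 1
            while it < max_sweeps:
                it += 1
                max_change = 0.0
                for a in range(n_act):
                    ch = _update_coord(D, y, b, r, active[a], n, n_unpen, lam, dl, inv_factor)
                    if ch > max_change:
                        max_change = ch
                if max_change < tol:
                    break
            # one full pass over every coordinate
            it += 1
            max_change = 0.0
            for j in range(m):
                ch = _update_coord(D, y, b, r, j, n, n_unpen, lam, dl, inv_factor)
                if ch > max_change:
                    max_change = ch
            if max_change < tol:
                converged = True
                break
        sweeps[li] = it
        conv[li] = converged
        coefs[li, :] = b
    return coefs, sweeps, conv


def fit_mcp_path(
    Y: np.ndarray,
    X: np.ndarray,
    M: np.ndarray,
    extra: Optional[np.ndarray] = None,
    weights: Optional[np.ndarray] = None,
    lambda_grid: Optional[Sequence[float]] = None,
    nlambda: int = DEFAULT_NLAMBDA,
    delta: float = DEFAULT_DELTA,
    tol: float = _TOL,
    max_sweeps: int = _MAX_SWEEPS,
    strict: bool = True,
) -> list[McpFit]:
    """Solve the MCP-penalized outcome model along a lambda path.

    X and the optional ``extra`` covariates (e.g. the propensity score for
    the PS-regression variant, or the confounders for direct covariate
    adjustment) are never penalized. ``weights`` turn the squared-error
    loss into a weighted loss (default: unweighted). When ``lambda_grid``
    is omitted, 50 log-spaced values from lambda_max (smallest lambda with
    an empty mediator support) down to 0.01*lambda_max are used.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    X = np.asarray(X, dtype=float).ravel()
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.shape[0] != len(Y):
        raise ValueError("M and Y have inconsistent numbers of rows")
    n, d = M.shape
    if extra is not None:
        extra = np.asarray(extra, dtype=float)
        if extra.ndim == 1:
            extra = extra.reshape(-1, 1)
    else:
        extra = np.empty((n, 0))
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if (w <= 0).any():
            raise ValueError("weights must be strictly positive")
    if delta <= 1:
        raise ValueError(f"delta must exceed 1, got {delta}")

    U = np.column_stack([X, extra])  # unpenalized, X first
    q = U.shape[1]
    raw = np.column_stack([U, M])
    wsum = w.sum()
    wmean = (w @ raw) / wsum
    ymean = (w @ Y) / wsum
    sw = np.sqrt(w)
    Dc = sw[:, None] * (raw - wmean[None, :])
    yc = sw * (Y - ymean)
    scale = np.sqrt(np.einsum("ij,ij->j", Dc, Dc) / n)
    if (scale[:q] <= 0).any():
        raise ValueError("an unpenalized covariate is constant (rank-deficient design)")
    keep_pen = scale[q:] > 0  # constant mediators stay at coefficient 0
    scale_safe = np.where(scale > 0, scale, 1.0)
    D = np.asfortranarray(Dc / scale_safe[None, :])
    if not keep_pen.all():
        D = np.asfortranarray(D[:, np.concatenate([np.ones(q, bool), keep_pen])])

    if lambda_grid is None:
        # residual of the unpenalized-only fit determines lambda_max
        Uc = D[:, :q]
        coef_u, *_ = np.linalg.lstsq(Uc, yc, rcond=None)
        r0 = yc - Uc @ coef_u
        lam_max = float(np.abs(D[:, q:].T @ r0).max() / n) if D.shape[1] > q else 1e-8
        lam_max = max(lam_max, 1e-8)
        lambdas = np.geomspace(lam_max, LAMBDA_MIN_RATIO * lam_max, nlambda)
    else:
        lambdas = np.asarray(lambda_grid, dtype=float)
        if len(lambdas) > 1 and not (np.diff(lambdas) < 0).all():
            raise ValueError("lambda_grid must be strictly decreasing")
        if (lambdas < 0).any():
            raise ValueError("lambda values must be non-negative")

    coefs_std, sweeps, conv = _cd_path(
        D, yc, q, lambdas, float(delta), float(tol), int(max_sweeps)
    )
    if not conv.all():
        # cyclic coordinate descent can cycle between local minima of the
        # non-convex objective when mediators are strongly correlated
        bad = int(np.flatnonzero(~conv)[0])
        if strict:
            raise McpConvergenceError(
                f"coordinate descent did not converge at lambda index {bad} "
                f"(lambda={lambdas[bad]:.4g}) within {max_sweeps} sweeps"
            )

    fits: list[McpFit] = []
    pen_idx = np.flatnonzero(keep_pen)
    for li, lam in enumerate(lambdas):
        b_std = coefs_std[li]
        resid = yc - D @ b_std
        rss = float(resid @ resid)
        full = np.zeros(q + d)
        full[:q] = b_std[:q] / scale_safe[:q]
        full[q + pen_idx] = b_std[q:] / scale_safe[q:][keep_pen]
        beta = full[q:]
        support = np.flatnonzero(beta != 0.0)
        intercept = float(ymean - wmean @ full)
        fits.append(
            McpFit(
                beta=beta,
                gamma_hat=float(full[0]),
                extra_coef=full[1:q].copy(),
                intercept=intercept,
                support=support,
                lam=float(lam),
                delta=float(delta),
                rss=rss,
                n=n,
                df=len(support) + q + 1,
                converged=bool(conv[li]),
                n_sweeps=int(sweeps[li]),
            )
        )
    return fits


def select_lambda(
    path: Sequence[McpFit],
    criterion: str = "bic",
    n_candidates: Optional[int] = None,
    ebic_gamma: float = 1.0,
) -> McpFit:
    """Pick the path fit minimizing an information criterion.

    ``bic``: n*ln(RSS/n) + df*ln(n); ``aic``: 2*df instead; ``ebic``: the
    extended BIC, which adds 2*gamma*df*ln(d) for d screened candidates —
    plain BIC loses model-selection consistency when the candidate count d
    grows with n, and EBIC restores it. df counts the selected mediators
    plus all unpenalized terms (intercept included).
    """
    if len(path) == 0:
        raise ValueError("empty path")
    path = [f for f in path if f.converged]
    if not path:
        raise McpConvergenceError("no converged fit on the lambda path")
    criterion = criterion.lower()
    if criterion not in ("bic", "aic", "ebic"):
        raise ValueError(f"criterion must be 'bic', 'aic' or 'ebic', got {criterion!r}")
    if criterion == "ebic" and n_candidates is None:
        n_candidates = len(path[0].beta)
    ic_path = []
    best, best_ic = None, np.inf
    for fit in path:
        n = fit.n
        rss = max(fit.rss, 1e-300)
        if criterion == "aic":
            pen = 2.0 * fit.df
        elif criterion == "bic":
            pen = fit.df * np.log(n)
        else:
            pen = fit.df * (np.log(n) + 2.0 * ebic_gamma * np.log(max(n_candidates, 1)))
        ic = n * np.log(rss / n) + pen
        ic_path.append((fit.lam, float(ic)))
        if ic < best_ic:
            best, best_ic = fit, ic
    best.ic_path = ic_path
    return best


def oracle_se(
    Y: np.ndarray,
    X: np.ndarray,
    M_support: np.ndarray,
    extra: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Post-selection standard errors for the support mediators.

    Unpenalized OLS refit of Y on (1, X, extra, M_support); the MCP oracle
    property makes this the asymptotically valid inference after selection.
    Returns the SEs of the mediator coefficients (empty for empty support).
    """
    M_support = np.atleast_2d(np.asarray(M_support, dtype=float))
    if M_support.size == 0 or M_support.shape[1] == 0:
        return np.empty(0)
    Y = np.asarray(Y, dtype=float).ravel()
    X = np.asarray(X, dtype=float).ravel()
    cols = [np.ones_like(Y), X]
    if extra is not None:
        extra = np.asarray(extra, dtype=float)
        if extra.ndim == 1:
            extra = extra.reshape(-1, 1)
        cols.append(extra)
    Dm = np.column_stack(cols + [M_support])
    q = Dm.shape[1] - M_support.shape[1]
    coef, _, rank, _ = np.linalg.lstsq(Dm, Y, rcond=None)
    if rank < Dm.shape[1]:
        raise ValueError("refit design is rank-deficient")
    resid = Y - Dm @ coef
    dof = len(Y) - Dm.shape[1]
    if dof <= 0:
        raise ValueError("not enough observations for the oracle refit")
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(Dm.T @ Dm)
    return np.sqrt(np.diag(cov)[q:])
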