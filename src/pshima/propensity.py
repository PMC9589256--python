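"""Propensity-score estimation and inverse-probability weights.

The propensity score S_i = P(X_i = 1 | Z_i) concentrates all measured
confounders into one scalar. It is estimated by maximum-likelihood logistic
regression (IRLS); the Horvitz-Thompson-style weights

    w_i = X_i / S_i + (1 - X_i) / (1 - S_i)

re-weight the sample so that exposure is (approximately) independent of the
baseline covariates. Weights are not normalized, and scores are not trimmed
unless ``clip`` is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = ["PropensityResult", "fit_propensity", "ipw_weights", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """Raised when the logistic MLE does not exist or IRLS fails."""


@dataclass
class PropensityResult:
    coef: np.ndarray  # (l0, l1..lw)
    scores: np.ndarray  # S in (0, 1)
    weights: np.ndarray  # w > 1
    converged: bool
    n_iter: int


# Scores this close to 0/1 indicate (quasi-)separation: the MLE diverges.
_SEPARATION_TOL = 1e-10


def fit_propensity(
    X: np.ndarray,
    Z: np.ndarray,
    clip: bool = False,
    clip_bounds: tuple[float, float] = (0.01, 0.99),
) -> PropensityResult:
    """Fit logit(S) = l0 + l'Z by IRLS and build IPW weights.

    With ``clip`` the fitted scores are truncated to ``clip_bounds`` before
    weighting (off by default: the plain MLE scores are used as-is).
    """
    X = np.asarray(X, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z.reshape(-1, 1) if Z.size else Z.reshape(len(X), 0)
    if Z.shape[0] != len(X):
        raise ValueError("X and Z have inconsistent numbers of rows")
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("X must be binary 0/1")
    n1 = X.sum()
    if n1 == 0 or n1 == len(X):
        raise ValueError("both exposure groups must be non-empty")

    design = sm.add_constant(Z, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("confounder matrix is rank-deficient after adding an intercept")

    model = sm.GLM(X, design, family=sm.families.Binomial())
    try:
        fit = model.fit(maxiter=100, tol=1e-8)
    except Exception as exc:  # pragma: no cover - statsmodels failure modes vary
        raise ConvergenceError(f"logistic IRLS failed: {exc}") from exc

    scores = np.asarray(fit.fittedvalues, dtype=float)
    if (scores < _SEPARATION_TOL).any() or (scores > 1 - _SEPARATION_TOL).any():
        raise ConvergenceError(
            "fitted scores reached 0/1: the exposure groups are (quasi-)separated "
            "and the logistic MLE does not exist"
        )
    if clip:
        scores = np.clip(scores, *clip_bounds)
    weights = ipw_weights(X, scores)
    return PropensityResult(
        coef=np.asarray(fit.params, dtype=float),
        scores=scores,
        weights=weights,
        converged=bool(fit.converged),
        n_iter=int(getattr(fit, "fit_history", {}).get("iteration", 0) or 0),
    )


def ipw_weights(X: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Elementwise w = X/S + (1-X)/(1-S)."""
    X = np.asarray(X, dtype=float).ravel()
    S = np.asarray(S, dtype=float).ravel()
    if X.shape != S.shape:
        raise ValueError("X and S must have the same length")
    if ((S <= 0) | (S >= 1)).any():
        raise ValueError("scores must lie strictly inside (0, 1)")
    return X / S + (1.0 - X) / (1.0 - S)
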