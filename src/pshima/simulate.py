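"""Synthetic data for high-dimensional mediation studies with confounding.

The generator reproduces a standard observational-epigenomics benchmark:
ten baseline confounders (five independent Bernoulli(0.3), five jointly
normal with exchangeable 0.3 correlation) drive both a binary exposure
(logistic assignment) and linear mediator/outcome models,

    M_k = c_k + alpha_k * X + Theta' Z + e_k,      e_k ~ N(0, sigma_e^2)
    Y   = c   + gamma  * X + beta' M  + Phi' Z + xi, xi ~ N(0, sigma_xi^2)

so that naive (unadjusted) mediation estimates are confounded by design.
Only the first eight mediators carry a true indirect effect alpha_k*beta_k;
positions 9-12 are decoys with exactly one of alpha, beta nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SimulationConfig",
    "MediationDataset",
    "generate_confounders",
    "generate_exposure",
    "mode_coefficients",
    "generate_dataset",
    "DEFAULT_EXPOSURE_COEF",
    "DEFAULT_THETA",
    "DEFAULT_PHI",
    "BASE_EFFECT",
]

#: Base effect profile t; mode m uses alpha = a_m * t, beta = b_m * t on the
#: first eight mediators.
BASE_EFFECT = np.array([0.50, 0.60, 0.75, 0.80, 1.00, 1.20, 1.50, 2.00])

#: Logistic exposure coefficients l_1..l_10 (intercept l_0 defaults to 0).
DEFAULT_EXPOSURE_COEF = np.array(
    [0.1, 0.3, 0.4, 0.4, 0.6, 0.1, 0.3, 0.4, 0.4, 0.6]
)

#: Confounder -> mediator coefficients Theta (shared across mediators).
DEFAULT_THETA = np.array([0.2, 0.3, 0.3, 0.5, 0.6, 0.2, 0.3, 0.3, 0.5, 0.6])

#: Confounder -> outcome coefficients Phi.
DEFAULT_PHI = np.array([0.1, 0.3, 0.4, 0.4, 0.6, 0.1, 0.3, 0.4, 0.4, 0.6])

_N_CONFOUNDERS = 10
_N_BERNOULLI = 5
_BERNOULLI_P = 0.3
_NORMAL_CORR = 0.3

# Scale factors (a, b) per mode: alpha = a*t, beta = b*t on mediators 1-8.
_MODE_SCALES = {1: (0.6, 0.4), 2: (0.5, 0.5), 3: (0.4, 0.6)}


def _exchangeable_cov(dim: int, rho: float) -> np.ndarray:
    sigma = np.full((dim, dim), rho)
    np.fill_diagonal(sigma, 1.0)
    return sigma


@dataclass
class SimulationConfig:
    """Full description of one simulated mediation study.

    Defaults correspond to the benchmark's mode-1 setting; ``sigma_e`` and
    ``sigma_xi`` are standard deviations.
    """

    n: int = 300
    p: int = 1000
    mode: int = 1
    seed: int = 1
    l0: float = 0.0
    l: np.ndarray = field(default_factory=lambda: DEFAULT_EXPOSURE_COEF.copy())
    Theta: np.ndarray = field(default_factory=lambda: DEFAULT_THETA.copy())
    Phi: np.ndarray = field(default_factory=lambda: DEFAULT_PHI.copy())
    gamma: float = 0.5
    c: float = 0.5
    intercept_range: tuple[float, float] = (0.0, 2.0)
    sigma_e: float = 1.2
    sigma_xi: float = 1.0
    alpha: Optional[np.ndarray] = None  # overrides mode_coefficients if set
    beta: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=float)
        self.Theta = np.asarray(self.Theta, dtype=float)
        self.Phi = np.asarray(self.Phi, dtype=float)
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.alpha is None and self.beta is None and self.p < 12:
            raise ValueError(f"p must be >= 12 for the mode layouts, got {self.p}")
        if self.mode not in _MODE_SCALES:
            raise ValueError(f"mode must be one of {sorted(_MODE_SCALES)}, got {self.mode}")
        if self.sigma_e < 0 or self.sigma_xi < 0:
            raise ValueError("noise scales must be non-negative")
        for name, vec in (("l", self.l), ("Theta", self.Theta), ("Phi", self.Phi)):
            if vec.shape != (_N_CONFOUNDERS,):
                raise ValueError(f"{name} must have length {_N_CONFOUNDERS}, got {vec.shape}")
        if self.alpha is not None:
            self.alpha = np.asarray(self.alpha, dtype=float)
            if self.alpha.shape != (self.p,):
                raise ValueError("alpha must have length p")
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float)
            if self.beta.shape != (self.p,):
                raise ValueError("beta must have length p")

    def effects(self) -> tuple[np.ndarray, np.ndarray]:
        """The (alpha, beta) vectors actually used for generation."""
        if self.alpha is not None and self.beta is not None:
            return self.alpha, self.beta
        alpha, beta = mode_coefficients(self.mode, self.p)
        if self.alpha is not None:
            alpha = self.alpha
        if self.beta is not None:
            beta = self.beta
        return alpha, beta


@dataclass
class MediationDataset:
    """One study's exposure, outcome, mediators and confounders.

    Samples are rows. ``true_alpha``/``true_beta`` are present for simulated
    data only.
    """

    X: np.ndarray
    Y: np.ndarray
    M: np.ndarray
    Z: np.ndarray
    true_alpha: Optional[np.ndarray] = None
    true_beta: Optional[np.ndarray] = None
    mediator_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float).ravel()
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        self.M = np.atleast_2d(np.asarray(self.M, dtype=float))
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim == 1:
            self.Z = self.Z.reshape(-1, 1) if self.Z.size else self.Z.reshape(len(self.X), 0)
        n = len(self.X)
        if self.Y.shape != (n,):
            raise ValueError(f"Y has length {self.Y.shape[0]}, expected {n}")
        if self.M.shape[0] != n:
            raise ValueError(f"M has {self.M.shape[0]} rows, expected {n}")
        if self.Z.shape[0] != n:
            raise ValueError(f"Z has {self.Z.shape[0]} rows, expected {n}")
        if not np.isin(self.X, (0.0, 1.0)).all():
            raise ValueError("X must be binary 0/1")
        for name, arr in (("X", self.X), ("Y", self.Y), ("M", self.M), ("Z", self.Z)):
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains missing or non-finite values")
        if self.mediator_names is None:
            self.mediator_names = [f"M{k + 1}" for k in range(self.M.shape[1])]

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def p(self) -> int:
        return self.M.shape[1]

    @property
    def w(self) -> int:
        return self.Z.shape[1]


def generate_confounders(n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw the n x 10 confounder matrix.

    Columns 1-5 are independent Bernoulli(0.3); columns 6-10 are jointly
    normal with zero mean, unit variances and 0.3 exchangeable correlation.
    """
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    zb = (rng.random((n, _N_BERNOULLI)) < _BERNOULLI_P).astype(float)
    chol = np.linalg.cholesky(
        _exchangeable_cov(_N_CONFOUNDERS - _N_BERNOULLI, _NORMAL_CORR)
    )
    zn = rng.standard_normal((n, _N_CONFOUNDERS - _N_BERNOULLI)) @ chol.T
    return np.hstack([zb, zn])


def generate_exposure(
    Z: np.ndarray,
    l: np.ndarray,
    seed: int | np.random.Generator,
    l0: float = 0.0,
) -> np.ndarray:
    """Draw binary exposure with P(X=1|Z) = logistic(l0 + l'Z)."""
    Z = np.asarray(Z, dtype=float)
    l = np.asarray(l, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != l.shape[0]:
        raise ValueError(
            f"coefficient length {l.shape[0]} does not match Z with {Z.shape} columns"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eta = l0 + Z @ l
    pz = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(Z.shape[0]) < pz).astype(float)


def mode_coefficients(mode: int, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Full length-p (alpha, beta) vectors for effect mode 1, 2 or 3.

    Mediators 1-8 carry alpha_k*beta_k != 0; 9-10 are beta-only decoys,
    11-12 alpha-only decoys; everything beyond is zero.
    """
    if mode not in _MODE_SCALES:
        raise ValueError(f"unknown mode {mode}; expected one of {sorted(_MODE_SCALES)}")
    if p < 12:
        raise ValueError(f"p must be >= 12, got {p}")
    a_scale, b_scale = _MODE_SCALES[mode]
    alpha = np.zeros(p)
    beta = np.zeros(p)
    alpha[:8] = a_scale * BASE_EFFECT
    beta[:8] = b_scale * BASE_EFFECT
    decoy = b_scale * BASE_EFFECT[-1]  # magnitude of the strongest beta
    alpha[10:12] = a_scale * BASE_EFFECT[-1]
    beta[8:10] = decoy
    return alpha, beta


def generate_dataset(config: SimulationConfig) -> MediationDataset:
    """Generate one study under the linear structural model.

    A single seeded generator drives all draws in a fixed order
    (Z, X, mediator intercepts, mediator noise, outcome noise), so identical
    configs give bit-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n, config.p
    alpha, beta = config.effects()

    Z = generate_confounders(n, rng)
    X = generate_exposure(Z, config.l, rng, l0=config.l0)
    lo, hi = config.intercept_range
    ck = rng.uniform(lo, hi, size=p)
    e = rng.standard_normal((n, p))
    xi = rng.standard_normal(n)

    zeff = Z @ config.Theta  # shared across mediators
    M = (
        ck[None, :]
        + X[:, None] * alpha[None, :]
        + zeff[:, None]
        + config.sigma_e * e
    )
    Y = (
        config.c
        + config.gamma * X
        + M @ beta
        + Z @ config.Phi
        + config.sigma_xi * xi
    )
    return MediationDataset(
        X=X, Y=Y, M=M, Z=Z, true_alpha=alpha, true_beta=beta
    )
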