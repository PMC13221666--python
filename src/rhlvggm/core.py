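"""Numeric primitives shared by the EM and ADMM solvers.

The model is a K-component Gaussian mixture with a shared precision matrix
Theta = S - L (S sparse: direct conditional dependencies; L positive
semi-definite and low-rank: the footprint of marginalised latent variables),
plus an improper uniform "noise" component of constant density ``delta``
weighted by ``pi_0`` that absorbs outliers.  This module holds the domain
containers, the Gaussian log-density evaluated on the precision side, the
minimax concave penalty (MCP) with its proximal operator, soft thresholding,
eigenvalue projection onto the PSD cone, and the penalised objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.special import logsumexp

__all__ = [
    "DefinitenessError",
    "ObservedData",
    "ModelParameters",
    "PenaltyConfig",
    "ObjectiveValue",
    "gaussian_logdensity",
    "mcp_penalty",
    "soft_threshold",
    "mcp_prox",
    "project_psd",
    "mixture_logdensity",
    "penalized_objective",
]


class DefinitenessError(ValueError):
    """Raised when a matrix that must be positive definite is not."""


@dataclass
class ObservedData:
    """An n-samples by p-variables data matrix with optional column names."""

    X: np.ndarray
    var_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-dimensional, got shape {self.X.shape}")
        if not np.all(np.isfinite(self.X)):
            bad = np.argwhere(~np.isfinite(self.X))[0]
            raise ValueError(f"X contains a non-finite value at row {bad[0]}, column {bad[1]}")
        n, p = self.X.shape
        if n < 2 or p < 2:
            raise ValueError(f"need n >= 2 and p >= 2, got n={n}, p={p}")
        if self.var_names is not None and len(self.var_names) != p:
            raise ValueError("var_names length must equal p")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class ModelParameters:
    """Full estimand set (mu_1..mu_K, delta, S, L, pi_0..pi_K)."""

    K: int
    mu: np.ndarray          # (K, p)
    delta: float            # improper uniform density, in [0, 1)
    S: np.ndarray           # (p, p) sparse component
    L: np.ndarray           # (p, p) low-rank PSD component
    pi: np.ndarray          # (K+1,) with pi[0] the noise weight

    @property
    def theta(self) -> np.ndarray:
        return self.S - self.L

    def validate(self, atol: float = 1e-8) -> None:
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.pi = np.asarray(self.pi, dtype=float)
        if self.mu.shape[0] != self.K:
            raise ValueError(f"mu must have K={self.K} rows, got {self.mu.shape[0]}")
        if self.pi.shape != (self.K + 1,):
            raise ValueError(f"pi must have length K+1={self.K + 1}")
        if np.any(self.pi < -1e-10) or np.any(self.pi > 1 + 1e-10):
            raise ValueError("pi entries must lie in [0, 1]")
        if abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError(f"pi must sum to 1, got {self.pi.sum()!r}")
        if not (0.0 <= self.delta < 1.0):
            raise ValueError(f"delta must lie in [0, 1), got {self.delta}")
        for name, M in (("S", self.S), ("L", self.L)):
            if not np.allclose(M, M.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
        lmin = float(linalg.eigvalsh(self.L, subset_by_index=[0, 0])[0])
        if lmin < -atol:
            raise ValueError(f"L must be PSD; min eigenvalue {lmin}")
        tmin = float(linalg.eigvalsh(self.theta, subset_by_index=[0, 0])[0])
        if tmin <= 0:
            raise DefinitenessError(f"S - L must be PD; min eigenvalue {tmin}")


@dataclass
class PenaltyConfig:
    """Tuning parameters of the penalised objective and the ADMM solver.

    ``lambda2 = inf`` is the sentinel for "no low-rank component" (plain GGM
    variants); ``l1`` swaps the MCP sparsity prox for soft thresholding
    (graphical-lasso variant).
    """

    lambda1: float = 0.1
    lambda2: float = 0.5
    a: float = 3.0          # MCP concavity
    rho: float = 1.0        # ADMM penalty parameter
    eps_pd: float = 1e-3    # eigenvalue floor for the consensus block A
    l1: bool = False

    def __post_init__(self) -> None:
        if self.lambda1 < 0:
            raise ValueError("lambda1 must be nonnegative")
        if self.lambda2 < 0:
            raise ValueError("lambda2 must be nonnegative")
        if self.a <= 1:
            raise ValueError("MCP concavity a must exceed 1")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.eps_pd < 0:
            raise ValueError("eps_pd must be nonnegative")


@dataclass
class ObjectiveValue:
    penalized_loglik: float
    loglik: float
    penalty: float


def _symmetrize(M: np.ndarray) -> np.ndarray:
    return (M + M.T) / 2.0


def gaussian_logdensity(
    x: np.ndarray, mu_k: np.ndarray, S: np.ndarray, L: np.ndarray
) -> np.ndarray | float:
    """Gaussian log-density with precision Theta = S - L, no explicit inverse.

    ``x`` may be a single length-p vector or an (n, p) matrix of rows; returns
    a scalar or a length-n vector accordingly.  logdet comes from a Cholesky
    factorisation of Theta, and the quadratic form is computed directly on the
    precision side.
    """
    theta = _symmetrize(np.asarray(S, dtype=float) - np.asarray(L, dtype=float))
    p = theta.shape[0]
    try:
        chol = linalg.cholesky(theta, lower=True)
    except linalg.LinAlgError:
        tmin = float(linalg.eigvalsh(theta, subset_by_index=[0, 0])[0])
        raise DefinitenessError(
            f"S - L is not positive definite (min eigenvalue {tmin:.3e})"
        ) from None
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    d = np.atleast_2d(x) - np.asarray(mu_k, dtype=float)
    # quadratic form d' Theta d via the Cholesky factor: ||chol' d||^2
    q = np.sum((d @ chol) ** 2, axis=1)
    out = -0.5 * p * np.log(2.0 * np.pi) + 0.5 * logdet - 0.5 * q
    return float(out[0]) if single else out


def mcp_penalty(c, lam: float, a: float = 3.0):
    """Minimax concave penalty, elementwise.

    p(c; lam, a) = lam|c| - c^2/(2a) for |c| <= a*lam, and a*lam^2/2 beyond.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if a <= 1:
        raise ValueError("a must exceed 1")
    c = np.abs(np.asarray(c, dtype=float))
    if np.isinf(lam):
        out = np.where(c == 0, 0.0, np.inf)
        return float(out) if out.ndim == 0 else out
    inside = lam * c - c**2 / (2.0 * a)
    out = np.where(c <= a * lam, inside, a * lam**2 / 2.0)
    return float(out) if out.ndim == 0 else out


def soft_threshold(c, lam: float):
    """ST_lam(c) = sign(c) * max(|c| - lam, 0), elementwise."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    c = np.asarray(c, dtype=float)
    out = np.sign(c) * np.maximum(np.abs(c) - lam, 0.0)
    return float(out) if out.ndim == 0 else out


def mcp_prox(c, lam: float, a: float = 3.0):
    """Proximal operator of the MCP: argmin_x (x-c)^2/2 + p(x; lam, a).

    ST_lam(c) / (1 - 1/a) inside the knot |c| <= a*lam, identity beyond.
    Elementwise on arrays (used on matrix entries and on eigenvalues).
    """
    if a <= 1:
        raise ValueError("a must exceed 1")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    c = np.asarray(c, dtype=float)
    if np.isinf(lam):
        out = np.zeros_like(c)
        return float(out) if out.ndim == 0 else out
    shrunk = np.sign(c) * np.maximum(np.abs(c) - lam, 0.0) / (1.0 - 1.0 / a)
    out = np.where(np.abs(c) <= a * lam, shrunk, c)
    return float(out) if out.ndim == 0 else out


def project_psd(M: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Floor every eigenvalue of (the symmetrised) M at eps and reconstruct."""
    M = _symmetrize(np.asarray(M, dtype=float))
    w, V = linalg.eigh(M)
    w = np.maximum(w, eps)
    return _symmetrize((V * w) @ V.T)


def mixture_logdensity(X: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Per-sample log of pi_0*delta + sum_k pi_k f_k(x_i), length n.

    Components with zero weight (or a zero-weight/zero-density noise term)
    contribute -inf in the log-sum-exp and thus drop out exactly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    K = params.K
    log_terms = np.full((n, K + 1), -np.inf)
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.maximum(params.pi, 0.0))
    if params.pi[0] > 0 and params.delta > 0:
        log_terms[:, 0] = log_pi[0] + np.log(params.delta)
    for k in range(K):
        if params.pi[k + 1] > 0:
            log_terms[:, k + 1] = log_pi[k + 1] + gaussian_logdensity(
                X, params.mu[k], params.S, params.L
            )
    return logsumexp(log_terms, axis=1)


def _sparsity_penalty(S: np.ndarray, pen: PenaltyConfig) -> float:
    off = S[~np.eye(S.shape[0], dtype=bool)]
    if pen.l1:
        return float(pen.lambda1 * np.sum(np.abs(off)))
    return float(np.sum(mcp_penalty(np.abs(off), pen.lambda1, pen.a)))


def _lowrank_penalty(L: np.ndarray, pen: PenaltyConfig) -> float:
    if np.isinf(pen.lambda2):
        return 0.0 if np.allclose(L, 0.0) else np.inf
    sig = linalg.eigvalsh(_symmetrize(L))
    return float(np.sum(mcp_penalty(sig, pen.lambda2, pen.a)))


def penalized_objective(
    data: ObservedData, params: ModelParameters, pen: PenaltyConfig
) -> ObjectiveValue:
    """Averaged mixture log-likelihood minus the MCP penalties on S and L.

    The sparsity penalty runs over off-diagonal entries of S only; the
    low-rank penalty over the eigenvalues of L.  With lambda2 = inf the
    eigenvalue term is 0 for L = 0 and +inf otherwise.
    """
    loglik = float(np.mean(mixture_logdensity(data.X, params)))
    penalty = _sparsity_penalty(params.S, pen) + _lowrank_penalty(params.L, pen)
    return ObjectiveValue(loglik - penalty, loglik, penalty)
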