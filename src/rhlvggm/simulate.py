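"""Synthetic-data generator for the simulation study conditions.

Builds a sparse (p+r) x (p+r) joint precision matrix over p observed and r
independent latent variables, shifts its spectrum to be safely positive
definite, and extracts the ground-truth sparse component S, low-rank
component L = B D^-1 B' (Schur complement of the latent block) and marginal
precision Theta = S - L.  Samples come from a K=3 mixture with mean shifts
on the first p~ = p/10 coordinates plus, optionally, uniform-box outliers on
the first p~ coordinates ([-20, 5] on the first half, [-10, 10] on the
second half) with the remaining coordinates Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["SimulationConfig", "SimulationTruth", "build_truth", "build_means",
           "sample", "simulate"]


@dataclass
class SimulationConfig:
    """Study conditions of the generator; defaults are the reference setting."""

    p: int = 40
    r: int = 5
    K: int = 3
    n: int = 1500
    pi0: float = 0.04
    balance: str = "balanced"          # or "imbalanced"
    mu_scale: float = 1.5
    obs_density: float = 0.10          # nonzero fraction, observed off-diagonals
    cross_density: float = 0.70        # nonzero fraction, observed-latent block
    entry_low: float = 0.2
    entry_high: float = 0.6
    n_test: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r >= self.p:
            raise ValueError("latent dimension r must be smaller than p")
        if not (0.0 <= self.pi0 < 0.5):
            raise ValueError("pi0 must lie in [0, 0.5)")
        if self.balance not in ("balanced", "imbalanced"):
            raise ValueError("balance must be 'balanced' or 'imbalanced'")
        p_shift = self.p // 10
        if p_shift < 1:
            raise ValueError("p must be at least 10 (p~ = p/10 shifted coordinates)")
        if p_shift % 2 != 0:
            raise ValueError(
                "floor(p/10) must be even (mean and outlier-box splits use p~/2)"
            )

    @property
    def p_shift(self) -> int:
        """Number of coordinates with subgroup-specific means (p~ = floor(p/10))."""
        return self.p // 10

    @property
    def pi(self) -> np.ndarray:
        """Component weights (pi_0, pi_1, ..., pi_K)."""
        if self.K == 3:
            w = (
                np.array([1 / 3, 1 / 3, 1 / 3])
                if self.balance == "balanced"
                else np.array([1 / 2, 1 / 4, 1 / 4])
            )
        else:
            w = np.full(self.K, 1.0 / self.K)
        return np.concatenate([[self.pi0], (1.0 - self.pi0) * w])


@dataclass
class SimulationTruth:
    S_true: np.ndarray
    L_true: np.ndarray
    Theta_true: np.ndarray
    mu_true: np.ndarray                # (K, p)
    X: np.ndarray                      # (n, p)
    labels: np.ndarray                 # 0 = outlier, 1..K subgroups
    X_test: np.ndarray | None = None
    labels_test: np.ndarray | None = None
    config: SimulationConfig | None = None


def _random_symmetric_support(
    rng: np.random.Generator, p: int, density: float, low: float, high: float
) -> np.ndarray:
    """Symmetric hollow matrix with ~density nonzero off-diagonal pairs."""
    M = np.zeros((p, p))
    iu, ju = np.triu_indices(p, k=1)
    mask = rng.random(iu.shape[0]) < density
    vals = rng.uniform(low, high, size=mask.sum()) * rng.choice([-1.0, 1.0], size=mask.sum())
    M[iu[mask], ju[mask]] = vals
    return M + M.T


def build_truth(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Construct ground-truth (S, L, Theta) from the joint precision matrix.

    The joint matrix has a hollow symmetric observed block (obs_density
    nonzeros), a dense-ish observed-latent block (cross_density nonzeros)
    and a positive diagonal latent block; its spectrum is shifted so the
    minimum eigenvalue is at least 0.1, guaranteeing a PD marginal Theta.
    """
    p, r = cfg.p, cfg.r
    for attempt in range(2):
        theta_bar = np.zeros((p + r, p + r))
        theta_bar[:p, :p] = _random_symmetric_support(
            rng, p, cfg.obs_density, cfg.entry_low, cfg.entry_high
        )
        if r > 0:
            mask = rng.random((p, r)) < cfg.cross_density
            B = np.where(
                mask,
                rng.uniform(cfg.entry_low, cfg.entry_high, size=(p, r))
                * rng.choice([-1.0, 1.0], size=(p, r)),
                0.0,
            )
            theta_bar[:p, p:] = B
            theta_bar[p:, :p] = B.T
            theta_bar[p:, p:] = np.diag(rng.uniform(1.0, 2.0, size=r))
            if np.all(B == 0.0):
                if attempt == 0:
                    continue
                raise RuntimeError("observed-latent block degenerate after resampling")
        break
    sigma_min = float(linalg.eigvalsh(theta_bar, subset_by_index=[0, 0])[0])
    theta_tilde = theta_bar + (0.1 + max(0.0, -sigma_min)) * np.eye(p + r)
    S = theta_tilde[:p, :p]
    if r > 0:
        D_inv = 1.0 / np.diag(theta_tilde[p:, p:])
        L = theta_tilde[:p, p:] * D_inv @ theta_tilde[p:, :p]
        L = (L + L.T) / 2.0
    else:
        L = np.zeros((p, p))
    return S, L, S - L


def build_means(cfg: SimulationConfig) -> np.ndarray:
    """Subgroup mean vectors: shifts of size mu on the first p~ coordinates.

    K = 3 uses the reference pattern
        mu_1 = ( mu 1_p~,            0, ..., 0)
        mu_2 = ( mu 1_{p~/2}, -mu 1_{p~/2}, 0, ..., 0)
        mu_3 = (-mu 1_p~,            0, ..., 0);
    other K fall back to evenly spaced shift levels in [mu, -mu].
    """
    p, K, mu = cfg.p, cfg.K, cfg.mu_scale
    pt = cfg.p_shift
    means = np.zeros((K, p))
    if K == 3:
        means[0, :pt] = mu
        means[1, : pt // 2] = mu
        means[1, pt // 2 : pt] = -mu
        means[2, :pt] = -mu
    elif K > 1:
        for k, level in enumerate(np.linspace(1.0, -1.0, K)):
            means[k, :pt] = level * mu
    return means


def sample(
    cfg: SimulationConfig,
    truth: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    rng: np.random.Generator,
) -> SimulationTruth:
    """Draw labels and observations (plus an independent test draw).

    Inliers in subgroup k are N(mu_k, Theta^-1).  Outliers have their first
    p~/2 coordinates uniform on [-20, 5], the next p~/2 uniform on [-10, 10],
    and the remaining p - p~ coordinates Gaussian with precision given by
    the corresponding submatrix of Theta.
    """
    S, L, theta, means = truth
    p, n, pt = cfg.p, cfg.n, cfg.p_shift
    pi = cfg.pi
    cov_chol = linalg.cholesky(linalg.inv(theta), lower=True)
    # outlier tail block: submatrix of Theta over the last p - p~ coordinates
    tail_cov = linalg.inv(theta[pt:, pt:])
    tail_chol = linalg.cholesky(tail_cov, lower=True)

    def draw(size: int) -> tuple[np.ndarray, np.ndarray]:
        labels = rng.choice(cfg.K + 1, size=size, p=pi)
        X = np.empty((size, p))
        for k in range(1, cfg.K + 1):
            idx = labels == k
            z = rng.standard_normal((int(idx.sum()), p))
            X[idx] = means[k - 1] + z @ cov_chol.T
        out = labels == 0
        n_out = int(out.sum())
        if n_out:
            block = np.empty((n_out, p))
            block[:, : pt // 2] = rng.uniform(-20.0, 5.0, size=(n_out, pt // 2))
            block[:, pt // 2 : pt] = rng.uniform(-10.0, 10.0, size=(n_out, pt // 2))
            z = rng.standard_normal((n_out, p - pt))
            block[:, pt:] = z @ tail_chol.T
            X[out] = block
        return X, labels

    X, labels = draw(n)
    X_test, labels_test = (None, None)
    if cfg.n_test > 0:
        X_test, labels_test = draw(cfg.n_test)
    return SimulationTruth(
        S_true=S, L_true=L, Theta_true=theta, mu_true=means, X=X, labels=labels,
        X_test=X_test, labels_test=labels_test, config=cfg,
    )


def simulate(cfg: SimulationConfig, seed: int | None = None) -> SimulationTruth:
    """One-call generator: truth matrices, means, and a seeded sample."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    S, L, theta = build_truth(cfg, rng)
    means = build_means(cfg)
    return sample(cfg, (S, L, theta, means), rng)
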