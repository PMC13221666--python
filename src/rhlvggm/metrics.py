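"""Evaluation suite: matrix errors, support recovery and the three ARIs."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.metrics import adjusted_rand_score

from .core import ModelParameters, ObservedData
from .em import FitConfig, FitResult, e_step
from .simulate import SimulationTruth

ZERO_TOL = 1e-8  # shared numerical-zero threshold for support and rank

__all__ = ["MetricsReport", "relative_frobenius", "support_rates", "ari",
           "rank_estimate", "evaluate", "ZERO_TOL"]


@dataclass
class MetricsReport:
    """One row of the simulation summary; nan marks undefined entries."""

    err_S: float
    err_L: float
    err_Theta: float
    rank_hat: float
    tpr: float
    fpr: float
    ari_c: float
    ari_o: float
    ari_p: float

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def relative_frobenius(est: np.ndarray, truth: np.ndarray) -> float:
    """||est - truth||_F / ||truth||_F; nan when the truth is all zero."""
    est, truth = np.asarray(est, float), np.asarray(truth, float)
    if est.shape != truth.shape:
        raise ValueError(f"shape mismatch {est.shape} vs {truth.shape}")
    denom = float(np.linalg.norm(truth, "fro"))
    if denom == 0.0:
        return math.nan
    return float(np.linalg.norm(est - truth, "fro")) / denom


def support_rates(
    S_hat: np.ndarray, S_true: np.ndarray, tol: float = ZERO_TOL
) -> tuple[float, float]:
    """TPR/FPR for recovering the off-diagonal support of S.

    TPR over true non-zeros, FPR over true zeros, both off-diagonal only;
    a side with no eligible positions yields nan.
    """
    S_hat, S_true = np.asarray(S_hat, float), np.asarray(S_true, float)
    if S_hat.shape != S_true.shape or S_hat.shape[0] != S_hat.shape[1]:
        raise ValueError("S_hat and S_true must be square with identical shapes")
    off = ~np.eye(S_hat.shape[0], dtype=bool)
    hat_nz = np.abs(S_hat[off]) > tol
    true_nz = S_true[off] != 0
    n_pos = int(true_nz.sum())
    n_neg = int((~true_nz).sum())
    tpr = float((hat_nz & true_nz).sum() / n_pos) if n_pos else math.nan
    fpr = float((hat_nz & ~true_nz).sum() / n_neg) if n_neg else math.nan
    return tpr, fpr


def ari(labels_a, labels_b) -> float:
    """Permutation-model adjusted Rand index between two labelings.

    Conventions for degenerate inputs: identical single-cluster partitions
    score 1; a degenerate contingency where the expected index equals the
    maximum index scores 0 unless the partitions agree exactly.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1 or a.shape[0] < 2:
        raise ValueError("labelings must be equal-length 1-d arrays of length >= 2")
    n_a, n_b = len(np.unique(a)), len(np.unique(b))
    if n_a == 1 and n_b == 1:
        return 1.0
    score = float(adjusted_rand_score(a, b))
    if math.isnan(score):
        return 0.0
    return score


def rank_estimate(L_hat: np.ndarray, tol: float = ZERO_TOL) -> int:
    """Number of eigenvalues of L_hat above the numerical-zero threshold."""
    return int(np.sum(linalg.eigvalsh((L_hat + L_hat.T) / 2.0) > tol))


def predict_labels(X: np.ndarray, params: ModelParameters, cfg: FitConfig) -> np.ndarray:
    """Max-posterior component labels (0 = noise) for new samples."""
    gamma = e_step(ObservedData(X), params, cfg)
    return np.argmax(gamma, axis=1)


def evaluate(
    fit: FitResult,
    truth: SimulationTruth,
    cfg: FitConfig,
    has_lowrank: bool = True,
) -> MetricsReport:
    """Score one fitted model against one simulation truth.

    For variants without a low-rank estimate the convention is S_hat :=
    Theta_hat, with the L error and rank left undefined.  ARI_c compares
    true subgroup labels with fitted hard labels over true inliers only
    (fitted outlier assignments are retained as class 0); ARI_o compares
    the binarised outlier/inlier labelings; ARI_p scores max-posterior
    classification of the held-out test draw.
    """
    theta_hat = fit.params.theta
    err_theta = relative_frobenius(theta_hat, truth.Theta_true)
    if has_lowrank:
        err_S = relative_frobenius(fit.params.S, truth.S_true)
        err_L = relative_frobenius(fit.params.L, truth.L_true)
        rank_hat = float(rank_estimate(fit.params.L))
        S_for_support = fit.params.S
    else:
        err_S = relative_frobenius(theta_hat, truth.S_true)
        err_L = math.nan
        rank_hat = math.nan
        S_for_support = theta_hat
    tpr, fpr = support_rates(S_for_support, truth.S_true)

    ari_c = math.nan
    ari_o = math.nan
    ari_p = math.nan
    if cfg.effective_K > 1:
        inlier = truth.labels != 0
        if inlier.sum() >= 2:
            ari_c = ari(truth.labels[inlier], fit.hard_labels[inlier])
    if cfg.has_noise:
        ari_o = ari((truth.labels == 0).astype(int), (fit.hard_labels == 0).astype(int))
    if cfg.effective_K > 1 and truth.X_test is not None:
        pred = predict_labels(truth.X_test, fit.params, cfg)
        ari_p = ari(truth.labels_test, pred)
    return MetricsReport(
        err_S=err_S, err_L=err_L, err_Theta=err_theta, rank_hat=rank_hat,
        tpr=tpr, fpr=fpr, ari_c=ari_c, ari_o=ari_o, ari_p=ari_p,
    )
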