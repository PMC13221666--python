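"""AIC model selection: the tuning-parameter line search and K selection.

The criterion is

    AIC(l1, l2) = -sum_i log(pi0 d + sum_k pik f_k(x_i)) + 2 (p r_hat + s_hat)

with s_hat the number of non-zero off-diagonal entries of S_hat (both
triangles) and r_hat the rank of L_hat.  Rather than a full grid, the search
fixes lambda2 at the median of its grid, tunes lambda1, then tunes lambda2
at the chosen lambda1 — the usual one-dimensional line search for
two-penalty graphical models.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import ModelParameters, ObservedData, PenaltyConfig, mixture_logdensity
from .em import FitConfig, FitResult, GGM_VARIANTS, fit, initialize
from .metrics import ZERO_TOL, rank_estimate

logger = logging.getLogger(__name__)

__all__ = ["TuningGrid", "SelectionResult", "aic", "line_search", "select_K"]


def _default_lambda1() -> np.ndarray:
    return np.geomspace(0.01, 1.0, 16)


def _default_lambda2() -> np.ndarray:
    return np.geomspace(0.05, 2.0, 11)


@dataclass
class TuningGrid:
    lambda1_grid: np.ndarray = field(default_factory=_default_lambda1)
    lambda2_grid: np.ndarray = field(default_factory=_default_lambda2)
    K_candidates: tuple[int, ...] = tuple(range(1, 11))

    def __post_init__(self) -> None:
        for name in ("lambda1_grid", "lambda2_grid"):
            g = np.asarray(getattr(self, name), dtype=float)
            if g.size == 0 or np.any(g <= 0) or np.any(np.diff(g) <= 0):
                raise ValueError(f"{name} must be non-empty, positive, strictly increasing")
            setattr(self, name, g)

    @property
    def lambda2_median(self) -> float:
        """Lower-middle element of the lambda2 grid (median for odd length)."""
        g = self.lambda2_grid
        return float(g[(len(g) - 1) // 2])


@dataclass
class SelectionResult:
    best_lambda1: float
    best_lambda2: float
    best_K: int
    aic_table: list[dict]
    best_fit: FitResult


def count_nonzero_offdiag(S: np.ndarray, tol: float = ZERO_TOL) -> int:
    """s_hat: off-diagonal entries of S above tol, both triangles counted."""
    off = ~np.eye(S.shape[0], dtype=bool)
    return int(np.sum(np.abs(S[off]) > tol))


def aic(data: ObservedData, fit_result: FitResult) -> float:
    """Negative total mixture log-likelihood plus 2(p * r_hat + s_hat)."""
    loglik = float(np.sum(mixture_logdensity(data.X, fit_result.params)))
    s_hat = count_nonzero_offdiag(fit_result.params.S)
    r_hat = rank_estimate(fit_result.params.L)
    return -loglik + 2.0 * (data.p * r_hat + s_hat)


def _record(
    data: ObservedData, fr: FitResult, lam1: float, lam2: float, K: int
) -> dict:
    return {
        "K": K,
        "lambda1": lam1,
        "lambda2": lam2,
        "AIC": aic(data, fr),
        "s_hat": count_nonzero_offdiag(fr.params.S),
        "r_hat": rank_estimate(fr.params.L),
        "converged": fr.converged,
        "n_outer": fr.n_outer,
    }


def line_search(
    data: ObservedData,
    grid: TuningGrid,
    cfg: FitConfig,
    pen_base: PenaltyConfig | None = None,
    init: tuple[ModelParameters, np.ndarray] | None = None,
) -> SelectionResult:
    """Two-phase AIC line search over (lambda1, lambda2).

    Phase 1 fixes lambda2 at the grid median and sweeps lambda1 from the
    sparsest (largest) value down, warm-starting each fit from the previous
    grid point; phase 2 sweeps lambda2 at the chosen lambda1.  Variants with
    no low-rank component skip phase 2.  AIC ties go to the sparser model
    (larger lambda1, then larger lambda2).
    """
    pen_base = pen_base or PenaltyConfig()
    if init is None:
        init = initialize(data, cfg)
    records: list[dict] = []
    failures: list[str] = []
    ggm = cfg.variant in GGM_VARIANTS
    lam2_phase1 = math.inf if ggm else grid.lambda2_median

    def run(lam1: float, lam2: float, warm) -> FitResult | None:
        pen = PenaltyConfig(
            lambda1=lam1,
            lambda2=lam2 if not math.isinf(lam2) else pen_base.lambda2,
            a=pen_base.a, rho=pen_base.rho, eps_pd=pen_base.eps_pd,
        )
        try:
            return fit(data, pen, cfg, init=warm)
        except Exception as exc:  # individual grid points may fail
            logger.warning("fit failed at lambda1=%g lambda2=%g: %s", lam1, lam2, exc)
            failures.append(f"lambda1={lam1:g}, lambda2={lam2:g}: {exc}")
            return None

    # sweep from the densest (smallest lambda1) fit upward so the warm-start
    # chain inherits a well-separated clustering; ties prefer the sparser
    # model (larger lambda1), hence the non-strict comparison while ascending
    best1: tuple[float, float, FitResult] | None = None  # (AIC, lam1, fit)
    warm = init
    for lam1 in grid.lambda1_grid:
        fr = run(lam1, lam2_phase1, warm)
        if fr is None:
            continue
        warm = (fr.params, fr.gamma)
        rec = _record(data, fr, lam1, lam2_phase1, cfg.effective_K)
        records.append(rec)
        if best1 is None or rec["AIC"] <= best1[0]:
            best1 = (rec["AIC"], lam1, fr)
    if best1 is None:
        raise RuntimeError(
            "all fits failed during the lambda1 search:\n" + "\n".join(failures)
        )
    _, lam1_star, best_fit = best1
    best = (best1[0], lam1_star, lam2_phase1, best_fit)

    if not ggm:
        warm = (best_fit.params, best_fit.gamma)
        for lam2 in grid.lambda2_grid:
            if lam2 == lam2_phase1:
                continue  # already fitted in phase 1
            fr = run(lam1_star, lam2, warm)
            if fr is None:
                continue
            warm = (fr.params, fr.gamma)
            rec = _record(data, fr, lam1_star, lam2, cfg.effective_K)
            records.append(rec)
            if rec["AIC"] <= best[0] and lam2 > best[2]:
                best = (rec["AIC"], lam1_star, lam2, fr)
            elif rec["AIC"] < best[0]:
                best = (rec["AIC"], lam1_star, lam2, fr)

    return SelectionResult(
        best_lambda1=best[1], best_lambda2=best[2], best_K=cfg.effective_K,
        aic_table=records, best_fit=best[3],
    )


def select_K(
    data: ObservedData,
    grid: TuningGrid,
    cfg: FitConfig,
    pen_base: PenaltyConfig | None = None,
) -> SelectionResult:
    """Run the line search per candidate K and compare AICs across K.

    Because the within-K criterion omits terms constant in (lambda1,
    lambda2), the cross-K comparison adds 2(K p + K) for the mean and
    proportion parameters.  Ties prefer the smaller K.
    """
    candidates = sorted(set(grid.K_candidates))
    if not candidates:
        raise ValueError("K_candidates must be non-empty")
    best: tuple[float, SelectionResult, int] | None = None
    table: list[dict] = []
    for K in candidates:
        cfg_k = FitConfig(
            K=K, pi_max=cfg.pi_max, outer_tol=cfg.outer_tol,
            max_outer=cfg.max_outer, max_inner=cfg.max_inner,
            seed=cfg.seed, variant=cfg.variant,
        )
        res = line_search(data, grid, cfg_k, pen_base)
        crit = min(r["AIC"] for r in res.aic_table) + 2.0 * (K * data.p + K)
        for r in res.aic_table:
            r = dict(r)
            r["AIC_cross_K"] = r["AIC"] + 2.0 * (K * data.p + K)
            table.append(r)
        if best is None or crit < best[0]:
            best = (crit, res, K)
    assert best is not None
    res = best[1]
    return SelectionResult(
        best_lambda1=res.best_lambda1, best_lambda2=res.best_lambda2,
        best_K=best[2], aic_table=table, best_fit=res.best_fit,
    )
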