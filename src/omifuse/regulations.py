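"""Cross-disease estimation of expression-on-CNV regulations.

For each gene j and disease k, expression is modelled as a sparse linear
function of all CNV measurements, ``x_j = Z eta_j + error``; the two
diseases are fit jointly by minimizing

    sum_k (1/2 n_k) sum_j ||x_j^(k) - Z^(k) eta_j^(k)||^2
    + lam3 * sum_{k,j} ||eta_j^(k)||_1
    + lam4 * sum_j rho(eta_j^(1), eta_j^(2))

with the same magnitude (C1) / sign (C2) fusion penalties as the marker
module, and the separate-Lasso baseline C3 (also used for the normal group).
The problem decouples over genes and is solved by cyclic coordinate descent
with a per-gene monotonicity safeguard, so every per-gene objective - and
hence the recorded total trace - is non-increasing.

CNV predictors are standardized and expression responses centered inside the
solver; ``eta`` is on the standardized-Z scale with scalers attached. Both
cis entries (the diagonal, a gene's own CNV) and trans entries are penalized
alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _solver
from .data_io import OmicsDataset
from .markers import SIGN_TAU, _PEN_CODE, _sgn

logger = logging.getLogger(__name__)

PENALTIES = ("magnitude", "sign", "none")


@dataclass
class RegulationFit:
    """Fitted regulation matrices, one (genes x CNVs) block per group."""

    eta: tuple[np.ndarray, ...]
    lambda3: float
    lambda4: float
    penalty: str
    objective_trace: np.ndarray
    n_sweeps: int
    converged: bool
    gene_ids: list[str]
    cnv_ids: list[str]
    z_centers: tuple[np.ndarray, ...]
    z_scales: tuple[np.ndarray, ...]
    x_centers: tuple[np.ndarray, ...]
    path: list[dict] = field(default_factory=list)

    def support(self, k: int) -> np.ndarray:
        """Boolean genes-by-CNVs support mask for group ``k``."""
        return self.eta[k] != 0

    def eta_original(self, k: int) -> np.ndarray:
        """Coefficients rescaled to the original CNV units."""
        return self.eta[k] / self.z_scales[k][None, :]


def dist_matrices(etaA: np.ndarray, etaB: np.ndarray) -> float:
    """Squared-difference distance between two regulation matrices.

    Sum over genes and CNVs of ``(etaA_jl - etaB_jl)**2`` - sensitive to both
    magnitude and sign differences.
    """
    etaA = np.asarray(etaA, dtype=float)
    etaB = np.asarray(etaB, dtype=float)
    if etaA.shape != etaB.shape:
        raise ValueError(f"shape mismatch: {etaA.shape} vs {etaB.shape}")
    return float(np.sum((etaA - etaB) ** 2))


def signdist_matrices(etaA: np.ndarray, etaB: np.ndarray) -> float:
    """Sign-difference distance: sum of ``(Sgn(etaA) - Sgn(etaB))**2``."""
    etaA = np.asarray(etaA, dtype=float)
    etaB = np.asarray(etaB, dtype=float)
    if etaA.shape != etaB.shape:
        raise ValueError(f"shape mismatch: {etaA.shape} vs {etaB.shape}")
    return float(np.sum((_sgn(etaA) - _sgn(etaB)) ** 2))


def _prep_xz(d: OmicsDataset):
    Z = d.block("cnv")
    X = d.block("expression")
    zc = Z.mean(axis=0)
    zs = Z.std(axis=0)
    dead = zs == 0
    if dead.any():
        logger.warning(
            "%d constant CNV column(s); their coefficients are fixed at 0",
            int(dead.sum()),
        )
    zs = np.where(dead, 1.0, zs)
    xc = X.mean(axis=0)
    return (Z - zc) / zs, X - xc, zc, zs, xc, dead


def solve_penalized_regulation(
    d1: OmicsDataset,
    d2: OmicsDataset,
    lambda3: float,
    lambda4: float,
    penalty: str = "magnitude",
    init: RegulationFit | None = None,
    tol: float = 1e-5,
    max_sweeps: int = 1000,
) -> RegulationFit:
    """Fit the fused regulation pair at fixed (lam3, lam4) by coordinate descent."""
    if penalty not in PENALTIES:
        raise ValueError(f"penalty must be one of {PENALTIES}")
    if lambda3 < 0 or lambda4 < 0:
        raise ValueError("tuning parameters must be non-negative")
    if d1.gene_ids != d2.gene_ids:
        raise ValueError("datasets must share gene_ids")
    Z1, X1, zc1, zs1, xc1, dead1 = _prep_xz(d1)
    Z2, X2, zc2, zs2, xc2, dead2 = _prep_xz(d2)
    q, p = X1.shape[1], Z1.shape[1]
    lam3, lam4 = float(lambda3), float(lambda4)

    if init is not None:
        e1 = init.eta[0].copy()
        e2 = init.eta[1].copy()
    else:
        e1 = np.zeros((q, p))
        e2 = np.zeros((q, p))

    # canonical ordering: the sequential CD trajectory depends on which
    # group goes first; ordering by content makes the fit argument-order
    # invariant (swapping the groups mirrors the solution exactly)
    key1 = (Z1.shape[0], float(X1.sum()), float(Z1.sum()), float(np.abs(X1).sum()))
    key2 = (Z2.shape[0], float(X2.sum()), float(Z2.sum()), float(np.abs(X2).sum()))
    swapped = key2 < key1
    if swapped:
        trace, _, converged, n_sweeps = _solver.cd_solve_regulation(
            np.asfortranarray(Z2), np.asfortranarray(X2),
            np.asfortranarray(Z1), np.asfortranarray(X1),
            lam3, lam4, _PEN_CODE[penalty], SIGN_TAU, tol, max_sweeps,
            e2, e1, dead2, dead1,
        )
    else:
        trace, _, converged, n_sweeps = _solver.cd_solve_regulation(
            np.asfortranarray(Z1), np.asfortranarray(X1),
            np.asfortranarray(Z2), np.asfortranarray(X2),
            lam3, lam4, _PEN_CODE[penalty], SIGN_TAU, tol, max_sweeps,
            e1, e2, dead1, dead2,
        )
    if np.any(~np.isfinite(trace)):
        raise FloatingPointError("objective became non-finite during CD")
    if not converged:
        logger.warning(
            "regulation CD did not converge in %d sweeps (lambda3=%g, lambda4=%g)",
            max_sweeps, lambda3, lambda4,
        )
    e1[:, dead1] = 0.0
    e2[:, dead2] = 0.0
    return RegulationFit(
        eta=(e1, e2),
        lambda3=float(lambda3),
        lambda4=float(lambda4),
        penalty=penalty,
        objective_trace=np.asarray(trace),
        n_sweeps=n_sweeps,
        converged=converged,
        gene_ids=list(d1.gene_ids),
        cnv_ids=list(getattr(d1, "cnv_ids", d1.gene_ids)),
        z_centers=(zc1, zc2),
        z_scales=(zs1, zs2),
        x_centers=(xc1, xc2),
    )


def fit_lasso_regulation(
    d: OmicsDataset,
    lambda3: float,
    tol: float = 1e-5,
    max_sweeps: int = 1000,
) -> RegulationFit:
    """Single-group Lasso regulation fit (C3 baseline / normal group)."""
    return solve_penalized_regulation(
        d, d, lambda3, 0.0, penalty="none", tol=tol, max_sweeps=max_sweeps
    )


def lambda3_max(d1: OmicsDataset, d2: OmicsDataset | None = None) -> float:
    """Smallest lam3 at which every regulation coefficient is zero."""
    out = 0.0
    for d in (d1, d2):
        if d is None:
            continue
        Z, X, *_ = _prep_xz(d)
        out = max(out, float(np.abs(Z.T @ X).max() / Z.shape[0]))
    return out


def _bic_regulation(fit: RegulationFit, datasets) -> float:
    """Refit-based Gaussian BIC per gene and group, summed.

    The fusion penalty deliberately biases coefficients toward cross-disease
    similarity, inflating the penalized fit's residuals; scoring the RAW
    residuals would make any fused model look worse than the null. Each
    selected support is therefore refit by per-gene OLS, and
    ``n log(RSS/n) + log(n) df`` is computed on the refitted residuals,
    identically for fused and separate fits.
    """
    total = 0.0
    for k, d in enumerate(datasets):
        Z, X, *_ = _prep_xz(d)
        n = Z.shape[0]
        null_rss = (X**2).sum(axis=0)
        for j in range(X.shape[1]):
            sup = np.flatnonzero(fit.eta[k][j])
            df = len(sup)
            if df == 0:
                rss = null_rss[j]
            elif df > n // 2:
                # a refit with more coefficients than half the samples has
                # no reliable residual estimate (the profile variance
                # collapses); score such supports as buying nothing
                rss = null_rss[j]
            else:
                coef, _, _, _ = np.linalg.lstsq(Z[:, sup], X[:, j], rcond=None)
                rss = float(((X[:, j] - Z[:, sup] @ coef) ** 2).sum())
            rss = max(rss, 1e-6 * null_rss[j])
            total += n * np.log(rss / n) + np.log(n) * df
    return float(total)


DEFAULT_LAMBDA4_GRID = (0.1, 0.5, 2.0)


def _subset_xz(d: OmicsDataset, idx: np.ndarray) -> OmicsDataset:
    out = OmicsDataset.__new__(type(d))
    out.sample_ids = [d.sample_ids[i] for i in idx]
    out.gene_ids = list(d.gene_ids)
    if hasattr(d, "cnv_ids"):
        out.cnv_ids = list(d.cnv_ids)
    out.X = d.X[idx]
    out.Z = d.Z[idx]
    out.y = None
    out.group_label = d.group_label
    return out


def _cv_press(d1, d2, lam3, lam4, penalty, n_folds, seed, tol, max_sweeps):
    """Out-of-fold squared prediction error, summed over genes and groups."""
    rng = np.random.default_rng(seed)
    press = 0.0
    folds = []
    for d in (d1, d2):
        idx = rng.permutation(d.n)
        folds.append(np.array_split(idx, n_folds))
    for f in range(n_folds):
        tr1 = np.setdiff1d(np.arange(d1.n), folds[0][f])
        tr2 = np.setdiff1d(np.arange(d2.n), folds[1][f])
        fit = solve_penalized_regulation(
            _subset_xz(d1, tr1), _subset_xz(d2, tr2), lam3, lam4,
            penalty=penalty, tol=tol, max_sweeps=max_sweeps,
        )
        for k, d, fold in ((0, d1, folds[0][f]), (1, d2, folds[1][f])):
            Zte = (d.Z[fold] - fit.z_centers[k]) / fit.z_scales[k]
            Xte = d.X[fold] - fit.x_centers[k]
            press += float(((Xte - Zte @ fit.eta[k].T) ** 2).sum())
    return press


def select_tuning_regulations(
    d1: OmicsDataset,
    d2: OmicsDataset,
    penalty: str = "magnitude",
    lambda3_grid=None,
    lambda4_grid=None,
    criterion: str = "bic",
    cv_folds: int = 5,
    seed: int = 0,
    tol: float = 1e-5,
    max_sweeps: int = 1000,
) -> RegulationFit:
    """Grid search over a single global (lam3, lam4).

    ``criterion='bic'`` (default) scores candidate supports by a per-gene
    refit BIC summed over genes and groups; ``'cv'`` scores by out-of-fold
    squared prediction error, which rewards the estimation gain of fusion
    that support-based scores cannot see. One (lam3, lam4) is shared by all
    genes; the unfused path is warm-started along descending lam3 and ties
    go to the sparser (larger lam3) / more strongly fused fit.
    """
    if lambda3_grid is None:
        # tiny upward nudge so the top of the path is the exact null fit
        # despite summation-order rounding between lambda3_max and the kernel;
        # 16 points: scores move steeply along the path, and each fusion
        # strength needs to land near its own density optimum
        lmax = lambda3_max(d1, d2) * (1 + 1e-8)
        lambda3_grid = np.geomspace(lmax, 0.05 * lmax, 16)
    lambda3_grid = np.sort(np.asarray(lambda3_grid, dtype=float))[::-1]
    if lambda4_grid is None:
        lambda4_grid = [0.0] if penalty == "none" else list(DEFAULT_LAMBDA4_GRID)
    lambda4_grid = sorted(float(v) for v in lambda4_grid)
    if len(lambda3_grid) == 0 or len(lambda4_grid) == 0:
        raise ValueError("tuning grids must be non-empty")
    if criterion not in ("bic", "cv"):
        raise ValueError(f"unknown criterion {criterion!r}")

    best = None
    best_score = np.inf
    path: list[dict] = []
    for lam4 in lambda4_grid:
        warm = None
        for lam3 in lambda3_grid:
            fit = solve_penalized_regulation(
                d1, d2, lam3, lam4, penalty=penalty, init=warm,
                tol=tol, max_sweeps=max_sweeps,
            )
            # warm starts speed the unfused path but set the fused s-pattern
            # off on oscillatory micro-steps; fused fits restart from zero
            warm = fit if (lam4 == 0.0 or penalty == "none") else None
            if criterion == "cv":
                score = _cv_press(
                    d1, d2, lam3, lam4, penalty, cv_folds, seed, tol, max_sweeps
                )
            else:
                score = _bic_regulation(fit, (d1, d2))
            path.append(
                {"lambda3": float(lam3), "lambda4": float(lam4), "score": score}
            )
            # ties go to the sparser fit within a lam4 column and to the
            # stronger coupling across columns (equal refit scores mean
            # equal supports; the fused fit has smaller effective complexity)
            better = score < best_score - 1e-9
            tie_stronger_fusion = (
                best is not None
                and score <= best_score + 1e-9
                and lam4 > best.lambda4
            )
            if best is None or better or tie_stronger_fusion:
                best_score = min(best_score, score)
                best = fit
    assert best is not None
    best.path = path
    return best
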