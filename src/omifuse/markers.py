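"""Cross-disease marker identification by fused penalized logistic regression.

Two case/control contrasts (e.g. bipolar-vs-control and
schizophrenia-vs-control) are fit jointly by minimizing

    -l(beta1) - l(beta2) + lam1 * sum_k ||beta_k||_1 + (lam2/2) * rho(beta1, beta2)

where rho is either the magnitude-based fusion penalty (B1), which shrinks
the value difference of same-sign coefficient pairs, or the sign-based
penalty (B2), which shrinks sign disagreements. lam2 = 0 recovers two
independent Lasso-logistic fits; the single-disease Lasso baseline (B3) is
exposed as :func:`fit_lasso_logistic`.

Log-likelihoods are sample-size normalized by default so tuning values are
comparable across contrasts of different size; ``normalize=False`` restores
the unnormalized form (lam values are rescaled internally, the optimum is
identical up to that rescaling). Predictors are standardized inside the
solver; coefficients are returned on the standardized scale with the
centering/scaling vectors attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _solver
from .data_io import OmicsDataset

logger = logging.getLogger(__name__)

PENALTIES = ("magnitude", "sign", "none")
_PEN_CODE = {
    "none": _solver.PEN_NONE,
    "magnitude": _solver.PEN_MAGNITUDE,
    "sign": _solver.PEN_SIGN,
}
SIGN_TAU = 1e-2


def _sgn(x: np.ndarray) -> np.ndarray:
    return np.sign(np.asarray(x, dtype=float))


def magnitude_penalty(beta1: np.ndarray, beta2: np.ndarray) -> float:
    """Magnitude-based fusion penalty rho(beta1, beta2), exact evaluation.

    Sum over coordinates and ordered disease pairs of
    ``(beta_j^(k) - s_j * beta_j^(k'))**2`` with ``s_j = 1`` iff the two
    coefficients have equal sign (Sgn(0) = 0).
    """
    beta1 = np.asarray(beta1, dtype=float)
    beta2 = np.asarray(beta2, dtype=float)
    if beta1.shape != beta2.shape:
        raise ValueError("beta vectors must have equal length")
    s = (_sgn(beta1) == _sgn(beta2)).astype(float)
    return float(np.sum((beta1 - s * beta2) ** 2 + (beta2 - s * beta1) ** 2))


def sign_penalty(beta1: np.ndarray, beta2: np.ndarray) -> float:
    """Sign-based fusion penalty: ordered-pair sum of squared sign differences."""
    beta1 = np.asarray(beta1, dtype=float)
    beta2 = np.asarray(beta2, dtype=float)
    if beta1.shape != beta2.shape:
        raise ValueError("beta vectors must have equal length")
    return float(2.0 * np.sum((_sgn(beta1) - _sgn(beta2)) ** 2))


@dataclass
class MarkerFit:
    """Fused two-disease penalized logistic fit (standardized scale)."""

    beta: tuple[np.ndarray, np.ndarray]
    intercepts: tuple[float, float]
    lambda1: float
    lambda2: float
    penalty: str
    objective_trace: np.ndarray
    n_sweeps: int
    converged: bool
    gene_ids: list[str]
    centers: tuple[np.ndarray, np.ndarray]
    scales: tuple[np.ndarray, np.ndarray]
    path: list[dict] = field(default_factory=list)

    def support(self, k: int) -> np.ndarray:
        """Indices of nonzero coefficients for disease ``k`` (0 or 1)."""
        return np.flatnonzero(self.beta[k])

    def beta_original(self, k: int) -> np.ndarray:
        """Coefficients transformed back to the original predictor scale."""
        return self.beta[k] / self.scales[k]

    def intercept_original(self, k: int) -> float:
        return float(
            self.intercepts[k] - np.sum(self.beta[k] * self.centers[k] / self.scales[k])
        )

    def penalty_value(self) -> float:
        """Exact fusion penalty rho at the solution (exact signs for 'sign')."""
        if self.penalty == "magnitude":
            return magnitude_penalty(*self.beta)
        if self.penalty == "sign":
            return sign_penalty(*self.beta)
        return 0.0


def _standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = M.mean(axis=0)
    scale = M.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    return (M - center) / scale, center, scale


def _prep(dataset: OmicsDataset, feature: str):
    y = dataset.require_outcome().astype(float)
    Xs, center, scale = _standardize(dataset.block(feature))
    # Fortran order: the CD kernel accesses columns
    return np.asfortranarray(Xs), y, center, scale


def _canonical_key(X: np.ndarray, y: np.ndarray) -> tuple:
    """Data-derived ordering key so the fit is invariant to argument order.

    The sequential CD trajectory depends on which dataset is updated first;
    ordering the pair by content (not position) makes swapping the inputs
    return the exact mirrored solution.
    """
    return (
        X.shape[0],
        float(y.sum()),
        float(X.sum()),
        float(np.abs(X).sum()),
        float((X**3).sum()),
    )


def lambda_max(
    d1: OmicsDataset, d2: OmicsDataset, feature: str = "expression"
) -> float:
    """Smallest lam1 at which both coefficient vectors are entirely zero."""
    out = 0.0
    for d in (d1, d2):
        Xs, y, _, _ = _prep(d, feature)
        out = max(out, float(np.abs(Xs.T @ (y - y.mean())).max() / len(y)))
    return out


def solve_penalized_logistic(
    d1: OmicsDataset,
    d2: OmicsDataset,
    lambda1: float,
    lambda2: float,
    penalty: str = "magnitude",
    feature: str = "expression",
    init: MarkerFit | None = None,
    tol: float = 1e-5,
    max_sweeps: int = 1000,
    normalize: bool = True,
) -> MarkerFit:
    """Fit the fused pair at fixed tuning parameters by coordinate descent."""
    if penalty not in PENALTIES:
        raise ValueError(f"penalty must be one of {PENALTIES}")
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("tuning parameters must be non-negative")
    if d1.gene_ids != d2.gene_ids:
        raise ValueError("datasets must share gene_ids")
    X1, y1, c1, s1 = _prep(d1, feature)
    X2, y2, c2, s2 = _prep(d2, feature)
    swapped = _canonical_key(X2, y2) < _canonical_key(X1, y1)
    if swapped:
        X1, y1, X2, y2 = X2, y2, X1, y1

    lam1, lam2 = float(lambda1), float(lambda2)
    if not normalize:
        # literal unnormalized likelihoods: divide penalties by the mean n
        nbar = 0.5 * (len(y1) + len(y2))
        lam1, lam2 = lam1 / nbar, lam2 / nbar

    if init is not None:
        k1, k2 = (1, 0) if swapped else (0, 1)
        b1 = init.beta[k1].copy()
        b2 = init.beta[k2].copy()
        a1, a2 = init.intercepts[k1], init.intercepts[k2]
    else:
        b1 = np.zeros(X1.shape[1])
        b2 = np.zeros(X2.shape[1])
        ybar1, ybar2 = y1.mean(), y2.mean()
        a1 = float(np.log(ybar1 / (1 - ybar1)))
        a2 = float(np.log(ybar2 / (1 - ybar2)))

    a1, a2, trace, _, converged, n_sweeps = _solver.cd_solve_pair(
        X1, y1, X2, y2, lam1, lam2, _PEN_CODE[penalty], SIGN_TAU,
        tol, max_sweeps, b1, a1, b2, a2,
    )
    if swapped:
        b1, b2 = b2, b1
        a1, a2 = a2, a1
    if np.any(~np.isfinite(trace)):
        raise FloatingPointError("objective became non-finite during CD")
    if not converged:
        logger.warning(
            "coordinate descent did not converge in %d sweeps "
            "(lambda1=%g, lambda2=%g)", max_sweeps, lambda1, lambda2,
        )
    return MarkerFit(
        beta=(b1, b2),
        intercepts=(float(a1), float(a2)),
        lambda1=float(lambda1),
        lambda2=float(lambda2),
        penalty=penalty,
        objective_trace=trace,
        n_sweeps=n_sweeps,
        converged=converged,
        gene_ids=list(d1.gene_ids),
        centers=(c1, c2),
        scales=(s1, s2),
    )


def fit_lasso_logistic(
    d: OmicsDataset,
    lambda1: float,
    feature: str = "expression",
    tol: float = 1e-5,
    max_sweeps: int = 1000,
) -> MarkerFit:
    """Single-disease Lasso-logistic baseline (the lam2 = 0 special case)."""
    fit = solve_penalized_logistic(
        d, d, lambda1, 0.0, penalty="none", feature=feature,
        tol=tol, max_sweeps=max_sweeps,
    )
    return fit


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray, alpha: float) -> float:
    lp = X @ beta + alpha
    return float(np.sum(y * lp - np.logaddexp(0.0, lp)))


def _refit_loglik(X: np.ndarray, y: np.ndarray, ridge: float = 1e-2) -> float:
    """Log-likelihood of a ridge-stabilized unpenalized logistic refit.

    The small ridge keeps the refit finite under separation; on the
    standardized scale its bias is negligible for the effect sizes that
    matter here.
    """
    n, d = X.shape
    D = np.column_stack([np.ones(n), X])
    beta = np.zeros(d + 1)
    pen = ridge * np.eye(d + 1)
    pen[0, 0] = 0.0
    for _ in range(60):
        lp = D @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(lp, -35, 35)))
        W = np.clip(p * (1 - p), 1e-10, None)
        H = D.T @ (W[:, None] * D) + pen
        g = D.T @ (y - p) - pen @ beta
        step = np.linalg.solve(H, g)
        beta += step
        if np.abs(step).max() < 1e-9:
            break
    return _loglik(D[:, 1:], y, beta[1:], float(beta[0]))


def _bic(fit: MarkerFit, X1, y1, X2, y2) -> float:
    """Sum of per-dataset BICs on REFITTED supports.

    The fusion penalty biases coefficients toward cross-disease similarity,
    which deflates the penalized fit's likelihood; judging candidate
    supports by a refit puts fused and separate fits on the same footing.
    """
    out = 0.0
    for X, y, k in ((X1, y1, 0), (X2, y2, 1)):
        n = len(y)
        sup = np.flatnonzero(fit.beta[k])
        df = len(sup)
        if df == 0 or df >= n - 1:
            pbar = y.mean()
            ll = float(n * (pbar * np.log(pbar) + (1 - pbar) * np.log1p(-pbar)))
        else:
            ll = _refit_loglik(X[:, sup], y)
        out += -2.0 * ll + np.log(n) * df
    return out


def default_lambda1_grid(
    d1: OmicsDataset, d2: OmicsDataset, feature: str = "expression",
    n: int = 16, ratio: float = 0.05,
) -> np.ndarray:
    # tiny upward nudge: the top of the path must be the exact null fit
    # despite summation-order rounding between lambda_max and the kernel
    lmax = lambda_max(d1, d2, feature) * (1 + 1e-8)
    return np.geomspace(lmax, ratio * lmax, n)


# Fusion strengths spanning moderate to near-equality coupling; on the
# normalized-likelihood scale the cross-disease quadratic dominates the
# likelihood curvature (~1/4 per coordinate) from about lam2 = 2 upward.
DEFAULT_LAMBDA2_GRID = (2.0, 8.0, 32.0)


def select_tuning_markers(
    d1: OmicsDataset,
    d2: OmicsDataset,
    penalty: str = "magnitude",
    lambda1_grid=None,
    lambda2_grid=None,
    criterion: str = "bic",
    feature: str = "expression",
    cv_folds: int = 5,
    seed: int = 0,
    tol: float = 1e-5,
    max_sweeps: int = 1000,
) -> MarkerFit:
    """Grid search over (lam1, lam2) with warm starts; best model by criterion.

    ``criterion='bic'`` uses -2(l1+l2) + log(n1+n2) * #nonzeros (ties broken
    toward larger lam1, i.e. the sparser model); ``'cv'`` uses stratified
    ``cv_folds``-fold out-of-fold deviance.
    """
    if lambda1_grid is None:
        lambda1_grid = default_lambda1_grid(d1, d2, feature)
    lambda1_grid = np.sort(np.asarray(lambda1_grid, dtype=float))[::-1]
    if lambda2_grid is None:
        lambda2_grid = [0.0] if penalty == "none" else list(DEFAULT_LAMBDA2_GRID)
    lambda2_grid = sorted(float(v) for v in lambda2_grid)
    if len(lambda1_grid) == 0 or len(lambda2_grid) == 0:
        raise ValueError("tuning grids must be non-empty")

    X1, y1, _, _ = _prep(d1, feature)
    X2, y2, _, _ = _prep(d2, feature)

    if criterion == "cv":
        folds1 = _stratified_folds(d1.require_outcome(), cv_folds, seed)
        folds2 = _stratified_folds(d2.require_outcome(), cv_folds, seed + 1)

    best = None
    best_score = np.inf
    path: list[dict] = []
    for lam2 in lambda2_grid:
        warm = None
        for lam1 in lambda1_grid:
            fit = solve_penalized_logistic(
                d1, d2, lam1, lam2, penalty=penalty, feature=feature,
                init=warm, tol=tol, max_sweeps=max_sweeps,
            )
            warm = fit
            if criterion == "bic":
                score = _bic(fit, X1, y1, X2, y2)
            elif criterion == "cv":
                score = _cv_deviance(
                    d1, d2, lam1, lam2, penalty, feature, folds1, folds2,
                    tol, max_sweeps,
                )
            else:
                raise ValueError(f"unknown criterion {criterion!r}")
            path.append(
                {
                    "lambda1": float(lam1),
                    "lambda2": float(lam2),
                    "score": float(score),
                    "df": int(
                        np.count_nonzero(fit.beta[0]) + np.count_nonzero(fit.beta[1])
                    ),
                }
            )
            # Ties: within one lam2 column the earlier (larger lam1, sparser)
            # fit wins; across lam2 the stronger coupling wins — with the
            # refit criterion, equal scores mean equal supports, and the
            # more strongly fused fit has the smaller effective complexity.
            better = score < best_score - 1e-9
            tie_stronger_fusion = (
                best is not None
                and score <= best_score + 1e-9
                and lam2 > best.lambda2
            )
            if best is None or better or tie_stronger_fusion:
                best_score = min(best_score, score)
                best = fit
    assert best is not None
    best.path = path
    return best


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls} has fewer samples ({len(idx)}) than folds")
        rng.shuffle(idx)
        for i, s in enumerate(idx):
            folds[i % k].append(int(s))
    return [np.array(sorted(f)) for f in folds]


def _subset(d: OmicsDataset, idx: np.ndarray) -> OmicsDataset:
    return OmicsDataset(
        sample_ids=[d.sample_ids[i] for i in idx],
        gene_ids=list(d.gene_ids),
        X=None if d.X is None else d.X[idx],
        Z=None if d.Z is None else d.Z[idx],
        y=None if d.y is None else d.y[idx],
        group_label=d.group_label,
    )


def _cv_deviance(
    d1, d2, lam1, lam2, penalty, feature, folds1, folds2, tol, max_sweeps
) -> float:
    dev = 0.0
    all1 = np.arange(d1.n)
    all2 = np.arange(d2.n)
    for f1, f2 in zip(folds1, folds2):
        tr1 = _subset(d1, np.setdiff1d(all1, f1))
        tr2 = _subset(d2, np.setdiff1d(all2, f2))
        fit = solve_penalized_logistic(
            d1=tr1, d2=tr2, lambda1=lam1, lambda2=lam2, penalty=penalty,
            feature=feature, tol=tol, max_sweeps=max_sweeps,
        )
        for d, fold, k in ((d1, f1, 0), (d2, f2, 1)):
            Xte = (d.block(feature)[fold] - fit.centers[k]) / fit.scales[k]
            yte = d.y[fold].astype(float)
            lp = Xte @ fit.beta[k] + fit.intercepts[k]
            dev += -2.0 * float(np.sum(yte * lp - np.logaddexp(0.0, lp)))
    return dev
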