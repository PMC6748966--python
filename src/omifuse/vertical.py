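"""Vertical integration of gene expression and CNV into one outcome model.

The integrative pipeline (A1) runs, per disease contrast:

1. SPCA of the expression matrix; keep the top K (default 10) sparse PCs.
2. "Reversed" regression of each CNV on those expression PC scores,
   ``Z = Xpc @ omega + E``; the fitted part carries the CNV information that
   overlaps with expression, the residual carries the independent part.
3. SPCA of the CNV residuals; keep the top K sparse PCs.
4. Unpenalized maximum-likelihood logistic regression of the case/control
   outcome on the 2K scores.

Comparators: A2 stacks SPCA of expression and of raw CNV (no decomposition),
A3 uses expression PCs only, A4 CNV PCs only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from .data_io import OmicsDataset
from .spca import SparsePCResult, sparse_pca

logger = logging.getLogger(__name__)

VARIANTS = ("A1", "A2", "A3", "A4")


@dataclass
class VerticalFit:
    """Fitted vertical pipeline for one disease contrast."""

    variant: str
    expr_spca: SparsePCResult | None
    omega_hat: np.ndarray | None
    resid_spca: SparsePCResult | None
    theta_x: np.ndarray | None
    theta_z: np.ndarray | None
    alpha: float
    gene_ids: list[str]
    ridge_fallback: bool = False

    @property
    def coefficients(self) -> np.ndarray:
        parts = [v for v in (self.theta_x, self.theta_z) if v is not None]
        return np.concatenate(parts) if parts else np.empty(0)


def reverse_regress(
    Z: np.ndarray, Xpc: np.ndarray, ridge: float = 1e-6
) -> np.ndarray:
    """Least-squares coefficients of each CNV column on the expression PC scores.

    Returns the K x p matrix ``omega_hat``; a small ridge penalty is applied
    only if the score matrix is rank deficient.
    """
    Z = np.asarray(Z, dtype=float)
    Xpc = np.asarray(Xpc, dtype=float)
    if Z.shape[0] != Xpc.shape[0]:
        raise ValueError(
            f"row mismatch: Z has {Z.shape[0]} rows, scores have {Xpc.shape[0]}"
        )
    G = Xpc.T @ Xpc
    if np.linalg.matrix_rank(Xpc) < Xpc.shape[1]:
        logger.warning("rank-deficient PC scores; using ridge(%g) fallback", ridge)
        G = G + ridge * np.eye(Xpc.shape[1])
    return np.linalg.solve(G, Xpc.T @ Z)


def residualize(
    Z: np.ndarray, Xpc: np.ndarray, omega_hat: np.ndarray
) -> np.ndarray:
    """CNV residual matrix ``Z - Xpc @ omega_hat`` (the independent component)."""
    Z = np.asarray(Z, dtype=float)
    Xpc = np.asarray(Xpc, dtype=float)
    omega_hat = np.asarray(omega_hat, dtype=float)
    if Xpc.shape[1] != omega_hat.shape[0] or Z.shape != (
        Xpc.shape[0],
        omega_hat.shape[1],
    ):
        raise ValueError(
            f"shape mismatch: Z{Z.shape}, Xpc{Xpc.shape}, omega{omega_hat.shape}"
        )
    return Z - Xpc @ omega_hat


def _fit_logistic_ml(
    S: np.ndarray, y: np.ndarray, ridge: float = 1e-4
) -> tuple[np.ndarray, float, bool]:
    """Unpenalized logistic ML on score matrix S; ridge-stabilized on failure.

    Returns (coefficients, intercept, used_ridge_fallback).
    """
    D = sm.add_constant(S, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, D, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-8
            )
            params = np.asarray(res.params)
            if np.all(np.isfinite(params)) and np.abs(params).max() < 1e6:
                return params[1:], float(params[0]), False
        except Exception:  # separation / singular information
            pass
    logger.warning("logistic ML unstable; using ridge(%g)-stabilized IRLS", ridge)
    beta = np.zeros(D.shape[1])
    pen = ridge * np.eye(D.shape[1])
    pen[0, 0] = 0.0  # intercept unpenalized
    for _ in range(100):
        eta = D @ beta
        p = expit(eta)
        W = np.clip(p * (1 - p), 1e-10, None)
        H = D.T @ (W[:, None] * D) + pen
        g = D.T @ (y - p) - pen @ beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(step).max() < 1e-8:
            break
    return beta[1:], float(beta[0]), True


def fit_vertical(
    dataset: OmicsDataset,
    variant: str = "A1",
    n_components: int = 10,
    c_expr: float | None = None,
    c_cnv: float | None = None,
    scale: bool = False,
    reverse_regression: bool = True,
) -> VerticalFit:
    """Fit one vertical pipeline variant on a case/control dataset.

    ``n_components`` is truncated to ``min(n-1, p)``; the default of ten
    sparse PCs per omics block mirrors fixing the component count rather
    than selecting it. ``reverse_regression=False`` forces omega_hat to zero
    in A1, which makes the A1 decomposition coincide with A2 exactly.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    y = dataset.require_outcome()
    K = min(n_components, dataset.n - 1, dataset.p)

    expr_spca = omega = resid_spca = None
    blocks = []
    if variant in ("A1", "A2", "A3"):
        expr_spca = sparse_pca(dataset.block("expression"), K, c=c_expr, scale=scale)
        blocks.append(expr_spca.scores)
    if variant == "A1":
        Z = dataset.block("cnv")
        if reverse_regression:
            omega = reverse_regress(Z, expr_spca.scores)
        else:
            omega = np.zeros((expr_spca.n_components, dataset.p))
        R = residualize(Z, expr_spca.scores, omega)
        resid_spca = sparse_pca(R, K, c=c_cnv, scale=scale)
        blocks.append(resid_spca.scores)
    elif variant in ("A2", "A4"):
        resid_spca = sparse_pca(dataset.block("cnv"), K, c=c_cnv, scale=scale)
        blocks.append(resid_spca.scores)

    S = np.column_stack(blocks)
    coef, alpha, fallback = _fit_logistic_ml(S, y)

    theta_x = theta_z = None
    if expr_spca is not None:
        theta_x = coef[: expr_spca.n_components]
    if resid_spca is not None:
        theta_z = coef[-resid_spca.n_components :]
    return VerticalFit(
        variant=variant,
        expr_spca=expr_spca,
        omega_hat=omega,
        resid_spca=resid_spca,
        theta_x=theta_x,
        theta_z=theta_z,
        alpha=alpha,
        gene_ids=list(dataset.gene_ids),
        ridge_fallback=fallback,
    )


def predict_vertical(fit: VerticalFit, dataset: OmicsDataset) -> np.ndarray:
    """Case probabilities for (new) samples under a fitted vertical model.

    New samples are centered with the training centering and projected on the
    training loadings; for A1 the CNV residuals use the training omega_hat.
    """
    if list(dataset.gene_ids) != fit.gene_ids:
        raise ValueError("gene_ids of dataset do not match the training fit")
    blocks = []
    if fit.expr_spca is not None:
        xpc = fit.expr_spca.transform(dataset.block("expression"))
        blocks.append(xpc)
    if fit.variant == "A1":
        R = residualize(dataset.block("cnv"), xpc, fit.omega_hat)
        blocks.append(fit.resid_spca.transform(R))
    elif fit.variant in ("A2", "A4"):
        blocks.append(fit.resid_spca.transform(dataset.block("cnv")))
    S = np.column_stack(blocks)
    eta = S @ fit.coefficients + fit.alpha
    return expit(eta)
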