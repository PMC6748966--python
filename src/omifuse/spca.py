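"""Sparse principal component analysis via rank-one penalized matrix decomposition.

Each component solves

    maximize  u' A v   subject to  ||u||_2 <= 1, ||v||_2 <= 1, ||v||_1 <= c

by alternating updates: u is the normalized image A v, and v is the
soft-thresholded, renormalized image A' u with the threshold chosen by
bisection so the L1 bound holds. Subsequent components come from rank-one
deflation A <- A - d u v'. With a loose bound (c = sqrt(p)) this reduces to
ordinary PCA of the centered matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_DEFAULT_TOL = 1e-7
_MAX_ALTERNATIONS = 200


@dataclass
class SparsePCResult:
    """Sparse loadings, scores and singular values from SPCA.

    Attributes
    ----------
    loadings : ndarray (p, K)
        Unit-norm sparse loading vectors, one per component.
    scores : ndarray (n, K)
        Component scores of the centered input, ``(A - mean) @ loadings``.
    singular_values : ndarray (K,)
        Values ``d_k = u_k' A_k v_k`` in non-increasing order.
    sparsity_bound : float
        The L1 bound ``c`` applied to every loading vector.
    center : ndarray (p,)
        Column means removed before decomposition (needed to score new data).
    scale : ndarray (p,) or None
        Column standard deviations, when variance scaling was requested.
    """

    loadings: np.ndarray
    scores: np.ndarray
    singular_values: np.ndarray
    sparsity_bound: float
    center: np.ndarray
    scale: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, A: np.ndarray) -> np.ndarray:
        """Score new samples with the training centering/scaling and loadings."""
        A = np.asarray(A, dtype=float) - self.center
        if self.scale is not None:
            A = A / self.scale
        return A @ self.loadings


def _soft(a: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - thr, 0.0)


def _l1_constrained_unit(a: np.ndarray, c: float, tol: float = 1e-10) -> np.ndarray:
    """Unit vector proportional to soft(a, thr) with L1 norm <= c.

    The L1 norm of the normalized soft-thresholded vector decreases
    continuously in the threshold (from ||a||_1/||a||_2 down to 1), so the
    smallest feasible threshold is found by bisection; ties break toward the
    smaller threshold.
    """
    v = a / np.linalg.norm(a)
    if np.abs(v).sum() <= c:
        return v
    lo, hi = 0.0, np.abs(a).max()
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        s = _soft(a, mid)
        nrm = np.linalg.norm(s)
        if nrm == 0.0:
            hi = mid
            continue
        if np.abs(s).sum() / nrm > c:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * (np.abs(a).max() + 1.0):
            break
    s = _soft(a, hi)
    return s / np.linalg.norm(s)


def pmd_rank_one(
    A: np.ndarray, c: float, tol: float = _DEFAULT_TOL
) -> tuple[np.ndarray, float, np.ndarray]:
    """One penalized rank-one factor (u, d, v) of a column-centered matrix.

    ``v`` is sign-normalized so its largest-magnitude entry is positive; the
    alternations stop when ``d`` changes by less than ``tol``.
    """
    A = np.asarray(A, dtype=float)
    n, p = A.shape
    if c < 1:
        raise ValueError("sparsity bound c must be >= 1 (no feasible unit vector)")
    if not np.any(A):
        raise ValueError("cannot decompose an all-zero matrix")
    # warm start from the dense leading right singular vector
    v = np.linalg.svd(A, full_matrices=False)[2][0]
    v = _l1_constrained_unit(v, c)
    d_old = -np.inf
    for _ in range(_MAX_ALTERNATIONS):
        Av = A @ v
        nrm = np.linalg.norm(Av)
        if nrm == 0.0:
            break
        u = Av / nrm
        v = _l1_constrained_unit(A.T @ u, c)
        d = float(u @ A @ v)
        if abs(d - d_old) < tol:
            break
        d_old = d
    d = float(u @ A @ v)
    imax = int(np.argmax(np.abs(v)))
    if v[imax] < 0:
        v = -v
        u = -u
    return u, d, v


def sparse_pca(
    A: np.ndarray,
    K: int,
    c: float | None = None,
    scale: bool = False,
    tol: float = _DEFAULT_TOL,
) -> SparsePCResult:
    """K sparse principal components of ``A`` by repeated rank-one PMD.

    Columns are mean-centered (and optionally variance-scaled) first; each
    extracted factor is deflated out before the next. ``c`` defaults to
    ``sqrt(p)/2``. Components are returned ordered by ``d``.
    """
    A = np.asarray(A, dtype=float)
    n, p = A.shape
    if K > min(n - 1, p):
        raise ValueError(f"K={K} exceeds min(n-1, p)={min(n - 1, p)}")
    center = A.mean(axis=0)
    Ac = A - center
    scl = None
    if scale:
        scl = Ac.std(axis=0, ddof=1)
        scl[scl == 0] = 1.0
        Ac = Ac / scl
    if c is None:
        c = np.sqrt(p) / 2.0
    c = float(min(max(c, 1.0), np.sqrt(p)))

    work = Ac.copy()
    us, ds, vs = [], [], []
    thresh = 1e-12 * max(np.abs(Ac).max(), 1.0)
    for _ in range(K):
        if not np.any(np.abs(work) > thresh):
            break  # matrix exhausted before K factors
        u, d, v = pmd_rank_one(work, c, tol=tol)
        work = work - d * np.outer(u, v)
        us.append(u)
        ds.append(d)
        vs.append(v)
    # a rank-deficient (or all-zero) input yields fewer than K factors; the
    # remainder are padded as zero-variance components so downstream models
    # keep a fixed design width
    while len(ds) < K:
        ds.append(0.0)
        vs.append(np.zeros(p))
    order = np.argsort(ds)[::-1]
    loadings = np.column_stack([vs[i] for i in order])
    singular_values = np.array([ds[i] for i in order])
    return SparsePCResult(
        loadings=loadings,
        scores=Ac @ loadings,
        singular_values=singular_values,
        sparsity_bound=c,
        center=center,
        scale=scl,
    )


def bound_for_nonzeros(
    A: np.ndarray, target_nnz: int, tol: int = 0
) -> float:
    """Sparsity bound c whose leading loading has about ``target_nnz`` nonzeros.

    Convenience bisection over c in [1, sqrt(p)] on the first component.
    """
    A = np.asarray(A, dtype=float)
    p = A.shape[1]
    Ac = A - A.mean(axis=0)
    lo, hi = 1.0, float(np.sqrt(p))
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        _, _, v = pmd_rank_one(Ac, mid)
        nnz = int(np.count_nonzero(v))
        if abs(nnz - target_nnz) <= tol:
            return mid
        if nnz > target_nnz:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
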