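"""Synthetic-data generators mirroring the study's simulation designs.

Two designs are implemented as stated for the marker and regulation
analyses, plus a latent-factor generator used to exercise the vertical
pipeline (which has no published simulation design):

* **Marker scenarios I-IV** — gene-expression vectors for disease k drawn
  from N(mu_k, Sigma) and controls from N(0, Sigma); Sigma is block-diagonal
  over the 8 outcome-associated variables and the remaining null ones, each
  block AR with correlation 0.3^|j-l|; n = 40 per group, p = 100. The four
  built-in mean configurations range from identical effects (I) through
  same-sign different-magnitude (II, III) to conflicting signs (IV).
* **Regulation design** — each expression is regulated by 10% of the CNVs,
  coefficients half Uniform(0.6, 1.2) and half Uniform(-1.2, -0.6); the two
  diseases share six important CNVs per gene with matching signs; N(0, 1)
  errors. The study uses its observed CNV matrix as predictors; a synthetic
  AR-correlated surrogate (optionally discretized to {-1, 0, 1}) stands in
  when that matrix is unavailable.

One shared control draw per replicate supplies the controls of both disease
contrasts, matching the single normal group of the study design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import BIPOLAR, CONTROL, SCHIZOPHRENIA, OmicsDataset

_SCENARIO_MU2 = {
    "I": None,  # mu2 = mu1
    "II": (-1.0, -1.0, -4.0, -4.0, 2.0, 2.0, 4.0, 4.0),
    "III": (-2.0, -2.0, -0.5, -0.5, 3.0, 3.0, 1.0, 1.0),
    "IV": (2.0, 2.0, -0.5, -0.5, 3.0, 3.0, -1.0, -1.0),
}
_MU1_HEAD = (-1.0, -1.0, -1.0, -1.0, 2.0, 2.0, 2.0, 2.0)


@dataclass
class MarkerScenarioSpec:
    """Settings of the four-scenario multivariate-normal marker simulation."""

    scenario: str = "I"
    n_per_group: int = 40
    p: int = 100
    rho: float = 0.3
    n_important: int = 8
    mu1: np.ndarray | None = None
    mu2: np.ndarray | None = None

    def resolve_means(self) -> tuple[np.ndarray, np.ndarray]:
        if self.scenario == "custom":
            if self.mu1 is None or self.mu2 is None:
                raise ValueError("custom scenario needs explicit mu1 and mu2")
            return np.asarray(self.mu1, float), np.asarray(self.mu2, float)
        if self.scenario not in _SCENARIO_MU2:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.p < self.n_important:
            raise ValueError("p must be at least the number of important variables")
        mu1 = np.zeros(self.p)
        mu1[: len(_MU1_HEAD)] = _MU1_HEAD
        head2 = _SCENARIO_MU2[self.scenario]
        mu2 = mu1.copy()
        if head2 is not None:
            mu2 = np.zeros(self.p)
            mu2[: len(head2)] = head2
        return mu1, mu2


@dataclass
class RegulationSimSpec:
    """Settings of the sparse expression-on-CNV regulation simulation."""

    cnv_source: str = "synthetic"
    regulated_fraction: float = 0.10
    coef_pos: tuple[float, float] = (0.6, 1.2)
    coef_neg: tuple[float, float] = (-1.2, -0.6)
    n_shared: int = 6
    noise_sd: float = 1.0
    n_genes: int | None = None  # defaults to the CNV dimension


def ar_covariance(p: int, rho: float) -> np.ndarray:
    """AR correlation matrix with entry rho^|j-l| (positive definite for |rho|<1)."""
    if not -1 < rho < 1:
        raise ValueError("AR correlation must satisfy |rho| < 1")
    idx = np.arange(p)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def block_ar_covariance(p: int, n_important: int, rho: float) -> np.ndarray:
    """Block-diagonal covariance: AR block over the important variables,
    AR block over the rest, zero across."""
    S = np.zeros((p, p))
    S[:n_important, :n_important] = ar_covariance(n_important, rho)
    S[n_important:, n_important:] = ar_covariance(p - n_important, rho)
    return S


def _mvn(rng: np.random.Generator, mean: np.ndarray, chol: np.ndarray, n: int):
    return mean + rng.standard_normal((n, chol.shape[0])) @ chol.T


def simulate_marker_scenario(
    spec: MarkerScenarioSpec, seed: int
) -> tuple[OmicsDataset, OmicsDataset, np.ndarray]:
    """Draw one replicate of the marker simulation.

    Returns the two case/control datasets (expression block only; the 40
    controls are one shared draw) and the true important indices.
    """
    rng = np.random.default_rng(seed)
    mu1, mu2 = spec.resolve_means()
    p, n = spec.p, spec.n_per_group
    Sigma = block_ar_covariance(p, spec.n_important, spec.rho)
    chol = np.linalg.cholesky(Sigma)
    cases1 = _mvn(rng, mu1, chol, n)
    cases2 = _mvn(rng, mu2, chol, n)
    controls = _mvn(rng, np.zeros(p), chol, n)

    gene_ids = [f"g{j}" for j in range(p)]
    y = np.concatenate([np.ones(n, int), np.zeros(n, int)])
    datasets = []
    for label, cases in ((BIPOLAR, cases1), (SCHIZOPHRENIA, cases2)):
        datasets.append(
            OmicsDataset(
                sample_ids=[f"{label[:2]}_case{i}" for i in range(n)]
                + [f"ctrl{i}" for i in range(n)],
                gene_ids=gene_ids,
                X=np.vstack([cases, controls]),
                y=y,
                group_label=label,
            )
        )
    truth = np.arange(spec.n_important)
    return datasets[0], datasets[1], truth


def simulate_cnv_matrix(
    n: int, p: int, seed: int, rho: float = 0.3, discretize: bool = False
) -> np.ndarray:
    """Synthetic CNV predictor matrix: AR(rho)-correlated Gaussian columns,
    optionally cut at tertiles into copy-number-like levels {-1, 0, 1}.

    This is a stand-in surrogate for an observed CNV matrix, not a model of
    array-derived copy-number data.
    """
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(ar_covariance(p, rho))
    Z = rng.standard_normal((n, p)) @ chol.T
    if discretize:
        lo, hi = np.quantile(Z, [1 / 3, 2 / 3], axis=0)
        Z = np.where(Z < lo, -1.0, np.where(Z > hi, 1.0, 0.0))
    return Z


def _draw_signed_coefs(
    rng: np.random.Generator, signs: np.ndarray, spec: RegulationSimSpec
) -> np.ndarray:
    out = np.empty(len(signs))
    pos = signs > 0
    out[pos] = rng.uniform(*spec.coef_pos, size=pos.sum())
    out[~pos] = rng.uniform(*spec.coef_neg, size=(~pos).sum())
    return out


def _half_signs(rng: np.random.Generator, m: int) -> np.ndarray:
    """m signs, half +1 half -1 (odd m: extra sign random), shuffled."""
    signs = np.concatenate([np.ones(m // 2), -np.ones(m // 2)])
    if m % 2:
        signs = np.append(signs, rng.choice([-1.0, 1.0]))
    rng.shuffle(signs)
    return signs


def simulate_regulation_data(
    spec: RegulationSimSpec,
    Z1: np.ndarray,
    Z2: np.ndarray,
    seed: int,
) -> tuple[OmicsDataset, OmicsDataset, tuple[np.ndarray, np.ndarray]]:
    """Fill in expression matrices from a sparse linear model on given CNVs.

    Per gene j and disease k the support has size round(regulated_fraction*p)
    and includes ``n_shared`` CNVs common to both diseases whose coefficients
    carry the same signs; remaining support indices and all magnitudes are
    disease-specific. Returns the two datasets and the true (genes x CNVs)
    coefficient matrices.
    """
    rng = np.random.default_rng(seed)
    Z1 = np.asarray(Z1, float)
    Z2 = np.asarray(Z2, float)
    if Z1.shape[1] != Z2.shape[1]:
        raise ValueError("CNV matrices must share the predictor dimension")
    p = Z1.shape[1]
    q = spec.n_genes if spec.n_genes is not None else p
    m = int(round(spec.regulated_fraction * p))
    if m < spec.n_shared or m < 2:
        raise ValueError(
            f"support size {m} too small for {spec.n_shared} shared CNVs "
            "plus sign-split halves"
        )

    eta1 = np.zeros((q, p))
    eta2 = np.zeros((q, p))
    for j in range(q):
        shared = rng.choice(p, size=spec.n_shared, replace=False)
        shared_signs = _half_signs(rng, spec.n_shared)
        rest = np.setdiff1d(np.arange(p), shared)
        for eta in (eta1, eta2):
            own = rng.choice(rest, size=m - spec.n_shared, replace=False)
            own_signs = _half_signs(rng, m - spec.n_shared)
            eta[j, shared] = _draw_signed_coefs(rng, shared_signs, spec)
            eta[j, own] = _draw_signed_coefs(rng, own_signs, spec)

    gene_ids = [f"g{j}" for j in range(q)]
    cnv_gene_ids = [f"g{j}" for j in range(p)]
    datasets = []
    for label, Z, eta in ((BIPOLAR, Z1, eta1), (SCHIZOPHRENIA, Z2, eta2)):
        X = Z @ eta.T + spec.noise_sd * rng.standard_normal((Z.shape[0], q))
        if q == p:
            ds = OmicsDataset(
                sample_ids=[f"{label[:2]}_{i}" for i in range(Z.shape[0])],
                gene_ids=gene_ids,
                X=X,
                Z=Z,
                group_label=label,
            )
        else:
            # responses and predictors have different dimensions: keep the
            # CNV block on its own gene axis via a rectangular container pair
            ds = _RectangularOmics(
                sample_ids=[f"{label[:2]}_{i}" for i in range(Z.shape[0])],
                gene_ids=gene_ids,
                cnv_ids=cnv_gene_ids,
                X=X,
                Z=Z,
                group_label=label,
            )
        datasets.append(ds)
    return datasets[0], datasets[1], (eta1, eta2)


class _RectangularOmics(OmicsDataset):
    """OmicsDataset variant whose CNV block has its own feature axis."""

    def __init__(self, sample_ids, gene_ids, cnv_ids, X, Z, group_label=""):
        self.sample_ids = sample_ids
        self.gene_ids = gene_ids
        self.cnv_ids = cnv_ids
        self.X = np.asarray(X, float)
        self.Z = np.asarray(Z, float)
        self.y = None
        self.group_label = group_label
        if self.X.shape != (len(sample_ids), len(gene_ids)):
            raise ValueError("X shape mismatch")
        if self.Z.shape != (len(sample_ids), len(cnv_ids)):
            raise ValueError("Z shape mismatch")


def simulate_vertical_data(
    n: int,
    p: int,
    seed: int,
    overlap_strength: float = 1.0,
    independent_cnv_effect: float = 1.0,
    expr_effect: float = 1.5,
    noise_sd: float = 1.0,
) -> tuple[OmicsDataset, dict]:
    """Latent-factor test data for the vertical pipeline.

    Expression is driven by two sparse latent factors; CNV is the sum of an
    expression-driven part (weight ``overlap_strength``) and an independent
    sparse factor; the outcome follows a logistic model on one expression
    factor and the independent CNV factor (weight ``independent_cnv_effect``).
    Returns the dataset and a dict with the true factors and memberships.
    """
    rng = np.random.default_rng(seed)
    f1 = rng.standard_normal(n)
    f2 = rng.standard_normal(n)
    g1 = rng.standard_normal(n)
    third = max(p // 3, 1)
    a1 = np.zeros(p)
    a1[:third] = rng.uniform(0.8, 1.2, third)
    a2 = np.zeros(p)
    a2[third : 2 * third] = rng.uniform(0.8, 1.2, third)
    c1 = np.zeros(p)
    c1[2 * third :] = rng.uniform(0.8, 1.2, p - 2 * third)

    X = np.outer(f1, a1) + np.outer(f2, a2) + noise_sd * rng.standard_normal((n, p))
    Z = (
        overlap_strength * np.outer(f1, a1)
        + np.outer(g1, c1)
        + noise_sd * rng.standard_normal((n, p))
    )
    lp = expr_effect * f1 + independent_cnv_effect * g1
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-lp))).astype(int)
    ds = OmicsDataset(
        sample_ids=[f"s{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(p)],
        X=X,
        Z=Z,
        y=y,
        group_label="synthetic",
    )
    truth = {
        "expr_factor": f1,
        "second_factor": f2,
        "cnv_factor": g1,
        "expr_loadings": a1,
        "cnv_loadings": c1,
    }
    return ds, truth
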