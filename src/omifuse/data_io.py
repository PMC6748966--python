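"""Input/output and dataset assembly for paired expression/CNV analyses.

Matrices are stored samples-by-features internally (rows = subjects, columns =
genes); on disk the default orientation is features-in-rows, the common
convention for omics distribution files. Group labels distinguish the two
disease groups (bipolar disorder, schizophrenia) from the shared normal
controls, and the two case/control contrasts reuse the one control pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BIPOLAR = "bipolar"
SCHIZOPHRENIA = "schizophrenia"
CONTROL = "control"
KNOWN_GROUPS = (BIPOLAR, SCHIZOPHRENIA, CONTROL)


class Orientation(str, Enum):
    features_in_rows = "features_in_rows"
    samples_in_rows = "samples_in_rows"


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass
class OmicsDataset:
    """One case/control contrast with paired expression and CNV matrices.

    Parameters
    ----------
    sample_ids : list of str
        Subject identifiers, length ``n``.
    gene_ids : list of str
        Gene identifiers shared by the expression and CNV blocks, length ``p``.
    X : ndarray of shape (n, p), optional
        Gene-expression matrix (subjects by genes).
    Z : ndarray of shape (n, p), optional
        Copy-number matrix aligned to the same genes.
    y : ndarray of shape (n,), optional
        Binary outcome, 1 = case, 0 = control. ``None`` for analyses that do
        not involve the outcome (e.g. regulation estimation on one group).
    group_label : str
        Which contrast/group this dataset represents.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    X: np.ndarray | None = None
    Z: np.ndarray | None = None
    y: np.ndarray | None = None
    group_label: str = ""

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        p = len(self.gene_ids)
        if len(set(self.gene_ids)) != p:
            raise DataError("gene_ids are not unique")
        for name, M in (("X", self.X), ("Z", self.Z)):
            if M is None:
                continue
            M = np.asarray(M, dtype=float)
            if M.shape != (n, p):
                raise DataError(
                    f"{name} has shape {M.shape}, expected ({n}, {p})"
                )
            if not np.all(np.isfinite(M)):
                raise DataError(f"{name} contains non-finite entries")
            setattr(self, name, M)
        if self.X is None and self.Z is None:
            raise DataError("dataset needs at least one of X, Z")
        if self.y is not None:
            y = np.asarray(self.y)
            if y.shape != (n,):
                raise DataError(f"y has length {y.shape}, expected {n}")
            if not np.isin(y, [0, 1]).all():
                raise DataError("y must contain only 0/1")
            self.y = y.astype(int)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def p(self) -> int:
        return len(self.gene_ids)

    def require_outcome(self) -> np.ndarray:
        if self.y is None:
            raise DataError("dataset has no outcome vector")
        if len(np.unique(self.y)) < 2:
            raise DataError("outcome modelling needs both classes present")
        return self.y

    def block(self, feature: str) -> np.ndarray:
        """Return the expression ('expression') or CNV ('cnv') matrix."""
        if feature == "expression":
            M = self.X
        elif feature == "cnv":
            M = self.Z
        else:
            raise ValueError(f"unknown feature block {feature!r}")
        if M is None:
            raise DataError(f"dataset has no {feature} block")
        return M


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. pathways used for prescreening."""

    sets: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


def load_matrix(
    path: str | Path,
    orientation: Orientation | str = Orientation.features_in_rows,
) -> pd.DataFrame:
    """Read a TSV matrix and return it samples-by-features.

    The file must have one header row and a leading identifier column with a
    numeric body; ``features_in_rows`` input is transposed so that rows are
    samples internally. Non-numeric cells and duplicate identifiers raise
    :class:`DataError` naming the offending cell/identifier.
    """
    orientation = Orientation(orientation)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise DataError(f"duplicate row identifier {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise DataError(f"duplicate column identifier {dup!r} in {path}")
    try:
        # validate with pandas (for error locating); parse with Python's
        # float, which is round-trip exact where pd.to_numeric is not
        df.apply(pd.to_numeric, errors="raise")
        values = df.apply(lambda col: col.map(float))
    except (ValueError, TypeError):
        # locate the first bad cell for the error message
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce")
            mask = bad.isna()
            if mask.any():
                row = df.index[mask.to_numpy()][0]
                raise DataError(
                    f"non-numeric value {df.loc[row, col]!r} at row "
                    f"{row!r}, column {col!r} in {path}"
                ) from None
        raise
    if not np.all(np.isfinite(values.to_numpy())):
        raise DataError(f"non-finite value in {path}")
    if orientation is Orientation.features_in_rows:
        values = values.T
    return values


def write_matrix(
    df: pd.DataFrame,
    path: str | Path,
    orientation: Orientation | str = Orientation.features_in_rows,
) -> None:
    """Write a samples-by-features frame to TSV (inverse of :func:`load_matrix`)."""
    orientation = Orientation(orientation)
    out = df.T if orientation is Orientation.features_in_rows else df
    # %.17g keeps the round trip bit-identical for doubles
    out.to_csv(path, sep="\t", float_format="%.17g")


def load_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV (sample_id, group) into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"}.issubset(df.columns):
        raise DataError("label file needs columns 'sample_id' and 'group'")
    if df["sample_id"].duplicated().any():
        raise DataError("duplicate sample_id in label file")
    return df.set_index("sample_id")["group"]


def load_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name, description, tab-separated member genes."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"GMT line {lineno} has {len(fields)} fields, expected >= 3"
                )
            name = fields[0]
            if name in sets:
                raise DataError(f"duplicate gene set name {name!r} (line {lineno})")
            sets[name] = frozenset(g for g in fields[2:] if g)
    return GeneSetCollection(sets)


def assemble_contrasts(
    X: pd.DataFrame,
    Z: pd.DataFrame,
    labels: pd.Series,
    share_controls: bool = True,
    seed: int | None = None,
) -> tuple[OmicsDataset, OmicsDataset]:
    """Build the two disease-vs-control datasets from labelled matrices.

    Every sample must be labelled bipolar / schizophrenia / control; each
    returned dataset holds that disease's cases plus the controls (shared
    across the two contrasts by default; ``share_controls=False`` splits the
    control pool disjointly at random).
    """
    unknown = set(labels.unique()) - set(KNOWN_GROUPS)
    if unknown:
        raise DataError(f"unknown group label(s): {sorted(unknown)}")
    samples = list(X.index)
    if list(Z.index) != samples or list(labels.index) != samples:
        # align by identifier rather than position
        missing = (set(samples) ^ set(Z.index)) | (set(samples) ^ set(labels.index))
        if missing:
            raise DataError(f"samples not aligned across X/Z/labels: {sorted(missing)[:5]}")
        Z = Z.loc[samples]
        labels = labels.loc[samples]

    controls = [s for s in samples if labels[s] == CONTROL]
    if not controls:
        raise DataError("no control samples")
    control_split: dict[str, list[str]] = {BIPOLAR: controls, SCHIZOPHRENIA: controls}
    if not share_controls:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(controls))
        half = len(controls) // 2
        control_split = {
            BIPOLAR: [controls[i] for i in perm[:half]],
            SCHIZOPHRENIA: [controls[i] for i in perm[half:]],
        }

    out = []
    for disease in (BIPOLAR, SCHIZOPHRENIA):
        cases = [s for s in samples if labels[s] == disease]
        if not cases:
            raise DataError(f"no {disease} cases")
        ids = cases + control_split[disease]
        y = np.array([1] * len(cases) + [0] * len(control_split[disease]))
        out.append(
            OmicsDataset(
                sample_ids=ids,
                gene_ids=list(X.columns),
                X=X.loc[ids].to_numpy(float),
                Z=Z.loc[ids].to_numpy(float),
                y=y,
                group_label=disease,
            )
        )
    return out[0], out[1]


def subset_to_gene_set(
    dataset: OmicsDataset, gene_set: Sequence[str] | frozenset[str]
) -> OmicsDataset:
    """Restrict a dataset to the genes in ``gene_set`` (original order kept)."""
    gene_set = set(gene_set)
    keep = [j for j, g in enumerate(dataset.gene_ids) if g in gene_set]
    missing = gene_set - set(dataset.gene_ids)
    if missing:
        logger.warning(
            "%d gene set member(s) absent from data: %s%s",
            len(missing),
            sorted(missing)[:5],
            "..." if len(missing) > 5 else "",
        )
    if not keep:
        raise DataError("gene set has empty intersection with the data")
    return OmicsDataset(
        sample_ids=list(dataset.sample_ids),
        gene_ids=[dataset.gene_ids[j] for j in keep],
        X=None if dataset.X is None else dataset.X[:, keep],
        Z=None if dataset.Z is None else dataset.Z[:, keep],
        y=None if dataset.y is None else dataset.y.copy(),
        group_label=dataset.group_label,
    )
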