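"""Selection and prediction metrics.

TPR/FPR score support recovery against a known truth. Prediction is scored
by the corrected prediction ratio (CPR), implemented as balanced accuracy —
the mean of sensitivity and specificity at a 0.5 threshold — so a useless
classifier scores 0.5 regardless of class imbalance; ties at the threshold
predict class 0. The resampling evaluation repeatedly splits the data into
stratified train/test sets, refits the whole procedure on the training part
only, and averages the test-set CPR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .data_io import OmicsDataset

CPR_FORMULA = "CPR = 0.5*(sensitivity + specificity) at threshold 0.5 (ties -> 0)"


@dataclass
class SelectionMetrics:
    tpr: float
    fpr: float
    n_true: int
    n_selected: int


@dataclass
class CPRSummary:
    mean: float
    sd: float
    n_splits: int
    per_split: np.ndarray


def selection_metrics(
    selected: Iterable[int], truth: Iterable[int], p: int
) -> SelectionMetrics:
    """True/false positive rates of a selected index set against the truth."""
    selected = set(int(i) for i in selected)
    truth = set(int(i) for i in truth)
    if not truth:
        raise ValueError("empty truth set: TPR undefined")
    if any(i >= p or i < 0 for i in selected | truth):
        raise ValueError("indices must lie in [0, p)")
    tp = len(selected & truth)
    fp = len(selected - truth)
    n_null = p - len(truth)
    return SelectionMetrics(
        tpr=tp / len(truth),
        fpr=fp / n_null if n_null else 0.0,
        n_true=len(truth),
        n_selected=len(selected),
    )


def cpr(
    y_true: np.ndarray,
    p_hat: np.ndarray,
    threshold: float = 0.5,
    raw_accuracy: bool = False,
) -> float:
    """Corrected prediction ratio (balanced accuracy) of probability forecasts."""
    y_true = np.asarray(y_true).astype(int)
    p_hat = np.asarray(p_hat, dtype=float)
    pred = (p_hat > threshold).astype(int)  # ties predict class 0
    if raw_accuracy:
        return float((pred == y_true).mean())
    sens = float((pred[y_true == 1] == 1).mean()) if (y_true == 1).any() else np.nan
    spec = float((pred[y_true == 0] == 0).mean()) if (y_true == 0).any() else np.nan
    return 0.5 * (sens + spec)


def _stratified_split(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_tr = int(round(train_fraction * len(idx)))
        n_tr = min(max(n_tr, 1), len(idx) - 1)
        train.extend(idx[:n_tr])
        test.extend(idx[n_tr:])
    return np.array(sorted(train)), np.array(sorted(test))


def _take(d: OmicsDataset, idx: np.ndarray) -> OmicsDataset:
    return OmicsDataset(
        sample_ids=[d.sample_ids[i] for i in idx],
        gene_ids=list(d.gene_ids),
        X=None if d.X is None else d.X[idx],
        Z=None if d.Z is None else d.Z[idx],
        y=None if d.y is None else d.y[idx],
        group_label=d.group_label,
    )


def evaluate_cpr_resampling(
    dataset: OmicsDataset,
    fit_procedure: Callable[[OmicsDataset], Callable[[OmicsDataset], np.ndarray]],
    n_splits: int = 200,
    train_fraction: float = 0.75,
    seed: int = 0,
    raw_accuracy: bool = False,
) -> CPRSummary:
    """Resampled out-of-sample CPR of a modelling procedure.

    ``fit_procedure(train_dataset)`` must return a predictor mapping a
    dataset to case probabilities; the entire procedure (including any
    dimension-reduction steps) is refit on each training split. Splits are
    stratified, so both classes are present in every training set by
    construction.
    """
    y = dataset.require_outcome()
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least two samples per class for stratified splits")
    rng = np.random.default_rng(seed)
    values = np.empty(n_splits)
    for s in range(n_splits):
        tr, te = _stratified_split(y, train_fraction, rng)
        predictor = fit_procedure(_take(dataset, tr))
        p_hat = predictor(_take(dataset, te))
        values[s] = cpr(y[te], p_hat, raw_accuracy=raw_accuracy)
    return CPRSummary(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if n_splits > 1 else 0.0,
        n_splits=n_splits,
        per_split=values,
    )
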