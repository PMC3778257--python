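"""Nested leave-one-subject-out cross-validation with inner (C, k) grid search.

The outer loop holds out one subject for unbiased evaluation; for each
outer fold an inner leave-one-subject-out loop over the remaining N-1
subjects selects the regularization constant C and the number of
top-ranked Fisher voxels k. Voxel scoring and selection are recomputed
inside every inner fold on its own N-2 training subjects, so no
information about a held-out subject ever enters scoring, selection or
model choice (the leakage invariant asserted in the test suite).

Inner model quality is balanced accuracy over the inner out-of-fold
predictions; grid ties are broken toward smaller k, then smaller C.
Degenerate inner folds whose training remainder contains one class are
skipped and the inner metric is computed over the realised folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import fisher_scores, rank_and_select
from .svm import SVMModel, train_linear_svm, decision_values
from .volumes import CohortDataset

__all__ = ["HyperparameterGrid", "FoldRecord", "CVResult",
           "inner_select", "outer_loso", "final_model", "DEFAULT_GRID"]


@dataclass
class HyperparameterGrid:
    """Search grid over regularization constants and voxel counts."""

    C_values: tuple = tuple(2.0 ** p for p in range(-5, 16, 2))
    k_values: tuple = (10, 20, 50, 100, 200, 310, 360, 500)

    def __post_init__(self) -> None:
        self.C_values = tuple(float(c) for c in self.C_values)
        self.k_values = tuple(int(k) for k in self.k_values)
        if not self.C_values or not self.k_values:
            raise ValueError("grid must have at least one C and one k")
        if any(c <= 0 for c in self.C_values):
            raise ValueError("C values must be positive")
        if any(k < 1 for k in self.k_values):
            raise ValueError("k values must be >= 1")
        if list(self.C_values) != sorted(set(self.C_values)) \
                or list(self.k_values) != sorted(set(self.k_values)):
            raise ValueError("grid values must be strictly increasing")


#: libsvm-convention log-spaced C grid; k grid spans sparse to dense selection.
DEFAULT_GRID = HyperparameterGrid()


@dataclass
class FoldRecord:
    """Hyperparameters and voxel columns chosen within one outer fold."""

    test_subject: str
    C: float
    k: int
    columns: np.ndarray
    w: np.ndarray = field(default=None, repr=False)
    b: float = None


@dataclass
class CVResult:
    """Out-of-fold predictions and per-fold choices from nested LOSO."""

    subject_ids: list[str]
    y_true: np.ndarray
    decision_value: np.ndarray
    y_pred: np.ndarray
    folds: list[FoldRecord]
    grid: HyperparameterGrid

    def to_frame(self) -> pd.DataFrame:
        """Per-subject table in the layout of the study's supplementary tables."""
        return pd.DataFrame({
            "subject_id": self.subject_ids,
            "label": self.y_true,
            "decision_value": self.decision_value,
            "predicted_label": self.y_pred,
        })


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    accs = []
    for cls in (1, -1):
        m = y_true == cls
        if m.any():
            accs.append(np.mean(y_pred[m] == cls))
    return float(np.mean(accs))


def inner_select(
    train_X: np.ndarray,
    train_y: np.ndarray,
    grid: HyperparameterGrid,
    sd: str = "population",
    denominator: str = "sd",
) -> tuple[float, int]:
    """Choose (C*, k*) by leave-one-subject-out over the training set.

    Every inner fold recomputes Fisher scores and its own top-k columns
    from the N-2 remaining subjects. Returns the grid cell with maximal
    inner balanced accuracy; ties go to smaller k, then smaller C.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    n = train_X.shape[0]
    if np.sum(train_y == 1) < 2 or np.sum(train_y == -1) < 2:
        raise ValueError("inner training set needs >= 2 subjects per class")
    k_values = [k for k in grid.k_values if k <= train_X.shape[1]]
    if not k_values:
        raise ValueError(
            f"all grid k values exceed the {train_X.shape[1]} available voxels")
    if len(grid.C_values) == 1 and len(k_values) == 1:
        return grid.C_values[0], k_values[0]  # nothing to search

    # predictions[(C, k)] -> list of (true, pred) over realised inner folds
    preds: dict[tuple[float, int], list[tuple[int, int]]] = {
        (C, k): [] for C in grid.C_values for k in k_values}
    for i in range(n):
        rest = np.arange(n) != i
        y_rest = train_y[rest]
        if np.sum(y_rest == 1) < 2 or np.sum(y_rest == -1) < 2:
            continue  # degenerate fold: skip, metric renormalises over the rest
        X_rest = train_X[rest]
        fs = fisher_scores(X_rest, y_rest, sd=sd, denominator=denominator)
        for k in k_values:
            cols = rank_and_select(fs, k)
            Xk = X_rest[:, cols]
            xt = train_X[i, cols]
            for C in grid.C_values:
                model = train_linear_svm(Xk, y_rest, C)
                f = decision_values(model, xt[None, :])[0]
                preds[(C, k)].append((train_y[i], 1 if f > 0 else -1))

    best = None
    best_score = -np.inf
    for k in k_values:            # ascending k, then ascending C: first strict
        for C in grid.C_values:   # improvement wins => value-based tie-break
            pairs = preds[(C, k)]
            if not pairs:
                continue
            yt, yp = zip(*pairs)
            score = _balanced_accuracy(np.array(yt), np.array(yp))
            if score > best_score + 1e-12:
                best_score = score
                best = (C, k)
    if best is None:
        raise ValueError("no inner fold could be evaluated")
    return best


def outer_loso(
    dataset: CohortDataset,
    grid: HyperparameterGrid = DEFAULT_GRID,
    sd: str = "population",
    denominator: str = "sd",
) -> CVResult:
    """Nested leave-one-subject-out evaluation of the full pipeline.

    For each held-out subject: hyperparameters are picked by
    :func:`inner_select` on the other N-1 subjects, Fisher scores and the
    top-k* columns are recomputed on those N-1 subjects, an SVM is trained
    at C*, and the held-out subject's decision value is recorded.
    """
    X, y = dataset.X, dataset.y
    n = X.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 subjects, got {n}")
    if np.sum(y == 1) < 2 or np.sum(y == -1) < 2:
        raise ValueError("need at least 2 subjects per class")

    decisions = np.empty(n)
    folds: list[FoldRecord] = []
    for i in range(n):
        rest = np.arange(n) != i
        X_tr, y_tr = X[rest], y[rest]
        C_star, k_star = inner_select(X_tr, y_tr, grid, sd=sd, denominator=denominator)
        fs = fisher_scores(X_tr, y_tr, sd=sd, denominator=denominator)
        cols = rank_and_select(fs, k_star)
        model = train_linear_svm(X_tr[:, cols], y_tr, C_star, selected_columns=cols)
        decisions[i] = decision_values(model, X[i, cols][None, :])[0]
        folds.append(FoldRecord(
            test_subject=dataset.subject_ids[i], C=C_star, k=k_star,
            columns=cols, w=model.w, b=model.b))
    y_pred = np.where(decisions > 0, 1, -1)
    return CVResult(
        subject_ids=list(dataset.subject_ids),
        y_true=y.copy(),
        decision_value=decisions,
        y_pred=y_pred,
        folds=folds,
        grid=grid,
    )


def final_model(
    dataset: CohortDataset,
    grid: HyperparameterGrid = DEFAULT_GRID,
    sd: str = "population",
    denominator: str = "sd",
) -> tuple[SVMModel, np.ndarray, tuple[float, int]]:
    """One model refit on the whole cohort for map back-projection.

    (C*, k*) are chosen by the same LOSO grid search run over all N
    subjects; the model is then fit once on everyone using the top-k*
    Fisher columns computed from everyone.
    """
    C_star, k_star = inner_select(dataset.X, dataset.y, grid, sd=sd,
                                  denominator=denominator)
    fs = fisher_scores(dataset.X, dataset.y, sd=sd, denominator=denominator)
    cols = rank_and_select(fs, k_star)
    model = train_linear_svm(dataset.X[:, cols], dataset.y, C_star,
                             selected_columns=cols)
    return model, cols, (C_star, k_star)
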