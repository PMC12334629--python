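"""Confusion-matrix metrics and the stratified K-fold harness."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = ["ConfusionCounts", "confusion_from_predictions", "compute_metrics",
           "Metrics", "kfold_evaluate"]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.accuracy, self.sensitivity, self.specificity)


def confusion_from_predictions(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Binary confusion counts with class 1 as positive."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy (TP+TN)/all, sensitivity TP/(TP+FN), specificity TN/(TN+FP)."""
    if counts.total == 0:
        raise ValueError("empty evaluation: all confusion counts are zero")
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    if pos == 0:
        raise ValueError("sensitivity undefined: no positive samples")
    if neg == 0:
        raise ValueError("specificity undefined: no negative samples")
    return Metrics(
        accuracy=(counts.tp + counts.tn) / counts.total,
        sensitivity=counts.tp / pos,
        specificity=counts.tn / neg,
    )


def kfold_evaluate(samples: Sequence, labels: Sequence[int], k: int,
                   fit_predict: Callable[[list, np.ndarray, list], np.ndarray],
                   seed: int = 0) -> dict:
    """Stratified K-fold evaluation.

    ``fit_predict(train_samples, train_labels, test_samples)`` must return
    predicted labels for the test samples; any augmentation it applies
    therefore touches the training fold only. Fold assignment is seeded
    and reproducible. Folds are stratified whenever each class has at
    least ``k`` members; beyond that (e.g. leave-one-out) plain shuffled
    folds are used. Returns per-fold metrics plus their mean and sd.
    """
    y = np.asarray(labels, dtype=int)
    if not 2 <= k <= y.size:
        raise ValueError(f"k must be in [2, n_samples], got {k}")
    if k <= np.bincount(y).min():
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics: list[Metrics] = []
    for train_idx, test_idx in splitter.split(np.zeros(y.size), y):
        train = [samples[i] for i in train_idx]
        test = [samples[i] for i in test_idx]
        y_pred = fit_predict(train, y[train_idx], test)
        counts = confusion_from_predictions(y[test_idx], y_pred)
        # leave-one-out folds can miss a class; fall back to plain accuracy
        try:
            fold_metrics.append(compute_metrics(counts))
        except ValueError:
            acc = (counts.tp + counts.tn) / counts.total
            fold_metrics.append(Metrics(acc, float("nan"), float("nan")))
    arr = np.array([m.as_tuple() for m in fold_metrics])
    # leave-one-out can make a whole sensitivity/specificity column NaN
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
        sd = np.nanstd(arr, axis=0)
    return {
        "folds": fold_metrics,
        "mean": Metrics(*mean),
        "sd": Metrics(*sd),
    }
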