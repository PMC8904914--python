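"""Confusion-matrix metrics and group-aware evaluation protocols.

A 16-way (or K-way) recognizer is scored with one-vs-rest accuracy,
sensitivity and specificity per class; headline numbers are the unweighted
(macro) class means, with the micro accuracy (trace / total) reported
alongside.  Splitting utilities are stratified and *group-aware*: noisy
augmented copies of a trial always land on the same side of a split as
their source trial, so augmentation can never leak near-duplicates from
train into test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, train_test_split

from .exceptions import ConfigurationError


def confusion(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K x K count matrix, rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ConfigurationError("label sequences must have equal length")
    if len(y_true) == 0:
        return np.zeros((n_classes, n_classes), dtype=int)
    for arr, name in ((y_true, "true"), (y_pred, "predicted")):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ConfigurationError(f"{name} labels outside [0, {n_classes})")
    return _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))


@dataclass
class MetricReport:
    """Per-class one-vs-rest metrics plus macro and micro summaries.

    Per-class ratios with a zero denominator are NaN and are excluded from
    the macro means.
    """

    per_class_accuracy: np.ndarray
    per_class_sensitivity: np.ndarray
    per_class_specificity: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    micro_accuracy: float
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "macro": {
                "accuracy": self.accuracy,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            },
            "micro_accuracy": self.micro_accuracy,
            "per_class": {
                "accuracy": self.per_class_accuracy.tolist(),
                "sensitivity": self.per_class_sensitivity.tolist(),
                "specificity": self.per_class_specificity.tolist(),
            },
            "n_samples": self.n_samples,
        }


def metrics(cm: np.ndarray) -> MetricReport:
    """One-vs-rest accuracy / sensitivity / specificity from a confusion matrix.

    Per class k: Tp = cm[k,k]; Fn = row_k - Tp; Fp = col_k - Tp;
    Tn = total - Tp - Fn - Fp; then

        accuracy    = (Tp + Tn) / (Tp + Tn + Fp + Fn)
        sensitivity = Tp / (Tp + Fn)
        specificity = Tn / (Tn + Fp)
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or total <= 0:
        raise ConfigurationError("confusion matrix must be square with positive total")
    tp = np.diag(cm)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp

    def _safe(num, den):
        den = np.asarray(den, dtype=float)
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)

    acc = _safe(tp + tn, tp + tn + fp + fn)
    sens = _safe(tp, tp + fn)
    spec = _safe(tn, tn + fp)
    return MetricReport(
        per_class_accuracy=acc,
        per_class_sensitivity=sens,
        per_class_specificity=spec,
        accuracy=float(np.nanmean(acc)),
        sensitivity=float(np.nanmean(sens)),
        specificity=float(np.nanmean(spec)),
        micro_accuracy=float(np.trace(cm) / total),
        n_samples=int(total),
    )


def evaluate_predictions(y_true, y_pred, n_classes: int) -> MetricReport:
    """Convenience: confusion + metrics in one call."""
    return metrics(confusion(y_true, y_pred, n_classes))


# ---------------------------------------------------------------------------
# Splitting protocols
# ---------------------------------------------------------------------------

def _group_table(labels: np.ndarray, groups: np.ndarray):
    """Unique groups with their (single) label; augmented copies inherit
    their source trial's label, so the group label is well defined."""
    uniq = np.unique(groups)
    group_label = np.empty(len(uniq), dtype=int)
    for j, g in enumerate(uniq):
        lab = np.unique(labels[groups == g])
        if len(lab) != 1:
            raise ConfigurationError(f"group {g} carries multiple labels {lab}")
        group_label[j] = lab[0]
    return uniq, group_label


def split_train_percentage(
    labels: np.ndarray,
    pct: float,
    seed: int | None = None,
    groups: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test row indices with ``pct`` percent of groups in train.

    Stratification is per class; when ``groups`` is given the split is made
    over source trials and then expanded to rows, keeping every noisy copy
    with its original.
    """
    labels = np.asarray(labels, dtype=int)
    if not 0 < pct < 100:
        raise ConfigurationError("pct must lie strictly between 0 and 100")
    if groups is None:
        groups = np.arange(len(labels))
    groups = np.asarray(groups, dtype=int)
    uniq, group_label = _group_table(labels, groups)
    counts = np.bincount(group_label)
    if (counts[counts > 0] < 2).any():
        raise ConfigurationError("every class needs >= 2 groups for stratification")
    train_g, test_g = train_test_split(
        uniq,
        train_size=pct / 100.0,
        stratify=group_label,
        random_state=seed,
    )
    train_mask = np.isin(groups, train_g)
    return np.flatnonzero(train_mask), np.flatnonzero(~train_mask)


def kfold(
    labels: np.ndarray,
    n_splits: int,
    seed: int | None = None,
    groups: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified K-fold over groups; every group's rows appear in exactly
    one test fold."""
    labels = np.asarray(labels, dtype=int)
    if n_splits < 2:
        raise ConfigurationError("n_splits must be >= 2")
    if groups is None:
        groups = np.arange(len(labels))
    groups = np.asarray(groups, dtype=int)
    uniq, group_label = _group_table(labels, groups)
    if n_splits > len(uniq):
        raise ConfigurationError(
            f"n_splits={n_splits} exceeds {len(uniq)} distinct groups"
        )
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = []
    for train_j, test_j in skf.split(uniq.reshape(-1, 1), group_label):
        test_mask = np.isin(groups, uniq[test_j])
        folds.append((np.flatnonzero(~test_mask), np.flatnonzero(test_mask)))
    return folds
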