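"""Confusion-matrix metrics, ROC/AUC, stratified splitting and k-fold CV.

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
(TP+TN)/(TP+FN+TN+FP), F1 = 2*precision*recall/(precision+recall).
Metrics are kept at full precision internally; display rounding is a
presentation choice (the literature mixes integer, one- and two-decimal
percent forms, all available here). AUC uses trapezoidal integration
over thresholds, which equals the positive-negative pair concordance
statistic with ties counted half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self):
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """Metric values as percentages in [0, 100]; NaN marks an undefined
    (zero-denominator) metric."""

    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    auc: float = float("nan")

    def rounded(self, decimals: int = 1) -> dict:
        return {k: (round(v, decimals) if np.isfinite(v) else v)
                for k, v in self.__dict__.items()}


def confusion(labels, predictions, positive_class) -> ConfusionCounts:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    pos = labels == positive_class
    pred_pos = predictions == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


def _safe_div(num, den, name):
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)")
        return float("nan")
    return num / den


def metrics_from_confusion(c: ConfusionCounts) -> MetricReport:
    sens = _safe_div(c.tp, c.tp + c.fn, "sensitivity")
    spec = _safe_div(c.tn, c.tn + c.fp, "specificity")
    acc = _safe_div(c.tp + c.tn, c.total, "accuracy")
    prec = _safe_div(c.tp, c.tp + c.fp, "precision")
    if np.isnan(prec) or np.isnan(sens) or (prec + sens) == 0:
        f1 = float("nan")
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricReport(sensitivity=100 * sens, specificity=100 * spec,
                        accuracy=100 * acc, f1=100 * f1)


def roc_auc(scores, labels) -> float:
    """AUC by trapezoidal integration of the ROC curve over all
    thresholds; tied scores contribute half (rank-statistic form)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    # keep only the last point of each tied-score run
    keep = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tps[keep] / n_pos]
    fpr = np.r_[0.0, fps[keep] / n_neg]
    return float(np.trapezoid(tpr, fpr))


def stratified_split(labels, test_fraction: float = 0.2, seed: int = 0):
    """Per-class test counts round(class_size * fraction); reproducible."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        n_test = int(round(idx.size * test_fraction))
        n_test = min(max(n_test, 1), idx.size - 1)
        test_idx.append(rng.permutation(idx)[:n_test])
    test_idx = np.sort(np.concatenate(test_idx))
    train_idx = np.setdiff1d(np.arange(labels.size), test_idx)
    return train_idx, test_idx


@dataclass
class CVReport:
    fold_reports: list
    fold_assignment: np.ndarray
    seed: int
    mean: dict = field(init=False)
    sd: dict = field(init=False)

    def __post_init__(self):
        keys = ("sensitivity", "specificity", "accuracy", "f1", "auc")
        self.mean, self.sd = {}, {}
        for k in keys:
            vals = np.array([getattr(r, k) for r in self.fold_reports])
            vals = vals[np.isfinite(vals)]
            self.mean[k] = float(vals.mean()) if vals.size else float("nan")
            self.sd[k] = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")


def kfold_cv(labels, pipeline, k: int = 5, seed: int = 0) -> CVReport:
    """Stratified k-fold cross-validation.

    ``pipeline(train_idx, test_idx)`` must fit on the training fold only
    (any oversampling included) and return ``(predictions, scores)`` for
    the test fold, with scores the positive-class probability. Labels are
    boolean/int with 1 = positive.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError("every class needs at least k samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.full(y.size, -1)
    reports = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(y.size), y)):
        assignment[te] = fold
        preds, scores = pipeline(tr, te)
        rep = metrics_from_confusion(confusion(y[te], np.asarray(preds), 1))
        rep.auc = roc_auc(scores, y[te]) * 100
        reports.append(rep)
    return CVReport(reports, assignment, seed)


def format_report(rep: MetricReport, decimals: int = 1) -> str:
    rows = rep.rounded(decimals)
    width = max(len(k) for k in rows)
    return "\n".join(f"{k.ljust(width)}  {v:.{decimals}f}%"
                     if np.isfinite(v) else f"{k.ljust(width)}  n/a"
                     for k, v in rows.items())
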