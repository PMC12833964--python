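"""Evaluation utilities: stratified splitting, binary-classification
metrics (rank AUC, accuracy, precision, recall), ROC/confusion outputs and
a proportion-estimate sample-size calculator.

The positive class throughout is "at-risk" (screening score >= 3).  AUC is
the Mann-Whitney rank statistic with ties counted 0.5, identical to the
trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "SplitPlan", "MetricsReport",
    "stratified_split", "compute_metrics", "roc_points", "confusion",
    "rank_auc", "required_sample_size",
]


@dataclass
class SplitPlan:
    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: np.ndarray        # fold id per training-set position
    n_folds: int
    seed: int


@dataclass
class MetricsReport:
    auc: float
    acc: float
    precision: float
    recall: float
    tp: int
    fp: int
    tn: int
    fn: int
    roc: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "acc": self.acc,
            "precision": self.precision, "recall": self.recall,
            "confusion": {"tp": self.tp, "fp": self.fp,
                          "tn": self.tn, "fn": self.fn},
        }


def stratified_split(y: np.ndarray, test_fraction: float = 0.15,
                     n_folds: int = 5, seed: int = 0) -> SplitPlan:
    """85/15 stratified train/test split plus a stratified k-fold plan on
    the training part.  Class proportions in the test set match the global
    proportions within one sample per class."""
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed)
    train_idx = np.sort(train_idx)
    test_idx = np.sort(test_idx)
    folds = np.empty(len(train_idx), dtype=int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for f, (_, val_pos) in enumerate(skf.split(train_idx, y[train_idx])):
        folds[val_pos] = f
    return SplitPlan(train_idx, test_idx, folds, n_folds, seed)


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank statistic; tied scores count 0.5."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = stats.rankdata(scores)  # average ranks handle ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confusion(scores: np.ndarray, labels: np.ndarray,
              threshold: float = 0.5) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) at the given decision threshold (score >= t -> 1)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    return tp, fp, tn, fn


def roc_points(scores: np.ndarray, labels: np.ndarray) -> list[tuple[float, float]]:
    """(FPR, TPR) at every distinct threshold, from (0,0) to (1,1).

    The trapezoidal area under these points equals the rank AUC.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined with a single class")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    l = labels[order]
    tps = np.cumsum(l)
    fps = np.cumsum(1 - l)
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    pts = [(0.0, 0.0)]
    pts += [(fps[i] / n_neg, tps[i] / n_pos) for i in distinct]
    return pts


def compute_metrics(scores: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> MetricsReport:
    """Full metric bundle: rank AUC plus thresholded ACC/precision/recall.

    Precision is 0 by convention when nothing is predicted positive.
    """
    tp, fp, tn, fn = confusion(scores, labels, threshold)
    n = tp + fp + tn + fn
    acc = (tp + tn) / n
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return MetricsReport(
        auc=rank_auc(scores, labels), acc=acc,
        precision=precision, recall=recall,
        tp=tp, fp=fp, tn=tn, fn=fn,
        roc=roc_points(scores, labels),
    )


def required_sample_size(prevalence: float, conf_level: float = 0.95,
                         half_width: float = 0.05) -> int:
    """Sample size for estimating a proportion to a given precision.

    ceil(z^2 p (1 - p) / d^2) with z the two-sided normal quantile of the
    confidence level and d the half-width of the confidence interval (a
    "10% interval width" corresponds to d = 0.05).  At p = 0.5, 95%
    confidence and d = 0.05 this gives the classic 385.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    if not 0.0 < half_width < 1.0:
        raise ValueError("half_width must lie in (0, 1)")
    if not 0.0 < conf_level < 1.0:
        raise ValueError("conf_level must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - (1.0 - conf_level) / 2.0)
    return int(np.ceil(z**2 * prevalence * (1.0 - prevalence) / half_width**2))
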