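"""Evaluation harness: confusion counts, the four headline metrics, ROC/AUC,
and multi-run mean +/- SD summaries.

Senescent is the positive class throughout. With TP/TN/FP/FN the usual
four-cell counts:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 TP / (2 TP + FP + FN)   (harmonic mean of precision, recall)

AUC is the area under the ROC curve (trapezoidal rule over the threshold
sweep), equivalent to the pairwise concordance probability. To decouple
results from single-training luck, experiments repeat the full training
nine times and report per-metric mean and standard deviation across runs,
plus the maximum AUC.

Degenerate denominators (e.g. precision with no predicted positives) are
reported as NaN rather than silently coerced to 0, so summaries cannot be
inflated by empty cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import Label


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}

    def as_percent(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in self.as_dict().items()}


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class RunSummary:
    """Mean and SD of each metric over repeated training runs; max AUC."""

    runs: list[MetricSet]
    aucs: list[float] = field(default_factory=list)

    @property
    def mean(self) -> MetricSet:
        return MetricSet(*(float(np.nanmean([getattr(r, k) for r in self.runs]))
                           for k in ("accuracy", "precision", "recall", "f1")))

    @property
    def sd(self) -> MetricSet:
        # population SD over the runs (n denominator)
        return MetricSet(*(float(np.nanstd([getattr(r, k) for r in self.runs]))
                           for k in ("accuracy", "precision", "recall", "f1")))

    @property
    def max_auc(self) -> float:
        return float(np.nanmax(self.aucs)) if self.aucs else float("nan")


def _to_binary(labels: Sequence) -> np.ndarray:
    out = []
    for v in labels:
        if isinstance(v, Label):
            out.append(1 if v is Label.SENESCENT else 0)
        else:
            out.append(int(v))
    return np.asarray(out)


def confusion_counts(pred: Sequence, truth: Sequence) -> ConfusionCounts:
    """Four-cell confusion counts, senescent positive."""
    p = _to_binary(pred)
    t = _to_binary(truth)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("pred and truth must be equal-length and non-empty")
    return ConfusionCounts(
        tp=int(np.sum((p == 1) & (t == 1))),
        tn=int(np.sum((p == 0) & (t == 0))),
        fp=int(np.sum((p == 1) & (t == 0))),
        fn=int(np.sum((p == 0) & (t == 1))),
    )


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, recall, F1 from confusion counts.

    Zero-denominator cells give NaN (undefined), never 0.
    """
    if c.total == 0:
        raise ValueError("no evaluated images")
    acc = (c.tp + c.tn) / c.total
    prec = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else float("nan")
    rec = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    f1 = 2 * c.tp / (2 * c.tp + c.fp + c.fn) if (2 * c.tp + c.fp + c.fn) else float("nan")
    return MetricSet(acc, prec, rec, f1)


def roc_curve(probs: Sequence[float], truth: Sequence) -> ROCCurve:
    """ROC curve over all decision thresholds, with trapezoidal AUC.

    Thresholds sweep the unique predicted probabilities plus +inf; an image
    is called senescent when its probability is >= the threshold. Raises on
    single-class truth (the curve is undefined there).
    """
    p = np.asarray(probs, dtype=float)
    t = _to_binary(truth)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("probs and truth must be equal-length and non-empty")
    n_pos = int(t.sum())
    n_neg = int(t.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC/AUC undefined with a single-class truth")
    thresholds = np.concatenate([[np.inf], np.unique(p)[::-1]])
    fpr = np.empty(len(thresholds))
    tpr = np.empty(len(thresholds))
    for i, th in enumerate(thresholds):
        call = p >= th
        tpr[i] = np.sum(call & (t == 1)) / n_pos
        fpr[i] = np.sum(call & (t == 0)) / n_neg
    order = np.lexsort((tpr, fpr))
    fpr, tpr, thresholds = fpr[order], tpr[order], thresholds[order]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr, tpr, thresholds, auc)


def summarize_runs(metric_sets: Sequence[MetricSet], aucs: Sequence[float] = ()) -> RunSummary:
    """Mean/SD per metric over runs plus the maximum AUC across runs."""
    if len(metric_sets) == 0:
        raise ValueError("need at least one run")
    return RunSummary(list(metric_sets), list(aucs))
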