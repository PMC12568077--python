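"""Classification evaluation: confusion matrices, accuracy / precision /
recall / F1, Wilson score intervals, and gait-mask reports.

The four metrics are the standard one-vs-rest ratios
accuracy = (TP+TN)/(TP+TN+FP+FN), precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN). Confidence intervals on each
ratio use the Wilson score method. Rounding happens only at presentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from statsmodels.stats.proportion import proportion_confint

from .containers import GaitMask


@dataclass
class ConfusionMatrix:
    """K x K counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts shape {self.counts.shape} != ({k}, {k})")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def _idx(self, cls) -> int:
        return self.classes.index(cls)

    def one_vs_rest(self, positive_class):
        """(TP, TN, FP, FN) treating ``positive_class`` against the rest."""
        i = self._idx(positive_class)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn

    # Binary-mask convenience accessors (classes ordered (False, True)).
    @property
    def tp(self) -> int:
        return self.one_vs_rest(self.classes[-1])[0]

    @property
    def tn(self) -> int:
        return self.one_vs_rest(self.classes[-1])[1]

    @property
    def fp(self) -> int:
        return self.one_vs_rest(self.classes[-1])[2]

    @property
    def fn(self) -> int:
        return self.one_vs_rest(self.classes[-1])[3]


@dataclass
class MetricsReport:
    """The four metrics with optional Wilson intervals and support ``n``."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    n: int
    intervals: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {"n": self.n, "accuracy": self.accuracy, "precision": self.precision,
               "recall": self.recall, "f1": self.f1}
        for name, (lo, hi) in self.intervals.items():
            row[f"{name}_ci_lo"] = lo
            row[f"{name}_ci_hi"] = hi
        return row


def confusion(true_labels, pred_labels, classes=None) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if len(true_labels) != len(pred_labels):
        raise ValueError("label vectors must have equal length")
    if classes is None:
        classes = tuple(sorted(set(true_labels) | set(pred_labels), key=str))
    counts = _sk_confusion(true_labels, pred_labels, labels=list(classes))
    return ConfusionMatrix(counts, tuple(classes))


def _ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def wilson_interval(successes: int, n: int, confidence: float = 0.95):
    """Two-sided Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - confidence,
                                method="wilson")
    # the closed form is exactly 0/1 at the k=0 and k=n boundaries; guard
    # round-off so the interval always contains the point estimate
    lo = 0.0 if successes == 0 else float(min(max(lo, 0.0), 1.0))
    hi = 1.0 if successes == n else float(min(max(hi, 0.0), 1.0))
    return lo, hi


def classification_metrics(
    cm: ConfusionMatrix,
    positive_class,
    with_intervals: bool = False,
    confidence: float = 0.95,
) -> MetricsReport:
    """One-vs-rest metrics for ``positive_class`` from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    tp, tn, fp, fn = cm.one_vs_rest(positive_class)
    report = MetricsReport(
        accuracy=_ratio(tp + tn, tp + tn + fp + fn, "accuracy"),
        precision=_ratio(tp, tp + fp, "precision"),
        recall=_ratio(tp, tp + fn, "recall"),
        f1=_ratio(2 * tp, 2 * tp + fp + fn, "F1"),
        n=cm.total,
    )
    if with_intervals:
        pairs = {"accuracy": (tp + tn, cm.total), "precision": (tp, tp + fp),
                 "recall": (tp, tp + fn)}
        for name, (k, n) in pairs.items():
            if n > 0:
                report.intervals[name] = wilson_interval(k, n, confidence)
    return report


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def mask_report(
    truth: GaitMask,
    pred: GaitMask,
    valid: np.ndarray | None = None,
    with_intervals: bool = False,
) -> MetricsReport:
    """Per-sample binary metrics of a predicted mask against truth,
    restricted to ``valid`` (labeled) samples."""
    if truth.n_samples != pred.n_samples:
        raise ValueError("masks must have equal length")
    t = truth.is_walking
    p = pred.is_walking
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        t, p = t[valid], p[valid]
    if len(t) == 0:
        raise ValueError("no valid samples to evaluate")
    cm = confusion(t, p, classes=(False, True))
    return classification_metrics(cm, True, with_intervals=with_intervals)


def per_class_report(cm: ConfusionMatrix, with_intervals: bool = True) -> pd.DataFrame:
    """One row per class of one-vs-rest metrics (per-activity table layout)."""
    rows = []
    for cls in cm.classes:
        rep = classification_metrics(cm, cls, with_intervals=with_intervals)
        row = {"class": cls, "support": int(cm.counts[cm._idx(cls)].sum())}
        row.update(rep.to_row())
        rows.append(row)
    return pd.DataFrame(rows)


def median_report(reports: list) -> MetricsReport:
    """Median of each metric across participants (test-set aggregation)."""
    if not reports:
        raise ValueError("no reports to aggregate")
    return MetricsReport(
        accuracy=float(np.nanmedian([r.accuracy for r in reports])),
        precision=float(np.nanmedian([r.precision for r in reports])),
        recall=float(np.nanmedian([r.recall for r in reports])),
        f1=float(np.nanmedian([r.f1 for r in reports])),
        n=int(sum(r.n for r in reports)),
    )
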