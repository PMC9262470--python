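"""Two-class evaluation reports: confusion matrices, percent metrics, curves.

Conventions: rows of the confusion matrix are true classes, columns
predicted, in a fixed class order (default ``("cancer", "noncancer")``).
Metrics are percentages; the "average" row is the unweighted (macro)
mean of the per-class columns computed from UNROUNDED values, and
half-up rounding to two decimals happens only at display time.  The
accuracy column repeats the overall accuracy on every class row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "SplitReport",
    "confusion",
    "metrics_from_confusion",
    "f_from_pr",
    "roc_points",
    "pr_points",
    "round_half_up",
]

DEFAULT_CLASS_ORDER = ("cancer", "noncancer")


def round_half_up(value: float, decimals: int = 2) -> float:
    """Display rounding: half-up (92.305 -> 92.31), unlike banker's rounding."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_order: tuple[str, str] = DEFAULT_CLASS_ORDER

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (2, 2):
            raise ValueError(f"expected a 2x2 matrix, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(
    true_labels: Sequence,
    predicted_labels: Sequence,
    class_order: tuple[str, str] = DEFAULT_CLASS_ORDER,
) -> ConfusionMatrix:
    """Count (true, predicted) pairs over the two known classes."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) == 0:
        raise ValueError("empty label sequences")
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((2, 2), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in ({t!r}, {p!r}); expected {class_order}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=class_order)


@dataclass(frozen=True)
class ClassMetrics:
    """Percent metrics per class plus unweighted macro averages.

    All values are unrounded; use :meth:`rounded` or :meth:`to_rows` for
    the 2-decimal display form.  ``zero_division_flags`` lists the
    (class, metric) pairs reported as 0 because of an empty denominator.
    """

    class_order: tuple[str, str]
    accuracy: float
    precision: tuple[float, float]
    recall: tuple[float, float]
    f_score: tuple[float, float]
    zero_division_flags: tuple[tuple[str, str], ...] = ()

    @property
    def average_precision(self) -> float:
        return float(np.mean(self.precision))

    @property
    def average_recall(self) -> float:
        return float(np.mean(self.recall))

    @property
    def average_f_score(self) -> float:
        return float(np.mean(self.f_score))

    def rounded(self) -> dict:
        r = round_half_up
        return {
            "accuracy": r(self.accuracy),
            "precision": tuple(r(p) for p in self.precision),
            "recall": tuple(r(x) for x in self.recall),
            "f_score": tuple(r(x) for x in self.f_score),
            "average": (
                r(self.accuracy),
                r(self.average_precision),
                r(self.average_recall),
                r(self.average_f_score),
            ),
        }

    def to_rows(self) -> list[list]:
        """Rows (label, accuracy, precision, recall, f-score), then Average."""
        r = round_half_up
        rows = [
            [
                label,
                r(self.accuracy),
                r(self.precision[k]),
                r(self.recall[k]),
                r(self.f_score[k]),
            ]
            for k, label in enumerate(self.class_order)
        ]
        rows.append(
            [
                "Average",
                r(self.accuracy),
                r(self.average_precision),
                r(self.average_recall),
                r(self.average_f_score),
            ]
        )
        return rows


def _safe_ratio(num: float, den: float, flags: list, cls: str, metric: str) -> float:
    if den == 0:
        flags.append((cls, metric))
        return 0.0
    return 100.0 * num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> ClassMetrics:
    """Percent precision/recall/F per class, overall accuracy, macro averages."""
    counts = cm.counts
    if counts.sum() == 0:
        raise ValueError("confusion matrix is empty")
    flags: list[tuple[str, str]] = []
    precision, recall, f_score = [], [], []
    for k, cls in enumerate(cm.class_order):
        tp = counts[k, k]
        fp = counts[1 - k, k]
        fn = counts[k, 1 - k]
        p = _safe_ratio(tp, tp + fp, flags, cls, "precision")
        r = _safe_ratio(tp, tp + fn, flags, cls, "recall")
        if p + r == 0:
            flags.append((cls, "f_score"))
            f = 0.0
        else:
            f = 2.0 * p * r / (p + r)
        precision.append(p)
        recall.append(r)
        f_score.append(f)
    accuracy = 100.0 * counts.trace() / counts.sum()
    return ClassMetrics(
        class_order=cm.class_order,
        accuracy=float(accuracy),
        precision=(precision[0], precision[1]),
        recall=(recall[0], recall[1]),
        f_score=(f_score[0], f_score[1]),
        zero_division_flags=tuple(flags),
    )


def f_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of percent precision and recall (F-score, percent)."""
    if precision == 0 and recall == 0:
        return 0.0
    if precision < 0 or recall < 0:
        raise ValueError("precision/recall must be non-negative")
    return 2.0 * precision * recall / (precision + recall)


def _check_scores(scores, true_labels, positive_class):
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if t == positive_class else 0 for t in true_labels])
    if np.unique(y).size < 2:
        raise ValueError("both classes must appear in the true labels")
    return scores, y


def roc_points(
    scores: Sequence[float],
    true_labels: Sequence,
    positive_class: str = DEFAULT_CLASS_ORDER[0],
) -> list[tuple[float, float]]:
    """(FPR, TPR) over a descending threshold sweep; (0,0) to (1,1)."""
    scores, y = _check_scores(scores, true_labels, positive_class)
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist()))


def pr_points(
    scores: Sequence[float],
    true_labels: Sequence,
    positive_class: str = DEFAULT_CLASS_ORDER[0],
) -> list[tuple[float, float]]:
    """(recall, precision) over a descending threshold sweep."""
    scores, y = _check_scores(scores, true_labels, positive_class)
    precision, recall, _ = precision_recall_curve(y, scores)
    return list(zip(recall.tolist(), precision.tolist()))


@dataclass
class SplitReport:
    """Everything reported for one train/test split ratio."""

    split_label: str
    confusion_matrix: ConfusionMatrix
    metrics: ClassMetrics
    roc: list[tuple[float, float]] = field(default_factory=list)
    pr: list[tuple[float, float]] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["class", "accuracy", "precision", "recall", "f_score"])
            writer.writerows(self.metrics.to_rows())

    def to_json_dict(self) -> dict:
        return {
            "split": self.split_label,
            "confusion": self.confusion_matrix.counts.tolist(),
            "class_order": list(self.confusion_matrix.class_order),
            "metrics": self.metrics.rounded(),
            "roc": self.roc,
            "pr": self.pr,
            **self.extra,
        }
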