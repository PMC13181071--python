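"""Screening metrics, ROC-AUC, and decision-threshold optimization.

Conventions: labels are 0 = No_DR, 1 = DR; the decision rule is inclusive
(predict DR iff score ≥ τ); the confusion matrix follows the row layout
``[[TN, FP], [FN, TP]]`` (rows = true class, columns = predicted class);
all metrics are reported as percentages in [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidInputError
from .fusion import FusedScores

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "ThresholdResult",
    "apply_threshold",
    "confusion",
    "metrics_from_confusion",
    "roc_auc",
    "optimize_threshold",
]

OBJECTIVES = ("f1", "balanced_accuracy", "accuracy")


def _as_scores(scores) -> np.ndarray:
    if isinstance(scores, FusedScores):
        return scores.scores
    return np.asarray(scores, dtype=float)


def _as_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.ndim != 1 or y.size == 0:
        raise InvalidInputError("labels must be a non-empty vector")
    if not np.isin(y, (0, 1)).all():
        raise InvalidInputError("labels must be 0 (No_DR) or 1 (DR)")
    return y.astype(int)


@dataclass(frozen=True)
class ConfusionMatrix:
    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self):
        for name in ("tn", "fp", "fn", "tp"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise InvalidInputError("confusion counts must be nonnegative integers")
            object.__setattr__(self, name, int(v))
        if self.total < 1:
            raise InvalidInputError("confusion matrix must count at least one sample")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def to_array(self) -> np.ndarray:
        """Row convention [[TN, FP], [FN, TP]]."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])

    @classmethod
    def from_array(cls, arr) -> "ConfusionMatrix":
        a = np.asarray(arr)
        if a.shape != (2, 2):
            raise InvalidInputError("expected a 2x2 matrix [[TN, FP], [FN, TP]]")
        return cls(tn=a[0, 0], fp=a[0, 1], fn=a[1, 0], tp=a[1, 1])


@dataclass(frozen=True)
class MetricReport:
    """Screening metrics as percentages; ``auc`` may be absent."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    balanced_accuracy: float
    auc: float = None

    def as_dict(self, ndigits: int = None) -> dict:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "balanced_accuracy": self.balanced_accuracy,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        if ndigits is not None:
            d = {k: round(v, ndigits) for k, v in d.items()}
        return d


@dataclass(frozen=True)
class ThresholdResult:
    """Grid-search result: smallest τ attaining the maximal objective."""

    tau_star: float
    objective: str
    best_value: float
    curve: tuple  # ((tau, objective value), ...)


def apply_threshold(fused, tau: float) -> np.ndarray:
    """Binarize fused scores: predict DR (1) iff score ≥ τ (inclusive)."""
    if not 0.0 <= tau <= 1.0:
        raise InvalidInputError("tau must lie in [0, 1]")
    return (_as_scores(fused) >= tau).astype(int)


def confusion(labels, preds) -> ConfusionMatrix:
    """Cross-tabulate true labels against binary predictions."""
    y = _as_labels(labels)
    p = np.asarray(preds)
    if p.shape != y.shape:
        raise InvalidInputError("labels and predictions differ in length")
    p = p.astype(int)
    return ConfusionMatrix(
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
        tp=int(np.sum((y == 1) & (p == 1))),
    )


def metrics_from_confusion(cm: ConfusionMatrix, auc: float = None) -> MetricReport:
    """Accuracy, precision, recall, specificity, F1 and balanced accuracy (%).

    Zero-denominator convention: precision = 0 when no positive predictions,
    recall = 0 when no positive labels, F1 = 0 when precision + recall = 0 —
    so a degenerate all-negative predictor reports 0.00 rather than NaN.
    """
    total = cm.total
    accuracy = (cm.tp + cm.tn) / total
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0.0
    specificity = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else 0.0
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return MetricReport(
        accuracy=100.0 * accuracy,
        precision=100.0 * precision,
        recall=100.0 * recall,
        specificity=100.0 * specificity,
        f1=100.0 * f1,
        balanced_accuracy=100.0 * (recall + specificity) / 2.0,
        auc=auc,
    )


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve as a percentage.

    Computed as the Mann–Whitney U statistic with midrank tie handling,
    U / (n_pos · n_neg), which equals the trapezoidal area under the ROC
    curve swept over all score thresholds.
    """
    y = _as_labels(labels)
    s = _as_scores(scores)
    if s.shape != y.shape:
        raise InvalidInputError("labels and scores differ in length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError("ROC-AUC needs both classes present")
    ranks = stats.rankdata(s, method="average")
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return 100.0 * u / (n_pos * n_neg)


def _objective_value(cm: ConfusionMatrix, objective: str) -> float:
    report = metrics_from_confusion(cm)
    if objective not in OBJECTIVES:
        raise InvalidInputError(f"unknown objective {objective!r}")
    return getattr(report, objective)


def optimize_threshold(
    labels, scores, objective: str = "f1", step: float = 0.01
) -> ThresholdResult:
    """Sweep τ over the grid {0, step, 2·step, ..., 1} and maximize the objective.

    Returns the smallest grid point attaining the maximum (tie-break favors
    recall, the screening priority) along with the full (τ, value) curve.
    """
    if not 0.0 < step <= 1.0:
        raise InvalidInputError("step must lie in (0, 1]")
    y = _as_labels(labels)
    s = _as_scores(scores)
    if s.shape != y.shape:
        raise InvalidInputError("labels and scores differ in length")
    if y.min() == y.max():
        raise InvalidInputError("threshold optimization needs both classes present")

    grid = np.arange(0.0, 1.0 + step * 0.5, step)
    grid = np.round(grid, 12)
    if grid[-1] < 1.0:
        grid = np.append(grid, 1.0)

    curve = []
    best_tau, best_val = grid[0], -np.inf
    for tau in grid:
        cm = confusion(y, apply_threshold(s, tau))
        val = _objective_value(cm, objective)
        curve.append((float(tau), float(val)))
        if val > best_val + 1e-12:
            best_tau, best_val = float(tau), float(val)
    return ThresholdResult(best_tau, objective, best_val, tuple(curve))
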