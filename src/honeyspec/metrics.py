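"""Confusion matrices and the per-class metric suite.

Multiclass predictions are reduced one-vs-rest to (TP, FP, FN, TN) per
class, from which

    precision   = 100 * TP / (TP + FP)
    recall      = 100 * TP / (TP + FN)
    specificity = 100 * TN / (TN + FP)
    F1          = 2 * P * Re / (P + Re)

are computed, plus the unweighted macro average across classes and the
overall accuracy 100 * trace / total.  A zero denominator yields 0 with
a degeneracy flag rather than an error, so empty predicted classes do
not abort reports.

Report values are rounded to one decimal with half-away-from-zero (the
convention of printed bench reports); the underlying table keeps full
precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, LabelError
from .classify import PredictionSet


def round_report(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix; cell (i, j) = true class i predicted as j."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        n = len(self.classes)
        if c.shape != (n, n):
            raise DomainError("confusion matrix must be square over the class order")
        if np.any(c < 0):
            raise DomainError("confusion counts must be >= 0")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "classes", tuple(str(k) for k in self.classes))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="true\\pred")


class OneVsRestCounts(NamedTuple):
    tp: int
    fp: int
    fn: int
    tn: int


def confusion_matrix(
    predictions: PredictionSet | tuple, class_order: Sequence[str]
) -> ConfusionMatrix:
    """Tally a prediction set into a confusion matrix with fixed class order."""
    if isinstance(predictions, PredictionSet):
        y_true, y_pred = predictions.y_true, predictions.y_pred
    else:
        y_true, y_pred = predictions
    classes = [str(k) for k in class_order]
    index = {k: i for i, k in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        t, p = str(t), str(p)
        if t not in index or p not in index:
            raise LabelError(f"label '{t if t not in index else p}' not in class order")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=tuple(classes))


def one_vs_rest_counts(cm: ConfusionMatrix, cls: str) -> OneVsRestCounts:
    """Reduce the multiclass matrix to binary counts for one class."""
    if cls not in cm.classes:
        raise LabelError(f"class '{cls}' not in class order")
    i = cm.classes.index(cls)
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[:, i].sum()) - tp
    fn = int(cm.counts[i, :].sum()) - tp
    tn = cm.total - tp - fp - fn
    return OneVsRestCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def class_metrics(counts: OneVsRestCounts) -> tuple[float, float, float, bool]:
    """(precision %, recall %, specificity %, degenerate flag)."""
    if min(counts) < 0:
        raise DomainError("counts must be >= 0")
    degenerate = False

    def _ratio(num, den):
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return 100.0 * num / den

    precision = _ratio(counts.tp, counts.tp + counts.fp)
    recall = _ratio(counts.tp, counts.tp + counts.fn)
    specificity = _ratio(counts.tn, counts.tn + counts.fp)
    return precision, recall, specificity, degenerate


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (percent in, percent out)."""
    for v in (precision, recall):
        if not 0.0 <= v <= 100.0:
            raise DomainError(f"metric {v} outside [0, 100]")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """100 * correct predictions / total predictions."""
    if cm.total == 0:
        raise DomainError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def macro_average(per_class_values: Sequence[float]) -> float:
    """Unweighted arithmetic mean of a per-class metric."""
    values = list(per_class_values)
    if not values:
        raise DomainError("need at least one class")
    return float(np.mean(values))


@dataclass(frozen=True)
class MetricsTable:
    """Per-class metrics plus macro averages and overall accuracy (all %)."""

    per_class: pd.DataFrame  # index: class; columns precision/recall/specificity/f1/degenerate
    accuracy: float

    @property
    def macro(self) -> pd.Series:
        return self.per_class[["precision", "recall", "specificity", "f1"]].mean()

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        """Per-class rows plus an Average row, optionally report-rounded."""
        body = self.per_class[["precision", "recall", "specificity", "f1"]].copy()
        body.loc["Average"] = self.macro
        if rounded:
            body = body.map(round_report)
        return body

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="class")

    def to_json(self, path=None):
        payload = {
            "per_class": {
                k: {m: float(v) for m, v in row.items()}
                for k, row in self.per_class.drop(columns="degenerate").iterrows()
            },
            "macro": {m: float(v) for m, v in self.macro.items()},
            "accuracy": float(self.accuracy),
        }
        if path is None:
            return payload
        with open(path, "w") as f:
            json.dump(payload, f, indent=2, sort_keys=True)
        return payload


def metrics_table(cm: ConfusionMatrix) -> MetricsTable:
    """Full metric suite from a confusion matrix."""
    rows = {}
    for cls in cm.classes:
        p, r, s, degenerate = class_metrics(one_vs_rest_counts(cm, cls))
        rows[cls] = {
            "precision": p,
            "recall": r,
            "specificity": s,
            "f1": f1_score(p, r),
            "degenerate": degenerate,
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index").loc[list(cm.classes)]
    return MetricsTable(per_class=per_class, accuracy=overall_accuracy(cm))
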