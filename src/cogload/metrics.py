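"""Confusion-matrix bookkeeping and the imbalance-aware metric suite.

The evaluation problem here is a class-imbalanced one (in the reference
cohort 178 of 721 windows carry the hardest task), so plain accuracy is
reported alongside balanced accuracy (BACC), Matthews correlation
coefficient (MCC) and the F1 score, which carry the burden of imbalance.

Multiclass confusion matrices are stored with rows = predicted class and
columns = actual class; one-vs-rest reduction turns the K×K matrix into K
binary TP/FP/FN/TN tuples that conserve the total count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "compute_metrics",
    "ovr_counts",
    "evaluate_multiclass_ovr",
    "confusion_from_predictions",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts. All counts are non-negative integers."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"confusion count {f.name!r} must be >= 0, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """PRE/SEN/SPE/ACC/BACC/F1/MCC for one binary problem.

    Members whose defining ratio has a zero denominator are ``None``
    (flagged undefined) rather than NaN so they serialize cleanly.
    """

    counts: ConfusionCounts
    pre: float | None = field(init=False)
    sen: float | None = field(init=False)
    spe: float | None = field(init=False)
    acc: float | None = field(init=False)
    bacc: float | None = field(init=False)
    f1: float | None = field(init=False)
    mcc: float | None = field(init=False)

    def __post_init__(self) -> None:
        tp, fp, fn, tn = self.counts.tp, self.counts.fp, self.counts.fn, self.counts.tn

        def ratio(num: float, den: float) -> float | None:
            return num / den if den > 0 else None

        object.__setattr__(self, "pre", ratio(tp, tp + fp))
        object.__setattr__(self, "sen", ratio(tp, tp + fn))
        object.__setattr__(self, "spe", ratio(tn, tn + fp))
        object.__setattr__(self, "acc", ratio(tp + tn, self.counts.total))
        bacc = None
        if self.sen is not None and self.spe is not None:
            bacc = (self.sen + self.spe) / 2.0
        object.__setattr__(self, "bacc", bacc)
        object.__setattr__(self, "f1", ratio(2 * tp, 2 * tp + fp + fn))
        den = math.sqrt(
            float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
        )
        mcc = (tp * tn - fp * fn) / den if den > 0 else None
        object.__setattr__(self, "mcc", mcc)

    def as_dict(self, ndigits: int | None = None) -> dict[str, float | None]:
        out: dict[str, float | None] = {
            "TP": self.counts.tp,
            "FP": self.counts.fp,
            "FN": self.counts.fn,
            "TN": self.counts.tn,
        }
        for name in ("pre", "sen", "spe", "acc", "bacc", "f1", "mcc"):
            v = getattr(self, name)
            if v is not None and ndigits is not None:
                v = round_half_up(v, ndigits)
            out[name.upper()] = v
        return out


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Compute the full metric suite from binary confusion counts.

    PRE = TP/(TP+FP), SEN = TP/(TP+FN), SPE = TN/(TN+FP),
    ACC = (TP+TN)/total, BACC = (SEN+SPE)/2, F1 = 2TP/(2TP+FP+FN),
    MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    return MetricsReport(counts)


def _check_square(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"confusion matrix must be square, got shape {m.shape}")
    if (m < 0).any():
        raise ValueError("confusion matrix entries must be >= 0")
    return m


def ovr_counts(matrix: np.ndarray, class_index: int) -> ConfusionCounts:
    """One-vs-rest reduction of a K×K matrix (rows predicted, cols actual)."""
    m = _check_square(matrix)
    k = class_index
    tp = int(m[k, k])
    fp = int(m[k, :].sum() - m[k, k])  # predicted k, actually other
    fn = int(m[:, k].sum() - m[k, k])  # actually k, predicted other
    tn = int(m.sum() - tp - fp - fn)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def evaluate_multiclass_ovr(
    matrix: np.ndarray, class_names: list[str] | None = None
) -> dict[str, MetricsReport]:
    """Per-class metric suite via one-vs-rest reduction of a K×K matrix."""
    m = _check_square(matrix)
    names = class_names if class_names is not None else [str(i) for i in range(m.shape[0])]
    if len(names) != m.shape[0]:
        raise ValueError("class_names length must match matrix size")
    return {name: compute_metrics(ovr_counts(m, i)) for i, name in enumerate(names)}


def confusion_from_predictions(
    y_true, y_pred, class_order: list | None = None
) -> tuple[np.ndarray, list]:
    """K×K confusion matrix, rows = predicted, columns = actual."""
    from sklearn.metrics import confusion_matrix

    labels = class_order if class_order is not None else sorted(set(y_true) | set(y_pred))
    m = confusion_matrix(y_true, y_pred, labels=labels)
    # sklearn rows are actual; transpose to the predicted-by-actual layout
    return m.T, list(labels)
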