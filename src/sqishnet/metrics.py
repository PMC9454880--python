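"""Confusion-matrix statistics for the binary classifier.

Positive class defaults to malignant (= 1).  Precision = TP/(TP+FP),
recall = TP/(TP+FN), accuracy = (TP+TN)/total.  The classification report
computes each class's precision/recall treating that class as positive and
summarizes with the unweighted (macro) mean of the two.

A statistic with a zero denominator is reported as the explicit
:data:`UNDEFINED` marker, never silently as zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "UNDEFINED",
    "ConfusionMatrix",
    "confusion",
    "precision",
    "recall",
    "accuracy",
    "classification_report",
    "ClassificationReport",
]


class _Undefined:
    """Marker for a statistic whose denominator is zero."""

    def __repr__(self) -> str:
        return "undefined"

    def __eq__(self, other) -> bool:
        return isinstance(other, _Undefined)

    def __hash__(self) -> int:
        return hash("sqishnet-undefined")


UNDEFINED = _Undefined()


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts; positive class = malignant by convention."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def swapped(self) -> "ConfusionMatrix":
        """Counts with the positive class exchanged (TP<->TN, FP<->FN)."""
        return ConfusionMatrix(TP=self.TN, FP=self.FN, FN=self.FP, TN=self.TP)


def confusion(predicted, true, positive_class: int = 1) -> ConfusionMatrix:
    predicted = np.asarray(predicted, dtype=int)
    true = np.asarray(true, dtype=int)
    if predicted.shape != true.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape} predictions vs "
            f"{true.shape} truths"
        )
    p = predicted == positive_class
    t = true == positive_class
    return ConfusionMatrix(
        TP=int(np.sum(p & t)),
        FP=int(np.sum(p & ~t)),
        FN=int(np.sum(~p & t)),
        TN=int(np.sum(~p & ~t)),
    )


def _ratio(num: int, den: int):
    return UNDEFINED if den == 0 else num / den


def precision(cm: ConfusionMatrix):
    return _ratio(cm.TP, cm.TP + cm.FP)


def recall(cm: ConfusionMatrix):
    return _ratio(cm.TP, cm.TP + cm.FN)


def accuracy(cm: ConfusionMatrix):
    return _ratio(cm.TP + cm.TN, cm.total)


@dataclass(frozen=True)
class ClassificationReport:
    """Per-class precision/recall with macro (unweighted-mean) summary."""

    per_class: dict      # class -> {"precision": .., "recall": .., "support": n}
    macro_precision: object
    macro_recall: object
    accuracy: object
    matrix: ConfusionMatrix

    def to_text(self) -> str:
        lines = [f"{'class':>10} {'precision':>10} {'recall':>10} {'support':>8}"]
        for c in sorted(self.per_class):
            e = self.per_class[c]
            lines.append(
                f"{c:>10} {_fmt(e['precision']):>10} "
                f"{_fmt(e['recall']):>10} {e['support']:>8}"
            )
        lines.append(
            f"{'macro':>10} {_fmt(self.macro_precision):>10} "
            f"{_fmt(self.macro_recall):>10} {self.matrix.total:>8}"
        )
        lines.append(f"accuracy: {_fmt(self.accuracy)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def val(v):
            return None if v is UNDEFINED else v
        return {
            "per_class": {
                str(c): {k: val(v) for k, v in e.items()}
                for c, e in self.per_class.items()
            },
            "macro_precision": val(self.macro_precision),
            "macro_recall": val(self.macro_recall),
            "accuracy": val(self.accuracy),
            "confusion": {"TP": self.matrix.TP, "FP": self.matrix.FP,
                          "FN": self.matrix.FN, "TN": self.matrix.TN},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _fmt(v) -> str:
    return "undef" if v is UNDEFINED else f"{v:.4f}"


def _macro(values):
    if any(v is UNDEFINED for v in values):
        return UNDEFINED
    return float(np.mean(values))


def classification_report(predicted, true,
                          positive_class: int = 1) -> ClassificationReport:
    cm = confusion(predicted, true, positive_class)
    neg = cm.swapped()
    per_class = {
        0: {"precision": precision(neg), "recall": recall(neg),
            "support": neg.TP + neg.FN},
        1: {"precision": precision(cm), "recall": recall(cm),
            "support": cm.TP + cm.FN},
    }
    return ClassificationReport(
        per_class=per_class,
        macro_precision=_macro([per_class[0]["precision"],
                                per_class[1]["precision"]]),
        macro_recall=_macro([per_class[0]["recall"], per_class[1]["recall"]]),
        accuracy=accuracy(cm),
        matrix=cm,
    )
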