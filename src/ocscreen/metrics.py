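"""Confusion-count bookkeeping and classifier evaluation statistics.

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP) and accuracy =
(TP+TN)/(TP+FP+TN+FN) are computed in exact rational arithmetic and
rendered at 9 decimal places, so reported values are bit-stable across
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "sensitivity",
    "specificity",
    "accuracy",
    "UndefinedMetricError",
    "metrics_report",
    "render_metric",
]

PRINT_DECIMALS = 9


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for these counts."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(predicted: Sequence[int], truth: Sequence[int],
                     positive_label: int = 1) -> ConfusionCounts:
    """Tally TP/FP/TN/FN from parallel predicted and true label lists."""
    if len(predicted) != len(truth):
        raise ValueError(
            f"predicted ({len(predicted)}) and truth ({len(truth)}) length mismatch")
    tp = fp = tn = fn = 0
    for p, t in zip(predicted, truth):
        if t == positive_label:
            if p == positive_label:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_label:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def sensitivity(c: ConfusionCounts) -> Fraction:
    """TP / (TP + FN); the fraction of true positives recovered."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive instances")
    return Fraction(c.tp, c.tp + c.fn)


def specificity(c: ConfusionCounts) -> Fraction:
    """TN / (TN + FP); the fraction of true negatives recovered."""
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative instances")
    return Fraction(c.tn, c.tn + c.fp)


def accuracy(c: ConfusionCounts) -> Fraction:
    """(TP + TN) / total."""
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined: empty counts")
    return Fraction(c.tp + c.tn, c.total)


def render_metric(value: Fraction, decimals: int = PRINT_DECIMALS) -> str:
    """Render an exact fraction at fixed decimal precision, trailing zeros trimmed."""
    scaled = value * 10**decimals
    rounded = int(scaled) + (1 if 2 * (scaled - int(scaled)) >= 1 else 0)
    text = f"{rounded / 10**decimals:.{decimals}f}".rstrip("0").rstrip(".")
    return text if text else "0"


def metrics_report(counts_by_method: dict[str, ConfusionCounts],
                   path: str | Path | None = None) -> str:
    """TSV report with one column per method, rows TP/FN/TN/FP + the 3 metrics."""
    methods = list(counts_by_method)
    lines = ["Statistics\t" + "\t".join(methods)]
    for row in ("TP", "FN", "TN", "FP"):
        vals = [str(getattr(counts_by_method[m], row.lower())) for m in methods]
        lines.append(row + "\t" + "\t".join(vals))
    for label, fn in (("Sensitivity", sensitivity), ("Specificity", specificity),
                      ("Accuracy", accuracy)):
        vals = [render_metric(fn(counts_by_method[m])) for m in methods]
        lines.append(label + "\t" + "\t".join(vals))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
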