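"""Confusion counting and the SN / SP / ACC / MCC evaluation measures.

The positive class is the antifreeze proteins (label 1), the negative
class the non-AFPs (label 2).  Sensitivity SN = TP/(TP+FN) is the
positive-class accuracy, specificity SP = TN/(TN+FP) the negative-class
accuracy, ACC the overall accuracy, and the Matthews correlation
coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

summarises the whole 2x2 table in [-1, 1].  MCC is the model-selection
measure throughout: with ~4.5% positives, ACC is dominated by the
negative class while MCC remains balanced.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np

from .domain_encoding import NEGATIVE, POSITIVE


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.FP + other.FP,
            self.FN + other.FN,
            self.TN + other.TN,
        )


@dataclasses.dataclass(frozen=True)
class MetricSet:
    SN: float
    SP: float
    ACC: float
    MCC: float
    #: True when any metric's denominator was 0 and the 0-convention applied.
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {"SN": self.SN, "SP": self.SP, "ACC": self.ACC, "MCC": self.MCC}


def confusion_counts(
    y_true: Sequence[int] | np.ndarray,
    y_pred: Sequence[int] | np.ndarray,
    positive: int = POSITIVE,
    negative: int = NEGATIVE,
) -> ConfusionCounts:
    """Count TP/FP/FN/TN with the given positive / negative label codes."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D and of equal length")
    valid = np.array([positive, negative])
    if not (np.isin(yt, valid).all() and np.isin(yp, valid).all()):
        raise ValueError(f"labels must be in {{{positive}, {negative}}}")
    tp = int(((yt == positive) & (yp == positive)).sum())
    fn = int(((yt == positive) & (yp == negative)).sum())
    fp = int(((yt == negative) & (yp == positive)).sum())
    tn = int(((yt == negative) & (yp == negative)).sum())
    return ConfusionCounts(tp, fp, fn, tn)


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Evaluate SN, SP, ACC and MCC from a confusion table.

    Any measure whose denominator is 0 is defined as 0 and the result is
    flagged degenerate (e.g. the all-negative predictor has MCC = 0).
    """
    if c.total < 1:
        raise ValueError("need at least one evaluated sample")
    degenerate = False

    def ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    sn = ratio(c.TP, c.TP + c.FN)
    sp = ratio(c.TN, c.TN + c.FP)
    acc = (c.TP + c.TN) / c.total
    denom2 = (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    if denom2 == 0:
        degenerate = True
        mcc = 0.0
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom2)
    return MetricSet(sn, sp, acc, mcc, degenerate)


def metrics_from_labels(y_true, y_pred) -> MetricSet:
    return compute_metrics(confusion_counts(y_true, y_pred))


def write_metric_report(metrics: MetricSet, path: str | Path) -> None:
    """One-row TSV report with columns SN, SP, ACC, MCC."""
    with open(path, "w") as fh:
        fh.write("SN\tSP\tACC\tMCC\n")
        fh.write(
            f"{metrics.SN:.6f}\t{metrics.SP:.6f}\t{metrics.ACC:.6f}\t{metrics.MCC:.6f}\n"
        )
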