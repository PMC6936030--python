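"""Confusion counts and the four binary-classification metrics.

Sensitivity SN = TP/(TP+FN), specificity SP = TN/(TN+FP), accuracy
ACC = (TP+TN)/N, and the Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

Degenerate denominators are handled explicitly: a metric whose defining
ratio has no observations (e.g. SN with zero positives) is reported as
NaN, never silently as 0, while MCC with a single zero factor in the
root follows the standard convention and returns 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(
        cls, y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "ConfusionCounts":
        if len(y_true) != len(y_pred):
            raise ValueError("y_true and y_pred lengths differ")
        tp = fp = tn = fn = 0
        for t, p in zip(y_true, y_pred):
            if t not in (0, 1) or p not in (0, 1):
                raise ValueError("labels must be 0 or 1")
            if t == 1:
                tp, fn = (tp + 1, fn) if p == 1 else (tp, fn + 1)
            else:
                tn, fp = (tn + 1, fp) if p == 0 else (tn, fp + 1)
        return cls(tp=tp, fp=fp, tn=tn, fn=fn)


def sensitivity(c: ConfusionCounts) -> float:
    """True-positive rate; NaN when there are no positives."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else math.nan


def specificity(c: ConfusionCounts) -> float:
    """True-negative rate; NaN when there are no negatives."""
    denom = c.tn + c.fp
    return c.tn / denom if denom else math.nan


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total if c.total else math.nan


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1].

    Any zero factor under the square root yields 0 by convention; an
    empty confusion matrix yields NaN.
    """
    if c.total == 0:
        return math.nan
    factors = [c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn]
    if any(f == 0 for f in factors):
        return 0.0
    num = c.tp * c.tn - c.fp * c.fn
    return num / math.sqrt(math.prod(factors))


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts plus the four derived metrics (as proportions)."""

    counts: ConfusionCounts
    sn: float
    sp: float
    acc: float
    mcc: float

    @classmethod
    def from_counts(cls, counts: ConfusionCounts) -> "EvalResult":
        return cls(counts=counts, sn=sensitivity(counts), sp=specificity(counts),
                   acc=accuracy(counts), mcc=mcc(counts))

    @classmethod
    def from_labels(
        cls, y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "EvalResult":
        return cls.from_counts(ConfusionCounts.from_labels(y_true, y_pred))

    def to_dict(self) -> dict:
        c = self.counts
        return {"TP": c.tp, "FP": c.fp, "TN": c.tn, "FN": c.fn,
                "SN": self.sn, "SP": self.sp, "ACC": self.acc, "MCC": self.mcc}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_tsv(self, path) -> None:
        d = self.to_dict()
        keys = list(d)
        lines = ["\t".join(keys),
                 "\t".join(f"{d[k]:.6g}" if isinstance(d[k], float) else str(d[k])
                           for k in keys)]
        Path(path).write_text("\n".join(lines) + "\n")
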