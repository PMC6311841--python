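"""Confusion-matrix evaluation (positive class = malignant).

Derived metrics: precision TP/(TP+FP), recall TP/(TP+FN), specificity
TN/(TN+FP), accuracy (TP+TN)/total and the F-measure (harmonic mean of
precision and recall). A 0/0 denominator yields 0 with a logged
warning. Report rounding is half-away-from-zero to 2 decimals.
"""

from __future__ import annotations

import decimal
import logging
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise InvalidArgumentError(f"{name} must be a nonnegative integer")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(labels_true, labels_pred) -> ConfusionCounts:
    """Tally TP/TN/FP/FN from parallel {0,1} label sequences."""
    t = np.asarray(labels_true).ravel()
    p = np.asarray(labels_pred).ravel()
    if t.size != p.size:
        raise InvalidArgumentError("label sequences differ in length")
    if t.size == 0:
        raise InvalidArgumentError("empty label sequences")
    if not (np.all(np.isin(t, (0, 1))) and np.all(np.isin(p, (0, 1)))):
        raise InvalidArgumentError("labels must be 0 or 1")
    return ConfusionCounts(
        TP=int(np.sum((t == 1) & (p == 1))),
        TN=int(np.sum((t == 0) & (p == 0))),
        FP=int(np.sum((t == 0) & (p == 1))),
        FN=int(np.sum((t == 1) & (p == 0))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("0/0 in %s; reporting 0", name)
        return 0.0
    return num / den


def metric_suite(c: ConfusionCounts) -> dict[str, float]:
    """All five derived metrics from a count table."""
    if c.total < 1:
        raise InvalidArgumentError("metric computation needs at least one sample")
    precision = _ratio(c.TP, c.TP + c.FP, "precision")
    recall = _ratio(c.TP, c.TP + c.FN, "recall")
    specificity = _ratio(c.TN, c.TN + c.FP, "specificity")
    accuracy = (c.TP + c.TN) / c.total
    f_measure = _ratio(2.0 * precision * recall, precision + recall, "f_measure")
    return {
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "accuracy": accuracy,
        "f_measure": f_measure,
    }


def round_report(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention used for report tables
    (0.825 -> 0.83, unlike banker's rounding). Works on the shortest
    decimal repr of the float so 33/40 rounds up as intended."""
    q = decimal.Decimal(10) ** -ndigits
    d = decimal.Decimal(repr(float(value))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def rounded_suite(c: ConfusionCounts, ndigits: int = 2) -> dict[str, float]:
    return {k: round_report(v, ndigits) for k, v in metric_suite(c).items()}
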