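"""Confusion-matrix statistics for binary classifiers.

Six statistics are computed from TP/FP/TN/FN: precision, recall, negative
predictive value, specificity, balanced accuracy, and the Matthews
correlation coefficient. Rates whose denominator is zero are *undefined*
(``None``) rather than silently 0, and summaries track how many repeats
were excluded per metric for that reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

METRIC_NAMES = ("precision", "recall", "npv", "specificity", "ba", "mcc")


@dataclass(frozen=True)
class ConfusionMetrics:
    TP: int
    FP: int
    TN: int
    FN: int
    precision: float | None
    recall: float | None
    npv: float | None
    specificity: float | None
    ba: float | None
    mcc: float | None

    def as_dict(self) -> dict:
        return {
            "TP": self.TP,
            "FP": self.FP,
            "TN": self.TN,
            "FN": self.FN,
            **{name: getattr(self, name) for name in METRIC_NAMES},
        }


@dataclass
class MetricSummary:
    """Mean and population standard deviation per metric over repeats."""

    repeats: list[ConfusionMetrics]
    mean: dict[str, float | None]
    sd: dict[str, float | None]
    n_undefined: dict[str, int]

    def __str__(self) -> str:  # paper-style "0.96 ± 0.01" rows, 2 d.p.
        parts = []
        for name in METRIC_NAMES:
            m, s = self.mean[name], self.sd[name]
            if m is None:
                parts.append(f"{name}=undefined")
            else:
                parts.append(f"{name}={display_round(m)} ± {display_round(s)}")
        return ", ".join(parts)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(TP: int, FP: int, TN: int, FN: int) -> ConfusionMetrics:
    """Evaluate all six statistics from raw confusion counts.

    precision = TP/(TP+FP); recall = TP/(TP+FN); npv = TN/(TN+FN);
    specificity = TN/(TN+FP); ba = (recall+specificity)/2;
    mcc = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    Any statistic with a zero denominator is ``None``.
    """
    counts = (TP, FP, TN, FN)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative count in {counts}")
    if not any(int(c) == c for c in counts):
        raise ValueError("counts must be integers")
    if sum(counts) < 1:
        raise ValueError("empty confusion matrix")
    TP, FP, TN, FN = (int(c) for c in counts)

    precision = _ratio(TP, TP + FP)
    recall = _ratio(TP, TP + FN)
    npv = _ratio(TN, TN + FN)
    specificity = _ratio(TN, TN + FP)
    ba = None
    if recall is not None and specificity is not None:
        ba = (recall + specificity) / 2
    denom = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    mcc = None if denom == 0 else (TP * TN - FP * FN) / math.sqrt(denom)
    return ConfusionMetrics(TP, FP, TN, FN, precision, recall, npv, specificity, ba, mcc)


def balanced_accuracy(recall: float, specificity: float) -> float:
    """Balanced accuracy from its two component rates."""
    return (recall + specificity) / 2


def summarize_repeats(
    repeats: Sequence[ConfusionMetrics], ddof: int = 0
) -> MetricSummary:
    """Per-metric mean and standard deviation over repeats.

    Undefined values are excluded from the aggregation; their count is
    recorded in ``n_undefined``. ``ddof=0`` (population sd) by default.
    """
    if not repeats:
        raise ValueError("summarize_repeats needs at least one repeat")
    mean: dict[str, float | None] = {}
    sd: dict[str, float | None] = {}
    n_undef: dict[str, int] = {}
    for name in METRIC_NAMES:
        vals = [getattr(r, name) for r in repeats]
        defined = [v for v in vals if v is not None]
        n_undef[name] = len(vals) - len(defined)
        if not defined:
            mean[name] = sd[name] = None
            continue
        mu = sum(defined) / len(defined)
        mean[name] = mu
        if len(defined) - ddof <= 0:
            sd[name] = 0.0
        else:
            sd[name] = math.sqrt(
                sum((v - mu) ** 2 for v in defined) / (len(defined) - ddof)
            )
    return MetricSummary(list(repeats), mean, sd, n_undef)


def success_rate(n_correct: int, n_total: int) -> float:
    """Percentage of correct predictions: 100 * n_correct / n_total."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_correct <= n_total:
        raise ValueError(f"n_correct={n_correct} outside [0, {n_total}]")
    return 100.0 * n_correct / n_total


def display_round(x: float, ndigits: int = 2) -> float:
    """Half-even display rounding used in report tables."""
    return round(x, ndigits)


def metrics_from_predictions(y_true, y_pred) -> ConfusionMetrics:
    """Confusion metrics from 0/1 label arrays (1 = active/positive)."""
    import numpy as np

    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch between y_true and y_pred")
    TP = int(np.sum((y_true == 1) & (y_pred == 1)))
    FP = int(np.sum((y_true == 0) & (y_pred == 1)))
    TN = int(np.sum((y_true == 0) & (y_pred == 0)))
    FN = int(np.sum((y_true == 1) & (y_pred == 0)))
    return compute_metrics(TP, FP, TN, FN)
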