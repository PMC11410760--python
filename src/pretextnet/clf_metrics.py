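"""Confusion-matrix classification metrics.

All metrics derive from TP/FP/TN/FN counted at a stated threshold (default
0.5; ties predicted positive). The positive class is label 1 (abnormal).
Report display rounds to 4 decimals, half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "UndefinedMetricError",
    "confusion",
    "compute_metrics",
    "balanced_accuracy",
    "youden_index",
    "round_half_away",
]


class UndefinedMetricError(ValueError):
    """A metric's denominator is zero for the given confusion counts."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float = 0.5

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    f_score: float
    mcc: float
    kappa: float
    youden: float


def confusion(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Count TP/FP/TN/FN; predicted positive iff ``p_abnormal >= threshold``."""
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels)
    if p.shape[0] != y.shape[0]:
        raise ValueError("probabilities and labels length mismatch")
    if p.ndim == 2:  # probability rows [p_normal, p_abnormal]
        p = p[:, 1]
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be binary")
    pred = p >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        threshold=threshold,
    )


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Mean of the two per-class recalls."""
    return (sensitivity + specificity) / 2.0


def youden_index(sensitivity: float, specificity: float) -> float:
    """``sensitivity + specificity - 1``; 0 at chance, 1 when perfect."""
    return sensitivity + specificity - 1.0


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if tp + fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive samples")
    if tn + fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative samples")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    if 2 * tp + fp + fn == 0:
        raise UndefinedMetricError("f_score undefined: no positives anywhere")
    f_score = 2 * tp / (2 * tp + fp + fn)
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if mcc_den == 0:
        raise UndefinedMetricError("mcc undefined: a marginal count is zero")
    mcc = (tp * tn - fp * fn) / mcc_den
    kappa_den = float(tp + fp) * float(fp + tn) + float(tp + fn) * float(fn + tn)
    if kappa_den == 0:
        raise UndefinedMetricError("kappa undefined: degenerate marginals")
    kappa = 2.0 * (tp * tn - fn * fp) / kappa_den
    return MetricReport(
        balanced_accuracy=balanced_accuracy(sens, spec),
        sensitivity=sens,
        specificity=spec,
        f_score=f_score,
        mcc=float(mcc),
        kappa=float(kappa),
        youden=youden_index(sens, spec),
    )


def round_half_away(value: float, decimals: int = 4) -> float:
    """Round half away from zero on the decimal (printed) representation."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
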