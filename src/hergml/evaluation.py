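"""Confusion-matrix statistics for binary hERG-blockade classification.

Cooper statistics (sensitivity, specificity, balanced accuracy), the Matthews
correlation coefficient, and a rank-based ROC AUC.  The blocker class (ACT)
is the positive class throughout.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

ACT = "ACT"
INA = "INA"
ABSTAIN = "ABSTAIN"


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is empty (a class is absent)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with ACT as the positive class."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.TP + self.FP + self.TN + self.FN < 1:
            raise ValueError("confusion counts must describe at least one sample")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricReport:
    """Metric suite for one model/dataset pair.

    AUC is None when no continuous scores are available (e.g. a consensus of
    hard calls).  ``n_abstained`` and ``n_out_of_domain`` record rows excluded
    before scoring; metrics refer only to in-domain, non-abstained rows.
    """

    SE: float
    SP: float
    BA: float
    MCC: float
    AUC: Optional[float]
    counts: ConfusionCounts
    n_abstained: int = 0
    n_out_of_domain: int = 0

    def as_row(self) -> dict:
        """Flat dict in report column order (BA first, counts last)."""
        return {
            "BA": self.BA,
            "SE": self.SE,
            "SP": self.SP,
            "MCC": self.MCC,
            "AUC": self.AUC,
            "TP": self.counts.TP,
            "FP": self.counts.FP,
            "TN": self.counts.TN,
            "FN": self.counts.FN,
            "n_abstained": self.n_abstained,
            "n_out_of_domain": self.n_out_of_domain,
        }


def confusion(labels: Sequence[str], predictions: Sequence[str]) -> ConfusionCounts:
    """Tally 2x2 counts.  Abstained rows must be excluded upstream."""
    if len(labels) != len(predictions):
        raise ValueError(f"length mismatch: {len(labels)} labels vs {len(predictions)} predictions")
    tp = fp = tn = fn = 0
    for y, p in zip(labels, predictions):
        if y not in (ACT, INA) or p not in (ACT, INA):
            raise ValueError(f"labels and predictions must be ACT/INA, got ({y!r}, {p!r})")
        if p == ACT:
            if y == ACT:
                tp += 1
            else:
                fp += 1
        else:
            if y == INA:
                tn += 1
            else:
                fn += 1
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def cooper_stats(c: ConfusionCounts) -> tuple[float, float, float]:
    """SE = TP/(TP+FN), SP = TN/(TN+FP), BA = (SE+SP)/2."""
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("no positive samples: SE undefined")
    if c.TN + c.FP == 0:
        raise UndefinedMetricError("no negative samples: SP undefined")
    se = c.TP / (c.TP + c.FN)
    sp = c.TN / (c.TN + c.FP)
    return se, sp, (se + sp) / 2.0


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty.

    Products of four counts overflow int32-sized intermediates for large
    datasets, so the denominator is computed in log space.
    """
    marginals = (c.TP + c.FP, c.TP + c.FN, c.TN + c.FP, c.TN + c.FN)
    if any(m == 0 for m in marginals):
        return 0.0
    num = float(c.TP) * c.TN - float(c.FP) * c.FN
    log_den = 0.5 * sum(math.log(m) for m in marginals)
    return num * math.exp(-log_den)


def auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Mann-Whitney (rank) AUC with ties counted one half.

    Equals the probability that a uniformly chosen blocker is scored above a
    uniformly chosen nonblocker.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == ACT else 0 for l in labels])
    if len(scores) != len(y):
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def metric_report(
    labels: Sequence[str],
    predictions: Sequence[str],
    scores: Optional[Sequence[float]] = None,
    n_abstained: int = 0,
    n_out_of_domain: int = 0,
) -> MetricReport:
    """Compute the full suite over non-abstained, in-domain rows."""
    c = confusion(labels, predictions)
    se, sp, ba = cooper_stats(c)
    a = auc(scores, labels) if scores is not None else None
    return MetricReport(
        SE=se, SP=sp, BA=ba, MCC=mcc(c), AUC=a, counts=c,
        n_abstained=n_abstained, n_out_of_domain=n_out_of_domain,
    )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up rounding used for 2-decimal report display.

    Decimal-based so that shortest-repr values like 0.865 round up instead
    of falling victim to their binary representation.
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(str(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))
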