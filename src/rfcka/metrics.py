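"""Matthews correlation coefficient and inter-model prediction agreement.

The MCC summarizes a binary confusion table in [-1, 1]:

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with 1 perfect classification, -1 perfectly inverted prediction.  When any
denominator factor is zero (e.g. all predictions one class) the value is
defined as 0 by the standard convention, which keeps validation pipelines
running on degenerate forests.

``mcc_inter`` applies the same formula to the predictions of two models,
measuring agreement rather than accuracy; swapping the two prediction vectors
swaps FP and FN, which leaves the formula unchanged, so it is symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DimensionMismatchError, InvalidInputError
from .kernels import LabelVector

__all__ = ["ConfusionCounts", "confusion", "mcc", "mcc_inter"]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies of a binary confusion table."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise InvalidInputError(f"{name} must be a nonnegative integer")
        if self.TP + self.TN + self.FP + self.FN < 1:
            raise InvalidInputError("confusion table must count at least one sample")


def _as_binary(v) -> np.ndarray:
    if isinstance(v, LabelVector):
        return v.labels
    arr = np.asarray(v)
    if not np.isin(np.unique(arr), [0, 1]).all():
        raise InvalidInputError("labels must be binary 0/1")
    return arr.astype(int)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally the binary confusion table of predictions against truth."""
    t = _as_binary(y_true)
    p = _as_binary(y_pred)
    if len(t) != len(p):
        raise DimensionMismatchError(
            f"length mismatch: {len(t)} true vs {len(p)} predicted"
        )
    return ConfusionCounts(
        TP=int(np.sum((t == 1) & (p == 1))),
        TN=int(np.sum((t == 0) & (p == 0))),
        FP=int(np.sum((t == 0) & (p == 1))),
        FN=int(np.sum((t == 1) & (p == 0))),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient of a confusion table.

    Numerator and denominator factors are computed in exact integer
    arithmetic before a single square root, so large counts lose no precision.
    """
    tp, tn, fp, fn = int(c.TP), int(c.TN), int(c.FP), int(c.FN)
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    return float((tp * tn - fp * fn) / math.sqrt(denom_sq))


def mcc_inter(pred_a, pred_b) -> float:
    """MCC between two models' predictions: a symmetric agreement measure."""
    return mcc(confusion(pred_a, pred_b))
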