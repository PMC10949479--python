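"""Growth-prediction evaluation: confusion counts, F-score, MCC, RMSE.

Binary growth comparison follows the standard four outcomes: a true
positive means both model and experiment indicate growth on a substrate, a
false positive means the model grows without experimental support, and so
on.  F = TP / (TP + (FP + FN)/2);
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "ConfusionCounts",
    "GrowthObservation",
    "compare_growth",
    "f_score",
    "mcc",
    "rmse_growth",
]

GROWTH_TOL = 1e-6  # h^-1; aligned with the essentiality zero tolerance


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class GrowthObservation:
    substrate: str
    observed_growth: bool
    observed_rate: float | None = None

    def __post_init__(self):
        if self.observed_rate is not None and self.observed_rate < 0:
            raise ValueError("observed rate must be nonnegative")


def compare_growth(predictions: dict[str, float],
                   observations: list[GrowthObservation],
                   growth_tol: float = GROWTH_TOL) -> ConfusionCounts:
    """Binary growth comparison: predicted growth iff mu > growth_tol."""
    obs_by_substrate = {o.substrate: o for o in observations}
    shared = set(predictions) & set(obs_by_substrate)
    unmatched = (set(predictions) | set(obs_by_substrate)) - shared
    if not shared:
        raise ValueError("no substrate overlaps between predictions and "
                         "observations")
    if unmatched:
        warnings.warn(f"substrates without a counterpart: {sorted(unmatched)}")
    tp = fp = tn = fn = 0
    for substrate in shared:
        predicted = predictions[substrate] > growth_tol
        observed = obs_by_substrate[substrate].observed_growth
        if predicted and observed:
            tp += 1
        elif predicted and not observed:
            fp += 1
        elif not predicted and observed:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def f_score(c: ConfusionCounts) -> float:
    """F = TP / (TP + (FP + FN)/2); undefined when TP+FP+FN = 0."""
    denom = c.tp + 0.5 * (c.fp + c.fn)
    if denom == 0:
        raise ValueError("F-score undefined: TP + FP + FN = 0")
    return c.tp / denom


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 (flagged) when a factor is zero."""
    denom = math.sqrt(
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        warnings.warn("MCC denominator zero; returning 0 by convention")
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / denom


def rmse_growth(predicted: dict[str, float],
                observed: dict[str, float]) -> float:
    """Root-mean-square error of growth rates over paired substrates."""
    shared = sorted(set(predicted) & set(observed))
    if not shared:
        raise ValueError("no paired growth rates")
    sq = [(predicted[s] - observed[s]) ** 2 for s in shared]
    return math.sqrt(sum(sq) / len(sq))
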