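"""Classification metrics, threshold sweeps, and localization scoring.

Metrics follow the usual binary-classification definitions; a metric whose
denominator is zero is reported as ``None`` (flagged undefined) rather than
silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "metrics",
    "confusion_from_gaps",
    "sweep",
    "localization_score",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, precision, recall and F-measure (F1, the harmonic mean of
    precision and recall) from confusion counts."""
    if c.total == 0:
        raise ValueError("no evaluated traces: all counts are zero")
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f_measure = None
    else:
        f_measure = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f_measure": f_measure,
    }


def confusion_from_gaps(gaps: Sequence[float], labels: Sequence[bool],
                        threshold: float) -> ConfusionCounts:
    """Confusion counts for the rule ``predict positive iff gap > threshold``."""
    g = np.asarray(gaps, dtype=np.float64)
    y = np.asarray(labels, dtype=bool)
    if g.shape != y.shape or g.size == 0:
        raise ValueError("gaps and labels must be equal-length and non-empty")
    pred = g > threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & y)),
        fp=int(np.sum(pred & ~y)),
        fn=int(np.sum(~pred & y)),
        tn=int(np.sum(~pred & ~y)),
    )


def sweep(gaps: Sequence[float], labels: Sequence[bool],
          thresholds: Sequence[float]) -> pd.DataFrame:
    """One metrics row per threshold, from a single pass over the gaps.

    Because the predicted-positive set shrinks as the threshold rises,
    recall is non-increasing down an ascending sweep.
    """
    if len(thresholds) == 0:
        raise ValueError("need at least one threshold")
    rows = []
    for t in thresholds:
        c = confusion_from_gaps(gaps, labels, t)
        m = metrics(c)
        rows.append({"threshold": float(t), "tp": c.tp, "fp": c.fp,
                     "fn": c.fn, "tn": c.tn, **m})
    return pd.DataFrame(rows)


def localization_score(
    pred_interval: tuple[int, int] | None,
    truth_interval: tuple[int, int] | None,
) -> float:
    """Overlap fraction |∩| / |∪| between two half-open sample intervals.

    Both absent → 1 (correctly predicted nothing); exactly one absent → 0.
    """
    def _norm(iv):
        if iv is None:
            return None
        a, b = int(iv[0]), int(iv[1])
        if b < a:
            raise ValueError(f"malformed interval {iv}")
        return None if a == b else (a, b)

    p, t = _norm(pred_interval), _norm(truth_interval)
    if p is None and t is None:
        return 1.0
    if p is None or t is None:
        return 0.0
    inter = max(0, min(p[1], t[1]) - max(p[0], t[0]))
    union = (p[1] - p[0]) + (t[1] - t[0]) - inter
    return inter / union
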