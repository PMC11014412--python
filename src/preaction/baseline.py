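"""Whole-trace nearest-participant baseline classifier.

The comparison method: no strike anchoring, no time reversal, no growing
window.  The distance between two punches is the sum of three *independent*
single-axis DTW distances over the full traces; a query is labeled by the
group (with / without pre-action) of the participant whose punches lie
closest on average.  The query's own participant must be excluded from the
bank (leave-one-participant-out).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dtw import DtwConfig, dtw_distance_1d
from .io import AccelTrace

__all__ = ["Participant", "LabeledPunchBank", "baseline_distance", "baseline_classify"]


@dataclass(frozen=True)
class Participant:
    """One participant's punches with a binary group label."""

    participant_id: str
    punches: tuple[AccelTrace, ...]
    has_preaction: bool

    def __post_init__(self) -> None:
        if len(self.punches) < 1:
            raise ValueError(
                f"participant {self.participant_id!r} has no punches"
            )
        object.__setattr__(self, "punches", tuple(self.punches))


@dataclass(frozen=True)
class LabeledPunchBank:
    """Per-participant punch collections with group labels."""

    participants: tuple[Participant, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "participants", tuple(self.participants))

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self):
        return iter(self.participants)

    def excluding(self, participant_id: str) -> "LabeledPunchBank":
        """Bank without the named participant (leave-one-participant-out)."""
        return LabeledPunchBank(tuple(
            p for p in self.participants if p.participant_id != participant_id
        ))


def baseline_distance(a: AccelTrace, b: AccelTrace,
                      cfg: DtwConfig = DtwConfig()) -> float:
    """Sum of the three per-axis whole-trace DTW distances between punches."""
    return (
        dtw_distance_1d(a.x, b.x, cfg)
        + dtw_distance_1d(a.y, b.y, cfg)
        + dtw_distance_1d(a.z, b.z, cfg)
    )


def baseline_classify(query: AccelTrace, bank: LabeledPunchBank,
                      cfg: DtwConfig = DtwConfig()) -> bool:
    """Group label of the participant nearest to the query on average.

    For each participant the baseline distance is averaged over *that
    participant's* punches (per-participant averaging, not pooling across
    the bank); the verdict is the label of the participant with the
    smallest average, ties breaking to the earliest participant in bank
    order.
    """
    if len(bank) == 0:
        raise ValueError("punch bank is empty")
    best_avg = np.inf
    best_label: bool | None = None
    for participant in bank:
        avg = float(np.mean([
            baseline_distance(query, punch, cfg) for punch in participant.punches
        ]))
        if avg < best_avg:
            best_avg = avg
            best_label = participant.has_preaction
    assert best_label is not None
    return best_label
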