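"""Whole-trace nearest-participant baseline."""

from __future__ import annotations

import numpy as np
import pytest

from preaction import (
    LabeledPunchBank,
    Participant,
    SynthConfig,
    baseline_classify,
    baseline_distance,
    generate_punch,
)
from preaction.dtw import dtw_distance_1d

from conftest import make_trace


def _punch(seed, ptype="none"):
    return generate_punch(SynthConfig(seed=seed, preaction_type=ptype))[0]


def test_identical_traces_have_zero_distance():
    p = _punch(1)
    assert baseline_distance(p, p) == 0.0


def test_distance_is_sum_of_independent_per_axis_dtw():
    a, b = _punch(2), _punch(3, "arm_lower")
    expected = (
        dtw_distance_1d(a.x, b.x)
        + dtw_distance_1d(a.y, b.y)
        + dtw_distance_1d(a.z, b.z)
    )
    assert baseline_distance(a, b) == expected


def test_distance_symmetric():
    a, b = _punch(4), _punch(5)
    assert baseline_distance(a, b) == baseline_distance(b, a)


def test_single_participant_bank_returns_its_label():
    bank = LabeledPunchBank((Participant("p", (_punch(6),), True),))
    assert baseline_classify(_punch(7), bank) is True


def test_leave_one_participant_out_exclusion():
    bank = LabeledPunchBank((
        Participant("a", (_punch(8),), False),
        Participant("b", (_punch(9),), True),
    ))
    reduced = bank.excluding("a")
    assert [p.participant_id for p in reduced] == ["b"]
    assert len(bank) == 2  # original untouched


def _constant_trace(value, n=4):
    return make_trace(np.full(n, float(value)))


def test_per_participant_average_differs_from_pooled_nearest():
    """A participant holding the single globally nearest punch can still
    lose to a participant whose punches are uniformly close on average."""
    query = _constant_trace(0.0)
    near_then_far = Participant(
        "mixed", (_constant_trace(0.0), _constant_trace(10.0)), False
    )
    uniformly_close = Participant(
        "steady", (_constant_trace(1.0), _constant_trace(1.0)), True
    )
    bank = LabeledPunchBank((near_then_far, uniformly_close))
    # pooled-nearest would pick "mixed" (distance 0); averaging picks "steady"
    d_mixed = np.mean([baseline_distance(query, p) for p in near_then_far.punches])
    d_steady = np.mean([baseline_distance(query, p) for p in uniformly_close.punches])
    assert d_steady < d_mixed
    assert baseline_classify(query, bank) is True


def test_tie_breaks_to_earliest_participant():
    bank = LabeledPunchBank((
        Participant("first", (_constant_trace(1.0),), False),
        Participant("second", (_constant_trace(1.0),), True),
    ))
    assert baseline_classify(_constant_trace(0.0), bank) is False


def test_label_permutation_equivariance_without_ties():
    query = _punch(10)
    parts = [
        Participant("a", (_punch(11),), False),
        Participant("b", (_punch(12, "arm_lower"),), True),
        Participant("c", (_punch(13, "side_shake"),), True),
    ]
    verdict = baseline_classify(query, LabeledPunchBank(tuple(parts)))
    for perm in ([2, 0, 1], [1, 2, 0], [2, 1, 0]):
        permuted = LabeledPunchBank(tuple(parts[i] for i in perm))
        assert baseline_classify(query, permuted) == verdict


def test_empty_bank_rejected():
    with pytest.raises(ValueError):
        baseline_classify(_punch(14), LabeledPunchBank(()))
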