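"""Striking-sample detection, cost profiles, extrema, verdicts, calibration."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from preaction import (
    AccelTrace,
    CostProfile,
    DtwConfig,
    ReferenceSet,
    StrikeDetectionError,
    SynthConfig,
    Template,
    build_template,
    calibrate_threshold,
    compute_cost_profile,
    cut_and_reverse,
    detect_striking_index,
    dtw_distance,
    estimate_preaction,
    find_extrema,
    generate_punch,
)
from preaction.detector import default_ell_min

from conftest import make_trace


class TestStrikingIndex:
    def test_global_minimum(self):
        assert detect_striking_index(make_trace([0, -1, -5, -2, 3])) == 2

    def test_tie_breaks_to_earliest(self):
        assert detect_striking_index(make_trace([-5, -5, 0])) == 0

    def test_constant_x_undetectable(self):
        with pytest.raises(StrikeDetectionError):
            detect_striking_index(make_trace([1.0, 1.0, 1.0], y=[0, 1, 2]))

    def test_simulator_ground_truth_within_one_sample(self):
        for seed in range(100):
            trace, truth = generate_punch(SynthConfig(seed=seed))
            assert abs(detect_striking_index(trace) - truth.strike_index) <= 1


class TestCutAndReverse:
    def setup_method(self):
        self.trace = make_trace(np.arange(10.0))

    def test_minimal_window_is_strike_sample(self):
        w = cut_and_reverse(self.trace, 6, 1)
        np.testing.assert_array_equal(w, self.trace.samples[6:7])

    def test_full_prefix_at_boundary(self):
        w = cut_and_reverse(self.trace, 6, 7)
        np.testing.assert_array_equal(w, self.trace.samples[:7][::-1])

    def test_reversing_twice_restores_forward_order(self):
        w = cut_and_reverse(self.trace, 6, 4)
        np.testing.assert_array_equal(w[::-1], self.trace.samples[3:7])

    @pytest.mark.parametrize("length", [0, 8])
    def test_out_of_range_length(self, length):
        with pytest.raises(ValueError):
            cut_and_reverse(self.trace, 6, length)


class TestCostProfile:
    def test_identical_trace_reaches_zero_at_full_window(self):
        trace, _ = generate_punch(SynthConfig(seed=4, noise_sd=0.0))
        mu = detect_striking_index(trace)
        template = Template(trace, mu, "self")
        prof = compute_cost_profile(trace, mu, template)
        assert prof.distances[-1] == 0.0
        assert np.all(prof.distances >= 0.0)

    def test_incremental_equals_naive_per_length(self, small_refset):
        trace, _ = generate_punch(SynthConfig(seed=5))
        mu = detect_striking_index(trace)
        template = small_refset.templates[0]
        prof = compute_cost_profile(trace, mu, template, ell_min=2)
        w_rev = cut_and_reverse(
            template.trace, template.striking_index, template.striking_index + 1
        )
        for k, d in enumerate(prof.distances):
            ell = prof.ell(k)
            assert d == dtw_distance(cut_and_reverse(trace, mu, ell), w_rev)

    def test_default_ell_min_is_third_of_template(self, small_refset):
        trace, _ = generate_punch(SynthConfig(seed=6))
        mu = detect_striking_index(trace)
        template = small_refset.templates[0]
        prof = compute_cost_profile(trace, mu, template)
        assert prof.ell_min == default_ell_min(template.striking_index + 1)
        assert len(prof) == mu + 1 - prof.ell_min + 1


def _profile(values, ell_min=2):
    return CostProfile(np.asarray(values, dtype=float), "t", ell_min)


class TestFindExtrema:
    def test_first_min_then_first_max(self):
        ext = find_extrema(_profile([5, 3, 2, 4, 6, 1]))
        assert (ext.psi, ext.phi) == (2, 4)
        assert ext.gap == 6 - 2

    def test_plateau_collapses_to_first_index(self):
        ext = find_extrema(_profile([5, 2, 2, 2, 6, 1]))
        assert (ext.psi, ext.phi) == (1, 4)

    def test_strictly_decreasing_has_no_extrema(self):
        ext = find_extrema(_profile([9, 7, 4, 2, 1]))
        assert not ext.has_min and ext.gap == 0.0

    def test_terminal_ascent_counts_as_boundary_maximum(self):
        ext = find_extrema(_profile([5, 1, 2, 4, 9]))
        assert ext.psi == 1
        assert ext.phi == 4
        assert ext.gap == 8.0

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError):
            find_extrema(_profile([1, 2]))

    def test_gap_nonnegative_even_with_smoothing(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            ext = find_extrema(_profile(rng.uniform(0, 10, 30)), smoothing=3)
            assert ext.gap >= 0.0


class TestEstimate:
    def test_template_identity_input_gives_no_preaction(self, noiseless_refset):
        for template in noiseless_refset:
            res = estimate_preaction(template.trace, noiseless_refset, threshold=0.0)
            assert res.gap == 0.0
            assert not res.has_preaction
            assert res.interval is None

    def test_injected_fist_pull_detected_and_localized(self, small_refset):
        trace, truth = generate_punch(
            SynthConfig(seed=77, preaction_type="fist_pull")
        )
        res = estimate_preaction(trace, small_refset, threshold=1e7)
        assert res.has_preaction
        lo, hi = res.interval
        t_lo, t_hi = truth.preaction_interval
        assert lo < t_hi and t_lo < hi  # intervals overlap

    def test_verdict_invariant_to_post_strike_samples(self, small_refset):
        trace, _ = generate_punch(SynthConfig(seed=78, preaction_type="arm_lower"))
        res0 = estimate_preaction(trace, small_refset, threshold=1e7)
        extended = AccelTrace(
            np.vstack([trace.samples, np.zeros((25, 3))]),
            trace.sample_rate_hz, unit=trace.unit,
        )
        res1 = estimate_preaction(extended, small_refset, threshold=1e7)
        np.testing.assert_array_equal(res0.profile.distances, res1.profile.distances)
        assert res0.gap == res1.gap
        assert res0.has_preaction == res1.has_preaction
        assert res0.interval == res1.interval

    def test_best_template_minimizes_cmin(self, small_refset):
        trace, _ = generate_punch(SynthConfig(seed=79, preaction_type="side_shake"))
        mu = detect_striking_index(trace)
        cmins = {}
        for t in small_refset:
            ext = find_extrema(compute_cost_profile(trace, mu, t), smoothing=3)
            if ext.has_min:
                cmins[t.label] = ext.c_min
        res = estimate_preaction(trace, small_refset, threshold=1e7)
        assert res.best_template_id == min(cmins, key=cmins.get)

    def test_all_templates_ineligible_yields_no_preaction(self):
        # strike almost at trace start: profiles too short for any extrema
        query = make_trace([0.0, 1.0, -5.0, 0.0])
        template_trace = make_trace(np.linspace(2.0, -2.0, 30))
        refset = ReferenceSet((Template(template_trace, 29, "ramp"),))
        res = estimate_preaction(query, refset, threshold=0.0)
        assert not res.has_preaction and res.gap == 0.0

    def test_empty_refset_rejected(self, small_refset):
        trace, _ = generate_punch(SynthConfig(seed=80))
        with pytest.raises(Exception):
            ReferenceSet(())


class TestCalibration:
    def _labeled(self, small_refset, n=8):
        out = []
        for k in range(n):
            ptype = "arm_lower" if k % 2 else "none"
            tr, truth = generate_punch(SynthConfig(seed=500 + k, preaction_type=ptype))
            out.append((tr, truth.label))
        return out

    def test_picks_accuracy_maximizer_tie_to_smaller(self, small_refset):
        labeled = self._labeled(small_refset)
        best_t, table = calibrate_threshold(
            labeled, small_refset, [1e6, 1e7, 1e12]
        )
        # 1e6 and 1e7 both separate the classes perfectly; tie -> smaller
        assert best_t == 1e6
        assert table.loc[table["threshold"] == 1e12, "recall"].item() == 0.0

    def test_all_gaps_below_candidates_degenerate(self, small_refset):
        labeled = [
            (generate_punch(SynthConfig(seed=600 + k))[0], False) for k in range(3)
        ] + [(generate_punch(SynthConfig(seed=650, preaction_type="fist_pull"))[0], True)]
        best_t, table = calibrate_threshold(labeled, small_refset, [1e15, 2e15])
        assert best_t == 1e15
        assert (table["recall"] == 0.0).all()

    @given(st.integers(0, 2**31 - 1))
    def test_recall_nonincreasing_in_threshold(self, seed):
        from preaction.evaluation import sweep

        rng = np.random.default_rng(seed)
        gaps = rng.uniform(0, 1, 30)
        labels = rng.uniform(size=30) < 0.5
        if not labels.any():
            labels[0] = True
        table = sweep(gaps, labels, np.sort(rng.uniform(0, 1, 5)))
        recalls = table["recall"].to_numpy(dtype=float)
        assert np.all(np.diff(recalls) <= 0)


def test_scale_covariance_of_profiles_and_gap(small_refset):
    trace, _ = generate_punch(SynthConfig(seed=90, preaction_type="fist_pull"))
    c = 3.0
    res = estimate_preaction(trace, small_refset, threshold=1e7)
    res_scaled = estimate_preaction(
        trace.scaled(c), small_refset.scaled(c), threshold=1e7 * c**2
    )
    np.testing.assert_allclose(
        res_scaled.profile.distances, res.profile.distances * c**2, rtol=1e-9
    )
    np.testing.assert_allclose(res_scaled.gap, res.gap * c**2, rtol=1e-9)
    assert res_scaled.has_preaction == res.has_preaction
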