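"""Heel-strike detection and spatiotemporal step measures."""

import numpy as np
import pytest

from interlimb import (
    GaitEvents,
    MarkerTrial,
    detect_heel_strikes,
    spatiotemporal_summary,
    step_length,
    step_time,
    step_width,
    summarize_first_n,
)
from interlimb.exceptions import (
    ConfigurationError,
    EventContractError,
    InsufficientDataError,
)


def _trial_from_channels(heel_L_ap, heel_R_ap, sample_rate=100.0, belt_speed=1.1,
                         heel_L_ml=None, heel_R_ml=None, sacrum_ap=None):
    n = len(heel_L_ap)
    zeros = np.zeros(n)

    def pack(ap, ml):
        return np.column_stack([ap, ml if ml is not None else zeros, zeros])

    return MarkerTrial(
        positions={
            "heel_L": pack(np.asarray(heel_L_ap, float), heel_L_ml),
            "heel_R": pack(np.asarray(heel_R_ap, float), heel_R_ml),
            "sacrum": pack(sacrum_ap if sacrum_ap is not None else zeros, None),
        },
        sample_rate=sample_rate, belt_speed=belt_speed,
    )


class TestDetection:
    def test_matches_ground_truth_within_two_samples(self, healthy_trial):
        trial, truth = healthy_trial
        detected = detect_heel_strikes(trial)
        for det, ref in ((detected.heel_strikes_L, truth.heel_strikes_L),
                         (detected.heel_strikes_R, truth.heel_strikes_R)):
            hits = sum(np.min(np.abs(det - s)) <= 2 for s in ref)
            assert hits / len(ref) >= 0.99

    def test_constant_trial_insufficient(self):
        trial = _trial_from_channels(np.ones(500), np.ones(500))
        with pytest.raises(InsufficientDataError):
            detect_heel_strikes(trial)

    def test_pure_sinusoid_with_zero_sacrum_peaks_at_maxima(self):
        t = np.arange(2000) / 100.0
        ap = 300.0 * np.sin(2 * np.pi * 0.8 * t)  # maxima at t = 0.3125 + k/0.8
        trial = _trial_from_channels(ap, ap)
        events = detect_heel_strikes(trial)
        expected = np.round((0.3125 + np.arange(16) / 0.8) * 100).astype(int)
        for s in events.heel_strikes_L:
            assert np.min(np.abs(expected - s)) <= 1


class TestStepTime:
    def test_single_step_example(self):
        events = GaitEvents(heel_strikes_L=[0], heel_strikes_R=[58])
        times = step_time(events, sample_rate=100.0)
        assert times["R"] == pytest.approx([0.58])
        assert times["L"].size == 0

    def test_equal_spacing(self):
        events = GaitEvents(heel_strikes_L=np.arange(0, 500, 100),
                            heel_strikes_R=np.arange(50, 500, 100))
        times = step_time(events, sample_rate=100.0)
        np.testing.assert_allclose(times["L"], 0.5)
        np.testing.assert_allclose(times["R"], 0.5)

    def test_non_alternating_contract_error(self):
        events = GaitEvents(heel_strikes_L=[0, 40, 100], heel_strikes_R=[150])
        with pytest.raises(EventContractError, match="alternate"):
            step_time(events, sample_rate=100.0)

    def test_detected_mean_matches_ground_truth(self, healthy_trial):
        trial, truth = healthy_trial
        detected = detect_heel_strikes(trial)
        t_det = step_time(detected, trial.sample_rate)
        t_ref = step_time(truth, trial.sample_rate)
        for side in ("L", "R"):
            assert np.mean(t_det[side]) == pytest.approx(np.mean(t_ref[side]), abs=0.01)

    def test_times_sum_to_elapsed_time(self, healthy_trial):
        trial, truth = healthy_trial
        times = step_time(truth, trial.sample_rate)
        idx, _ = truth.merged()
        total = np.sum(times["L"]) + np.sum(times["R"])
        assert total == pytest.approx((idx[-1] - idx[0]) / trial.sample_rate,
                                      abs=1.0 / trial.sample_rate)


class TestStepLength:
    def test_pure_belt_term(self):
        # identical AP at both strikes: length = belt_speed * step time
        events = GaitEvents(heel_strikes_L=[0], heel_strikes_R=[53])
        ap = np.full(100, 120.0)
        lengths = step_length(events, ap, ap, belt_speed=1.10, sample_rate=100.0)
        assert lengths["R"] == pytest.approx([1.10 * 0.53])
        assert lengths["R"][0] == pytest.approx(0.58, abs=0.005)

    def test_marker_advance_without_belt(self):
        events = GaitEvents(heel_strikes_L=[0], heel_strikes_R=[50])
        ap_L, ap_R = np.zeros(100), np.full(100, 100.0)
        lengths = step_length(events, ap_L, ap_R, belt_speed=0.0, sample_rate=100.0)
        assert lengths["R"] == pytest.approx([0.10])

    def test_negative_length_flagged_and_excluded(self):
        events = GaitEvents(heel_strikes_L=[0], heel_strikes_R=[50])
        ap_L, ap_R = np.zeros(100), np.full(100, -200.0)
        with pytest.warns(UserWarning, match="negative"):
            lengths = step_length(events, ap_L, ap_R, belt_speed=0.0, sample_rate=100.0)
        assert lengths["R"].size == 0

    def test_belt_term_identity(self, healthy_trial):
        # two belt speeds at which every step stays positive (no exclusions):
        # the per-step difference is exactly (v1 - v2) * step_time
        trial, truth = healthy_trial
        ap_L, ap_R = trial.channel("heel_L", "AP"), trial.channel("heel_R", "AP")
        fast = step_length(truth, ap_L, ap_R, 1.10, trial.sample_rate)
        slow = step_length(truth, ap_L, ap_R, 0.90, trial.sample_rate)
        times = step_time(truth, trial.sample_rate)
        for side in ("L", "R"):
            assert fast[side].size == times[side].size == slow[side].size
            np.testing.assert_allclose(
                fast[side] - slow[side], 0.20 * times[side], atol=1e-12)

    def test_negative_belt_rejected(self):
        events = GaitEvents(heel_strikes_L=[0], heel_strikes_R=[50])
        with pytest.raises(ConfigurationError):
            step_length(events, np.zeros(100), np.zeros(100), -1.0, 100.0)


class TestStepWidth:
    def test_fixed_offsets(self):
        events = GaitEvents(heel_strikes_L=[0, 100], heel_strikes_R=[50, 150])
        ml_L, ml_R = np.full(200, 80.0), np.full(200, -80.0)
        widths = step_width(events, ml_L, ml_R)
        np.testing.assert_allclose(np.concatenate([widths["L"], widths["R"]]), 0.16)

    def test_coincident_positions(self):
        events = GaitEvents(heel_strikes_L=[0], heel_strikes_R=[50])
        widths = step_width(events, np.zeros(100), np.zeros(100))
        assert widths["R"] == pytest.approx([0.0])

    def test_synthetic_width_matches_configuration(self, healthy_trial, healthy_config):
        trial, truth = healthy_trial
        widths = step_width(truth, trial.channel("heel_L", "ML"),
                            trial.channel("heel_R", "ML"))
        mean_width = np.mean(np.concatenate([widths["L"], widths["R"]]))
        assert mean_width == pytest.approx(healthy_config.step_width_mean, abs=0.01)


class TestSummaries:
    def test_constant_steps(self):
        vals = {"L": np.full(250, 0.58), "R": np.full(250, 0.58)}
        summary = summarize_first_n(vals, vals, vals, n=200)
        assert summary.step_time_mean["L"] == pytest.approx(0.58)
        assert summary.step_time_sd["L"] == 0.0
        assert summary.n_steps_used["L"] == 200

    def test_fewer_steps_warns_and_uses_all(self):
        vals = {"L": np.ones(150), "R": np.ones(150)}
        with pytest.warns(UserWarning, match="only 150"):
            summary = summarize_first_n(vals, vals, vals, n=200)
        assert summary.n_steps_used["L"] == 150
        assert summary.warnings

    def test_only_first_n_used(self):
        rng = np.random.default_rng(0)
        base = rng.random(300) + 0.5
        permuted = base.copy()
        permuted[200:] = permuted[200:][::-1]
        s1 = summarize_first_n({"L": base, "R": base}, {"L": base, "R": base},
                               {"L": base, "R": base}, n=200)
        s2 = summarize_first_n({"L": permuted, "R": permuted},
                               {"L": permuted, "R": permuted},
                               {"L": permuted, "R": permuted}, n=200)
        assert s1.step_length_mean == s2.step_length_mean
        assert s1.step_length_sd == s2.step_length_sd

    def test_empty_side_is_error(self):
        vals = {"L": np.array([]), "R": np.ones(5)}
        with pytest.raises(InsufficientDataError):
            summarize_first_n(vals, vals, vals)

    def test_full_summary_on_synthetic_trial(self, healthy_trial, healthy_config):
        trial, truth = healthy_trial
        summary = spatiotemporal_summary(trial, events=truth)
        step_time_expected = 1.0 / (2.0 * healthy_config.stride_freq)
        for side in ("L", "R"):
            assert summary.step_time_mean[side] == pytest.approx(step_time_expected, abs=0.01)
            assert 0.54 <= summary.step_length_mean[side] <= 0.65
            assert summary.step_width_mean[side] == pytest.approx(0.16, abs=0.01)
            assert summary.step_length_mean[side] > 0
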