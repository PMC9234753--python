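"""Cross-recurrence plots, radius calibration, diagonal-line statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from interlimb import (
    EmbeddingParams,
    RecurrencePlot,
    calibrate_radius,
    cross_recurrence,
    diagonal_histogram,
    embed,
    generate_random_pair,
    generate_sinusoid_pair,
    mean_line,
    percent_determinism,
    run_crqa,
)
from interlimb.exceptions import CalibrationError, ConfigurationError, NoLinesError
from interlimb.io import AnalysisConfig


def _histogram_oracle(R, min_line=2):
    """Exhaustive run-length scan over every diagonal, pure Python."""
    n_a, n_b = R.shape
    counts = {}
    for off in range(-(n_a - 1), n_b):
        run = 0
        cells = [(i, i + off) for i in range(n_a) if 0 <= i + off < n_b]
        for i, j in cells + [(-1, -1)]:  # sentinel flushes the last run
            if i >= 0 and R[i, j]:
                run += 1
            else:
                if run >= min_line:
                    counts[run] = counts.get(run, 0) + 1
                run = 0
    return counts


class TestCrossRecurrence:
    def test_identical_trajectories_have_recurrent_main_diagonal(self):
        traj = np.random.default_rng(0).standard_normal((40, 3))
        plot = cross_recurrence(traj, traj, radius=1e-9)
        assert np.all(np.diagonal(plot.R))

    def test_radius_at_max_distance_gives_full_plot(self):
        a = np.random.default_rng(1).standard_normal((20, 2))
        b = np.random.default_rng(2).standard_normal((25, 2))
        radius = cdist(a, b).max()
        plot = cross_recurrence(a, b, radius)
        assert plot.recurrence_rate == 100.0

    def test_toy_grid_matches_distance_oracle(self):
        a = np.array([[0, 0], [1, 0], [2, 1], [3, 3], [0, 2], [1, 1], [2, 2], [3, 0]], float)
        b = np.array([[0, 1], [1, 1], [2, 0], [3, 2], [1, 3], [2, 3], [0, 0], [3, 3]], float)
        radius = 1.5
        plot = cross_recurrence(a, b, radius)
        for i in range(8):
            for j in range(8):
                dist = np.hypot(*(a[i] - b[j]))
                assert plot.R[i, j] == (dist <= radius)

    def test_dimension_mismatch(self):
        with pytest.raises(ConfigurationError, match="dimensions differ"):
            cross_recurrence(np.zeros((5, 2)), np.zeros((5, 3)), 1.0)

    def test_swap_transposes_and_preserves_statistics(self, decimated_pair):
        p = EmbeddingParams(tau=3, emb=4)
        a, b = embed(decimated_pair[0], p), embed(decimated_pair[1], p)
        radius, _ = calibrate_radius(a, b)
        fwd, rev = cross_recurrence(a, b, radius), cross_recurrence(b, a, radius)
        np.testing.assert_array_equal(fwd.R, rev.R.T)
        hf, hr = diagonal_histogram(fwd), diagonal_histogram(rev)
        assert hf == hr
        assert fwd.recurrence_rate == rev.recurrence_rate
        assert percent_determinism(hf, fwd) == percent_determinism(hr, rev)
        assert mean_line(hf) == mean_line(hr)


class TestCalibrateRadius:
    def test_target_hundred_returns_max_distance(self):
        a = np.random.default_rng(3).standard_normal((15, 2))
        b = np.random.default_rng(4).standard_normal((15, 2))
        radius, rr = calibrate_radius(a, b, target_rr=100.0)
        assert radius == pytest.approx(cdist(a, b).max())
        assert rr == 100.0

    def test_toy_radius_lies_between_order_statistics(self):
        rng = np.random.default_rng(9)
        a, b = rng.standard_normal((10, 2)), rng.standard_normal((10, 2))
        target = 10.0  # k = 10 of 100 cells: exactly achievable
        radius, rr = calibrate_radius(a, b, target_rr=target)
        assert rr == pytest.approx(target)
        d_sorted = np.sort(cdist(a, b).ravel())
        k = round(target * 100 / 100.0)
        assert d_sorted[k - 1] <= radius < d_sorted[k]

    def test_unreachable_tolerance_reports_bracket(self):
        a = np.zeros((3, 1))
        b = np.array([[0.0], [0.0], [10.0]])
        # achievable rates are multiples of 1/9; 50% +/- 0.05 pp is not
        with pytest.raises(CalibrationError, match="bracket"):
            calibrate_radius(a, b, target_rr=50.0)

    def test_rr_monotone_in_radius(self, decimated_pair):
        p = EmbeddingParams(tau=3, emb=4)
        a, b = embed(decimated_pair[0][:400], p), embed(decimated_pair[1][:400], p)
        dmax = cdist(a, b).max()
        rates = [cross_recurrence(a, b, f * dmax).recurrence_rate
                 for f in (0.01, 0.05, 0.1, 0.25, 0.5, 1.0)]
        assert np.all(np.diff(rates) >= 0)


class TestDiagonalHistogram:
    def test_full_5x5_grid_combinatorics(self):
        plot = RecurrencePlot(R=np.ones((5, 5), bool), radius=1.0)
        assert diagonal_histogram(plot, min_line=2) == {2: 2, 3: 2, 4: 2, 5: 1}

    def test_empty_grid(self):
        plot = RecurrencePlot(R=np.zeros((4, 6), bool), radius=1.0)
        assert diagonal_histogram(plot) == {}

    def test_runs_below_min_line_excluded(self):
        R = np.zeros((8, 8), bool)
        R[0, 3] = True                      # length 1: dropped
        R[2, 0], R[3, 1] = True, True       # length 2
        for i in range(5):                  # length 5
            R[i + 3, i + 2] = True
        hist = diagonal_histogram(RecurrencePlot(R=R, radius=1.0), min_line=2)
        assert hist == {2: 1, 5: 1}
        assert min(hist) >= 2

    def test_random_grid_matches_run_length_oracle(self):
        rng = np.random.default_rng(12)
        R = rng.random((30, 30)) < 0.1
        plot = RecurrencePlot(R=R, radius=1.0)
        assert diagonal_histogram(plot, min_line=2) == _histogram_oracle(R, 2)

    @given(st.integers(0, 2**31 - 1), st.floats(0.05, 0.5))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_oracle_equivalence_property(self, seed, density):
        rng = np.random.default_rng(seed)
        R = rng.random((25, 20)) < density
        plot = RecurrencePlot(R=R, radius=1.0)
        assert diagonal_histogram(plot) == _histogram_oracle(R)


class TestLineStatistics:
    def test_mean_line_full_grid_case(self):
        assert mean_line({2: 2, 3: 2, 4: 2, 5: 1}) == pytest.approx(23 / 7)

    def test_single_line(self):
        assert mean_line({7: 1}) == 7.0

    def test_empty_histogram_is_error(self):
        with pytest.raises(NoLinesError):
            mean_line({})

    def test_isolated_points_give_zero_determinism(self):
        R = np.zeros((6, 6), bool)
        R[0, 2], R[3, 0], R[5, 5] = True, True, True
        plot = RecurrencePlot(R=R, radius=1.0)
        assert percent_determinism(diagonal_histogram(plot), plot) == 0.0

    def test_empty_plot_is_error(self):
        plot = RecurrencePlot(R=np.zeros((3, 3), bool), radius=1.0)
        with pytest.raises(NoLinesError):
            percent_determinism({}, plot)

    def test_small_fixture_exact_oracle_statistics(self):
        # <=50-point embedded fixtures: %DET and MeanL equal the exhaustive
        # run-length oracle exactly
        rng = np.random.default_rng(21)
        a = rng.standard_normal((48, 3))
        b = rng.standard_normal((50, 3))
        plot = cross_recurrence(a, b, radius=1.8)
        hist = diagonal_histogram(plot)
        oracle = _histogram_oracle(plot.R)
        assert hist == oracle
        on_lines = sum(l * c for l, c in oracle.items())
        assert percent_determinism(hist, plot) == pytest.approx(
            100.0 * on_lines / plot.R.sum())
        assert mean_line(hist) == pytest.approx(on_lines / sum(oracle.values()))


class TestRunCRQA:
    def test_healthy_trial_pipeline(self, healthy_trial, analysis_config):
        trial, _ = healthy_trial
        res = run_crqa(trial.channel("heel_L", "AP"), trial.channel("heel_R", "AP"),
                       analysis_config)
        assert res.recurrence_rate == pytest.approx(2.5, abs=0.05)
        assert 3 <= res.tau <= 4
        assert 4 <= res.emb <= 6
        assert 0 <= res.percent_determinism <= 100
        assert res.mean_line >= analysis_config.min_line
        assert res.n_points[0] == 1200 - (res.emb - 1) * res.tau

    def test_random_pair_less_coordinated_than_gait(self, healthy_trial, analysis_config):
        trial, _ = healthy_trial
        gait = run_crqa(trial.channel("heel_L", "AP"), trial.channel("heel_R", "AP"),
                        analysis_config)
        ra, rb = generate_random_pair(1200, 7)
        cfg = AnalysisConfig(analysis_samples=None, decimation_factor=1)
        with pytest.warns(UserWarning):  # FNN does not converge on white noise
            rand = run_crqa(ra, rb, cfg)
        assert rand.mean_line < gait.mean_line
        assert rand.percent_determinism < gait.percent_determinism

    def test_deterministic_pair_highly_coordinated(self, deterministic_trial,
                                                   healthy_trial, analysis_config):
        det_trial, _ = deterministic_trial
        res = run_crqa(det_trial.channel("heel_L", "AP"),
                       det_trial.channel("heel_R", "AP"), analysis_config)
        trial, _ = healthy_trial
        noisy = run_crqa(trial.channel("heel_L", "AP"),
                         trial.channel("heel_R", "AP"), analysis_config)
        assert res.mean_line <= max(res.n_points)
        assert res.mean_line > noisy.mean_line

    def test_identical_sinusoid_pair_fully_deterministic_at_moderate_radius(self):
        # distance-threshold edges at very sparse RR leave isolated cells;
        # at a moderate radius every recurrence lies on a diagonal line
        a, b = generate_sinusoid_pair(0.86, 0.0, 1200, 10.0)
        p = EmbeddingParams(tau=3, emb=2)
        ta, tb = embed(a, p), embed(b, p)
        plot = cross_recurrence(ta, tb, 0.1 * cdist(ta, tb).max())
        det = percent_determinism(diagonal_histogram(plot), plot)
        assert det > 99.9

    def test_length_mismatch_rejected(self, analysis_config):
        with pytest.raises(ConfigurationError):
            run_crqa(np.zeros(100), np.zeros(101), analysis_config)
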