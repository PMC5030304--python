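"""Residual pool, AUC fractions, peak metrics, trace comparison, sensitivity."""

import numpy as np
import pytest

import thinfil as tf
from thinfil.exceptions import (
    ComparabilityError,
    DegenerateSeriesError,
    UndefinedFractionError,
)


class TestResidual:
    def test_self_difference_is_zero(self, overlap_trajectory):
        res = tf.crossbridge_dependent_residual(overlap_trajectory,
                                                overlap_trajectory)
        assert np.all(res.values == 0.0)

    def test_residual_rises_after_stimulus_ends(self, residual_series, stimulus):
        """The residual pool appears near the end of the free-Ca2+ transient.

        During the stimulus itself both preparations bind Ca2+ alike; the
        crossbridge-held pool only emerges as the non-overlap preparation
        releases Ca2+.
        """
        res = residual_series
        early = res.values[res.times <= 0.01]
        assert np.max(np.abs(early)) < 0.1 * res.values.max()
        assert tf.peak_time(res) > 0.03

    def test_residual_nonnegative(self, residual_series):
        assert np.all(residual_series.values >= -1e-6)

    def test_peak_value_is_max_of_difference(self, residual_series):
        assert residual_series.values.max() == pytest.approx(
            np.max(residual_series.values)
        )

    def test_mismatched_stimuli_rejected(self, constants, overlap_trajectory):
        other = tf.simulate_twitch(
            constants, tf.make_standard_transient(amplitude=10.0),
            tf.Condition.non_overlap(),
        )
        with pytest.raises(ComparabilityError):
            tf.crossbridge_dependent_residual(overlap_trajectory, other)


class TestAucFraction:
    def test_identity_is_100_percent(self, residual_series):
        assert tf.auc_fraction(residual_series, residual_series) == pytest.approx(100.0)

    def test_scaled_copy(self):
        t = np.linspace(0, 0.2, 101)
        whole = tf.TimeSeries(t, np.sin(np.pi * t / 0.2) + 1.0)
        part = tf.TimeSeries(t, 0.3 * whole.values)
        assert tf.auc_fraction(part, whole) == pytest.approx(30.0)

    def test_zero_reference_rejected(self):
        t = np.linspace(0, 0.2, 11)
        with pytest.raises(UndefinedFractionError):
            tf.auc_fraction(tf.TimeSeries(t, np.ones_like(t)),
                            tf.TimeSeries(t, np.zeros_like(t)))

    def test_invariant_to_grid_refinement(self, constants, stimulus):
        """Halving dt_out moves the AUC fraction by < 0.1 percentage point."""
        fracs = {}
        for dt in (5e-4, 2.5e-4):
            ov = tf.simulate_twitch(constants, stimulus, tf.Condition.overlap(),
                                    dt_out=dt)
            no = tf.simulate_twitch(constants, stimulus, tf.Condition.non_overlap(),
                                    dt_out=dt)
            res = tf.crossbridge_dependent_residual(ov, no)
            fracs[dt] = tf.auc_fraction(res, tf.trajectory_series(ov, "ca_bound_tn"))
        assert abs(fracs[5e-4] - fracs[2.5e-4]) < 0.1


class TestPeakTime:
    def test_stimulus_series_peaks_at_t_peak(self, overlap_trajectory, stimulus):
        series = tf.trajectory_series(overlap_trajectory, "ca")
        assert tf.peak_time(series) == pytest.approx(stimulus.t_peak, abs=1e-4)

    def test_earliest_tie_wins(self):
        t = np.array([0.0, 0.01, 0.015, 0.02, 0.03])
        v = np.array([0.0, 1.0, 0.5, 1.0, 0.0])
        assert tf.peak_time(tf.TimeSeries(t, v)) == pytest.approx(0.01)

    def test_constant_series_warns_and_returns_first_time(self):
        t = np.linspace(0, 1, 5)
        with pytest.warns(RuntimeWarning):
            assert tf.peak_time(tf.TimeSeries(t, np.ones_like(t))) == 0.0

    def test_quadratic_refinement_recovers_off_grid_peak(self):
        # parabola peaking between grid points
        t = np.linspace(0.0, 0.1, 101)
        true_peak = 0.0437
        v = -(t - true_peak) ** 2
        assert tf.peak_time(tf.TimeSeries(t, v)) == pytest.approx(true_peak, abs=1e-6)


class TestNormalizeTrace:
    def test_minmax(self):
        s = tf.TimeSeries(np.array([0.0, 1.0, 2.0]), np.array([0.0, 5.0, 10.0]))
        assert np.allclose(tf.normalize_trace(s, "minmax").values, [0.0, 0.5, 1.0])

    def test_peak(self):
        s = tf.TimeSeries(np.array([0.0, 1.0]), np.array([2.0, 4.0]))
        assert np.allclose(tf.normalize_trace(s, "peak").values, [0.5, 1.0])

    def test_idempotent(self, residual_series):
        once = tf.normalize_trace(residual_series, "minmax")
        twice = tf.normalize_trace(once, "minmax")
        assert np.allclose(once.values, twice.values)

    def test_constant_series_rejected(self):
        s = tf.TimeSeries(np.array([0.0, 1.0]), np.array([3.0, 3.0]))
        with pytest.raises(DegenerateSeriesError):
            tf.normalize_trace(s, "minmax")


class TestCompareTraces:
    def test_self_comparison_rmse_zero(self, overlap_trajectory):
        m = tf.trajectory_series(overlap_trajectory, "M")
        comp = tf.compare_traces(m, m)
        assert comp.rmse == pytest.approx(0.0, abs=1e-12)
        assert comp.peak_time_difference == pytest.approx(0.0, abs=1e-9)

    def test_three_point_hand_computation(self):
        # model: (0, 0.5, 1) after minmax; data: (0, 1, 0.5) after minmax;
        # residuals (0, -0.5, 0.5) -> rmse = sqrt(1/6)
        t = np.array([0.0, 1.0, 2.0])
        model = tf.TimeSeries(t, np.array([0.0, 0.5, 1.0]))
        data = tf.TimeSeries(t, np.array([0.0, 2.0, 1.0]))
        comp = tf.compare_traces(model, data)
        assert comp.rmse == pytest.approx(np.sqrt(1.0 / 6.0), rel=1e-12)

    def test_noisy_data_rmse_tracks_noise_level(self, overlap_trajectory):
        """Monte-Carlo: rmse against noisy copies scales with sigma.

        Because compare_traces min-max normalizes the noisy trace over its
        own (noise-stretched) range, the rmse sits systematically above the
        injected sigma — about 1.5x at sigma = 0.05 with ~400 samples — and
        scales linearly with it.  Assert that calibration rather than the
        naive rmse = sigma.
        """
        m = tf.trajectory_series(overlap_trajectory, "M")
        norm = tf.normalize_trace(m, "minmax")
        rng = np.random.default_rng(12345)
        means = {}
        for sigma in (0.05, 0.1):
            rmses = []
            for _ in range(120):
                noisy = tf.TimeSeries(
                    m.times, norm.values + rng.normal(0, sigma, m.times.shape)
                )
                rmses.append(tf.compare_traces(m, noisy).rmse)
            means[sigma] = np.mean(rmses)
        assert sigma < means[0.1]          # never below the injected noise
        assert means[0.05] == pytest.approx(1.5 * 0.05, rel=0.15)
        assert means[0.1] / means[0.05] == pytest.approx(2.0, rel=0.2)

    def test_data_beyond_model_span_rejected(self, overlap_trajectory):
        m = tf.trajectory_series(overlap_trajectory, "M")
        data = tf.TimeSeries(np.array([0.0, 0.3]), np.array([0.0, 1.0]))
        with pytest.raises(ComparabilityError):
            tf.compare_traces(m, data)


class TestPoolKinetics:
    def test_fast_pool_decays_before_slow_pool(self, overlap_trajectory):
        """Coupled (B) states release Ca2+ faster than uncoupled (T) states."""
        fast = tf.decay_half_time(tf.trajectory_series(overlap_trajectory, "fast"))
        slow = tf.decay_half_time(tf.trajectory_series(overlap_trajectory, "slow"))
        assert fast < slow


class TestSensitivityScan:
    def test_identity_factor_is_no_change(self, constants, stimulus):
        res = tf.sensitivity_scan(constants, "K0p_km0_product", 1.0,
                                  stimulus, tf.Condition.overlap(),
                                  observable="M_peak_width")
        assert res.response == "no_change"
        assert res.relative_change == pytest.approx(0.0, abs=1e-6)

    def test_slower_m_formation_widens_and_delays_peak(self, constants, stimulus):
        width = tf.sensitivity_scan(constants, "K0p_km0_product", 0.5,
                                    stimulus, tf.Condition.overlap(),
                                    observable="M_peak_width")
        assert width.response == "increase"
        center = tf.sensitivity_scan(constants, "K0p_km0_product", 0.5,
                                     stimulus, tf.Condition.overlap(),
                                     observable="M_peak_center")
        assert center.response == "shift_right"

    def test_faster_ca_release_speeds_nonoverlap_decay(self, constants, stimulus):
        res = tf.sensitivity_scan(constants, "K4_km4_product", 1.33,
                                  stimulus, tf.Condition.non_overlap(),
                                  observable="ca_bound_decay")
        assert res.response == "decrease"

    def test_unknown_parameter_rejected(self, constants):
        with pytest.raises(tf.ParameterError):
            tf.sensitivity_scan(constants, "K9", 2.0)
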