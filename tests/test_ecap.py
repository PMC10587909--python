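"""Epoching, median averaging, conduction-velocity windows, detrending,
RMS magnitude, and propagation-delay authenticity checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecaptools import (
    ECAPTrace,
    ElectrodeSpec,
    StimulationTrain,
    TimeSeriesRecording,
    apply_velocity_tolerance,
    detrend_exponential,
    ecap_rms,
    epoch_align,
    equalize_windows,
    estimate_propagation_velocity,
    fiber_window,
    median_average,
)
from ecaptools.ecap import EpochSet

FS = 25_000.0


def _trace(voltage, dt_ms=0.04, **kw):
    voltage = np.asarray(voltage, dtype=float)
    return ECAPTrace(voltage, np.arange(voltage.size) * dt_ms, n_averaged=1, **kw)


class TestEpochAlign:
    def test_750_pulses_give_750_epochs_of_250_samples(self):
        rec = TimeSeriesRecording(np.zeros((1, int(30.2 * FS))), FS,
                                  [ElectrodeSpec(id="e0")])
        train = StimulationTrain.regular(25.0, 30.0, 1.5)
        sets = epoch_align(rec, train, epoch_length_ms=10.0)
        assert sets[0].epochs.shape == (750, 250)

    def test_zero_pulses_is_empty_not_error(self):
        rec = TimeSeriesRecording(np.zeros((1, 1000)), FS, [ElectrodeSpec(id="e0")])
        train = StimulationTrain(np.empty(0), amplitude_ma=1.0)
        assert epoch_align(rec, train)[0].n_epochs == 0

    def test_constant_recording_gives_identical_epochs(self):
        rec = TimeSeriesRecording(np.full((1, int(2 * FS)), 3.3), FS,
                                  [ElectrodeSpec(id="e0")])
        train = StimulationTrain.regular(25.0, 1.0, 1.0)
        es = epoch_align(rec, train)[0]
        assert np.all(es.epochs == 3.3)

    def test_pulse_beyond_recording_rejected_with_indices(self):
        rec = TimeSeriesRecording(np.zeros((1, int(0.5 * FS))), FS,
                                  [ElectrodeSpec(id="e0")])
        train = StimulationTrain.regular(25.0, 1.0, 1.0)
        with pytest.raises(ValueError, match="beyond the recording"):
            epoch_align(rec, train)


class TestMedianAverage:
    def test_identical_epochs_returned_exactly(self):
        e = np.tile(np.sin(np.arange(100)), (5, 1))
        es = EpochSet(e, np.arange(100) / FS * 1e3, 1.0)
        assert np.array_equal(median_average(es).voltage_uv, e[0])

    def test_outlier_robustness(self):
        e = np.array([[1.0], [2.0], [100.0]])
        es = EpochSet(e, np.zeros(1), 1.0)
        assert median_average(es).voltage_uv[0] == 2.0

    def test_permutation_invariance(self, rng):
        e = rng.standard_normal((21, 50))
        es1 = EpochSet(e, np.arange(50.0), 1.0)
        es2 = EpochSet(e[rng.permutation(21)], np.arange(50.0), 1.0)
        assert np.array_equal(median_average(es1).voltage_uv,
                              median_average(es2).voltage_uv)

    def test_median_noise_efficiency(self, rng):
        """Point-wise median of n=750 Gaussian sweeps has RMS
        ~ sigma * sqrt(pi/(2n)) (Monte-Carlo oracle)."""
        sigma, n = 2.53, 750
        rms = []
        for _ in range(30):
            es = EpochSet(rng.normal(0, sigma, (n, 250)),
                          np.arange(250) / FS * 1e3, 0.0)
            tr = median_average(es)
            rms.append(np.sqrt(np.mean(tr.voltage_uv**2)))
        expected = sigma * np.sqrt(np.pi / (2 * n))
        assert np.mean(rms) == pytest.approx(expected, rel=0.10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_average(EpochSet(np.empty((0, 10)), np.arange(10.0), 1.0))


class TestFiberWindow:
    def test_abeta_window_at_5_cm(self):
        w = fiber_window(0.05, "Abeta")
        assert w.window_ms[0] == pytest.approx(0.714, abs=1e-3)
        assert w.window_ms[1] == pytest.approx(1.667, abs=1e-3)

    def test_b_window_at_5_cm(self):
        w = fiber_window(0.05, "B")
        assert w.window_ms[0] == pytest.approx(3.333, abs=1e-3)
        assert w.window_ms[1] == pytest.approx(16.667, abs=1e-3)

    def test_brute_force_velocity_grid_oracle(self):
        """Window bounds equal the min/max arrival time over a dense
        velocity grid."""
        d, (v_min, v_max) = 0.073, (30.0, 70.0)
        grid = np.linspace(v_min, v_max, 10_001)
        arrivals = d / grid * 1000.0
        w = fiber_window(d, "Abeta")
        assert w.window_ms[0] == pytest.approx(arrivals.min(), rel=1e-9)
        assert w.window_ms[1] == pytest.approx(arrivals.max(), rel=1e-9)

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(st.floats(0.01, 0.5), st.floats(1.2, 10.0))
    def test_scaling_distance_scales_both_bounds(self, d, factor):
        w1 = fiber_window(d, "Abeta")
        w2 = fiber_window(d * factor, "Abeta")
        assert w2.window_ms[0] == pytest.approx(w1.window_ms[0] * factor, rel=1e-9)
        assert w2.window_ms[1] == pytest.approx(w1.window_ms[1] * factor, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fiber_window(-0.05, "Abeta")
        with pytest.raises(ValueError):
            fiber_window(0.05, "Abeta", velocity_range=(70.0, 30.0))


class TestVelocityTolerance:
    def _trace_with_deflection(self, span_ms, n_ms=10.0, amp=10.0):
        n = int(n_ms * 1e-3 * FS)
        v = np.zeros(n)
        tb = np.arange(n) / FS * 1e3
        mask = (tb >= span_ms[0]) & (tb < span_ms[1])
        v[mask] = amp
        return ECAPTrace(v, tb, n_averaged=1)

    def test_contained_ecap_leaves_window_unchanged(self):
        w = fiber_window(0.05, "Abeta")
        tr = self._trace_with_deflection((0.9, 1.4))
        out = apply_velocity_tolerance(w, tr, noise_rms_uv=0.1)
        assert out.tolerance_applied == 0.0
        assert out.window_ms == w.window_ms

    def test_truncated_tail_widens_end_at_most_20_percent(self):
        w = fiber_window(0.05, "Abeta")
        tr = self._trace_with_deflection((1.5, 1.9))
        out = apply_velocity_tolerance(w, tr, noise_rms_uv=0.1)
        assert out.tolerance_applied > 0.0
        assert out.tolerance_applied <= 0.20 + 1e-12
        # deflection now contained; bound never beyond d / (0.8 v_min)
        assert out.window_ms[1] >= 1.9
        assert out.window_ms[1] <= 0.05 / (30.0 * 0.8) * 1000.0 + 1e-9

    def test_flat_trace_unchanged(self):
        w = fiber_window(0.05, "Abeta")
        tr = self._trace_with_deflection((2.0, 2.0), amp=0.0)
        out = apply_velocity_tolerance(w, tr)
        assert out.tolerance_applied == 0.0


class TestEqualizeWindows:
    def _channel(self, span_ms, d=0.05):
        w = fiber_window(d, "Abeta")
        n = int(10e-3 * FS)
        tb = np.arange(n) / FS * 1e3
        v = np.zeros(n)
        if span_ms is not None:
            v[(tb >= span_ms[0]) & (tb < span_ms[1])] = 10.0
        return w, ECAPTrace(v, tb, n_averaged=1)

    def test_common_duration_is_max_of_supports(self):
        w1, t1 = self._channel((0.9, 1.5))   # 0.6 ms support
        w2, t2 = self._channel((1.0, 1.4))   # 0.4 ms support
        out = equalize_windows([w1, w2], [t1, t2], noise_rms_uv=[0.1, 0.1])
        assert out[0].duration_ms == pytest.approx(out[1].duration_ms)
        assert out[0].duration_ms == pytest.approx(0.6, abs=0.1)

    def test_supports_remain_contained(self):
        w1, t1 = self._channel((0.9, 1.5))
        w2, t2 = self._channel((1.0, 1.4))
        out = equalize_windows([w1, w2], [t1, t2], noise_rms_uv=[0.1, 0.1])
        for w_out, tr in zip(out, (t1, t2)):
            supra = tr.time_base_ms[np.abs(tr.voltage_uv) > 0.3]
            assert w_out.window_ms[0] <= supra.min()
            assert w_out.window_ms[1] >= supra.max()

    def test_signal_free_channels_use_min_duration_centered(self):
        w1, t1 = self._channel(None, d=0.05)
        w2, t2 = self._channel(None, d=0.08)
        out = equalize_windows([w1, w2], [t1, t2], noise_rms_uv=[0.1, 0.1])
        min_dur = min(w1.duration_ms, w2.duration_ms)
        for w_in, w_out in zip([w1, w2], out):
            assert w_out.duration_ms == pytest.approx(min_dur)
            assert w_out.window_ms[0] >= w_in.window_ms[0] - 1e-9
            assert w_out.window_ms[1] <= w_in.window_ms[1] + 1e-9

    def test_single_channel_rejected(self):
        w, t = self._channel((1.0, 1.2))
        with pytest.raises(ValueError):
            equalize_windows([w], [t])


class TestDetrendExponential:
    def _exp_trace(self, A=50.0, b=0.8, c=0.0, n_ms=10.0):
        n = int(n_ms * 1e-3 * FS)
        tb = np.arange(n) / FS * 1e3
        return tb, A * np.exp(-b * (tb + c))

    def test_pure_exponential_removed(self):
        tb, y = self._exp_trace()
        tr = ECAPTrace(y, tb, n_averaged=1)
        out, fit = detrend_exponential(tr)
        assert fit.converged
        mask = ((tb >= 2.2) & (tb < 2.4)) | ((tb >= 5.8) & (tb < 6.0))
        assert np.sqrt(np.mean(out.voltage_uv[mask] ** 2)) < 1e-6

    def test_ecap_preserved_after_detrending(self):
        tb, y = self._exp_trace()
        ecap = np.zeros_like(y)
        mask = (tb >= 3.0) & (tb < 4.0)
        ecap[mask] = 5.0 * np.sin(2 * np.pi * (tb[mask] - 3.0))
        tr = ECAPTrace(y + ecap, tb, n_averaged=1)
        out, fit = detrend_exponential(tr)
        assert fit.converged
        err = out.voltage_uv[mask] - ecap[mask]
        assert np.sqrt(np.mean(err**2)) < 0.01 * np.sqrt(np.mean(ecap[mask] ** 2))

    def test_zero_trace_fits_zero_amplitude(self):
        tb = np.arange(int(10e-3 * FS)) / FS * 1e3
        tr = ECAPTrace(np.zeros_like(tb), tb, n_averaged=1)
        out, fit = detrend_exponential(tr)
        assert np.allclose(out.voltage_uv, 0.0, atol=1e-9)

    def test_trace_not_covering_windows_rejected(self):
        tb = np.arange(int(3e-3 * FS)) / FS * 1e3  # ends at 3 ms
        with pytest.raises(ValueError, match="fit windows"):
            detrend_exponential(ECAPTrace(np.zeros_like(tb), tb, n_averaged=1))


class TestEcapRms:
    def _window(self):
        return fiber_window(0.05, "Abeta")

    def test_constant_one(self):
        tr = _trace(np.ones(250))
        assert ecap_rms(tr, self._window()).rms_uv == pytest.approx(1.0)

    def test_full_cycle_sine(self):
        n = int(10e-3 * FS)
        tb = np.arange(n) / FS * 1e3
        w = self._window()
        v = np.sin(2 * np.pi * (tb - w.window_ms[0]) / (w.window_ms[1] - w.window_ms[0]))
        got = ecap_rms(ECAPTrace(v, tb, n_averaged=1), w).rms_uv
        assert got == pytest.approx(1 / np.sqrt(2), rel=0.01)

    def test_zero_trace(self):
        assert ecap_rms(_trace(np.zeros(250)), self._window()).rms_uv == 0.0

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(st.floats(0.01, 100.0))
    def test_scales_linearly_and_reversal_invariant(self, scale):
        rng = np.random.default_rng(7)
        v = rng.standard_normal(250)
        w = self._window()
        base = ecap_rms(_trace(v), w).rms_uv
        assert ecap_rms(_trace(scale * v), w).rms_uv == pytest.approx(
            scale * base, rel=1e-9
        )
        sl = _trace(v).window_slice(*w.window_ms)
        rev = v.copy()
        rev[sl] = rev[sl][::-1]
        assert ecap_rms(_trace(rev), w).rms_uv == pytest.approx(base, rel=1e-9)


class TestPropagationVelocity:
    def _trace_at(self, distance_m, latency_ms, n_ms=10.0, jitter_samples=0):
        n = int(n_ms * 1e-3 * FS)
        tb = np.arange(n) / FS * 1e3
        v = np.zeros(n)
        i = int(round(latency_ms * 1e-3 * FS)) + jitter_samples
        v[i] = -10.0
        v[i + 5] = 10.0
        ch = ElectrodeSpec(id=f"d{distance_m}", distance_to_stim_m=distance_m)
        return ECAPTrace(v, tb, n_averaged=1, channel=ch)

    def test_recovers_50_m_per_s(self):
        traces = [self._trace_at(0.05, 1.0), self._trace_at(0.08, 1.6)]
        v, authentic = estimate_propagation_velocity(traces, fiber_range=(30, 70))
        assert v == pytest.approx(50.0, rel=0.04)  # one-sample quantization
        assert authentic

    def test_zero_delay_artifact_flagged(self):
        traces = [self._trace_at(0.05, 1.2), self._trace_at(0.08, 1.2)]
        v, authentic = estimate_propagation_velocity(traces, fiber_range=(30, 70))
        assert not np.isfinite(v)
        assert not authentic

    def test_three_points_with_jitter(self):
        rng = np.random.default_rng(3)
        traces = [
            self._trace_at(d, d / 50.0 * 1e3, jitter_samples=int(rng.integers(-1, 2)))
            for d in (0.05, 0.08, 0.11)
        ]
        v, authentic = estimate_propagation_velocity(traces, fiber_range=(30, 70))
        assert v == pytest.approx(50.0, rel=0.10)
        assert authentic

    def test_single_trace_rejected(self):
        with pytest.raises(ValueError):
            estimate_propagation_velocity([self._trace_at(0.05, 1.0)])
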