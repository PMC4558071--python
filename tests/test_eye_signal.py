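"""Smoothing, velocity estimation and saccade-landmark detection."""

import numpy as np
import pytest

import sacpupil as sp
from sacpupil.eye_signal import GazeTrace, hanning_kernel

from conftest import make_trial_meta


def _trace(x, y=None, t0=0):
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    t = t0 + np.arange(len(x))
    return GazeTrace(t=t, x=x, y=y, pupil=np.full(len(x), 1000.0))


class TestSmoothing:
    def test_constant_trace_unchanged(self):
        tr = _trace(np.full(100, 5.0))
        out = sp.smooth_position(tr, 11)
        np.testing.assert_allclose(out.x, 5.0, atol=1e-12)

    @pytest.mark.parametrize("width", [3, 5, 11, 21])
    def test_kernel_unit_sum(self, width):
        assert hanning_kernel(width).sum() == pytest.approx(1.0, abs=1e-12)

    def test_impulse_yields_hanning_shape(self):
        x = np.zeros(101)
        x[50] = 1.0
        out = sp.smooth_position(_trace(x), 11)
        np.testing.assert_allclose(out.x[45:56], hanning_kernel(11), atol=1e-12)

    def test_window_longer_than_trace_errors(self):
        with pytest.raises(ValueError, match="longer"):
            sp.smooth_position(_trace(np.zeros(5)), 11)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            sp.smooth_position(_trace(np.zeros(50)), 10)


class TestVelocity:
    def test_linear_ramp(self):
        # x advances 0.4 deg per ms -> 400 deg/s everywhere
        tr = _trace(0.4 * np.arange(50))
        vx, vy = sp.compute_velocity(tr)
        np.testing.assert_allclose(vx, 400.0, rtol=1e-9)
        np.testing.assert_allclose(vy, 0.0, atol=1e-9)

    def test_stationary(self):
        vx, vy = sp.compute_velocity(_trace(np.full(30, 2.0)))
        np.testing.assert_allclose(vx, 0.0, atol=1e-12)

    def test_sinusoid_matches_analytic_derivative(self):
        t_ms = np.arange(1000)
        f = 5.0  # Hz
        x = np.sin(2 * np.pi * f * t_ms / 1000.0)
        vx, _ = sp.compute_velocity(_trace(x))
        expected = 2 * np.pi * f * np.cos(2 * np.pi * f * t_ms / 1000.0)
        interior = slice(5, -5)
        scale = 2 * np.pi * f  # peak of the true derivative
        np.testing.assert_allclose(vx[interior], expected[interior],
                                   atol=0.01 * scale)

    def test_nonuniform_sampling_rejected(self):
        tr = _trace(np.zeros(10))
        tr.t = np.array([0, 1, 2, 4, 5, 6, 7, 8, 9, 10])
        with pytest.raises(ValueError, match="non-uniform"):
            sp.compute_velocity(tr)


class TestPeaks:
    def test_componentwise_max(self):
        vx = np.array([0.0, 400.0, 0.0])
        vy = np.array([120.0, 0.0, 0.0])
        assert sp.peak_velocity(vx, vy) == pytest.approx(400.0)

    def test_all_masked_is_undeterminable(self):
        v = np.zeros(5)
        assert sp.peak_velocity(v, v, valid=np.zeros(5, bool)) is None

    def test_peak_at_least_each_axis(self, rng):
        vx, vy = rng.normal(size=100), rng.normal(size=100)
        pk = sp.peak_velocity(vx, vy)
        assert pk >= np.max(np.abs(vx)) - 1e-12
        assert pk >= np.max(np.abs(vy)) - 1e-12
        assert pk == pytest.approx(max(np.max(np.abs(vx)), np.max(np.abs(vy))))

    def test_time_reversal_invariance(self, rng):
        vx, vy = rng.normal(size=64), rng.normal(size=64)
        assert sp.peak_velocity(vx, vy) == sp.peak_velocity(vx[::-1], vy[::-1])
        assert (sp.orthogonal_velocity(vx, vy, "vertical")
                == sp.orthogonal_velocity(vx[::-1], vy[::-1], "vertical"))

    def test_orthogonal_straight_saccade_is_zero(self):
        vx = np.array([0.0, 300.0, 0.0])
        vy = np.zeros(3)
        assert sp.orthogonal_velocity(vx, vy, "horizontal") == pytest.approx(0.0)

    def test_orthogonal_sign_invariance(self):
        vx = np.array([10.0, -150.0, 30.0])
        vy = np.zeros(3)
        up = sp.orthogonal_velocity(vx, vy, "vertical")
        down = sp.orthogonal_velocity(-vx, vy, "vertical")
        assert up == down == pytest.approx(150.0)


class TestSimulatedSaccades:
    """Detection checked against the generator's programmed ground truth."""

    @pytest.mark.parametrize("direction,peak", [("right", 430.0), ("up", 380.0)])
    def test_programmed_peak_recovered(self, direction, peak):
        trial = sp.simulate_trial("p0", 0, direction, "no_percept",
                                  peak_velocity=peak, curvature=0.0,
                                  latency_ms=150.0, baseline=1200.0,
                                  cond_amp=0.0,
                                  cfg=sp.SimConfig(gaze_noise_deg=0.0,
                                                   noise_sd=0.0, blink_rate=0.0),
                                  rng=np.random.default_rng(0))
        sm = sp.smooth_position(trial.trace, 11)
        vx, vy = sp.compute_velocity(sm)
        measured = sp.peak_velocity(vx, vy, sm.valid)
        assert measured == pytest.approx(peak, rel=0.01)

    def test_curved_saccade_orthogonal_peak(self):
        trial = sp.simulate_trial("p0", 0, "up", "no_percept",
                                  peak_velocity=400.0, curvature=150.0,
                                  latency_ms=150.0, baseline=1200.0,
                                  cond_amp=0.0,
                                  cfg=sp.SimConfig(gaze_noise_deg=0.0,
                                                   noise_sd=0.0, blink_rate=0.0),
                                  rng=np.random.default_rng(0))
        sm = sp.smooth_position(trial.trace, 11)
        vx, vy = sp.compute_velocity(sm)
        ov = sp.orthogonal_velocity(vx, vy, "vertical", sm.valid)
        assert ov == pytest.approx(150.0, rel=0.01)

    def test_mid_saccade_at_profile_midpoint(self):
        # symmetric profile from -8.5 to +8.5: crossing at onset + D/2
        cfg = sp.SimConfig(gaze_noise_deg=0.0, noise_sd=0.0, blink_rate=0.0)
        trial = sp.simulate_trial("p0", 0, "right", "no_percept",
                                  peak_velocity=400.0, curvature=0.0,
                                  latency_ms=200.0, baseline=1200.0,
                                  cond_amp=0.0, cfg=cfg,
                                  rng=np.random.default_rng(0))
        sm = sp.smooth_position(trial.trace, 11)
        vx, vy = sp.compute_velocity(sm)
        ev = sp.detect_saccade(sm, trial.meta, vx, vy)
        dur = 2000.0 * 17.0 / 400.0
        expected_mid = cfg.cue_onset_ms + 200.0 + dur / 2.0
        assert ev.mid_saccade_t == pytest.approx(expected_mid, abs=1.0)
        assert ev.onset <= ev.mid_saccade_t
        assert ev.latency == pytest.approx(200.0, abs=15.0)

    def test_displacement_integrates_to_amplitude(self):
        seg = sp.simulate_saccade(17.0, "right", 400.0)
        v = np.gradient(seg.x, 0.001)
        assert np.trapezoid(v, dx=0.001) == pytest.approx(17.0, rel=0.01)

    def test_pinned_trace_raises_no_saccade(self):
        n = 3000
        tr = GazeTrace(t=np.arange(n), x=np.full(n, -8.5), y=np.zeros(n),
                       pupil=np.full(n, 1000.0))
        vx, vy = sp.compute_velocity(tr)
        with pytest.raises(sp.SaccadeError, match="no saccade"):
            sp.detect_saccade(tr, make_trial_meta("right"), vx, vy)

    def test_crossing_before_cue_gives_negative_latency(self):
        trial = sp.simulate_trial("p0", 0, "right", "no_percept",
                                  peak_velocity=400.0, curvature=0.0,
                                  latency_ms=0.0, baseline=1200.0,
                                  cond_amp=0.0,
                                  cfg=sp.SimConfig(gaze_noise_deg=0.0,
                                                   noise_sd=0.0, blink_rate=0.0),
                                  rng=np.random.default_rng(0),
                                  violation="anticipation")
        sm = sp.smooth_position(trial.trace, 11)
        vx, vy = sp.compute_velocity(sm)
        ev = sp.detect_saccade(sm, trial.meta, vx, vy)
        assert ev.latency < 0
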