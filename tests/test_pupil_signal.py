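"""Blink reconstruction, epoching and baseline normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sacpupil as sp
from sacpupil.eye_signal import GazeTrace

from conftest import make_trial_meta


def _pupil_trace(p, valid=None, t0=0):
    p = np.asarray(p, dtype=float)
    n = len(p)
    return GazeTrace(t=t0 + np.arange(n), x=np.zeros(n), y=np.zeros(n),
                     pupil=p, valid=valid)


class TestBlinkReconstruction:
    def test_no_blinks_identity(self, rng):
        p = 1000 + rng.normal(0, 5, 500)
        out = sp.reconstruct_blinks(_pupil_trace(p))
        np.testing.assert_array_equal(out.pupil, p)
        assert out.valid.all()

    def test_linear_segment_recovered(self):
        # blink cut into a straight ramp: spline must restore the line
        n = 1000
        p = np.linspace(1000.0, 1200.0, n)
        valid = np.ones(n, bool)
        valid[400:480] = False
        masked = p.copy()
        masked[~valid] = np.nan
        out = sp.reconstruct_blinks(_pupil_trace(masked, valid), margin_ms=50)
        assert out.valid.all()
        np.testing.assert_allclose(out.pupil, p, rtol=0.01)

    def test_blink_at_start_stays_masked(self):
        n = 400
        valid = np.ones(n, bool)
        valid[:60] = False
        p = np.full(n, 900.0)
        p[:60] = np.nan
        out = sp.reconstruct_blinks(_pupil_trace(p, valid))
        assert not out.valid[:60].any()

    def test_overlong_blink_stays_masked(self):
        n = 2000
        valid = np.ones(n, bool)
        valid[500:1200] = False  # 700 ms > default 500 ms maximum
        p = np.where(valid, 1000.0, np.nan)
        out = sp.reconstruct_blinks(_pupil_trace(p, valid))
        assert not out.valid[500:1200].any()

    def test_samples_outside_extended_runs_untouched(self, rng):
        n = 1000
        p = 1000 + rng.normal(0, 20, n)
        valid = np.ones(n, bool)
        valid[300:350] = False
        p2 = p.copy()
        p2[~valid] = np.nan
        out = sp.reconstruct_blinks(_pupil_trace(p2, valid), margin_ms=50)
        outside = np.ones(n, bool)
        outside[300 - 50:350 + 50] = False
        np.testing.assert_array_equal(out.pupil[outside], p[outside])


class TestEpochNormalization:
    def _mk(self, p, mid=2000):
        return sp.epoch_and_normalize(_pupil_trace(p), mid)

    def test_constant_series_normalizes_to_one(self):
        ep = self._mk(np.full(4000, 1200.0))
        np.testing.assert_allclose(ep.values[ep.valid], 1.0, atol=1e-12)
        assert ep.baseline == pytest.approx(1200.0)
        assert len(ep.rel_t) == 1501

    def test_step_change_scales(self):
        p = np.full(4000, 1000.0)
        p[2300:] = 900.0  # step at +300 ms relative to mid
        ep = self._mk(p)
        j = np.searchsorted(ep.rel_t, 299)
        assert ep.values[j] == pytest.approx(1.0)
        k = np.searchsorted(ep.rel_t, 400)
        assert ep.values[k] == pytest.approx(0.9)

    def test_all_blink_baseline_rejected(self):
        n = 4000
        valid = np.ones(n, bool)
        valid[1880:1910] = False  # covers the whole [-105, -95] window
        p = np.where(valid, 1000.0, np.nan)
        with pytest.raises(sp.EpochRejected, match="baseline"):
            sp.epoch_and_normalize(_pupil_trace(p, valid), 2000)

    def test_baseline_window_mean_is_one(self, rng):
        p = 1000 + rng.normal(0, 30, 4000)
        ep = self._mk(p)
        window = (ep.rel_t >= -105) & (ep.rel_t <= -95)
        assert np.nanmean(ep.values[window]) == pytest.approx(1.0, abs=1e-9)

    def test_out_of_coverage_masked(self):
        p = np.full(2500, 1000.0)
        ep = sp.epoch_and_normalize(_pupil_trace(p), 2000)
        # coverage ends 500 ms after mid; later samples must be masked
        assert not ep.valid[np.searchsorted(ep.rel_t, 600)]
        assert np.isnan(ep.values[np.searchsorted(ep.rel_t, 600)])

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    def test_divisive_normalization_scale_invariant(self, scale):
        p = 1000.0 + 50.0 * np.sin(np.arange(4000) / 300.0)
        a = sp.epoch_and_normalize(_pupil_trace(p), 2000)
        b = sp.epoch_and_normalize(_pupil_trace(p * scale), 2000)
        np.testing.assert_allclose(a.values[a.valid], b.values[b.valid],
                                   rtol=1e-9)

    def test_subtractive_mode(self):
        p = np.full(4000, 800.0)
        ep = sp.epoch_and_normalize(_pupil_trace(p), 2000,
                                    normalization="subtractive")
        np.testing.assert_allclose(ep.values[ep.valid], 0.0, atol=1e-12)


class TestPositionArtifact:
    def test_planted_slope_recovered_and_removed(self, rng):
        positions = [(x, y) for x in (-8.5, 0.0, 8.5) for y in (-8.5, 0.0, 8.5)]
        baselines = [1000.0 + 3.0 * x + 0.5 * y for x, y in positions]
        b0, bx, by = sp.fit_position_artifact(baselines, positions)
        assert bx == pytest.approx(3.0, abs=1e-9)
        assert by == pytest.approx(0.5, abs=1e-9)
        traces = [_pupil_trace(np.full(100, b)) for b in baselines]
        corrected = sp.remove_position_artifact(traces, baselines, positions)
        flat = [np.mean(c.pupil) for c in corrected]
        np.testing.assert_allclose(flat, 1000.0, atol=1e-9)

    def test_independent_pupil_gives_zero_slopes(self, rng):
        positions = [(x, 0.0) for x in (-8.5, 0.0, 8.5)] + [(0.0, 8.5)]
        baselines = [1000.0] * 4
        _, bx, by = sp.fit_position_artifact(baselines, positions)
        assert bx == pytest.approx(0.0, abs=1e-9)
        assert by == pytest.approx(0.0, abs=1e-9)

    def test_collinear_positions_error(self):
        positions = [(-8.5, 0.0), (0.0, 0.0), (8.5, 0.0)]
        with pytest.raises(ValueError, match="collinear|rank"):
            sp.fit_position_artifact([1.0, 2.0, 3.0], positions)
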