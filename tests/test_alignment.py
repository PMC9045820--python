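import numpy as np
import pytest

from cmequant import (align_and_average, calibrate_molecules,
                      CalibrationFactor, compute_speed, half_peak_times)


def _triangle(t, peak_t=10.0, rise=10.0, fall=10.0, peak=1.0):
    return peak * np.interp(t, [peak_t - rise, peak_t, peak_t + fall],
                            [0.0, 1.0, 0.0])


class TestAlignAndAverage:
    def test_identical_traces_align_trivially(self, triangle_trace):
        t, y = triangle_trace
        ens = align_and_average([(t, y)] * 4)
        rel = ens.offsets_s - ens.offsets_s[0]
        np.testing.assert_allclose(rel, 0.0, atol=1e-9)
        # mean reproduces the input triangle on the fine grid
        expected = _triangle(ens.t_s + 10.0)
        np.testing.assert_allclose(ens.mean, expected, atol=1e-6)
        assert ens.peak_value == pytest.approx(1.0, abs=1e-6)

    def test_subframe_offset_recovered(self):
        # one copy pre-shifted by 0.4 s, both sampled at 1 s
        t = np.arange(0.0, 21.0, 1.0)
        a = _triangle(t)
        b = _triangle(t - 0.4)
        ens = align_and_average([(t, a), (t, b)])
        # b lags a by 0.4 s, so its alignment shift is 0.4 s smaller
        rel = ens.offsets_s[0] - ens.offsets_s[1]
        assert rel == pytest.approx(0.4, abs=0.1)

    def test_noisy_ensemble_mean_tracks_template(self):
        rng = np.random.default_rng(11)
        t = np.arange(0.0, 21.0, 1.0)
        traces = [(t, _triangle(t - d) + rng.normal(0, 0.05, t.size))
                  for d in rng.uniform(-2, 2, 50)]
        ens = align_and_average(traces)
        template = _triangle(ens.t_s + 10.0)
        core = np.abs(ens.t_s) < 7.0   # fully overlapped region
        err = np.abs(ens.mean - template)[core]
        assert np.all(err <= 2 * ens.ci95[core] + 0.02)

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 21.0, 1.0)
        traces = [(t, _triangle(t - d) + rng.normal(0, 0.05, t.size))
                  for d in rng.uniform(-2, 2, 20)]
        ens = align_and_average(traces)
        hist = np.asarray(ens.objective_history)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_global_time_shift_leaves_shape_invariant(self, triangle_trace):
        t, y = triangle_trace
        traces = [(t, y), (t, np.roll(y, 0))]
        e1 = align_and_average(traces)
        e2 = align_and_average([(t + 100.0, y), (t + 100.0, y)])
        np.testing.assert_allclose(e1.mean, e2.mean, atol=1e-9)
        np.testing.assert_allclose(e1.t_s, e2.t_s, atol=1e-9)

    def test_peak_sits_at_time_zero(self, triangle_trace):
        t, y = triangle_trace
        ens = align_and_average([(t, y)] * 3)
        assert ens.mean[np.argmin(np.abs(ens.t_s))] == ens.mean.max()

    def test_too_short_traces_rejected(self):
        with pytest.raises(ValueError):
            align_and_average([(np.arange(3.0), np.ones(3))])


class TestCalibration:
    def test_unit_factor(self):
        from cmequant.alignment import AlignedEnsemble
        ens = AlignedEnsemble(t_s=np.array([0.0]), mean=np.array([830.0]),
                              ci95=np.zeros(1), n_per_point=np.ones(1),
                              offsets_s=np.zeros(1), n_tracks=1)
        out = calibrate_molecules(ens, CalibrationFactor(830.0))
        assert out.mean[0] == pytest.approx(830.0)
        assert out.units == "molecules"

    def test_half_intensity_control(self):
        from cmequant.alignment import AlignedEnsemble
        ens = AlignedEnsemble(t_s=np.array([0.0]), mean=np.array([207.5]),
                              ci95=np.zeros(1), n_per_point=np.ones(1),
                              offsets_s=np.zeros(1), n_tracks=1)
        out = calibrate_molecules(ens, CalibrationFactor(415.0))
        assert out.mean[0] == pytest.approx(415.0)

    def test_zero_control_peak_rejected(self):
        with pytest.raises(ValueError):
            CalibrationFactor(0.0)


class TestSpeed:
    def test_stationary_track_zero_speed(self):
        t, v = compute_speed(np.arange(5.0), np.ones((5, 2)))
        np.testing.assert_allclose(v, 0.0)

    def test_linear_motion(self):
        # 2 px/frame at 0.1 µm/px, 1 s interval → 0.2 µm/s
        pos = np.column_stack([np.zeros(10), np.arange(10) * 0.2])
        _, v = compute_speed(np.arange(10.0), pos)
        np.testing.assert_allclose(v, 0.2)

    def test_random_walk_rayleigh_mean(self):
        rng = np.random.default_rng(8)
        s = 0.05
        pos = np.cumsum(rng.normal(0, s, (1001, 2)), axis=0)
        _, v = compute_speed(np.arange(1001.0), pos)
        assert v.mean() == pytest.approx(s * np.sqrt(np.pi / 2), rel=0.05)

    def test_single_point_track_empty(self):
        t, v = compute_speed(np.array([0.0]), np.zeros((1, 2)))
        assert len(v) == 0


class TestHalfPeakTimes:
    @staticmethod
    def _ensemble_from(t, y):
        return align_and_average([(t, y)] * 2, sub_dt_s=0.1)

    def test_symmetric_triangle(self, triangle_trace):
        t, y = triangle_trace
        a, d = half_peak_times(self._ensemble_from(t, y))
        assert a == pytest.approx(5.0, abs=0.1)
        assert d == pytest.approx(5.0, abs=0.1)

    def test_asymmetric_triangle(self):
        t = np.arange(0.0, 12.5, 0.5)
        y = np.interp(t, [0.0, 4.0, 12.0], [0.0, 1.0, 0.0])
        a, d = half_peak_times(self._ensemble_from(t, y))
        assert a == pytest.approx(2.0, abs=0.1)
        assert d == pytest.approx(4.0, abs=0.1)

    def test_undefined_side_flagged(self):
        t = np.arange(0.0, 12.0, 1.0)
        y = np.interp(t, [0.0, 6.0, 11.0], [0.0, 1.0, 0.8])
        a, d = half_peak_times(self._ensemble_from(t, y))
        assert a is not None
        assert d is None
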