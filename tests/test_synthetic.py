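import numpy as np
import pytest

from cmequant import (PatchSceneParams, synth_patch_movie, synth_fm_trace,
                      synth_aspiration_series, synth_eisosome_series,
                      synth_survival_times, fit_exocytosis_rate)


class TestPatchMovie:
    def test_empty_scene_is_uniform_zero(self):
        p = PatchSceneParams(n_events=0, noise_sd=0.0, cytoplasm_level=0.0,
                             extracellular_level=0.0)
        stack, truth = synth_patch_movie(p)
        assert np.all(stack.data == 0)
        assert truth.n_events == 0

    def test_seed_determinism(self):
        p = PatchSceneParams(n_events=5, noise_sd=2.0, seed=42)
        s1, _ = synth_patch_movie(p)
        s2, _ = synth_patch_movie(p)
        np.testing.assert_array_equal(s1.data, s2.data)

    def test_photon_conservation_without_noise_or_bleach(self):
        # total added spot intensity equals the analytic profile integral
        p = PatchSceneParams(n_events=10, noise_sd=0.0, bleach_rate=0.0,
                             cytoplasm_level=0.0, extracellular_level=0.0,
                             seed=3)
        stack, truth = synth_patch_movie(p)
        analytic = sum(prof.sum() for prof in truth.intensities_au)
        assert stack.data.sum() == pytest.approx(analytic, rel=0.005)

    def test_ground_truth_consistency(self, noiseless_scene):
        params, stack, truth = noiseless_scene
        assert truth.n_events == params.n_events
        assert truth.density_per_um == pytest.approx(
            truth.mean_concurrent_events / params.cell_length_um)
        # anchor positions lie inside the cell mask
        for pos in truth.positions_px:
            y, x = np.round(pos[0]).astype(int)
            assert truth.cell_mask[y, x]

    @pytest.mark.parametrize("bad", [
        dict(n_events=-1), dict(rise_s=-1.0), dict(noise_sd=-0.1),
        dict(n_frames=0), dict(pixel_size_um=0.0),
        dict(cell_radius_um=0.2),          # capsule smaller than one ROI
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            synth_patch_movie(PatchSceneParams(**bad))

    def test_illumination_field_applied(self):
        p = PatchSceneParams(n_events=0, noise_sd=0.0, cytoplasm_level=10.0,
                             extracellular_level=10.0)
        stack0, _ = synth_patch_movie(p)
        ny, nx = stack0.data.shape[1:]
        field = np.full((ny, nx), 2.0)
        p2 = PatchSceneParams(n_events=0, noise_sd=0.0, cytoplasm_level=10.0,
                              extracellular_level=10.0,
                              illumination_field=field)
        stack2, _ = synth_patch_movie(p2)
        np.testing.assert_allclose(stack2.data, 2 * stack0.data)


class TestFMTrace:
    def test_zero_rate_flat_at_one(self):
        tr = synth_fm_trace(0.0, noise_sd=0.0)
        post = tr.f[tr.t_min >= tr.fast_phase_end_min]
        np.testing.assert_allclose(post, 1.0)

    def test_linear_growth_value(self):
        # k=4.4 %/min → 1 + 0.044·5 = 1.22 at 5 min past the fast phase
        tr = synth_fm_trace(4.4, noise_sd=0.0)
        val = np.interp(tr.fast_phase_end_min + 5.0, tr.t_min, tr.f)
        assert val == pytest.approx(1.22, abs=1e-9)

    def test_noisy_rate_recovered_by_fit(self):
        tr = synth_fm_trace(4.4, noise_sd=0.01, seed=7)
        k, _ = fit_exocytosis_rate(tr, window_min=(0.0, 5.0))
        assert k == pytest.approx(4.4, rel=0.05)

    def test_rejects_bad_dt(self):
        with pytest.raises(ValueError):
            synth_fm_trace(4.4, dt_s=0.0)


class TestAspirationSeries:
    def test_crossing_at_critical_pressure(self):
        series = synth_aspiration_series(4.9e-4, 2.5, 5.0,
                                         np.arange(0.0, 400.0, 10.0))
        # l = Rp exactly at ΔP* = 2σ(1−Rp/Rc)/Rp = 196 Pa
        crossing = np.interp(2.5, series["tongue_um"], series["pressure_pa"])
        assert crossing == pytest.approx(196.0, rel=1e-6)
        assert np.all(np.diff(series["tongue_um"]) > 0)

    def test_rejects_wide_pipette(self):
        with pytest.raises(ValueError):
            synth_aspiration_series(4.9e-4, 5.0, 5.0, [100.0])


class TestEisosomeSeries:
    def test_zero_rate_constant_one(self):
        df = synth_eisosome_series(decay_rate_per_min=0.0, noise_sd=0.0)
        np.testing.assert_allclose(df["area_fraction"], 1.0)

    def test_half_life_identity(self):
        df = synth_eisosome_series(decay_rate_per_min=np.log(2) / 5,
                                   noise_sd=0.0)
        f5 = np.interp(5.0, df["t_min"], df["area_fraction"])
        assert f5 == pytest.approx(0.5, abs=1e-9)

    def test_anchor_stays_one_with_noise(self):
        df = synth_eisosome_series(noise_sd=0.05, seed=1)
        assert df["area_fraction"].iloc[0] == 1.0

    def test_rejects_negative_rate(self):
        with pytest.raises(ValueError):
            synth_eisosome_series(decay_rate_per_min=-0.1)


class TestSurvivalTimes:
    def test_zero_hazard_all_censored(self):
        df = synth_survival_times(50, 0.0, 8, seed=0)
        assert (df["status"] == 0).all()
        assert (df["time"] == 8).all()

    def test_certain_death_at_first_interval(self):
        df = synth_survival_times(50, 1.0, 8, seed=0)
        assert (df["status"] == 1).all()
        assert (df["time"] == 1).all()

    def test_empty_table(self):
        assert len(synth_survival_times(0, 0.5, 8)) == 0

    def test_rejects_bad_probability(self):
        with pytest.raises(ValueError):
            synth_survival_times(10, 1.5, 8)
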