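import numpy as np
import pytest

from cmequant import (ImageStack, PatchSceneParams, synth_patch_movie,
                      detect_and_link, measure_track, filter_tracks)
from cmequant.tracking import RawTrack, _disc_offsets
from cmequant.synthetic import _render_gaussian


def _single_point_track(y=10.0, x=10.0, frame=0):
    return RawTrack(np.array([frame]), np.array([[y, x]]))


class TestDetectAndLink:
    def test_blank_stack_yields_no_tracks(self):
        assert detect_and_link(ImageStack(np.zeros((5, 30, 30)))) == []

    def test_three_separated_spots_recovered_with_subpixel_accuracy(self):
        params = PatchSceneParams(n_events=3, noise_sd=0.0,
                                  diffusion_step_px=0.0, seed=4)
        stack, truth = synth_patch_movie(params)
        tracks = detect_and_link(stack)
        kept = filter_tracks([measure_track(stack, t) for t in tracks])
        assert len(kept) == 3
        anchors = np.array([p[0] for p in truth.positions_px])
        for tr in kept:
            mid = (tr.positions_um[len(tr.times_s) // 2]
                   / stack.pixel_size_um)
            assert np.min(np.linalg.norm(anchors - mid, axis=1)) < 0.5

    def test_distant_detections_never_linked(self):
        # two spots 15 px apart in consecutive frames, gate 3 px
        data = np.zeros((2, 40, 40))
        _render_gaussian(data[0], 15.0, 10.0, 500.0, 1.3)
        _render_gaussian(data[1], 15.0, 25.0, 500.0, 1.3)
        tracks = detect_and_link(ImageStack(data), max_disp_px=3.0)
        assert len(tracks) == 2
        assert all(len(t.frames) == 1 for t in tracks)

    def test_gap_closing_bridges_one_missed_frame(self):
        data = np.zeros((3, 40, 40))
        _render_gaussian(data[0], 20.0, 20.0, 500.0, 1.3)
        _render_gaussian(data[2], 20.0, 20.0, 500.0, 1.3)
        tracks = detect_and_link(ImageStack(data), max_gap_frames=1)
        assert len(tracks) == 1
        assert list(tracks[0].frames) == [0, 2]


class TestMeasureTrack:
    def test_uniform_image_measures_zero(self):
        stack = ImageStack(np.full((1, 25, 25), 11.0))
        tr = measure_track(stack, _single_point_track(12, 12))
        assert tr.corrected_intensity[0] == pytest.approx(0.0)

    def test_single_bright_pixel_fully_recovered(self):
        data = np.zeros((1, 25, 25))
        data[0, 12, 12] = 100.0
        tr = measure_track(ImageStack(data), _single_point_track(12, 12))
        # median of the mostly-zero neighborhood is 0
        assert tr.corrected_intensity[0] == pytest.approx(100.0)

    def test_gaussian_spot_integral_within_five_percent(self):
        data = np.full((1, 31, 31), 20.0)
        _render_gaussian(data[0], 15.0, 15.0, 800.0, 1.3)
        tr = measure_track(ImageStack(data), _single_point_track(15, 15))
        assert tr.corrected_intensity[0] == pytest.approx(800.0, rel=0.05)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(2)
        data = np.full((1, 40, 40), 10.0)
        _render_gaussian(data[0], 14.0, 14.0, 600.0, 1.3)
        shifted = np.roll(np.roll(data, 7, axis=1), 5, axis=2)
        a = measure_track(ImageStack(data), _single_point_track(14, 14))
        b = measure_track(ImageStack(shifted), _single_point_track(21, 19))
        assert a.corrected_intensity[0] == pytest.approx(
            b.corrected_intensity[0], rel=1e-9)

    def test_border_frames_excluded_and_flagged(self):
        data = np.zeros((1, 25, 25))
        tr = measure_track(ImageStack(data), _single_point_track(1, 1))
        assert not tr.kept
        assert len(tr.times_s) == 0

    def test_roi_disc_is_7px_diameter(self):
        assert len(_disc_offsets(7)) == 37


class TestFilterTracks:
    @staticmethod
    def _track(duration_s, profile):
        n = len(profile)
        return_track = RawTrack(np.arange(n), np.zeros((n, 2)))
        from cmequant.tracking import PatchTrack
        t = np.linspace(0, duration_s, n)
        return PatchTrack(times_s=t, positions_um=np.zeros((n, 2)),
                          roi_sum=np.asarray(profile, dtype=float),
                          background=np.zeros(n),
                          corrected_intensity=np.asarray(profile, dtype=float),
                          frames=np.arange(n))

    def test_short_track_rejected(self):
        tr = self._track(3.0, [0, 1, 2, 1, 0])
        assert filter_tracks([tr]) == []
        assert tr.reason == "shorter than minimum duration"

    def test_monotone_track_rejected(self):
        tr = self._track(20.0, list(range(21)))
        assert filter_tracks([tr]) == []
        assert "rise-then-fall" in tr.reason

    def test_triangular_track_kept(self):
        profile = list(range(7)) + list(range(5, -1, -1))
        tr = self._track(12.0, profile)
        assert filter_tracks([tr]) == [tr]
        assert tr.kept

    def test_filtering_is_idempotent(self):
        tracks = [self._track(12.0, [0, 1, 3, 6, 8, 6, 3, 1, 0]),
                  self._track(20.0, list(range(21)))]
        once = filter_tracks(tracks)
        twice = filter_tracks(once)
        assert twice == once


class TestGroundTruthRecovery:
    def test_noiseless_scene_recovers_exact_count(self, noiseless_scene):
        params, stack, truth = noiseless_scene
        raw = detect_and_link(stack)
        kept = filter_tracks([measure_track(stack, t) for t in raw])
        assert len(kept) == truth.n_events

    def test_noisy_scene_recovers_exact_count(self, noisy_scene):
        params, stack, truth = noisy_scene
        raw = detect_and_link(stack)
        kept = filter_tracks([measure_track(stack, t) for t in raw])
        assert len(kept) == truth.n_events
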