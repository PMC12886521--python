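"""Diameter measurement: adjustment, thresholding, geometry oracles."""

import numpy as np
import pytest

from lumenpulse import ImageStack, extract_diameter_trace, minimum_diameter
from lumenpulse.segmentation import (
    SegmentationParams,
    TrialQualityError,
    adjust_intensity,
    binarize,
    select_vessel_component,
)

from conftest import rasterize_disk, rasterize_ellipse, rasterize_square


class TestAdjustIntensity:
    def test_identity_for_full_range_frame(self):
        rng = np.random.default_rng(0)
        frame = rng.uniform(size=(32, 32))
        frame[0, 0], frame[0, 1] = 0.0, 1.0
        out = adjust_intensity(frame, 0, 100)
        assert np.allclose(out, frame)

    def test_constant_frame_maps_to_zeros(self):
        assert np.all(adjust_intensity(np.full((16, 16), 3.7)) == 0.0)

    def test_two_valued_frame_maps_to_unit_interval(self):
        frame = np.where(np.arange(256).reshape(16, 16) % 2 == 0, 10.0, 200.0)
        out = adjust_intensity(frame, 0, 100)
        assert set(np.unique(out)) == {0.0, 1.0}
        assert np.all((frame == 200.0) == (out == 1.0))

    def test_bad_percentiles_rejected(self):
        with pytest.raises(ValueError):
            adjust_intensity(np.ones((8, 8)), 50, 40)


def _otsu_oracle(frame):
    """Exhaustive threshold sweep maximizing between-class variance."""
    vals = np.sort(np.unique(frame))
    best_t, best_v = vals[0], -1.0
    for t in (vals[:-1] + vals[1:]) / 2:
        lo = frame[frame <= t]
        hi = frame[frame > t]
        w0, w1 = lo.size, hi.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


class TestBinarize:
    def test_bimodal_threshold_between_modes(self):
        rng = np.random.default_rng(1)
        frame = np.where(rng.uniform(size=(64, 64)) < 0.5, 0.1, 0.9)
        frame += rng.normal(0, 0.02, frame.shape)
        frame = np.clip(frame, 0, 1)
        mask = binarize(frame)
        oracle_t = _otsu_oracle(frame)
        assert 0.2 < oracle_t < 0.8
        oracle_mask = frame > oracle_t
        assert (mask == oracle_mask).mean() > 0.999

    def test_all_equal_frame_gives_empty_mask(self):
        assert not binarize(np.zeros((16, 16))).any()

    def test_fixed_threshold_overrides(self):
        frame = np.where(np.arange(64).reshape(8, 8) % 2 == 0, 0.2, 0.8)
        mask = binarize(frame, fixed_threshold=0.5)
        assert np.all(mask == (frame == 0.8))


class TestSelectVesselComponent:
    def test_solid_disk_centroid(self):
        mask = rasterize_disk((64, 64), (30.0, 33.0), 10.0)
        vm = select_vessel_component(mask)
        assert abs(vm.centroid_rc[0] - 30.0) < 0.5
        assert abs(vm.centroid_rc[1] - 33.0) < 0.5
        assert not vm.touches_border

    def test_largest_component_wins_without_hint(self):
        mask = rasterize_disk((64, 64), (20.0, 20.0), 10.0)
        mask[50:52, 50:53] = True  # speck
        vm = select_vessel_component(mask)
        assert vm.mask[20, 20] and not vm.mask[50, 50]

    def test_tracking_hint_beats_size(self):
        mask = rasterize_disk((64, 64), (16.0, 16.0), 6.0) | rasterize_disk(
            (64, 64), (46.0, 46.0), 6.0
        )
        vm = select_vessel_component(mask, prev_centroid=(45.0, 44.0))
        assert vm.mask[46, 46] and not vm.mask[16, 16]

    def test_holes_are_filled(self):
        mask = rasterize_disk((64, 64), (32.0, 32.0), 12.0)
        mask[30:34, 30:34] = False
        vm = select_vessel_component(mask)
        assert vm.mask[31, 31]

    def test_empty_mask_flagged_not_raised(self):
        vm = select_vessel_component(np.zeros((32, 32), dtype=bool))
        assert vm.is_empty

    def test_border_contact_flag(self):
        mask = rasterize_disk((64, 64), (3.0, 32.0), 8.0)
        vm = select_vessel_component(mask)
        assert vm.touches_border


class TestMinimumDiameter:
    @pytest.mark.parametrize("radius", [5.3, 8.1, 10.0, 14.6, 19.7])
    def test_disk_diameter_is_2r(self, radius):
        mask = rasterize_disk((96, 96), (47.73, 47.28), radius)
        d, outlier = minimum_diameter(select_vessel_component(mask))
        assert not outlier
        assert d == pytest.approx(2 * radius, abs=0.5)

    def test_axis_aligned_ellipse_minor_axis(self):
        mask = rasterize_ellipse((96, 96), (47.7, 47.3), 8.0, 15.0, 0.0)
        d, _ = minimum_diameter(select_vessel_component(mask))
        assert d == pytest.approx(16.0, abs=0.5)

    def test_square_min_chord_is_side_not_diagonal(self):
        mask = rasterize_square((96, 96), 21)
        d, _ = minimum_diameter(select_vessel_component(mask))
        assert d == pytest.approx(21.0, abs=0.5)

    def test_crescent_falls_back_to_longest_run(self):
        mask = rasterize_disk((96, 96), (47.5, 47.5), 20.0) & ~rasterize_disk(
            (96, 96), (47.5, 40.5), 17.0
        )
        vm = select_vessel_component(mask)
        d, outlier = minimum_diameter(vm)
        assert outlier
        assert d > 0

    def test_monotone_in_true_minor_axis(self):
        # recovered diameter strictly increases with the true minor axis
        measured = []
        for b in np.arange(3.0, 20.1, 1.0):
            mask = rasterize_ellipse((112, 112), (55.71, 55.23), b, 1.3 * b, 0.4)
            d, _ = minimum_diameter(select_vessel_component(mask))
            measured.append(d)
        assert np.all(np.diff(measured) > 0)

    def test_angular_resolution_convergence(self):
        mask = rasterize_ellipse((96, 96), (47.6, 47.4), 9.0, 14.0, 0.7)
        vm = select_vessel_component(mask)
        d1, _ = minimum_diameter(vm, angular_step_deg=1.0)
        d05, _ = minimum_diameter(vm, angular_step_deg=0.5)
        assert abs(d1 - d05) < 0.2

    def test_empty_mask_rejected(self):
        vm = select_vessel_component(np.zeros((32, 32), dtype=bool))
        with pytest.raises(ValueError):
            minimum_diameter(vm)


class TestExtractDiameterTrace:
    def test_constant_vessel_recovered_everywhere(self, protocol):
        from lumenpulse import VesselGroundTruth, generate_diameter_timecourse, render_trial
        from lumenpulse.synthetic import NOISELESS

        truth = VesselGroundTruth(
            basal_diameter_um=20.0,
            dilation_amplitude_pct=0.0,
            center_rc=(55.5, 55.5),
            pixel_size_um=0.5,
            ellipticity=1.2,
        )
        trace = generate_diameter_timecourse(truth, protocol)
        trial = render_trial(trace, truth, NOISELESS, protocol, shape=(112, 112))
        dt = extract_diameter_trace(trial.stack)
        assert all(q == "ok" for q in dt.quality)
        assert np.abs(dt.values_um - 20.0).max() < 0.5  # 1 px-equivalent

    def test_noiseless_truth_recovered_per_frame(self, noiseless_trial):
        dt = extract_diameter_trace(noiseless_trial.stack)
        err = np.abs(dt.values_um - noiseless_trial.truth_trace)
        assert err.max() < 0.5  # 1 px-equivalent at 0.5 um/px

    def test_jitter_only_trace_matches_jitter_free(self, protocol, noiseless_trial):
        from lumenpulse import render_trial
        from lumenpulse.synthetic import NoiseModel

        jitter_only = NoiseModel(gaussian_sd=0.0, motion_jitter_sd_px=1.0, seed=4)
        trial_j = render_trial(
            noiseless_trial.truth_trace,
            noiseless_trial.truth,
            jitter_only,
            protocol,
            shape=(112, 112),
        )
        ref = extract_diameter_trace(noiseless_trial.stack)
        jit = extract_diameter_trace(trial_j.stack)
        assert np.abs(ref.values_um - jit.values_um).max() < 0.25  # 0.5 px

    def test_translation_invariance_integer_shift(self, noiseless_trial):
        ref = extract_diameter_trace(noiseless_trial.stack)
        shifted = np.roll(noiseless_trial.stack.frames, (4, -6), axis=(1, 2))
        out = extract_diameter_trace(
            ImageStack(shifted, noiseless_trial.stack.frame_rate_hz, 0.5)
        )
        assert np.abs(out.values_um - ref.values_um).max() < 0.25

    def test_intensity_gain_invariance(self, noiseless_trial):
        ref = extract_diameter_trace(noiseless_trial.stack)
        out = extract_diameter_trace(
            ImageStack(
                noiseless_trial.stack.frames * 11.7,
                noiseless_trial.stack.frame_rate_hz,
                0.5,
            )
        )
        assert np.abs(out.values_um - ref.values_um).max() < 1e-4

    def test_mostly_empty_trial_rejected(self, protocol):
        frames = np.zeros((40, 64, 64), dtype=np.float32)
        disk = rasterize_disk((64, 64), (32.0, 32.0), 10.0)
        for k in range(10):  # only 25% of frames contain a vessel
            frames[k][disk] = 1.0
        with pytest.raises(TrialQualityError):
            extract_diameter_trace(ImageStack(frames, 9.45, 0.5))

    def test_flagged_frames_interpolated(self, protocol, noiseless_trial):
        frames = noiseless_trial.stack.frames.copy()
        frames[50] = frames[50].mean()  # constant frame -> empty mask
        dt = extract_diameter_trace(ImageStack(frames, 9.45, 0.5))
        assert dt.quality[50] == "empty_mask"
        expected = 0.5 * (dt.values_um[49] + dt.values_um[51])
        assert dt.values_um[50] == pytest.approx(expected, abs=0.05)
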