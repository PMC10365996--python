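"""Difference imaging, reference gating, Hough detection and map assembly."""

import numpy as np
import pytest
from scipy import ndimage

import secretomap as sm
from secretomap.exceptions import (
    AlignmentError,
    BoundsError,
    DetectionError,
    InsufficientFramesError,
)


def stack_of(frames, dt=10.0):
    frames = np.asarray(frames, dtype=float)
    return sm.ImageStack(frames=frames, times=np.arange(len(frames)) * dt)


class TestDifferenceStack:
    def test_constant_stack_is_all_zero(self):
        diff = sm.difference_stack(stack_of(np.full((4, 8, 8), 5.0)), sigma=1.5)
        assert np.all(diff.frames == 0)

    def test_uniform_step_without_smoothing(self):
        diff = sm.difference_stack(
            stack_of([np.full((6, 6), 5.0), np.full((6, 6), 7.0)]), sigma=0
        )
        assert np.all(diff.frames[1] == 2.0)
        assert np.all(diff.frames[0] == 0.0)

    def test_smoothed_peak_matches_convolution_oracle(self):
        base = np.zeros((21, 21))
        bumped = base.copy()
        bumped[10, 10] = 10.0
        diff = sm.difference_stack(stack_of([base, bumped]), sigma=1.5)
        oracle = ndimage.gaussian_filter(bumped, 1.5, mode="reflect")
        assert np.allclose(diff.frames[1], oracle, atol=1e-9)

    def test_single_frame_rejected(self):
        with pytest.raises(InsufficientFramesError):
            sm.difference_stack(stack_of(np.zeros((1, 4, 4))))


class TestReferenceLevel:
    def test_constant_roi_level_is_mean(self):
        diff = sm.DiffStack(frames=np.ones((3, 10, 10)), times=np.arange(3.0))
        series = sm.reference_level(diff, (0, 0, 5, 5))
        assert np.allclose(series.levels, 1.0)

    def test_mu_plus_three_sigma(self):
        frame = np.zeros((1, 2, 2))
        frame[0] = [[0.5, 1.5], [0.5, 1.5]]  # mean 1.0, sd 0.5
        diff = sm.DiffStack(frames=frame, times=np.array([0.0]))
        series = sm.reference_level(diff, (0, 0, 2, 2))
        assert series.levels[0] == pytest.approx(2.5)

    def test_roi_outside_frame_raises(self):
        diff = sm.DiffStack(frames=np.zeros((1, 8, 8)), times=np.array([0.0]))
        with pytest.raises(BoundsError):
            sm.reference_level(diff, (0, 0, 12, 12))

    def test_level_tracks_shared_drift(self):
        """With additive drift d(t) on both wells, the level follows d(t)."""
        rng = np.random.default_rng(0)
        t = np.arange(10.0)
        drift = 0.02 * t * 10
        frames = np.abs(
            drift[:, None, None] + rng.normal(0, 0.05, size=(10, 20, 20))
        )
        diff = sm.DiffStack(frames=frames, times=t * 10)
        series = sm.reference_level(diff, (5, 5, 15, 15))
        assert np.allclose(series.levels[1:], drift[1:], atol=0.3)


class TestSubtractBackground:
    def test_subtraction(self):
        diff = sm.DiffStack(frames=np.full((2, 4, 4), 3.0), times=np.arange(2.0))
        levels = sm.BackgroundLevelSeries(levels=np.array([2.5, 2.5]), roi=(0, 0, 2, 2))
        corrected = sm.subtract_background(diff, levels)
        assert np.allclose(corrected.frames, 0.5)

    def test_clamped_at_zero(self):
        diff = sm.DiffStack(frames=np.full((1, 4, 4), 1.0), times=np.array([0.0]))
        levels = sm.BackgroundLevelSeries(levels=np.array([2.5]), roi=(0, 0, 2, 2))
        assert np.all(sm.subtract_background(diff, levels).frames == 0.0)

    def test_frame_count_mismatch(self):
        diff = sm.DiffStack(frames=np.zeros((3, 4, 4)), times=np.arange(3.0))
        levels = sm.BackgroundLevelSeries(levels=np.zeros(2), roi=(0, 0, 2, 2))
        with pytest.raises(AlignmentError):
            sm.subtract_background(diff, levels)

    def test_three_sigma_gate_on_pure_noise(self):
        """>= 99% of pure-noise pixels are zeroed by the mu+3sigma gate."""
        rng = np.random.default_rng(42)
        frames = np.abs(rng.normal(0, 1.0, size=(10, 64, 64)))
        diff = sm.DiffStack(frames=frames, times=np.arange(10.0))
        levels = sm.reference_level(diff, (7, 7, 57, 57))
        corrected = sm.subtract_background(diff, levels)
        assert (corrected.frames == 0).mean() >= 0.99


class TestDetectWellCircle:
    def draw_ring(self, shape=(200, 200), center=(100, 100), radius=70):
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        dist = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
        image = np.full(shape, 100.0)
        image[np.abs(dist - radius) <= 1.5] = 40.0
        return image

    def test_radius_recovered(self):
        circle = sm.detect_well_circle(self.draw_ring(), (50, 90))
        assert circle.radius == pytest.approx(70, abs=2)

    def test_translated_center_recovered(self):
        circle = sm.detect_well_circle(
            self.draw_ring(center=(105, 95)), (50, 90)
        )
        assert circle.center[0] == pytest.approx(105, abs=2)
        assert circle.center[1] == pytest.approx(95, abs=2)

    def test_blank_image_raises(self):
        with pytest.raises(DetectionError):
            sm.detect_well_circle(np.full((100, 100), 10.0), (20, 40))


class TestPruneClusters:
    def frame_with_blob(self):
        frame = np.zeros((256, 256))
        rr, cc = np.ogrid[:256, :256]
        frame[(rr - 128) ** 2 + (cc - 128) ** 2 <= 20**2] = 5.0  # halo at cell
        frame[10:11, 10:15] = 3.0  # 5-px blob ~165 px away
        return frame

    def test_small_far_blob_removed_halo_kept(self):
        pruned = sm.prune_clusters(
            self.frame_with_blob(), k=4, min_size=20, max_dist=100, cell_centroid=(128, 128)
        )
        assert pruned[10, 12] == 0.0
        assert pruned[128, 128] == 5.0

    def test_all_large_clusters_untouched(self):
        frame = np.zeros((64, 64))
        frame[:20, :20] = 1.0
        frame[40:, 40:] = 1.0
        pruned = sm.prune_clusters(frame, k=2, min_size=10, max_dist=5, cell_centroid=(0, 0))
        assert np.array_equal(pruned, frame)

    def test_empty_frame_unchanged(self):
        frame = np.zeros((16, 16))
        assert np.array_equal(sm.prune_clusters(frame, cell_centroid=(8, 8)), frame)

    def test_pruning_never_increases_tic(self):
        rng = np.random.default_rng(1)
        frame = np.where(rng.random((128, 128)) < 0.01, rng.random((128, 128)), 0.0)
        pruned = sm.prune_clusters(
            frame, k=4, min_size=20, max_dist=30, cell_centroid=(64, 64)
        )
        assert pruned.sum() <= frame.sum()


class TestBuildSecretionMaps:
    def test_no_secretion_noise_free_scene_yields_zero_maps(self):
        from conftest import make_scene_config

        # static cell: "sensing == baseline for all t" requires no motion,
        # otherwise sub-count smoothing tails of the moving cell edge survive
        # the (zero) noise gate
        config = make_scene_config(
            "none",
            seed=0,
            motion_msd_target_um2=0.0,
            noise=sm.NoiseConfig(read_sigma=0.0, drift_amplitude=0.0),
        )
        pair, truth = sm.simulate_pair(config)
        masks = sm.accumulate_masks(truth.cell_masks)
        center = (config.crop_side - 1) / 2.0
        circle = sm.WellCircle((center, center), config.well_radius_px)
        maps = sm.build_secretion_maps(pair, masks, circle=circle)
        assert np.all(maps.frames == 0.0)

    def test_support_and_provenance(self, constant_result):
        config, result, truth = constant_result
        maps = result.maps
        assert np.all(maps.frames[0] == 0.0)
        cum = sm.accumulate_masks(truth.cell_masks)
        assert np.all(maps.frames[cum] == 0.0)  # cell path excluded at every t
        outside = ~result.circle.mask(maps.frames.shape[1:])
        assert np.all(maps.frames[:, outside] == 0.0)
        steps = [p["step"] for p in maps.provenance]
        assert steps[0] == "difference"
        assert "cumulative_mask_exclusion" in steps

    def test_halo_support_overlaps_ground_truth(self, constant_result):
        config, result, truth = constant_result
        final = result.maps.frames[-1] > 0
        # ground-truth halo: smallest region holding 95% of the bound mass,
        # with the cell's ever-occupied pixels removed (the pipeline excludes
        # them by contract)
        bound = truth.bound_mass[-1].astype(float)
        order = np.argsort(bound.ravel())[::-1]
        mass = np.cumsum(bound.ravel()[order])
        truth_halo = np.zeros(bound.shape, dtype=bool)
        truth_halo.ravel()[order[mass <= 0.95 * bound.sum()]] = True
        truth_halo &= ~sm.accumulate_masks(truth.cell_masks)[-1]
        iou = (final & truth_halo).sum() / (final | truth_halo).sum()
        assert iou >= 0.6

    def test_translation_equivariance(self):
        """Shifting the scene shifts the output support identically."""
        rng = np.random.default_rng(0)
        base = np.full((64, 64), 100.0)
        signal = np.zeros((64, 64))
        signal[30:34, 28:32] = 20.0
        shift = (5, 3)

        def build(dr, dc):
            sens = np.stack([base, base + np.roll(signal, (dr, dc), (0, 1))])
            ref = np.stack([base, base])
            pair = sm.WellPair(
                sensing=sm.WellStack(stack_of(sens), "S", "sensing"),
                reference=sm.WellStack(stack_of(ref), "R", "reference"),
            )
            masks = np.zeros((2, 64, 64), dtype=bool)
            masks[:, 10 + dr : 13 + dr, 10 + dc : 13 + dc] = True
            circle = sm.WellCircle((31.5 + dr, 31.5 + dc), 28)
            return sm.build_secretion_maps(
                pair, masks, circle=circle, sigma=0, roi_margin=2, mask_dilation=1
            )

        unshifted = build(0, 0)
        shifted = build(*shift)
        rolled = np.roll(unshifted.frames[1] > 0, shift, (0, 1))
        assert np.array_equal(shifted.frames[1] > 0, rolled)
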