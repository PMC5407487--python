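"""Profile extraction, background handling, normalization and phase calls."""

import numpy as np
import pytest
import shapely

from kymoclock import (
    AxisSpec,
    RoiMask,
    SpatialProfile,
    assign_phase,
    build_matrix,
    control_level_from_sample,
    extract_profile,
    normalize_profile,
    project_stack,
    subtract_background_and_threshold,
)
from kymoclock.profiles import axial_coordinates


def pixel_oracle_profile(image, roi, axis, n_bins):
    """Independent per-pixel assignment oracle: loop, project, bin, average."""
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    poly = roi.shape
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            x, y = c + 0.5, r + 0.5
            if not shapely.contains_xy(poly, x, y):
                continue
            coord = axial_coordinates(np.array([[x, y]]), axis)[0]
            if not 0 <= coord <= 1:
                continue
            b = min(int(coord * n_bins), n_bins - 1)
            sums[b] += image[r, c]
            counts[b] += 1
    out = np.full(n_bins, np.nan)
    out[counts > 0] = sums[counts > 0] / counts[counts > 0]
    return out


class TestProjection:
    def test_single_plane_is_identity(self, rng):
        plane = rng.uniform(size=(5, 6))
        for method in ("max", "mean", "sum"):
            np.testing.assert_array_equal(project_stack(plane[None], method), plane)

    def test_max_of_constant_planes(self):
        stack = np.stack([np.full((3, 3), 3.0), np.full((3, 3), 7.0)])
        np.testing.assert_array_equal(project_stack(stack, "max"), np.full((3, 3), 7.0))

    def test_mean_matches_per_pixel_loop(self, rng):
        stack = rng.uniform(size=(3, 4, 4))
        projected = project_stack(stack, "mean")
        for y in range(4):
            for x in range(4):
                assert projected[y, x] == pytest.approx(sum(stack[z, y, x] for z in range(3)) / 3)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            project_stack(np.empty((0, 4, 4)))


class TestBackground:
    def test_zero_level_is_identity(self, rng):
        image = rng.uniform(size=(4, 4))
        np.testing.assert_array_equal(subtract_background_and_threshold(image, 0.0), image)

    def test_constant_at_level_becomes_zero(self):
        out = subtract_background_and_threshold(np.full((3, 3), 5.0), 5.0)
        np.testing.assert_array_equal(out, 0.0)

    def test_elementwise_example(self):
        out = subtract_background_and_threshold(np.array([[2.0, 9.0], [5.0, 7.0]]), 4.0)
        np.testing.assert_array_equal(out, [[0.0, 5.0], [1.0, 3.0]])

    def test_composition_law(self, rng):
        # max(max(p - a, 0) - b, 0) == max(p - (a + b), 0): repeated
        # subtraction composes additively, and level 0 afterwards is a no-op
        image = rng.uniform(0, 10, size=(6, 6))
        once = subtract_background_and_threshold(image, 3.0)
        np.testing.assert_array_equal(
            subtract_background_and_threshold(once, 2.0),
            subtract_background_and_threshold(image, 5.0),
        )
        np.testing.assert_array_equal(subtract_background_and_threshold(once, 0.0), once)

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            subtract_background_and_threshold(np.ones((2, 2)), -1.0)


class TestControlLevel:
    def test_constant_image_mean(self, box_roi):
        assert control_level_from_sample(np.full((40, 100), 4.2), box_roi, "mean") == pytest.approx(4.2)

    def test_small_roi_mean(self):
        image = np.zeros((4, 4))
        image[1, 1], image[1, 2], image[2, 1], image[2, 2] = 1, 2, 3, 4
        roi = RoiMask([[1, 1], [3, 1], [3, 3], [1, 3]], "ctrl")
        assert control_level_from_sample(image, roi, "mean") == pytest.approx(2.5)

    def test_percentile_matches_sort_oracle(self, rng, box_roi):
        image = rng.uniform(0, 100, size=(40, 100))
        got = control_level_from_sample(image, box_roi, "percentile-95")
        from kymoclock.profiles import _roi_pixel_mask

        pixels = np.sort(image[_roi_pixel_mask(image, box_roi)])
        # linear-interpolated order statistic, computed from the sorted array
        pos = 0.95 * (pixels.size - 1)
        lo, frac = int(pos), pos - int(pos)
        expected = pixels[lo] + frac * (pixels[min(lo + 1, pixels.size - 1)] - pixels[lo])
        assert got == pytest.approx(expected)

    def test_empty_roi_rejected(self):
        roi = RoiMask([[200, 200], [210, 200], [210, 210], [200, 210]], "ctrl")
        with pytest.raises(ValueError):
            control_level_from_sample(np.ones((10, 10)), roi, "mean")


class TestExtractProfile:
    def test_constant_field(self, box_roi, straight_axis):
        profile = extract_profile(np.full((40, 100), 3.5), box_roi, straight_axis, 5)
        np.testing.assert_allclose(profile.intensities, 3.5)

    def test_two_region_matches_pixel_oracle(self, two_region_image, box_roi, straight_axis):
        profile = extract_profile(two_region_image, box_roi, straight_axis, 4, channel="Dll1")
        oracle = pixel_oracle_profile(two_region_image, box_roi, straight_axis, 4)
        np.testing.assert_allclose(profile.intensities, oracle)
        np.testing.assert_allclose(profile.intensities, [10, 10, 20, 20])

    def test_roi_beyond_unit_length_rejected(self, two_region_image, box_roi):
        short_axis = AxisSpec(origin=[-200, 20], polyline=[[-200, 20], [100, 20]], unit_length=100)
        with pytest.raises(ValueError):
            extract_profile(two_region_image, box_roi, short_axis, 4)

    def test_reversed_axis_reverses_profile(self, two_region_image, box_roi, straight_axis):
        forward = extract_profile(two_region_image, box_roi, straight_axis, 10)
        backward_axis = AxisSpec(
            origin=[100, 20], polyline=[[100, 20], [0, 20]], unit_length=100
        )
        backward = extract_profile(two_region_image, box_roi, backward_axis, 10)
        # position x <-> 1 - x, tolerance of one bin at the region boundary
        assert np.sum(~np.isclose(forward.intensities, backward.intensities[::-1])) <= 1

    def test_constant_shift_linearity(self, two_region_image, box_roi, straight_axis):
        base = extract_profile(two_region_image, box_roi, straight_axis, 8)
        shifted = extract_profile(two_region_image + 2.5, box_roi, straight_axis, 8)
        np.testing.assert_allclose(shifted.intensities, base.intensities + 2.5)

    def test_empty_bins_interpolated_and_flagged(self, straight_axis):
        # ROI covering only the two ends of the axis leaves middle bins empty
        image = np.ones((40, 100))
        image[:, 60:] = 3.0
        roi = RoiMask([[1, 5], [20, 5], [20, 35], [1, 35]], "a")
        left = extract_profile(image, roi, straight_axis, 10)
        assert left.metadata["empty_bins"]  # bins beyond x=20 are unobserved
        # interpolation extends the last observed value
        np.testing.assert_allclose(left.intensities, 1.0)


class TestNormalize:
    def test_max_mode_identity_when_peak_is_one(self):
        p = SpatialProfile("s", "c", [0.25, 0.5, 0.75], [0.2, 1.0, 0.3])
        out = normalize_profile(p, "max")
        np.testing.assert_array_equal(out.intensities, p.intensities)
        assert out.normalized

    def test_max_mode_scales_to_peak(self):
        p = SpatialProfile("s", "c", [0.25, 0.5, 0.75], [2.0, 4.0, 8.0])
        np.testing.assert_allclose(normalize_profile(p, "max").intensities, [0.25, 0.5, 1.0])

    def test_area_mode_unit_integral(self, rng):
        x = np.linspace(0, 1, 33)
        p = SpatialProfile("s", "c", x, rng.uniform(0.1, 5.0, 33))
        out = normalize_profile(p, "area")
        assert np.trapezoid(out.intensities, out.positions) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_rejected(self):
        p = SpatialProfile("s", "c", [0.2, 0.8], [0.0, 0.0])
        with pytest.raises(ValueError):
            normalize_profile(p)


class TestBuildMatrix:
    def test_single_profile_on_target_grid(self):
        centers = (np.arange(10) + 0.5) / 10
        p = SpatialProfile("s0", "c", centers, np.arange(10, dtype=float) + 1)
        matrix = build_matrix([p], 10)
        np.testing.assert_allclose(matrix.values[:, 0], p.intensities)

    def test_constant_profiles_give_constant_columns(self):
        x = np.linspace(0.1, 0.9, 7)
        p1 = SpatialProfile("a", "c", x, np.full(7, 2.0))
        p2 = SpatialProfile("b", "c", x, np.full(7, 5.0))
        matrix = build_matrix([p1, p2], 12)
        np.testing.assert_allclose(matrix.values[:, 0], 2.0)
        np.testing.assert_allclose(matrix.values[:, 1], 5.0)
        assert matrix.sample_ids == ["a", "b"]

    def test_resampling_matches_hand_rolled_interpolation(self, rng):
        xp = np.sort(rng.uniform(0, 1, 7))
        fp = rng.uniform(1, 4, 7)
        matrix = build_matrix([SpatialProfile("s", "c", xp, fp)], 10)
        for i, x in enumerate((np.arange(10) + 0.5) / 10):
            # explicit piecewise-linear oracle with edge-segment extrapolation
            k = np.clip(np.searchsorted(xp, x) - 1, 0, 5)
            slope = (fp[k + 1] - fp[k]) / (xp[k + 1] - xp[k])
            assert matrix.values[i, 0] == pytest.approx(max(fp[k] + slope * (x - xp[k]), 0.0), abs=1e-12)

    def test_affine_profiles_resample_exactly(self):
        for n_src, n_dst in [(5, 17), (16, 4), (9, 9)]:
            x = (np.arange(n_src) + 0.5) / n_src
            p = SpatialProfile("s", "c", x, 1.0 + 2.0 * x)
            matrix = build_matrix([p], n_dst)
            expected = 1.0 + 2.0 * matrix.bin_centers
            np.testing.assert_allclose(matrix.values[:, 0], expected, atol=1e-12)

    def test_mixed_channels_and_duplicate_ids_rejected(self):
        x = [0.2, 0.8]
        a = SpatialProfile("a", "c1", x, [1, 2])
        b = SpatialProfile("b", "c2", x, [1, 2])
        with pytest.raises(ValueError):
            build_matrix([a, b], 4)
        with pytest.raises(ValueError):
            build_matrix([a, SpatialProfile("a", "c1", x, [3, 4])], 4)


class TestAssignPhase:
    def _band(self, center, width=0.05, n=100):
        x = (np.arange(n) + 0.5) / n
        return SpatialProfile("s", "Lfng_i", x, np.exp(-((x - center) ** 2) / (2 * width**2)))

    def test_posterior_band_is_phase_1(self):
        assert assign_phase(self._band(0.15)).label == 1

    def test_anterior_band_is_phase_3(self):
        assert assign_phase(self._band(0.80)).label == 3

    def test_bimodal_centroid_matches_weighted_mean_oracle(self):
        x = (np.arange(100) + 0.5) / 100
        intensity = 2.0 * np.exp(-((x - 0.2) ** 2) / 0.005) + np.exp(-((x - 0.8) ** 2) / 0.005)
        p = SpatialProfile("s", "c", x, intensity)
        call = assign_phase(p, threshold_fraction=0.3)
        band = intensity >= 0.3 * intensity.max()
        oracle = np.sum(x[band] * intensity[band]) / np.sum(intensity[band])
        assert call.centroid == pytest.approx(oracle)
        assert call.label == (1 if oracle < 1 / 3 else 2 if oracle < 2 / 3 else 3)

    def test_all_zero_rejected(self):
        p = SpatialProfile("s", "c", [0.2, 0.8], [0.0, 0.0])
        with pytest.raises(ValueError):
            assign_phase(p)
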