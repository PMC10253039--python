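"""Classical feature extraction: Otsu, mask cleanup, geometry, HSI color."""

import numpy as np
import pytest

from applegrade.features import (
    CalibrationConfig,
    area_and_perimeter,
    clean_mask,
    color_ratio,
    estimate_diameter,
    extract_features,
    otsu_threshold,
    rgb_to_hue255,
    segment_fruit,
    shape_index,
)

from conftest import disk_mask, ellipse_mask
from _oracles import otsu_brute_force, ramanujan_perimeter


class TestOtsu:
    def test_two_point_histogram_matches_exhaustive_search(self):
        values = np.array([50] * 100 + [200] * 100)
        t, degenerate = otsu_threshold(values)
        assert not degenerate
        assert t == otsu_brute_force(values)

    def test_constant_image_degenerate(self):
        t, degenerate = otsu_threshold(np.full((10, 10), 77))
        assert degenerate and t == 77

    def test_bimodal_gaussians_near_oracle(self):
        rng = np.random.default_rng(42)
        values = np.concatenate(
            [rng.normal(60, 10, 5000), rng.normal(190, 10, 5000)]
        ).clip(0, 255)
        t, _ = otsu_threshold(values)
        assert abs(t - otsu_brute_force(values)) <= 3

    def test_agrees_with_oracle_on_random_histograms(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            mus = rng.uniform(20, 235, size=2)
            sigmas = rng.uniform(3, 25, size=2)
            sizes = rng.integers(200, 2000, size=2)
            values = np.concatenate(
                [rng.normal(m, s, n) for m, s, n in zip(mus, sigmas, sizes)]
            ).clip(0, 255)
            t, _ = otsu_threshold(values)
            assert t == otsu_brute_force(values)

    def test_skimage_cross_check(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(3)
        img = np.concatenate([rng.normal(70, 12, 4000), rng.normal(180, 12, 4000)]).clip(0, 255)
        t, _ = otsu_threshold(img)
        assert abs(t - threshold_otsu(np.rint(img).astype(np.uint8))) <= 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.empty((0,)))


class TestCleanMask:
    def test_interior_hole_filled(self):
        m = disk_mask(30)
        holed = m.copy()
        c = m.shape[0] // 2
        holed[c - 2 : c + 3, c - 2 : c + 3] = False
        cleaned = clean_mask(holed)
        assert cleaned.sum() == m.sum()

    def test_small_speck_removed(self):
        m = disk_mask(20)
        m[1, 1] = m[1, 2] = True
        cleaned = clean_mask(m, min_area=10)
        assert not cleaned[1, 1] and not cleaned[1, 2]
        assert cleaned.sum() == disk_mask(20).sum()

    def test_all_false_passthrough(self):
        m = np.zeros((20, 20), dtype=bool)
        assert clean_mask(m).sum() == 0

    def test_idempotent_on_random_masks(self, rng):
        for _ in range(10):
            m = rng.random((48, 48)) > 0.6
            once = clean_mask(m)
            assert np.array_equal(clean_mask(once), once)


class TestGeometry:
    def test_square_area(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:15, 5:15] = True
        area, _ = area_and_perimeter(m)
        assert area == 100

    @pytest.mark.parametrize("radius", [30, 50, 100])
    def test_disk_area_and_perimeter_near_analytic(self, radius):
        area, perim = area_and_perimeter(disk_mask(radius))
        assert abs(area - np.pi * radius**2) / (np.pi * radius**2) < 0.02
        assert abs(perim - 2 * np.pi * radius) / (2 * np.pi * radius) < 0.03

    def test_sub_measurable_object_rejected(self):
        m = np.zeros((10, 10), dtype=bool)
        m[5, 5] = True
        with pytest.raises(ValueError):
            area_and_perimeter(m)

    def test_empty_and_multi_component_rejected(self):
        with pytest.raises(ValueError):
            area_and_perimeter(np.zeros((10, 10), dtype=bool))
        two = np.zeros((40, 80), dtype=bool)
        two[5:25, 5:25] = True
        two[5:25, 50:70] = True
        with pytest.raises(ValueError):
            area_and_perimeter(two)


class TestShapeIndex:
    def test_ideal_circle_is_exactly_one(self):
        assert shape_index(np.pi, 2 * np.pi) == pytest.approx(1.0, abs=1e-12)

    def test_unit_square(self):
        assert shape_index(1.0, 4.0) == pytest.approx(np.pi / 4, abs=1e-12)

    def test_two_to_one_ellipse_matches_arithmetic_oracle(self):
        a, b = 2.0, 1.0
        area = np.pi * a * b
        perim = ramanujan_perimeter(a, b)
        assert shape_index(area, perim) == pytest.approx(4 * np.pi * area / perim**2, abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            shape_index(0.0, 1.0)
        with pytest.raises(ValueError):
            shape_index(1.0, 0.0)

    @pytest.mark.parametrize("radius", [30, 50, 100])
    def test_rasterized_disk_circularity_near_one(self, radius):
        area, perim = area_and_perimeter(disk_mask(radius))
        assert 0.95 <= shape_index(area, perim) <= 1.05

    def test_strictly_decreasing_along_ellipse_family(self):
        """At fixed area, flatter ellipses have strictly lower circularity."""
        area = np.pi * 60**2
        values = []
        for q in (1.0, 0.8, 0.6, 0.4):
            a = np.sqrt(area / (np.pi * q))
            values.append(4 * np.pi * area / ramanujan_perimeter(a, a * q) ** 2)
        assert all(x > y for x, y in zip(values, values[1:]))
        # and the rasterized measurement agrees with the analytic ordering
        measured = []
        for q in (1.0, 0.8, 0.6, 0.4):
            a = np.sqrt(area / (np.pi * q))
            s, p = area_and_perimeter(ellipse_mask(a, a * q))
            measured.append(shape_index(s, p))
        assert all(x > y for x, y in zip(measured, measured[1:]))


class TestDiameter:
    def test_arithmetic_example(self):
        assert estimate_diameter(np.pi * 100**2, CalibrationConfig(0.35)) == pytest.approx(70.0)

    def test_unit_case(self):
        assert estimate_diameter(np.pi, CalibrationConfig(1.0)) == pytest.approx(2.0)

    def test_linear_in_calibration(self, rng):
        for _ in range(5):
            s = float(rng.uniform(100, 1e5))
            m = float(rng.uniform(0.1, 1.0))
            d1 = estimate_diameter(s, CalibrationConfig(m))
            d2 = estimate_diameter(s, CalibrationConfig(2 * m))
            assert d2 == pytest.approx(2 * d1, rel=1e-12)

    @pytest.mark.parametrize("radius", [60, 100])
    def test_disk_closure_with_area_measurement(self, radius, calib):
        area, _ = area_and_perimeter(disk_mask(radius))
        d = estimate_diameter(area, calib)
        assert d == pytest.approx(2 * radius * calib.mm_per_px, rel=0.02)

    def test_invalid_area(self, calib):
        with pytest.raises(ValueError):
            estimate_diameter(0.0, calib)


class TestHueConversion:
    def test_pure_red_hue_zero(self):
        img = np.zeros((1, 1, 3))
        img[0, 0] = (255, 0, 0)
        hue, sat, defined = rgb_to_hue255(img)
        assert defined[0, 0]
        assert hue[0, 0] == pytest.approx(0.0, abs=1e-6)
        assert sat[0, 0] == pytest.approx(1.0)

    def test_pure_green_hue(self):
        img = np.zeros((1, 1, 3))
        img[0, 0] = (0, 255, 0)
        hue, _, defined = rgb_to_hue255(img)
        assert defined[0, 0]
        assert abs(hue[0, 0] - 120 * 255 / 360) <= 1

    def test_gray_has_no_hue(self):
        img = np.full((2, 2, 3), 128.0)
        hue, sat, defined = rgb_to_hue255(img)
        assert not defined.any()
        assert (sat == 0).all()
        assert (hue == 0).all()


class TestColorRatio:
    def _image(self, colors):
        h = len(colors)
        img = np.zeros((h, 4, 3))
        for i, c in enumerate(colors):
            img[i, :, :] = c
        return img

    def test_fully_red_is_one(self):
        img = self._image([(255, 0, 0)] * 4)
        mask = np.ones((4, 4), dtype=bool)
        assert color_ratio(img, mask) == 1.0

    def test_half_red_half_green_is_half(self):
        img = self._image([(255, 0, 0), (255, 0, 0), (0, 255, 0), (0, 255, 0)])
        mask = np.ones((4, 4), dtype=bool)
        assert color_ratio(img, mask) == 0.5

    def test_gray_region_scores_zero(self):
        img = self._image([(120, 120, 120)] * 4)
        mask = np.ones((4, 4), dtype=bool)
        assert color_ratio(img, mask) == 0.0

    def test_permutation_invariant_within_mask(self, rng):
        img = rng.uniform(0, 255, size=(16, 16, 3))
        mask = np.ones((16, 16), dtype=bool)
        base = color_ratio(img, mask)
        flat = img.reshape(-1, 3)
        perm = rng.permutation(flat.shape[0])
        shuffled = flat[perm].reshape(16, 16, 3)
        assert color_ratio(shuffled, mask) == pytest.approx(base, abs=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            color_ratio(np.zeros((4, 4, 3)), np.zeros((4, 4), dtype=bool))


def test_extract_features_on_synthetic_disk(calib):
    """A flat red disk against dark background measures as a circular,
    fully red fruit of the analytically expected diameter."""
    mask = disk_mask(90)
    img = np.zeros(mask.shape + (3,))
    img[:] = (30, 32, 35)
    img[mask] = (200, 30, 40)
    feats = extract_features(img, calib)
    assert feats.color_ratio > 0.99
    assert 0.95 <= feats.shape_index <= 1.05
    assert feats.diameter_mm == pytest.approx(2 * 90 * calib.mm_per_px, rel=0.02)
    assert feats.defect_area_cm2 == 0.0


def test_segment_fruit_needs_contrast():
    with pytest.raises(ValueError):
        segment_fruit(np.full((20, 20, 3), 50.0))
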