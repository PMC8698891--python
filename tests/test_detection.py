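import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import vitreoct as vo
from oracles import (
    brute_force_otsu,
    covariance_moments,
    eccentricity_from_moments,
    flood_fill_label,
    quartile_fence,
    same_partition,
)
from vitreoct.detection import (
    DetectionParams,
    denoise_regions,
    horizontal_edge_filter,
    label_components,
    measure_opacity,
    otsu_threshold,
    tukey_upper_fence,
)
from vitreoct.synthetic import OpacitySpec


class TestEdgeFilter:
    def test_constant_image_zero_response(self):
        assert np.all(horizontal_edge_filter(np.full((10, 10), 37.0)) == 0)

    def test_horizontal_step_magnitude(self):
        img = np.zeros((10, 10))
        img[5:] = 100.0
        mag = horizontal_edge_filter(img)
        assert np.all(mag[4:6, :] == 400)
        assert np.all(mag[:4, :] == 0) and np.all(mag[6:, :] == 0)

    def test_vertical_edge_cancels(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 100.0
        mag = horizontal_edge_filter(img)
        assert np.all(mag[1:-1, :] == 0)

    def test_signed_response_antisymmetric(self):
        img = np.zeros((10, 10))
        img[5:] = 100.0
        signed = horizontal_edge_filter(img, signed=True)
        assert signed[4, 3] == -400 and signed[5, 3] == -400

    def test_too_small_image(self):
        with pytest.raises(ValueError):
            horizontal_edge_filter(np.zeros((2, 5)))


class TestOtsu:
    def test_bimodal_split(self):
        img = np.array([20] * 50 + [220] * 50, dtype=float).reshape(10, 10)
        t = otsu_threshold(img)
        assert 20 < t < 220
        assert np.array_equal(img > t, img == 220)

    def test_constant_image_convention(self):
        img = np.full((5, 5), 42.0)
        t = otsu_threshold(img)
        assert t == 42.0
        assert not np.any(img > t)

    def test_exhaustive_search_oracle(self, rng):
        for _ in range(100):
            img = rng.integers(0, 256, size=(32, 32)).astype(float)
            t = otsu_threshold(img)
            _, best_var = brute_force_otsu(img)
            # the returned threshold attains the optimal within-class variance
            lo = img[img <= t]
            hi = img[img > t]
            w = (lo.size * lo.var() + hi.size * hi.var()) / img.size
            assert w == pytest.approx(best_var, rel=1e-9, abs=1e-9)

    def test_agrees_with_skimage(self, rng):
        skimage_filters = pytest.importorskip("skimage.filters")
        for _ in range(20):
            img = rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
            ours = otsu_threshold(img)
            ref = skimage_filters.threshold_otsu(img, nbins=256)
            binwidth = (img.max() - img.min()) / 256
            assert abs(ours - ref) <= binwidth + 1e-9


class TestLabeling:
    def test_diagonal_touch_is_one_region_8conn(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        labels, n = label_components(mask)
        assert n == 1
        _, n4 = label_components(mask, connectivity=4)
        assert n4 == 2

    def test_blob_clipped_by_vitreous_mask(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3:7, 4] = True
        vitreous = np.zeros((10, 10), dtype=bool)
        vitreous[:5] = True
        labels, n = label_components(mask, vitreous)
        assert n == 1
        assert labels[:, 4].tolist() == [0, 0, 0, 1, 1, 0, 0, 0, 0, 0]

    def test_flood_fill_oracle_random_masks(self, rng):
        for _ in range(200):
            mask = rng.random((16, 16)) < 0.4
            labels, _ = label_components(mask)
            oracle = flood_fill_label(mask, connectivity=8)
            assert same_partition(labels, oracle)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            label_components(np.zeros((4, 4), bool), np.zeros((5, 4), bool))


class TestTukeyFence:
    def test_documented_example(self):
        values = [10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 250]
        fence = tukey_upper_fence(values)
        assert fence == pytest.approx(quartile_fence(values))
        assert [v for v in values if v > fence] == [250]

    def test_all_equal(self):
        assert tukey_upper_fence([5.0] * 8) == 5.0

    def test_fewer_than_four_is_infinite(self):
        assert tukey_upper_fence([1, 2, 3]) == math.inf

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            tukey_upper_fence([])

    @given(st.lists(st.floats(0, 255), min_size=4, max_size=40))
    def test_fence_at_least_q3(self, values):
        fence = tukey_upper_fence(values)
        assert fence >= np.percentile(values, 75) - 1e-9


def _label_image_with_means(shape, regions):
    """Build (labels, image) with given per-region intensities on a dark field."""
    labels = np.zeros(shape, dtype=np.int32)
    image = np.full(shape, 10.0)
    for i, (r, c, val) in enumerate(regions, start=1):
        labels[r, c : c + 2] = i
        image[r, c : c + 2] = val
    return labels, image


class TestDenoise:
    def test_region_reference_keeps_only_outlier(self):
        regions = [(2 * i, 2, 10 + i) for i in range(10)] + [(21, 2, 250)]
        labels, image = _label_image_with_means((24, 8), regions)
        survivors = denoise_regions(labels, image, reference="regions")
        assert survivors.tolist() == [11]

    def test_region_reference_equal_intensities_all_removed(self):
        regions = [(2 * i, 2, 100) for i in range(6)]
        labels, image = _label_image_with_means((16, 8), regions)
        assert denoise_regions(labels, image, reference="regions").size == 0

    def test_background_reference_keeps_bright_regions(self):
        regions = [(2 * i, 2, 100) for i in range(6)]
        labels, image = _label_image_with_means((16, 8), regions)
        vitreous = np.ones((16, 8), dtype=bool)
        survivors = denoise_regions(labels, image, vitreous_mask=vitreous)
        assert survivors.tolist() == [1, 2, 3, 4, 5, 6]

    def test_no_regions(self):
        labels = np.zeros((4, 4), dtype=np.int32)
        assert denoise_regions(labels, np.zeros((4, 4)), reference="regions").size == 0


class TestMeasure:
    CAL = vo.default_calibration()

    def test_single_pixel(self):
        op = measure_opacity((np.array([5]), np.array([7])), np.full((10, 10), 99.0), self.CAL)
        assert op.area_um2 == pytest.approx(3.815, abs=5e-4)
        assert op.eccentricity == 0.0
        assert op.orientation_deg == 0.0
        assert op.mean_intensity == 99.0

    def test_horizontal_line_closed_form(self):
        rows = np.zeros(20, dtype=int) + 3
        cols = np.arange(20)
        op = measure_opacity((rows, cols), np.zeros((10, 30)), self.CAL)
        assert op.eccentricity == pytest.approx(math.sqrt(1 - 1 / 400), abs=1e-12)
        assert op.orientation_deg == 0.0

    def test_vertical_line_is_90_degrees(self):
        rows = np.arange(20)
        cols = np.zeros(20, dtype=int) + 3
        op = measure_opacity((rows, cols), np.zeros((30, 10)), self.CAL)
        assert op.orientation_deg == 90.0

    def test_rasterized_disc_nearly_circular(self):
        rr, cc = np.meshgrid(np.arange(30), np.arange(30), indexing="ij")
        mask = (rr - 15) ** 2 + (cc - 15) ** 2 <= 100
        op = measure_opacity(mask, np.zeros((30, 30)), self.CAL)
        assert op.eccentricity <= 0.1

    def test_moments_match_covariance_oracle(self, rng):
        for _ in range(50):
            n = rng.integers(2, 60)
            rows = rng.integers(0, 40, n)
            cols = rng.integers(0, 40, n)
            op = measure_opacity((rows, cols), np.zeros((40, 40)), self.CAL)
            ecc = eccentricity_from_moments(*covariance_moments(rows, cols))
            assert op.eccentricity == pytest.approx(ecc, abs=1e-9, rel=1e-9)

    def test_translation_invariance_and_rotation_mapping(self, rng):
        rows = rng.integers(0, 10, 25)
        cols = rng.integers(0, 10, 25)
        img = np.zeros((60, 60))
        a = measure_opacity((rows, cols), img, self.CAL)
        b = measure_opacity((rows + 17, cols + 23), img, self.CAL)
        assert b.eccentricity == pytest.approx(a.eccentricity, abs=1e-12)
        assert b.orientation_deg == pytest.approx(a.orientation_deg, abs=1e-12)
        # 90-degree rotation: swap rows/cols mirrors the orientation range
        c = measure_opacity((cols, rows), img, self.CAL)
        if a.eccentricity > 1e-9:
            expected = 90.0 - a.orientation_deg
            if expected > 90.0:
                expected -= 180.0
            assert c.orientation_deg == pytest.approx(expected, abs=1e-9)

    def test_empty_region_errors(self):
        with pytest.raises(ValueError):
            measure_opacity((np.array([]), np.array([])), np.zeros((4, 4)), self.CAL)


class TestDetectPipeline:
    def test_noiseless_planted_opacities_recovered_exactly(
        self, clean_scene, clean_calibration
    ):
        specs = tuple(
            OpacitySpec(
                center=(80 + 90 * i, 60 + 12 * i),
                semi_major_px=6,
                semi_minor_px=3,
                orientation_deg=30.0 * i - 60,
                intensity=180,
            )
            for i in range(5)
        )
        scene = replace(clean_scene, opacities=specs)
        bscan, truth = vo.render_bscan(scene, clean_calibration, seed=0)
        _, masks = vo.segment(bscan)
        ops = vo.detect_opacities(bscan, masks, clean_calibration)
        assert len(ops) == 5
        detected = np.zeros(scene.shape, dtype=bool)
        for op in ops:
            detected[op.rows, op.cols] = True
        assert np.array_equal(detected, truth.labels > 0)

    def test_opacity_free_noisy_scene_rarely_spurious(self, speckle_scene, speckle_calibration):
        spurious = []
        for seed in range(30):
            bscan, _ = vo.render_bscan(speckle_scene, speckle_calibration, seed=seed)
            _, masks = vo.segment(bscan)
            spurious.append(len(vo.detect_opacities(bscan, masks, speckle_calibration)))
        assert np.mean(np.array(spurious) <= 1) >= 0.95

    def test_measured_area_within_perimeter_of_planted(self, clean_scene, clean_calibration):
        a, b = 8.0, 5.0
        spec = OpacitySpec(center=(120, 80), semi_major_px=a, semi_minor_px=b, intensity=170)
        bscan, truth = vo.render_bscan(
            replace(clean_scene, opacities=(spec,)), clean_calibration, seed=0
        )
        _, masks = vo.segment(bscan)
        ops = vo.detect_opacities(bscan, masks, clean_calibration)
        assert len(ops) == 1
        perimeter = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
        tolerance = perimeter * clean_calibration.pixel_area_um2
        assert abs(ops[0].area_um2 - truth.opacities[0].area_um2) <= tolerance

    def test_connectivity_option(self):
        params = DetectionParams(connectivity=4)
        assert params.connectivity == 4
        with pytest.raises(ValueError):
            DetectionParams(connectivity=6)
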