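"""Trait measurement: analytic shapes, caliper oracles, scaling laws."""

import numpy as np
import pytest
from skimage import draw

from conftest import random_blob_mask
from potpheno.imaging import Roi
from potpheno.morphometrics import (
    ChainCodeWeights,
    ColorTraitConfig,
    ScaleCalibration,
    box_and_ellipse,
    calibrate,
    color_areas,
    convex_metrics,
    max_feret,
    measure_all,
    min_feret,
    perimeter,
    pixel_corner_hull,
)

S01 = ScaleCalibration(0.1)
S1 = ScaleCalibration(1.0)


def brute_force_feret(points):
    """O(n^2) max pairwise distance oracle."""
    pts = np.asarray(points, float)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    return float(d.max())


class TestCalibrate:
    def test_ruler_example(self):
        assert calibrate(200, 10).cm_per_pixel == pytest.approx(0.05)

    def test_identity(self):
        assert calibrate(1, 1).cm_per_pixel == 1.0

    @pytest.mark.parametrize("px, cm", [(0, 10), (-5, 10), (10, 0)])
    def test_non_positive_rejected(self, px, cm):
        with pytest.raises(ValueError):
            calibrate(px, cm)

    def test_rendered_ruler_round_trip(self, fan_render):
        """Measuring the rendered ruler bar recovers the spec length."""
        img, _, spec = fan_render
        margin = img[-40:]  # ruler lives in the reserved bottom strip
        dark = (margin < 100).all(axis=-1)
        bar_cols = np.nonzero(dark.any(axis=0))[0]
        measured_px = bar_cols.max() - bar_cols.min() + 1
        cal = calibrate(measured_px, spec.ruler_length_cm)
        assert cal.cm_per_pixel == pytest.approx(spec.cm_per_pixel, rel=0.01)


class TestConvexMetrics:
    def test_rectangle_analytics(self, rect_mask):
        area, feret, mferet = convex_metrics(rect_mask, S01)
        assert area == pytest.approx(50.0, rel=0.02)
        assert feret == pytest.approx(np.hypot(10, 5), rel=0.02)
        assert mferet == pytest.approx(5.0, rel=0.02)

    def test_disc_analytics(self, disc_mask):
        _, feret, mferet = convex_metrics(disc_mask, S01)
        assert feret == pytest.approx(20.0, rel=0.01)
        assert mferet == pytest.approx(20.0, rel=0.01)
        assert feret >= mferet

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            convex_metrics(np.zeros((5, 5), bool), S1)

    def test_caliper_equals_brute_force_on_random_blobs(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            hull = pixel_corner_hull(random_blob_mask(rng))
            assert max_feret(hull) == pytest.approx(
                brute_force_feret(hull), abs=1e-9
            )

    def test_convex_area_bounds_pixel_area(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = random_blob_mask(rng)
            area, feret, mferet = convex_metrics(m, S1)
            assert area >= m.sum() - 1e-9
            assert feret >= mferet >= 0


class TestBoxAndEllipse:
    def test_rectangle_box(self, rect_mask):
        w, h, *_ = box_and_ellipse(rect_mask, S01)
        assert w == pytest.approx(10.0, abs=0.1)
        assert h == pytest.approx(5.0, abs=0.1)

    def test_disc_identities(self, disc_mask):
        _, _, major, minor, aspect, roundness = box_and_ellipse(disc_mask, S01)
        assert major == pytest.approx(20.0, rel=0.01)
        assert minor == pytest.approx(20.0, rel=0.01)
        assert aspect == pytest.approx(1.0, abs=0.01)
        assert roundness == pytest.approx(1.0, abs=0.02)

    def test_known_ellipse_recovery(self):
        m = np.zeros((220, 220), bool)
        rr, cc = draw.ellipse(110, 110, 30, 80)
        m[rr, cc] = True
        _, _, major, minor, _, _ = box_and_ellipse(m, S1)
        assert major / 2 == pytest.approx(80, rel=0.02)
        assert minor / 2 == pytest.approx(30, rel=0.02)


class TestPerimeter:
    def test_disc_against_circumference(self, disc_mask):
        p = perimeter(disc_mask, S01)
        assert p == pytest.approx(2 * np.pi * 10.0, rel=0.03)

    def test_naive_weights_overestimate_smooth_outlines(self, disc_mask):
        """The uncorrected (1, sqrt2) estimator carries the classic ~5%
        bias on smooth boundaries; the corrected default does not."""
        naive = perimeter(disc_mask, S01, weights=ChainCodeWeights.NAIVE)
        assert naive / (2 * np.pi * 10.0) == pytest.approx(1.05, abs=0.02)

    def test_single_pixel_constant(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert perimeter(m, ScaleCalibration(2.0)) == pytest.approx(8.0)

    def test_scale_linearity(self, disc_mask):
        assert perimeter(disc_mask, ScaleCalibration(0.3)) == pytest.approx(
            3 * perimeter(disc_mask, S01)
        )

    def test_sums_over_components_outer_boundaries_only(self):
        m = np.zeros((40, 80), bool)
        m[5:25, 5:25] = True
        m[10:20, 10:15] = False  # hole: must not contribute
        m[5:25, 45:65] = True
        single = np.zeros((40, 40), bool)
        single[5:25, 5:25] = True
        assert perimeter(m, S1) == pytest.approx(2 * perimeter(single, S1))


class TestColorAreas:
    def _uniform_roi(self, rgb, n=10):
        img = np.zeros((n, n, 3), dtype=np.uint8)
        img[...] = rgb
        mask = np.zeros((n, n), dtype=np.uint8)
        mask[2:8, 2:8] = 1
        color = img.astype(float).copy()
        color[mask == 0] = np.nan
        return Roi(mask=mask, color=color)

    def test_pure_green_plant(self):
        roi = self._uniform_roi((0, 255, 0))
        out = color_areas(roi, S1)
        assert out["green_area"] == pytest.approx(roi.pixel_count)
        assert out["green_index"] == pytest.approx(1.0)
        assert out["red_index"] == out["blue_index"] == pytest.approx(0.0)

    def test_achromatic_plant_has_zero_saturation_area(self):
        roi = self._uniform_roi((120, 120, 120))
        out = color_areas(roi, S1)
        assert out["saturation_area"] == 0.0
        assert out["ratio_sat_conv"] == 0.0

    def test_rgb_indices_normalized_on_random_rois(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            rgb = tuple(rng.integers(1, 256, 3))
            out = color_areas(self._uniform_roi(rgb), S1)
            total = out["red_index"] + out["green_index"] + out["blue_index"]
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_integrated_density_is_count_times_mean_brightness(self):
        roi = self._uniform_roi((0, 255, 0))
        out = color_areas(roi, S1)
        assert out["integrated_density"] == pytest.approx(roi.pixel_count * 100.0)


class TestMeasureAll:
    def test_fan_matches_ground_truth_within_5pct(self, fan_render, fan_roi):
        _, gt, _ = fan_render
        roi, scale = fan_roi
        rec = measure_all(roi, scale)
        assert rec.convex_area == pytest.approx(gt.true_convex_area, rel=0.05)
        assert rec.width == pytest.approx(gt.true_width, rel=0.05)
        assert rec.height == pytest.approx(gt.true_height, rel=0.05)
        assert rec.feret == pytest.approx(gt.true_feret, rel=0.05)
        assert rec.min_feret == pytest.approx(gt.true_minferet, rel=0.05)
        assert rec.perimeter == pytest.approx(gt.true_perimeter, rel=0.05)

    def test_record_invariants_on_disc(self, disc_mask):
        img = np.zeros(disc_mask.shape + (3,), dtype=np.uint8)
        img[disc_mask] = (40, 180, 60)
        color = img.astype(float)
        color[~disc_mask] = np.nan
        rec = measure_all(Roi(mask=disc_mask.astype(np.uint8), color=color), S01)
        assert rec.feret >= rec.min_feret >= 0
        assert rec.aspect_ratio >= 1.0
        assert 0 < rec.roundness <= 1.05
        assert 0 <= rec.ratio_sat_conv <= 1.05
        assert rec.red_index + rec.green_index + rec.blue_index == pytest.approx(1.0)

    def test_determinism(self, fan_roi):
        roi, scale = fan_roi
        assert measure_all(roi, scale) == measure_all(roi, scale)

    def test_length_and_area_scaling_laws(self, fan_roi):
        roi, _ = fan_roi
        a = measure_all(roi, ScaleCalibration(0.05))
        b = measure_all(roi, ScaleCalibration(0.15))
        for trait in ("width", "height", "feret", "min_feret", "perimeter",
                      "major", "minor"):
            assert getattr(b, trait) == pytest.approx(3 * getattr(a, trait))
        for trait in ("convex_area", "green_area", "saturation_area"):
            assert getattr(b, trait) == pytest.approx(9 * getattr(a, trait))

    def test_rotation_robustness(self):
        """Rotation-invariant traits move < 3% when the same vector
        shape is digitized at 0 and 30 degrees (width/height are
        axis-aligned by definition and exempt)."""
        import shapely
        from shapely import affinity
        from shapely.geometry import Point, box

        geom = Point(0, 0).buffer(100).union(box(-105, -25, 0, 25))

        def rasterize(g, pad=10):
            minx, miny, maxx, maxy = g.bounds
            g = affinity.translate(g, -minx + pad, -miny + pad)
            w, h = int(maxx - minx) + 2 * pad, int(maxy - miny) + 2 * pad
            cols, rows = np.meshgrid(np.arange(w), np.arange(h))
            return shapely.contains_xy(g, cols + 0.5, rows + 0.5)

        m0 = rasterize(geom)
        m30 = rasterize(affinity.rotate(geom, 30))
        a_area, a_feret, a_mferet = convex_metrics(m0, S1)
        b_area, b_feret, b_mferet = convex_metrics(m30, S1)
        assert b_area == pytest.approx(a_area, rel=0.03)
        assert b_feret == pytest.approx(a_feret, rel=0.03)
        assert b_mferet == pytest.approx(a_mferet, rel=0.03)
        assert perimeter(m30, S1) == pytest.approx(perimeter(m0, S1), rel=0.03)
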