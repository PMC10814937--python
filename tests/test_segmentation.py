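"""Boundary closing, automatic segmentation, band geometry and features."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lesioncolor import (
    ClosedBoundary,
    ScaleCalibration,
    SegmentationFailure,
    auto_segment,
    boundary_to_mask,
    calibrate_scale,
    close_boundary,
    geometry_features,
    normal_skin_band,
)
from lesioncolor.synthetic import SyntheticLesionSpec, generate_lesion_image


def circle_points(n, r=50.0, cx=100.0, cy=100.0):
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return np.c_[cx + r * np.cos(t), cy + r * np.sin(t)]


class TestCloseBoundary:
    def test_circle_points_recovered_within_half_pixel(self):
        boundary = close_boundary(circle_points(12), n_vertices=400)
        radii = np.hypot(*(boundary.vertices - [100, 100]).T)
        assert np.abs(radii - 50.0).max() < 0.5

    def test_spline_residual_not_worse_than_polyline(self, rng):
        # interpolating spline passes through the input points, so its
        # mean-square distance is <= any polygonal chain's
        pts = circle_points(10) + rng.normal(0, 2, size=(10, 2))
        boundary = close_boundary(pts, n_vertices=1000)
        d = np.min(
            np.linalg.norm(
                boundary.vertices[None, :, :] - pts[:, None, :], axis=2
            ),
            axis=1,
        )
        assert np.mean(d**2) < 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            close_boundary(circle_points(3))

    def test_collinear_points_rejected(self):
        pts = np.c_[np.arange(5.0), np.arange(5.0) * 2.0]
        with pytest.raises(ValueError, match="collinear"):
            close_boundary(pts)


class TestAutoSegment:
    def test_recovers_synthetic_ellipse_dice(self, lesion_sample):
        boundary = auto_segment(lesion_sample.image)
        mask = boundary_to_mask(boundary, lesion_sample.image.shape[:2])
        truth = lesion_sample.lesion_mask
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.95

    def test_uniform_image_signals_failure(self):
        img = np.full((64, 64, 3), 128, dtype=np.uint8)
        with pytest.raises(SegmentationFailure):
            auto_segment(img)

    def test_lesion_touching_edge_yields_simple_polygon(self):
        spec = SyntheticLesionSpec(center=(10.0, 128.0), seed=3)
        sample = generate_lesion_image(spec)
        boundary = auto_segment(sample.image)
        assert boundary.polygon.is_simple
        assert boundary.vertices[:, 0].min() >= 0
        mask = boundary_to_mask(boundary, sample.image.shape[:2])
        truth = sample.lesion_mask
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.9

    def test_segmented_area_within_5pct_of_truth(self, lesion_sample):
        boundary = auto_segment(lesion_sample.image)
        feats = geometry_features(boundary, ScaleCalibration(1.0))
        true_area = math.pi * 60.0 * 40.0
        assert feats.surface_cm2 == pytest.approx(true_area, rel=0.05)


class TestNormalSkinBand:
    def test_annulus_pixel_count_on_circle(self):
        boundary = ClosedBoundary(circle_points(200, r=40.0))
        band = normal_skin_band(boundary, (200, 200), factor=1.25)
        expected = math.pi * 40.0**2 * (1.25**2 - 1.0)
        assert band.sum() == pytest.approx(expected, rel=0.02)

    def test_factor_one_rejected(self):
        boundary = ClosedBoundary(circle_points(50))
        with pytest.raises(ValueError):
            normal_skin_band(boundary, (200, 200), factor=1.0)

    def test_band_disjoint_from_lesion_and_union_is_scaled_polygon(self, rng):
        # arbitrary (star-convex) simple polygon
        t = np.sort(rng.uniform(0, 2 * math.pi, 12))
        r = rng.uniform(20, 40, size=12)
        pts = np.c_[90 + r * np.cos(t), 90 + r * np.sin(t)]
        boundary = ClosedBoundary(pts)
        shape = (180, 180)
        lesion = boundary_to_mask(boundary, shape)
        band = normal_skin_band(boundary, shape, factor=1.25)
        assert not (band & lesion).any()
        from shapely.affinity import scale as shp_scale

        poly = boundary.polygon
        c = poly.centroid
        scaled = ClosedBoundary(
            np.asarray(
                shp_scale(poly, 1.25, 1.25, origin=(c.x, c.y)).exterior.coords
            )[:-1]
        )
        assert np.array_equal(band | lesion, boundary_to_mask(scaled, shape))

    def test_band_beyond_frame_warns_and_clips(self):
        boundary = ClosedBoundary(circle_points(100, r=40.0, cx=45.0, cy=45.0))
        with pytest.warns(UserWarning, match="clipping"):
            band = normal_skin_band(boundary, (90, 90), factor=1.25)
        assert band.any()


class TestScaleCalibration:
    def test_horizontal_ruler(self):
        assert calibrate_scale((0, 0), (100, 0), 1.0).cm_per_pixel == 0.01

    def test_3_4_5_triangle(self):
        assert calibrate_scale((0, 0), (30, 40), 5.0).cm_per_pixel == pytest.approx(0.1)

    @given(
        st.floats(-100, 100), st.floats(-100, 100),
        st.floats(-100, 100), st.floats(-100, 100),
    )
    def test_matches_euclidean_formula(self, x1, y1, x2, y2):
        if (x1, y1) == (x2, y2):
            return
        d = math.sqrt((x2 - x1) ** 2 + (y2 - y1) ** 2)
        got = calibrate_scale((x1, y1), (x2, y2), 2.5).cm_per_pixel
        assert got == pytest.approx(2.5 / d)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            calibrate_scale((5, 5), (5, 5), 1.0)


class TestGeometryFeatures:
    def test_unit_square(self):
        square = ClosedBoundary(
            np.array([[0, 0], [100, 0], [100, 100], [0, 100]], dtype=float)
        )
        feats = geometry_features(square, ScaleCalibration(0.01))
        assert feats.surface_cm2 == pytest.approx(1.0)
        assert feats.perimeter_cm == pytest.approx(4.0)
        assert feats.max_diameter_cm == pytest.approx(math.sqrt(2), abs=1e-9)

    def test_circle_closed_forms(self):
        boundary = ClosedBoundary(circle_points(200, r=100.0))
        feats = geometry_features(boundary, ScaleCalibration(0.01))
        assert feats.surface_cm2 == pytest.approx(math.pi, abs=0.01)
        assert feats.perimeter_cm == pytest.approx(2 * math.pi, abs=0.01)
        assert feats.max_diameter_cm == pytest.approx(2.0, abs=0.01)

    def test_diameter_matches_exhaustive_pairwise_scan(self, rng):
        for _ in range(10):
            pts = rng.uniform(0, 200, size=(12, 2))
            from scipy.spatial import ConvexHull

            hull = pts[ConvexHull(pts).vertices]
            boundary = ClosedBoundary(hull)
            feats = geometry_features(boundary, ScaleCalibration(1.0))
            brute = max(
                np.linalg.norm(p - q) for p in hull for q in hull
            )
            assert feats.max_diameter_cm == pytest.approx(brute)

    def test_isoperimetric_inequality_holds(self, rng):
        for _ in range(10):
            t = np.sort(rng.uniform(0, 2 * math.pi, 15))
            r = rng.uniform(10, 50, size=15)
            boundary = ClosedBoundary(np.c_[r * np.cos(t), r * np.sin(t)])
            feats = geometry_features(boundary, ScaleCalibration(0.05))
            assert 4 * math.pi * feats.surface_cm2 <= feats.perimeter_cm**2 + 1e-9


class TestClosedBoundary:
    def test_self_intersecting_polygon_rejected(self):
        bowtie = np.array([[0, 0], [10, 10], [10, 0], [0, 10]], dtype=float)
        with pytest.raises(ValueError):
            ClosedBoundary(bowtie)

    def test_csv_round_trip(self, tmp_path):
        boundary = ClosedBoundary(circle_points(30))
        path = tmp_path / "b.csv"
        boundary.to_csv(path)
        back = ClosedBoundary.from_csv(path)
        assert np.allclose(back.vertices, boundary.vertices)

    def test_geojson_ring_closed(self):
        boundary = ClosedBoundary(circle_points(10))
        ring = boundary.to_geojson()["coordinates"][0]
        assert ring[0] == ring[-1]
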