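"""Lesion boundary delineation, ring-band geometry and scale calibration.

A lesion is delineated either automatically (color-distance thresholding)
or manually, by placing points along the border that are closed with a
periodic second-order spline. The surrounding "normal skin" reference
region is the band between the lesion boundary and the same boundary
enlarged by 25% (a similarity transform about the area centroid). A
handheld ruler in the photograph provides the cm-per-pixel scale from
which maximal diameter, surface and perimeter are reported.

Coordinate convention: 0-based pixel centers, x to the right, y down,
origin at the top-left pixel center. Pixel membership in a polygon is
decided by pixel-center containment (even-odd rule).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.interpolate import splev, splprep
from shapely.affinity import scale as _shapely_scale
from shapely.geometry import Polygon
from skimage import filters, measure, morphology

from .colorimetry import image_to_lab

__all__ = [
    "ClosedBoundary",
    "ScaleCalibration",
    "GeometryFeatures",
    "SegmentationFailure",
    "close_boundary",
    "auto_segment",
    "boundary_to_mask",
    "normal_skin_band",
    "calibrate_scale",
    "geometry_features",
]


class SegmentationFailure(RuntimeError):
    """Automatic segmentation found no usable lesion component."""


@dataclass(frozen=True)
class ClosedBoundary:
    """Ordered simple polygon delineating a lesion, in pixel coordinates.

    The polygon is implicitly closed (last vertex connects to the first)
    and must be non-self-intersecting with positive enclosed area.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("boundary needs >=3 (x, y) vertices")
        if not np.isfinite(v).all():
            raise ValueError("boundary vertices must be finite")
        poly = Polygon(v)
        if not poly.is_simple or not poly.is_valid or poly.area <= 0.0:
            raise ValueError("boundary must be a simple polygon with area > 0")
        object.__setattr__(self, "vertices", v)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.vertices, columns=["x", "y"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ClosedBoundary":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df[["x", "y"]].to_numpy(dtype=float))

    def to_geojson(self) -> dict:
        ring = self.vertices.tolist() + [self.vertices[0].tolist()]
        return {"type": "Polygon", "coordinates": [ring]}


@dataclass(frozen=True)
class ScaleCalibration:
    """Physical scale of a photograph, in centimeters per pixel."""

    cm_per_pixel: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.cm_per_pixel) or self.cm_per_pixel <= 0.0:
            raise ValueError("cm_per_pixel must be positive and finite")


@dataclass(frozen=True)
class GeometryFeatures:
    """Maximal diameter (cm), surface (cm²) and perimeter (cm) of a lesion."""

    max_diameter_cm: float
    surface_cm2: float
    perimeter_cm: float

    def __post_init__(self) -> None:
        if min(self.max_diameter_cm, self.surface_cm2, self.perimeter_cm) <= 0:
            raise ValueError("geometry features must be positive")
        if self.max_diameter_cm > self.perimeter_cm / 2 + 1e-9:
            raise ValueError("diameter exceeds perimeter/2: not a polygon")
        if 4 * math.pi * self.surface_cm2 > self.perimeter_cm**2 + 1e-9:
            raise ValueError("isoperimetric inequality violated")


def close_boundary(
    points: np.ndarray, n_vertices: int = 200, smoothing: float = 0.0
) -> ClosedBoundary:
    """Close manually placed border points with a periodic quadratic spline.

    Fits a periodic order-2 B-spline through the points (least-squares
    smoothing controlled by ``smoothing``; 0 interpolates, so the mean
    squared distance from the points to the curve is 0) and samples it at
    ``n_vertices`` positions to return a polygonal boundary.

    Parameters
    ----------
    points : (N, 2) array
        At least 4 non-collinear (x, y) points in placement order.
    n_vertices : int
        Sampling density of the returned polygon.
    smoothing : float
        ``splprep`` smoothing factor; the spline minimizes curvature
        subject to sum of squared residuals <= smoothing.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array")
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 border points")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("border points are collinear")
    ring = np.vstack([pts, pts[:1]])
    tck, _ = splprep([ring[:, 0], ring[:, 1]], k=2, per=1, s=smoothing)
    u = np.linspace(0.0, 1.0, n_vertices, endpoint=False)
    x, y = splev(u, tck)
    return ClosedBoundary(np.column_stack([x, y]))


def boundary_to_mask(boundary: ClosedBoundary, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a boundary: True where the pixel center lies inside."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return _polygon_mask(boundary.polygon, xx, yy)


def _polygon_mask(poly: Polygon, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    # vectorized pixel-center containment
    shapely.prepare(poly)
    return shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)


def auto_segment(
    image: np.ndarray,
    closing_radius: int = 5,
    min_area: int = 100,
    n_vertices: int = 200,
    highlight_percentile: float | None = None,
) -> ClosedBoundary:
    """Segment the single dominant lesion of a clinical photograph.

    Assumes exactly one dominant lesion on a skin background. Pipeline:
    convert to CIELAB; compute each pixel's Euclidean Lab distance from the
    median color of the image border (taken as normal skin); threshold that
    distance with Otsu's method; close morphologically (disk of
    ``closing_radius``); keep the largest connected component; trace its
    outer contour.

    ``highlight_percentile``, if set (e.g. 99), excludes the brightest
    pixels by L* before thresholding — an optional guard against specular
    flash reflections, off by default since moderate highlights inside the
    lesion do not change the component found.

    Raises
    ------
    SegmentationFailure
        If no connected component reaches ``min_area`` pixels; manual
        delineation with :func:`close_boundary` is the fallback.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    lab = image_to_lab(image)
    border = np.concatenate(
        [lab[0, :], lab[-1, :], lab[1:-1, 0], lab[1:-1, -1]], axis=0
    )
    ref = np.median(border, axis=0)
    dist = np.sqrt(((lab - ref) ** 2).sum(axis=2))
    valid = np.ones(dist.shape, dtype=bool)
    if highlight_percentile is not None:
        valid &= lab[..., 0] <= np.percentile(lab[..., 0], highlight_percentile)
    values = dist[valid]
    if np.ptp(values) == 0.0:
        raise SegmentationFailure("image is uniform: no lesion found")
    thresh = filters.threshold_otsu(values)
    mask = (dist > thresh) & valid
    mask = morphology.closing(mask, morphology.disk(closing_radius))
    labels = measure.label(mask)
    if labels.max() == 0:
        raise SegmentationFailure("no foreground component found")
    sizes = np.bincount(labels.ravel())[1:]
    if sizes.max() < min_area:
        raise SegmentationFailure(
            f"largest component {sizes.max()} px < min_area {min_area}; "
            "consider manual delineation"
        )
    component = labels == (int(sizes.argmax()) + 1)
    # pad so components touching the frame still yield a closed contour
    padded = np.pad(component, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    contour = max(contours, key=len)
    # (row, col) in padded coordinates -> (x, y) in image coordinates
    xy = np.column_stack([contour[:, 1] - 1.0, contour[:, 0] - 1.0])
    xy[:, 0] = np.clip(xy[:, 0], 0, image.shape[1] - 1)
    xy[:, 1] = np.clip(xy[:, 1], 0, image.shape[0] - 1)
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    step = max(1, len(xy) // n_vertices)
    xy = xy[::step]
    poly = Polygon(xy)
    if not (poly.is_valid and poly.is_simple):
        poly = poly.buffer(0)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        xy = np.asarray(poly.exterior.coords)[:-1]
    return ClosedBoundary(xy)


def normal_skin_band(
    boundary: ClosedBoundary,
    shape: tuple[int, int],
    factor: float = 1.25,
) -> np.ndarray:
    """Mask of the surrounding normal-skin band of a lesion.

    The boundary is enlarged by ``factor`` (default 1.25, i.e. border
    incremented by 25%) about its area centroid; the band is every pixel
    inside the enlarged polygon but outside the original one. A band
    extending beyond the image frame is clipped with a warning.
    """
    if not factor > 1.0:
        raise ValueError("band factor must be > 1 (factor 1.0 gives an empty band)")
    poly = boundary.polygon
    c = poly.centroid
    scaled = _shapely_scale(poly, xfact=factor, yfact=factor, origin=(c.x, c.y))
    h, w = shape
    minx, miny, maxx, maxy = scaled.bounds
    if minx < -0.5 or miny < -0.5 or maxx > w - 0.5 or maxy > h - 0.5:
        warnings.warn(
            "normal-skin band extends beyond the image frame; clipping",
            stacklevel=2,
        )
    yy, xx = np.mgrid[0:h, 0:w]
    return _polygon_mask(scaled, xx, yy) & ~_polygon_mask(poly, xx, yy)


def calibrate_scale(p1, p2, known_cm: float) -> ScaleCalibration:
    """Scale from two ruler marks a known distance (cm) apart."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if known_cm <= 0:
        raise ValueError("known_cm must be positive")
    d = float(np.hypot(*(p2 - p1)))
    if d == 0.0:
        raise ValueError("calibration points coincide")
    return ScaleCalibration(known_cm / d)


def geometry_features(
    boundary: ClosedBoundary, scale: ScaleCalibration
) -> GeometryFeatures:
    """Maximal diameter, surface and perimeter of a lesion in cm units.

    Surface is the shoelace polygon area, perimeter the edge-length sum,
    and maximal diameter the largest pairwise vertex distance (computed
    on the convex hull, which attains the same maximum as the full
    brute-force scan).
    """
    poly = boundary.polygon
    hull = np.asarray(poly.convex_hull.exterior.coords)[:-1]
    diff = hull[:, None, :] - hull[None, :, :]
    diameter = float(np.sqrt((diff**2).sum(axis=2)).max())
    s = scale.cm_per_pixel
    return GeometryFeatures(
        max_diameter_cm=diameter * s,
        surface_cm2=poly.area * s**2,
        perimeter_cm=poly.length * s,
    )
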