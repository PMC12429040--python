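"""Polygon geometry and static morphometric descriptors.

A cell footprint is an implicitly closed polygon in pixel coordinates
(x right, y down, origin top-left). All shape moments are computed
analytically from the polygon boundary via Green's theorem, so
descriptors are exact for sub-pixel geometry and strictly invariant to
translation; intensity statistics, which need pixel support, use a
rasterized mask of the same polygon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sstats
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.draw import polygon as _raster_polygon
from skimage.measure import moments_hu as _moments_hu

__all__ = [
    "Polygon",
    "StaticFeatures",
    "InvalidGeometryError",
    "polygon_metrics",
    "polygon_iou",
    "ellipse_fit",
    "shape_ratios",
    "appearance_vector",
    "static_features",
]

#: Pixel calibration printed on the microscope used for the reference data.
DEFAULT_CALIBRATION_UM_PER_PX = 0.5199


class InvalidGeometryError(ValueError):
    """Raised for degenerate polygons (fewer than 3 vertices or zero area)."""


@dataclass(frozen=True)
class Polygon:
    """An implicitly closed polygon; vertices in pixel coordinates.

    Orientation is normalized internally; a polygon whose enclosed area
    is zero (collinear vertices) is rejected.
    """

    vertices: np.ndarray  # (n, 2) float array of (x, y)

    def __init__(self, vertices: Sequence) -> None:
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidGeometryError(
                f"polygon needs >=3 (x, y) vertices, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidGeometryError("polygon vertices must be finite")
        # normalize to counter-clockwise orientation (positive shoelace area)
        if _signed_area(v) < 0:
            v = v[::-1]
        if _signed_area(v) <= 0:
            raise InvalidGeometryError("polygon encloses zero area")
        v.setflags(write=False)
        object.__setattr__(self, "vertices", v)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def area_px2(self) -> float:
        return _signed_area(self.vertices)

    def perimeter_px(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def centroid(self) -> np.ndarray:
        """Area centroid (first moments of the filled region)."""
        m = raw_moments(self.vertices)
        return np.array([m[1, 0] / m[0, 0], m[0, 1] / m[0, 0]])

    def boundary_centroid(self) -> np.ndarray:
        """Mean of the boundary vertices (compatibility alternative)."""
        return self.vertices.mean(axis=0)

    def translated(self, dx: float, dy: float) -> "Polygon":
        return Polygon(self.vertices + np.array([dx, dy]))

    def bounds(self) -> tuple[float, float, float, float]:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return float(x.min()), float(y.min()), float(x.max()), float(y.max())

    def to_shapely(self) -> _ShapelyPolygon:
        p = _ShapelyPolygon(self.vertices)
        if not p.is_valid:
            p = p.buffer(0)
        return p


@dataclass(frozen=True)
class StaticFeatures:
    """Per-cell static morphometry in physical units."""

    area_um2: float
    perimeter_um: float
    circularity: float
    eccentricity: float
    orientation_deg: float
    solidity: float
    aspect_ratio: float
    fill_factor: float
    boundary_smoothness: float


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def raw_moments(v: np.ndarray) -> np.ndarray:
    """Raw area moments M[p, q] = ∫∫ x^p y^q dA up to order 3.

    Exact boundary integrals for a simple polygon (Green's theorem);
    returns a 4x4 array indexed [p, q] with entries of order p+q <= 3.
    Assumes counter-clockwise orientation (positive area).
    """
    x0, y0 = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    c = x0 * y1 - x1 * y0  # cross terms

    m = np.zeros((4, 4))
    m[0, 0] = c.sum() / 2.0
    m[1, 0] = (c * (x0 + x1)).sum() / 6.0
    m[0, 1] = (c * (y0 + y1)).sum() / 6.0
    m[2, 0] = (c * (x0**2 + x0 * x1 + x1**2)).sum() / 12.0
    m[0, 2] = (c * (y0**2 + y0 * y1 + y1**2)).sum() / 12.0
    m[1, 1] = (c * (2 * x0 * y0 + x0 * y1 + x1 * y0 + 2 * x1 * y1)).sum() / 24.0
    m[3, 0] = (c * (x0**3 + x0**2 * x1 + x0 * x1**2 + x1**3)).sum() / 20.0
    m[0, 3] = (c * (y0**3 + y0**2 * y1 + y0 * y1**2 + y1**3)).sum() / 20.0
    m[2, 1] = (
        c
        * (
            x0**2 * (3 * y0 + y1)
            + 2 * x0 * x1 * (y0 + y1)
            + x1**2 * (y0 + 3 * y1)
        )
    ).sum() / 60.0
    m[1, 2] = (
        c
        * (
            y0**2 * (3 * x0 + x1)
            + 2 * y0 * y1 * (x0 + x1)
            + y1**2 * (x0 + 3 * x1)
        )
    ).sum() / 60.0
    return m


def central_moments(poly: Polygon) -> np.ndarray:
    """Central moments mu[p, q] about the area centroid, order <= 3."""
    m = raw_moments(poly.vertices)
    m00 = m[0, 0]
    cx, cy = m[1, 0] / m00, m[0, 1] / m00
    mu = np.zeros((4, 4))
    mu[0, 0] = m00
    mu[2, 0] = m[2, 0] - cx * m[1, 0]
    mu[0, 2] = m[0, 2] - cy * m[0, 1]
    mu[1, 1] = m[1, 1] - cx * m[0, 1]
    mu[3, 0] = m[3, 0] - 3 * cx * m[2, 0] + 2 * cx**2 * m[1, 0]
    mu[0, 3] = m[0, 3] - 3 * cy * m[0, 2] + 2 * cy**2 * m[0, 1]
    mu[2, 1] = m[2, 1] - 2 * cx * m[1, 1] - cy * m[2, 0] + 2 * cx**2 * m[0, 1]
    mu[1, 2] = m[1, 2] - 2 * cy * m[1, 1] - cx * m[0, 2] + 2 * cy**2 * m[1, 0]
    return mu


def normalized_moments(poly: Polygon) -> np.ndarray:
    """Scale-normalized central moments eta[p, q] = mu_pq / mu00^(1+(p+q)/2)."""
    mu = central_moments(poly)
    eta = np.zeros((4, 4))
    m00 = mu[0, 0]
    for p in range(4):
        for q in range(4):
            if 2 <= p + q <= 3:
                eta[p, q] = mu[p, q] / m00 ** (1 + (p + q) / 2.0)
    return eta


def polygon_metrics(
    poly: Polygon, calib: float = DEFAULT_CALIBRATION_UM_PER_PX
) -> tuple[float, float, float]:
    """Area (µm²), perimeter (µm) and circularity of one cell footprint.

    Circularity is 4πA/P², 1 for a perfect circle and below 1 for any
    other shape; it is unit-free so the calibration cancels.
    """
    if calib <= 0:
        raise ValueError(f"calibration must be positive, got {calib}")
    area_px2 = poly.area_px2()
    perim_px = poly.perimeter_px()
    area = area_px2 * calib**2
    perim = perim_px * calib
    circularity = 4.0 * np.pi * area / perim**2
    return float(area), float(perim), float(circularity)


def polygon_iou(a: Polygon, b: Polygon) -> float:
    """Intersection-over-union of two filled polygons; symmetric, in [0, 1]."""
    sa, sb = a.to_shapely(), b.to_shapely()
    inter = sa.intersection(sb).area
    if inter == 0.0:
        return 0.0
    union = sa.union(sb).area
    return float(inter / union)


def ellipse_fit(poly: Polygon) -> tuple[float, float, float, float]:
    """Equivalent-ellipse fit from second-order central moments.

    Returns (eccentricity, orientation_deg, major, minor) where major and
    minor are full axis lengths of the ellipse with the same second
    moments, and orientation is the major-axis angle to the image x-axis
    in [0, 180). An isotropic region (circle) reports eccentricity 0 and
    orientation 0 by convention.
    """
    mu = central_moments(poly)
    m00 = mu[0, 0]
    # covariance of the uniform density over the region
    cxx, cyy, cxy = mu[2, 0] / m00, mu[0, 2] / m00, mu[1, 1] / m00
    tr, det = cxx + cyy, cxx * cyy - cxy**2
    disc = max((cxx - cyy) ** 2 + 4 * cxy**2, 0.0)
    lam1 = (tr + np.sqrt(disc)) / 2.0
    lam2 = max((tr - np.sqrt(disc)) / 2.0, 0.0)
    major = 4.0 * np.sqrt(lam1)
    minor = 4.0 * np.sqrt(lam2)
    if lam1 <= 0:
        raise InvalidGeometryError("zero-extent region in ellipse fit")
    ratio2 = lam2 / lam1
    eccentricity = float(np.sqrt(max(1.0 - ratio2, 0.0)))
    # isotropy convention: no meaningful axis direction
    if abs(cxx - cyy) < 1e-9 * tr and abs(cxy) < 1e-9 * tr:
        orientation = 0.0
        eccentricity = 0.0
    else:
        orientation = float(np.degrees(0.5 * np.arctan2(2 * cxy, cxx - cyy)))
        orientation %= 180.0
        if 180.0 - orientation < 1e-9:
            orientation = 0.0
    return eccentricity, orientation, float(major), float(minor)


def shape_ratios(poly: Polygon) -> tuple[float, float, float, float]:
    """Solidity, aspect ratio, fill factor and boundary smoothness.

    solidity = area / convex-hull area; aspect_ratio = major / minor of
    the equivalent ellipse (>= 1); fill_factor = area / axis-aligned
    bounding-box area; boundary_smoothness = convex-hull perimeter /
    polygon perimeter (1 for convex outlines, < 1 for ruffled ones).
    """
    sp = poly.to_shapely()
    hull = sp.convex_hull
    area = poly.area_px2()
    solidity = float(area / hull.area)
    _, _, major, minor = ellipse_fit(poly)
    aspect_ratio = float(major / minor) if minor > 0 else np.inf
    xmin, ymin, xmax, ymax = poly.bounds()
    bbox_area = (xmax - xmin) * (ymax - ymin)
    if bbox_area <= 0:
        raise InvalidGeometryError("degenerate bounding box")
    fill_factor = float(area / bbox_area)
    smoothness = float(hull.length / poly.perimeter_px())
    return solidity, aspect_ratio, fill_factor, smoothness


def static_features(
    poly: Polygon, calib: float = DEFAULT_CALIBRATION_UM_PER_PX
) -> StaticFeatures:
    """Full static descriptor set for one cell outline."""
    area, perim, circ = polygon_metrics(poly, calib)
    ecc, orient, _, _ = ellipse_fit(poly)
    sol, ar, ff, smooth = shape_ratios(poly)
    return StaticFeatures(area, perim, circ, ecc, orient, sol, ar, ff, smooth)


def rasterize(poly: Polygon, shape: Optional[tuple[int, int]] = None) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon.

    ``shape`` is (rows, cols); by default just covers the polygon bounds.
    """
    if shape is None:
        _, _, xmax, ymax = poly.bounds()
        shape = (int(np.ceil(ymax)) + 2, int(np.ceil(xmax)) + 2)
    rr, cc = _raster_polygon(
        poly.vertices[:, 1], poly.vertices[:, 0], shape=shape
    )
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def hu_moments(poly: Polygon) -> np.ndarray:
    """The seven Hu invariant moments of the filled polygon."""
    return np.asarray(_moments_hu(normalized_moments(poly)), dtype=float)


#: order of the normalized central-moment slots in the appearance vector
_NU_ORDER = [(1, 1), (2, 0), (0, 2), (2, 1), (1, 2), (3, 0), (0, 3)]


def appearance_vector(
    poly: Polygon, image: Optional[np.ndarray] = None
) -> np.ndarray:
    """The tracker's 24-dimension appearance descriptor, L2-normalized.

    Composition: 7 intensity statistics over pixels inside the polygon
    (mean, std, min, max, median, skewness, kurtosis — zero without an
    image), 7 Hu moments, 7 normalized central moments (µ11, µ20, µ02,
    µ21, µ12, µ30, µ03), solidity, aspect ratio and fill factor.
    """
    if image is not None:
        img = np.asarray(image, dtype=float)
        if img.ndim != 2:
            raise ValueError("intensity image must be 2-D grayscale")
        mask = rasterize(poly, shape=img.shape)
        vals = img[mask]
        if vals.size == 0:
            raise InvalidGeometryError("polygon rasterizes to zero pixels")
        intensity = np.array(
            [
                vals.mean(),
                vals.std(),
                vals.min(),
                vals.max(),
                np.median(vals),
                _sstats.skew(vals) if vals.std() > 0 else 0.0,
                _sstats.kurtosis(vals) if vals.std() > 0 else 0.0,
            ]
        )
    else:
        intensity = np.zeros(7)

    hu = hu_moments(poly)
    eta = normalized_moments(poly)
    nu = np.array([eta[p, q] for p, q in _NU_ORDER])
    sol, ar, ff, _ = shape_ratios(poly)
    vec = np.concatenate([intensity, hu, nu, [sol, ar, ff]])
    norm = np.linalg.norm(vec)
    if norm == 0.0 or not np.isfinite(norm):
        raise InvalidGeometryError("appearance vector is degenerate (zero norm)")
    return vec / norm
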