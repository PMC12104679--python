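"""Seedling-level morphometrics computed from a binary mask.

Conventions
-----------
Image coordinates are (row, col) with the origin top-left and y increasing
downward; reported coordinates are (x, y) = (col, row).

Two coordinate frames coexist by design:

* **corner lattice** -- each foreground pixel (r, c) is the closed unit square
  with corners (c, r)..(c+1, r+1).  The convex hull, its area, its vertex
  count, and the perimeter (crack boundary) are defined on this lattice, so a
  filled convex digital shape has solidity exactly 1 and area and hull area
  share units.
* **pixel centers** -- the center of mass, ellipse center and longest-path
  endpoints use the integer (col, row) coordinates of the pixels themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure

__all__ = [
    "MorphometricRecord",
    "area",
    "bounding_extents",
    "convex_hull",
    "solidity",
    "perimeter",
    "center_of_mass",
    "longest_path",
    "ellipse_center",
    "extract_all",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "area_px",
    "longest_path_px",
    "width_px",
    "height_px",
    "hull_area_px2",
    "solidity",
    "perimeter_px",
    "com_x",
    "com_y",
    "hull_vertices",
    "ellipse_x",
    "ellipse_y",
]


@dataclass
class MorphometricRecord:
    """One seedling x session row of mask-derived features.

    ``flags`` records which features could not be computed (empty mask,
    degenerate contour, longest-path fallback); undefined features are NaN.
    """

    seedling_id: str = ""
    day: int = -1
    session: str = ""
    area_px: float = np.nan
    longest_path_px: float = np.nan
    width_px: float = np.nan
    height_px: float = np.nan
    hull_area_px2: float = np.nan
    solidity: float = np.nan
    perimeter_px: float = np.nan
    com_x: float = np.nan
    com_y: float = np.nan
    hull_vertices: float = np.nan
    ellipse_x: float = np.nan
    ellipse_y: float = np.nan
    flags: list = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return "empty_mask" not in self.flags


def _as_mask(mask) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError("mask must be a 2-D array")
    return m.astype(bool)


def area(mask) -> int:
    """Foreground pixel count."""
    return int(_as_mask(mask).sum())


def bounding_extents(mask) -> tuple[int, int]:
    """Inclusive (width, height) of the foreground bounding box, in pixels."""
    m = _as_mask(mask)
    rows, cols = np.nonzero(m)
    if rows.size == 0:
        raise ValueError("empty mask has no bounding extents")
    return int(cols.max() - cols.min() + 1), int(rows.max() - rows.min() + 1)


def _corner_points(mask: np.ndarray) -> np.ndarray:
    """Unique (x, y) corners of the unit squares of all foreground pixels."""
    rows, cols = np.nonzero(mask)
    pts = np.concatenate(
        [
            np.stack([cols, rows], axis=1),
            np.stack([cols + 1, rows], axis=1),
            np.stack([cols, rows + 1], axis=1),
            np.stack([cols + 1, rows + 1], axis=1),
        ]
    )
    return np.unique(pts, axis=0).astype(float)


def _strip_collinear(verts: np.ndarray) -> np.ndarray:
    """Drop vertices lying on the segment between their hull neighbours."""
    n = len(verts)
    if n <= 3:
        return verts
    keep = []
    for i in range(n):
        p, q, r = verts[i - 1], verts[i], verts[(i + 1) % n]
        cross = (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
        if abs(cross) > 1e-9:
            keep.append(i)
    return verts[keep]


def convex_hull(mask) -> tuple[np.ndarray, float, int]:
    """Convex hull of the union of unit pixel squares.

    Returns ``(vertices, hull_area, n_vertices)`` where ``vertices`` is the
    counter-clockwise polygon on the pixel-corner lattice (collinear points
    removed), ``hull_area`` its shoelace area and ``n_vertices`` its length.
    """
    m = _as_mask(mask)
    if not m.any():
        raise ValueError("empty mask has no convex hull")
    pts = _corner_points(m)
    hull = ConvexHull(pts)
    verts = _strip_collinear(pts[hull.vertices])
    x, y = verts[:, 0], verts[:, 1]
    hull_area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return verts, float(hull_area), int(len(verts))


def solidity(area_px: float, hull_area_px2: float) -> float:
    """Mask area divided by convex hull area (1 for convex digital shapes)."""
    if hull_area_px2 <= 0:
        raise ValueError("hull area must be positive")
    return float(area_px) / float(hull_area_px2)


def perimeter(mask) -> float:
    """Total crack-boundary length: count of foreground/background pixel edges."""
    m = _as_mask(mask)
    padded = np.pad(m, 1)
    horiz = np.count_nonzero(padded[:, 1:] != padded[:, :-1])
    vert = np.count_nonzero(padded[1:, :] != padded[:-1, :])
    return float(horiz + vert)


def center_of_mass(mask) -> tuple[float, float]:
    """Unweighted mean of foreground pixel (col, row) coordinates."""
    m = _as_mask(mask)
    rows, cols = np.nonzero(m)
    if rows.size == 0:
        raise ValueError("empty mask has no center of mass")
    return float(cols.mean()), float(rows.mean())


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return float(np.hypot(*(p - a)))
    t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
    return float(np.hypot(*(p - (a + t * ab))))


def longest_path(mask, eps: float = 0.75) -> tuple[float, bool]:
    """Longest chord between hull vertices passing within ``eps`` of the centroid.

    Returns ``(length, fallback)``.  When no vertex pair's connecting segment
    passes within ``eps`` of the center of mass, falls back to twice the
    maximum centroid-to-hull-vertex distance and sets ``fallback``.
    """
    verts, _, _ = convex_hull(mask)
    com = np.array(center_of_mass(mask))
    best = -1.0
    n = len(verts)
    for i in range(n):
        for j in range(i + 1, n):
            if _point_segment_distance(com, verts[i], verts[j]) <= eps:
                d = float(np.hypot(*(verts[i] - verts[j])))
                if d > best:
                    best = d
    if best >= 0:
        return best, False
    radial = float(np.max(np.hypot(verts[:, 0] - com[0], verts[:, 1] - com[1])))
    return 2.0 * radial, True


def _outer_contour(mask: np.ndarray) -> np.ndarray:
    """Longest iso-contour of the mask as (x, y) points."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return np.empty((0, 2))
    longest = max(contours, key=len)
    return longest[:, ::-1]  # (row, col) -> (x, y)


def fit_ellipse_center(points: np.ndarray) -> tuple[float, float]:
    """Center of the least-squares algebraic conic fit to (x, y) points.

    Fits a x^2 + b xy + c y^2 + d x + e y + f = 0 by SVD on the scatter of the
    design matrix; the center solves the gradient system.
    """
    pts = np.asarray(points, dtype=float)
    pts = np.unique(pts, axis=0)
    if len(pts) < 6:
        raise ValueError("ellipse fit requires at least 6 distinct contour points")
    mu = pts.mean(axis=0)
    x, y = (pts - mu).T  # center the data for conditioning
    D = np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])
    _, s, vt = np.linalg.svd(D, full_matrices=False)
    if s[-2] < 1e-12 * s[0]:
        raise ValueError("degenerate (collinear) contour: ellipse fit undefined")
    a, b, c, d, e, _ = vt[-1]
    M = np.array([[2 * a, b], [b, 2 * c]])
    if abs(np.linalg.det(M)) < 1e-12:
        raise ValueError("degenerate conic: center undefined")
    cx, cy = np.linalg.solve(M, [-d, -e]) + mu
    return float(cx), float(cy)


def ellipse_center(mask) -> tuple[float, float]:
    """Center of the ellipse fitted to the mask's outer contour."""
    m = _as_mask(mask)
    if not m.any():
        raise ValueError("empty mask has no contour")
    contour = _outer_contour(m)
    return fit_ellipse_center(contour)


def extract_all(
    mask,
    seedling_id: str = "",
    day: int = -1,
    session: str = "",
    eps: float = 0.75,
) -> MorphometricRecord:
    """Populate the full feature record; degenerate inputs are flagged, not fatal."""
    rec = MorphometricRecord(seedling_id=seedling_id, day=day, session=session)
    m = _as_mask(mask)
    if not m.any():
        rec.flags.append("empty_mask")
        return rec
    rec.area_px = float(area(m))
    rec.width_px, rec.height_px = (float(v) for v in bounding_extents(m))
    _, hull_area, n_verts = convex_hull(m)
    rec.hull_area_px2 = hull_area
    rec.hull_vertices = float(n_verts)
    rec.solidity = solidity(rec.area_px, hull_area)
    rec.perimeter_px = perimeter(m)
    rec.com_x, rec.com_y = center_of_mass(m)
    lp, fallback = longest_path(m, eps=eps)
    rec.longest_path_px = lp
    if fallback:
        rec.flags.append("longest_path_fallback")
    try:
        rec.ellipse_x, rec.ellipse_y = ellipse_center(m)
    except ValueError as exc:
        rec.flags.append("ellipse_undefined")
        warnings.warn(f"ellipse center undefined for {seedling_id}/{session}: {exc}")
    return rec
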