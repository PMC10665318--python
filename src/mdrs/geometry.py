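"""Planar polygon primitives shared by ground-truth and measured shapes.

All functions take an ``(N, 2)`` float array of vertices in consistent
units (pixels or micrometres).  Polygons are implicitly closed (the last
vertex connects back to the first) and need not be convex.  These
primitives back both the continuous ground-truth descriptors of the
phantom generator and the measured descriptors of segmented particles,
so the same definitions apply on both sides of a recovery comparison.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon as _ShapelyPolygon


def as_polygon(vertices) -> np.ndarray:
    """Validate and return vertices as a float ``(N, 2)`` array, N >= 3."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError(f"polygon must be (N, 2), got shape {v.shape}")
    # drop an explicit closing vertex
    if len(v) > 1 and np.allclose(v[0], v[-1]):
        v = v[:-1]
    if len(v) < 3:
        raise ValueError("polygon needs at least 3 distinct vertices")
    if not np.all(np.isfinite(v)):
        raise ValueError("polygon vertices must be finite")
    return v


def polygon_area(vertices) -> float:
    """Unsigned area by the shoelace formula."""
    v = as_polygon(vertices)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_perimeter(vertices) -> float:
    """Arc length of the closed boundary."""
    v = as_polygon(vertices)
    d = np.diff(np.vstack([v, v[:1]]), axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def is_simple_polygon(vertices) -> bool:
    """True when the boundary does not self-intersect and encloses area."""
    try:
        v = as_polygon(vertices)
    except ValueError:
        return False
    p = _ShapelyPolygon(v)
    return p.is_valid and p.area > 0


def convex_hull_vertices(vertices) -> np.ndarray:
    """Hull vertices in counter-clockwise order.

    Raises ``ValueError`` for degenerate (collinear) input.
    """
    v = as_polygon(vertices)
    try:
        hull = ConvexHull(v)
    except QhullError as exc:
        raise ValueError("degenerate polygon: convex hull undefined") from exc
    return v[hull.vertices]


def hull_perimeter(vertices) -> float:
    return polygon_perimeter(convex_hull_vertices(vertices))


def feret_diameters(vertices) -> tuple[float, float]:
    """(min, max) Feret diameter: extreme distances between parallel tangents.

    Both are computed on the convex hull, whose Feret diameters equal those
    of the original set.  The maximum is the hull diameter (largest
    inter-vertex distance); the minimum width of a convex polygon is
    attained perpendicular to one of its edges, so it is minimised over
    hull-edge normal directions.  Exact for polygons.
    """
    h = convex_hull_vertices(vertices)
    # max Feret: diameter of the hull vertex set
    diff = h[:, None, :] - h[None, :, :]
    feret_max = float(np.sqrt((diff ** 2).sum(-1)).max())

    edges = np.roll(h, -1, axis=0) - h
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    keep = lengths > 0
    if not np.any(keep):
        raise ValueError("degenerate polygon: zero-length hull edges")
    normals = np.stack([-edges[keep, 1], edges[keep, 0]], axis=1) / lengths[keep, None]
    proj = h @ normals.T  # (n_vertices, n_edges)
    widths = proj.max(axis=0) - proj.min(axis=0)
    feret_min = float(widths.min())
    if feret_min <= 0:
        raise ValueError("degenerate polygon: zero minimum width")
    return feret_min, feret_max


def ecd_from_area(area: float) -> float:
    """Equivalent circular diameter, 2*sqrt(A/pi)."""
    if area < 0:
        raise ValueError("area must be non-negative")
    return 2.0 * np.sqrt(area / np.pi)


def regular_polygon(radius: float, n: int = 256, center=(0.0, 0.0)) -> np.ndarray:
    """n-gon approximation of a circle, used as the continuous disk model."""
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )
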