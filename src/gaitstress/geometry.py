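"""Planar polygon geometry: areas, centroids, second moments, simple predicates.

All polygon routines use exact Green's-theorem (shoelace-type) formulas, so
results are exact for polygonal boundaries up to floating point.  Vertex lists
are (n, 2) arrays; the closing edge from the last vertex back to the first is
implicit.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon


def as_vertices(poly) -> np.ndarray:
    """Coerce to an (n, 2) float array of polygon vertices (open ring)."""
    v = np.asarray(poly, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValueError("polygon must be an (n >= 3, 2) vertex array")
    if np.allclose(v[0], v[-1]):
        v = v[:-1]
        if v.shape[0] < 3:
            raise ValueError("degenerate polygon")
    return v


def is_simple(poly) -> bool:
    """True if the polygon boundary does not self-intersect."""
    v = as_vertices(poly)
    return _ShapelyPolygon(v).is_valid


def signed_area(poly) -> float:
    v = as_vertices(poly)
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * y1 - x1 * y))


def ensure_ccw(poly) -> np.ndarray:
    """Return vertices ordered counterclockwise (positive signed area)."""
    v = as_vertices(poly)
    if signed_area(v) < 0:
        v = v[::-1].copy()
    return v


def polygon_area_centroid(poly) -> tuple[float, np.ndarray]:
    """Area and centroid of a simple polygon (area always positive)."""
    v = ensure_ccw(poly)
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * np.sum(cross)
    if a <= 0:
        raise ValueError("polygon has non-positive area")
    cx = np.sum((x + x1) * cross) / (6.0 * a)
    cy = np.sum((y + y1) * cross) / (6.0 * a)
    return float(a), np.array([cx, cy])


def polygon_moments(poly) -> tuple[float, np.ndarray, float, float, float]:
    """Area, centroid and centroidal second moments of a simple polygon.

    Returns ``(A, centroid, Ix, Iy, Ixy)`` where Ix = ∫y² dA, Iy = ∫x² dA and
    Ixy = ∫xy dA are taken about axes through the centroid.  Results are
    independent of vertex orientation.
    """
    v = ensure_ccw(poly)
    if not is_simple(v):
        raise ValueError("polygon is self-intersecting")
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * np.sum(cross)
    cx = np.sum((x + x1) * cross) / (6.0 * a)
    cy = np.sum((y + y1) * cross) / (6.0 * a)
    ix = np.sum((y * y + y * y1 + y1 * y1) * cross) / 12.0
    iy = np.sum((x * x + x * x1 + x1 * x1) * cross) / 12.0
    ixy = np.sum((x * y1 + 2.0 * x * y + 2.0 * x1 * y1 + x1 * y) * cross) / 24.0
    # shift to centroid (parallel-axis theorem)
    ix -= a * cy * cy
    iy -= a * cx * cx
    ixy -= a * cx * cy
    return float(a), np.array([cx, cy]), float(ix), float(iy), float(ixy)


def polygon_planar_inertia(poly, mass: float) -> tuple[float, np.ndarray]:
    """Out-of-plane inertia (about the centroid) of a uniform lamina of given mass.

    The polar second moment of area Ix + Iy is scaled by mass / area, which is
    the planar rigid-body inertia of a uniform-density plate.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    a, c, ix, iy, _ = polygon_moments(poly)
    return mass * (ix + iy) / a, c


def regular_polygon(n: int, radius: float, center=(0.0, 0.0)) -> np.ndarray:
    """Vertices of a regular n-gon inscribed in a circle of given radius."""
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )


def perp(v: np.ndarray) -> np.ndarray:
    """90° counterclockwise rotation: (x, y) -> (-y, x)."""
    v = np.asarray(v, dtype=float)
    out = np.empty_like(v)
    out[..., 0] = -v[..., 1]
    out[..., 1] = v[..., 0]
    return out


def cross2(a, b) -> float | np.ndarray:
    """z-component of the cross product of planar vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])
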