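"""Planar geometry primitives shared by the home-range and niche modules.

All routines operate on ``(n, 2)`` float arrays.  The convex hull uses
Andrew's monotone chain and areas use the shoelace formula; both are
unit-free (square meters in, square meters out; per-mil² in, per-mil² out).
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import LineString, Point

__all__ = [
    "convex_hull",
    "polygon_area",
    "project_along_polyline",
    "polyline_length",
]


def _cross(o: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull of a point set via Andrew's monotone chain.

    Returns hull vertices in counterclockwise order without repeating the
    first vertex.  Degenerate inputs (fewer than 3 distinct points, or all
    collinear) return the distinct extreme points (< 3 vertices); callers
    treat such hulls as zero-area.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    uniq = np.unique(pts, axis=0)
    # lexicographic sort by (x, y)
    order = np.lexsort((uniq[:, 1], uniq[:, 0]))
    uniq = uniq[order]
    n = len(uniq)
    if n <= 2:
        return uniq

    lower: list[np.ndarray] = []
    for p in uniq:
        while len(lower) >= 2 and _cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[np.ndarray] = []
    for p in uniq[::-1]:
        while len(upper) >= 2 and _cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) < 3:  # all points collinear
        return np.array([uniq[0], uniq[-1]])
    return hull


def polygon_area(vertices: np.ndarray) -> float:
    """Area of a simple polygon by the shoelace formula (vertices ordered)."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polyline_length(axis: np.ndarray) -> float:
    """Total arclength of an ordered polyline, in the axis units."""
    a = np.asarray(axis, dtype=float)
    return float(np.sum(np.hypot(np.diff(a[:, 0]), np.diff(a[:, 1]))))


def project_along_polyline(points: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Arclength (from the polyline start) of each point's orthogonal projection.

    The nearest point on the polyline is found segment-wise; the return value
    is the along-axis distance from ``axis[0]`` to that projection, in the
    same units as the coordinates.
    """
    line = LineString(np.asarray(axis, dtype=float))
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return np.array([line.project(Point(p)) for p in pts])
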