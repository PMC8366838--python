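"""95% minimum convex polygon home ranges from position averages.

The percent MCP peels points by distance from the arithmetic centroid (the
adehabitat convention): the floor(f·n) points nearest the centroid are
kept, the hull of the kept points is taken, and its shoelace area is
reported in hectares.  Sedentary fish pinned to a single receiver yield
degenerate (zero-area) hulls rather than errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geometry import convex_hull, polygon_area

__all__ = ["HomeRange", "mcp95", "home_ranges"]


@dataclass(frozen=True)
class HomeRange:
    tag_id: str
    area_ha: float
    n_points_used: int
    hull_vertices: np.ndarray  # (k, 2), counterclockwise
    degenerate: bool = False


def mcp95(
    points: np.ndarray,
    keep_fraction: float = 0.95,
    tag_id: str = "",
    min_points: int = 5,
) -> HomeRange:
    """Percent minimum convex polygon of a point set (m² → hectares).

    Keeps the floor(keep_fraction·n) points nearest the centroid (ties
    broken by input order), hulls them with the monotone chain, and
    measures the shoelace area.  Collinear or single-receiver point sets
    return area 0 with ``degenerate=True``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    if len(pts) < min_points:
        raise ValueError(f"need at least {min_points} positions, got {len(pts)}")

    centroid = pts.mean(axis=0)
    dist = np.hypot(*(pts - centroid).T)
    n_keep = int(np.floor(keep_fraction * len(pts)))
    n_keep = max(n_keep, 1)
    keep = np.argsort(dist, kind="stable")[:n_keep]
    kept = pts[np.sort(keep)]  # stable: preserve input order among kept

    hull = convex_hull(kept)
    if len(hull) < 3:
        return HomeRange(tag_id, 0.0, n_keep, hull, degenerate=True)
    area_m2 = polygon_area(hull)
    return HomeRange(tag_id, area_m2 / 10_000.0, n_keep, hull, degenerate=False)


def home_ranges(
    position_avgs: pd.DataFrame,
    keep_fraction: float = 0.95,
    min_points: int = 5,
) -> pd.DataFrame:
    """Per-tag MCP areas from a position-average table.

    Tags with fewer than ``min_points`` positions are skipped (the study's
    inclusion rule for the home-range analysis).
    """
    rows = []
    for tag, grp in position_avgs.groupby("tag_id", observed=True, sort=True):
        pts = grp[["easting", "northing"]].to_numpy()
        if len(pts) < min_points:
            continue
        hr = mcp95(pts, keep_fraction=keep_fraction, tag_id=str(tag),
                   min_points=min_points)
        rows.append(
            {
                "tag_id": hr.tag_id,
                "area_ha": hr.area_ha,
                "n_points_used": hr.n_points_used,
                "degenerate": hr.degenerate,
            }
        )
    return pd.DataFrame(rows, columns=["tag_id", "area_ha", "n_points_used", "degenerate"])
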