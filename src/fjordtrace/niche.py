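"""Bivariate isotopic niche metrics on distance-adjusted values.

Because the δ15N baseline varies along the fjord, raw isotope values are
first residualized against each fish's mean residence distance to the
outlet (one pooled OLS per element); niche metrics are then computed on the
(δ13C, δ15N) residual cloud per ecotype and pooled:

* SEA — the standard ellipse area π√det(S) of the sample covariance S;
* SEAc — its small-sample correction SEA·(n−1)/(n−2);
* TA — the convex hull ("total area") of the cloud;
* pairwise overlap of the SEAc-scaled standard ellipses.

Areas are in ‰².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from shapely.geometry import Polygon

from ._geometry import convex_hull, polygon_area

__all__ = [
    "StandardEllipse",
    "NicheSummary",
    "residualize",
    "standard_ellipse",
    "hull_area",
    "ellipse_overlap",
    "ta_ratio",
    "niche_table",
    "plot_niche_biplot",
]


@dataclass(frozen=True)
class StandardEllipse:
    """1-SD Mahalanobis contour of a bivariate point cloud."""

    center: np.ndarray
    covariance: np.ndarray
    n: int
    degenerate: bool = False

    @property
    def sea(self) -> float:
        det = float(np.linalg.det(self.covariance))
        return 0.0 if det <= 0 else float(np.pi * np.sqrt(det))

    @property
    def seac(self) -> float:
        if self.n <= 2:
            return self.sea
        return self.sea * (self.n - 1) / (self.n - 2)

    def boundary(self, n_vertices: int = 1024, seac_scaled: bool = False) -> np.ndarray:
        """Polygonal discretization of the ellipse boundary (CCW)."""
        if self.degenerate:
            raise ValueError("degenerate ellipse has no boundary")
        theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        radius = 1.0
        if seac_scaled and self.n > 2:
            radius = np.sqrt((self.n - 1) / (self.n - 2))
        L = np.linalg.cholesky(self.covariance)
        return self.center + radius * circle @ L.T


@dataclass(frozen=True)
class NicheSummary:
    group: str
    n: int
    sea: float
    seac: float
    hull_area: float
    ellipse: StandardEllipse


def residualize(
    isotopes: pd.DataFrame,
    distances_km: pd.DataFrame,
    per_group: bool = False,
) -> pd.DataFrame:
    """Residuals of each isotope value against mean residence distance.

    ``isotopes`` needs columns sample_id, d15N, d13C (corrected, duplicate
    means); ``distances_km`` maps sample_id → distance_km (and optionally
    carries ecotype / length_cm columns, passed through).  One pooled OLS
    per element by default; ``per_group=True`` fits within ecotype instead.
    Residual columns are ``r_nitrogen`` and ``r_carbon``.
    """
    df = isotopes.merge(distances_km, on="sample_id", how="inner")
    if len(df) < 3:
        raise ValueError("need at least 3 fish to residualize")
    if df["distance_km"].isna().any():
        raise ValueError("every sample needs a mean residence distance")

    def fit_resid(sub: pd.DataFrame) -> pd.DataFrame:
        X = sm.add_constant(sub["distance_km"].to_numpy())
        out = sub.copy()
        for col, name in (("d15N", "r_nitrogen"), ("d13C", "r_carbon")):
            res = sm.OLS(sub[col].to_numpy(), X).fit()
            out[name] = res.resid
        return out

    if per_group:
        parts = [
            fit_resid(sub) for _, sub in df.groupby("ecotype", observed=True)
        ]
        return pd.concat(parts, ignore_index=True)
    return fit_resid(df)


def standard_ellipse(points: np.ndarray) -> StandardEllipse:
    """Standard ellipse of a bivariate sample (n ≥ 3).

    The covariance uses the n−1 denominator; SEA = π√det(S).  Collinear
    clouds yield a degenerate (zero-area) ellipse.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points for a standard ellipse")
    center = pts.mean(axis=0)
    cov = np.cov(pts.T, ddof=1)
    degenerate = float(np.linalg.det(cov)) <= 1e-300
    return StandardEllipse(center=center, covariance=cov, n=n, degenerate=degenerate)


def hull_area(points: np.ndarray) -> float:
    """Convex hull area of a point cloud (0 for collinear input)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points for a hull area")
    return polygon_area(convex_hull(pts))


def ellipse_overlap(
    e1: StandardEllipse,
    e2: StandardEllipse,
    n_vertices: int = 1024,
    seac_scaled: bool = True,
) -> float:
    """Area of intersection of two (SEAc-scaled) standard ellipses.

    Each boundary is discretized with ``n_vertices`` points and the two
    convex polygons are clipped against each other; disjoint or degenerate
    ellipses give 0.
    """
    if n_vertices < 8:
        raise ValueError("n_vertices must be at least 8")
    if e1.degenerate or e2.degenerate:
        return 0.0
    p1 = Polygon(e1.boundary(n_vertices, seac_scaled=seac_scaled))
    p2 = Polygon(e2.boundary(n_vertices, seac_scaled=seac_scaled))
    return float(p1.intersection(p2).area)


def ta_ratio(pooled_ta: float, group_ta: float) -> float:
    """Pooled-to-group convex hull area ratio, reported to 2 decimals."""
    if group_ta <= 0:
        raise ValueError("group hull area must be positive")
    return round(pooled_ta / group_ta, 2)


def niche_table(
    residuals: pd.DataFrame,
    group_col: str = "ecotype",
    n_vertices: int = 1024,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SEA/SEAc/TA per group and pooled, plus pairwise SEAc overlaps.

    Returns ``(summary, overlaps)``; the summary carries a
    ``pooled_ta_ratio`` column (pooled hull area over the group's own,
    rounded to 2 decimals), the pooled row's ratio is 1.
    """
    pts_of = {
        str(g): sub[["r_carbon", "r_nitrogen"]].to_numpy()
        for g, sub in residuals.groupby(group_col, observed=True, sort=True)
    }
    for g, pts in pts_of.items():
        if len(pts) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 fish")
    pooled = residuals[["r_carbon", "r_nitrogen"]].to_numpy()

    summaries: list[NicheSummary] = []
    for g, pts in list(pts_of.items()) + [("pooled", pooled)]:
        ell = standard_ellipse(pts)
        summaries.append(
            NicheSummary(
                group=g,
                n=len(pts),
                sea=ell.sea,
                seac=ell.seac,
                hull_area=hull_area(pts),
                ellipse=ell,
            )
        )
    pooled_ta = summaries[-1].hull_area
    summary = pd.DataFrame(
        {
            "group": [s.group for s in summaries],
            "n": [s.n for s in summaries],
            "sea": [s.sea for s in summaries],
            "seac": [s.seac for s in summaries],
            "hull_area": [s.hull_area for s in summaries],
            "pooled_ta_ratio": [
                ta_ratio(pooled_ta, s.hull_area) if s.hull_area > 0 else np.nan
                for s in summaries
            ],
        }
    )
    groups = list(pts_of)
    rows = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            ov = ellipse_overlap(
                standard_ellipse(pts_of[g1]),
                standard_ellipse(pts_of[g2]),
                n_vertices=n_vertices,
            )
            rows.append({"group_1": g1, "group_2": g2, "seac_overlap": ov})
    overlaps = pd.DataFrame(rows, columns=["group_1", "group_2", "seac_overlap"])
    return summary, overlaps


def plot_niche_biplot(
    residuals: pd.DataFrame,
    path=None,
    group_col: str = "ecotype",
    size_col: str | None = "length_cm",
):
    """Residual δ13C vs δ15N biplot with hulls and standard ellipses.

    Symbol size scales with fish length when available.  Returns the
    matplotlib figure (saved to ``path`` if given).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    colors = {"FJ": "tab:orange", "NS": "tab:blue"}
    for g, sub in residuals.groupby(group_col, observed=True, sort=True):
        pts = sub[["r_carbon", "r_nitrogen"]].to_numpy()
        color = colors.get(str(g), None)
        sizes = 30.0
        if size_col and size_col in sub.columns:
            sizes = 10.0 + 2.0 * (sub[size_col] - 30.0).clip(lower=0.0)
        ax.scatter(pts[:, 0], pts[:, 1], s=sizes, alpha=0.7, label=str(g), c=color)
        if len(pts) >= 3:
            hull = convex_hull(pts)
            if len(hull) >= 3:
                closed = np.vstack([hull, hull[:1]])
                ax.plot(closed[:, 0], closed[:, 1], "--", lw=1, c=color)
            ell = standard_ellipse(pts)
            if not ell.degenerate:
                b = ell.boundary(256)
                ax.plot(b[:, 0], b[:, 1], lw=1.5, c=color)
            ax.plot(*pts.mean(axis=0), marker="*", ms=12, c=color)
    ax.set_xlabel("residual δ13C (‰)")
    ax.set_ylabel("residual δ15N (‰)")
    ax.legend(title="ecotype")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
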