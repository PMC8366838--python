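"""From raw detections to positions, distances, fates, and cohorts.

The position estimator is the detection-count-weighted mean of receiver
coordinates within each 30-min period (a short-term center of activity);
distances are measured along the fjord axis to the outlet.  Fate
classification follows the gate rule: a fish has left the system when its
last detection sits on the outer receiver transect and nothing follows; a
re-detection within two days marks a short excursion, later re-detections a
prolonged (returned) departure.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fjord import FjordGeometry

__all__ = [
    "FateRecord",
    "position_average",
    "position_averages",
    "daily_positions",
    "distance_to_outlet",
    "classify_fate",
    "classify_all_fates",
    "fates_frame",
    "gate_consistency",
    "select_array_cohort",
]

#: absence shorter than this is a short excursion, not a departure
EXCURSION_MAX = dt.timedelta(hours=48)
#: minimum absence after an outer-transect detection to call it an exit
MIN_ABSENCE = dt.timedelta(hours=6)
#: a fish silent for longer than this before study end is "lost"
RESIDENT_GAP_MAX = dt.timedelta(days=7)


@dataclass(frozen=True)
class FateRecord:
    tag_id: str
    status: str  # resident | short_excursion | departed_returned | departed_permanent | lost
    departure_time: pd.Timestamp | None = None
    return_time: pd.Timestamp | None = None
    n_excursions: int = 0
    excursions: tuple[tuple[pd.Timestamp, pd.Timestamp], ...] = field(
        default_factory=tuple
    )

    @property
    def departed(self) -> bool:
        return self.status in ("departed_permanent", "departed_returned")


def _utc(ts) -> pd.Timestamp:
    t = pd.Timestamp(ts)
    return t.tz_localize("UTC") if t.tzinfo is None else t.tz_convert("UTC")


# -- positions --------------------------------------------------------------


def position_average(
    detections: pd.DataFrame, deployments: pd.DataFrame
) -> dict | None:
    """Count-weighted position for one tag in one 30-min period.

    ``detections`` must all share a tag and a half-hour period; the result's
    coordinates are sum(count_r x coords_r) / sum(count_r) over receivers r.
    An empty input yields no record (None), not a zero position.
    """
    if len(detections) == 0:
        return None
    tags = detections["tag_id"].unique()
    periods = pd.to_datetime(detections["timestamp"]).dt.floor("30min").unique()
    if len(tags) != 1 or len(periods) != 1:
        raise ValueError("detections must share one tag and one 30-min period")
    coords = deployments.set_index("receiver_id")[["easting", "northing"]]
    missing = set(detections["receiver_id"]) - set(coords.index)
    if missing:
        raise KeyError(f"unknown receiver(s): {sorted(missing)}")
    counts = detections["receiver_id"].value_counts()
    xy = coords.loc[counts.index].to_numpy()
    w = counts.to_numpy(dtype=float)
    e, n = (w @ xy) / w.sum()
    return {
        "tag_id": tags[0],
        "period_start": pd.Timestamp(periods[0]),
        "easting": float(e),
        "northing": float(n),
        "n_detections": int(w.sum()),
    }


def position_averages(
    detections: pd.DataFrame,
    deployments: pd.DataFrame,
    geometry: FjordGeometry | None = None,
) -> pd.DataFrame:
    """All 30-min position averages (one row per tag per period).

    Periods are aligned to the UTC clock half-hours.  If ``geometry`` is
    given, a ``distance_km`` column (along-axis distance to the outlet) is
    added.
    """
    df = detections.copy()
    df["period_start"] = pd.to_datetime(df["timestamp"]).dt.floor("30min")
    counts = (
        df.groupby(["tag_id", "period_start", "receiver_id"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    coords = deployments.set_index("receiver_id")[["easting", "northing"]]
    missing = set(counts["receiver_id"]) - set(coords.index)
    if missing:
        raise KeyError(f"unknown receiver(s): {sorted(missing)}")
    counts = counts.join(coords, on="receiver_id")
    counts["we"] = counts["n"] * counts["easting"]
    counts["wn"] = counts["n"] * counts["northing"]
    agg = counts.groupby(["tag_id", "period_start"], observed=True).agg(
        we=("we", "sum"), wn=("wn", "sum"), n_detections=("n", "sum")
    )
    out = pd.DataFrame(
        {
            "easting": agg["we"] / agg["n_detections"],
            "northing": agg["wn"] / agg["n_detections"],
            "n_detections": agg["n_detections"],
        }
    ).reset_index()
    if geometry is not None:
        out["distance_km"] = geometry.distance_to_outlet_km(
            out[["easting", "northing"]].to_numpy()
        )
    return out


def daily_positions(position_avgs: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-tag daily means of the 30-min position averages."""
    df = position_avgs.copy()
    df["date"] = pd.to_datetime(df["period_start"]).dt.floor("D")
    cols = ["easting", "northing"]
    if "distance_km" in df.columns:
        cols.append("distance_km")
    return (
        df.groupby(["tag_id", "date"], observed=True)[cols].mean().reset_index()
    )


def distance_to_outlet(point: np.ndarray, geometry: FjordGeometry) -> float:
    """Along-axis km from a point's orthogonal projection to the outlet."""
    return float(geometry.distance_to_outlet_km(np.atleast_2d(point))[0])


# -- fates ------------------------------------------------------------------


def classify_fate(
    detections: pd.DataFrame,
    deployments: pd.DataFrame,
    study_end,
    excursion_max: dt.timedelta = EXCURSION_MAX,
    min_absence: dt.timedelta = MIN_ABSENCE,
    resident_gap_max: dt.timedelta = RESIDENT_GAP_MAX,
) -> FateRecord:
    """Classify one tag's detection history.

    Scans outer-transect detections followed by an absence of *all*
    detections of at least ``min_absence``: no re-detection before
    ``study_end`` means a permanent departure (departure time = that outer
    detection); re-detection within ``excursion_max`` a short excursion;
    later re-detection a prolonged departure with return (return time = the
    first outer-transect detection back, falling back to the first
    re-detection).  A fish whose record simply dries up away from the outer
    transect is "lost".
    """
    if len(detections) == 0:
        raise ValueError("cannot classify a tag with no detections")
    tags = detections["tag_id"].unique()
    if len(tags) != 1:
        raise ValueError("classify_fate expects a single tag")
    end = _utc(study_end)
    df = detections.sort_values("timestamp", kind="stable")
    ts = pd.to_datetime(df["timestamp"])
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize("UTC")
    roles = df["receiver_id"].map(
        deployments.set_index("receiver_id")["role"]
    )
    if roles.isna().any():
        bad = sorted(df.loc[roles.isna(), "receiver_id"].unique())
        raise KeyError(f"unknown receiver(s): {bad}")
    times = ts.to_numpy()
    outer = (roles == "outer_transect").to_numpy()

    gap_after = np.append(np.diff(times), np.timedelta64(0, "s"))
    last_idx = len(times) - 1
    excursions: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    departure: pd.Timestamp | None = None
    return_time: pd.Timestamp | None = None
    status: str | None = None

    for i in np.nonzero(outer)[0]:
        t_i = pd.Timestamp(times[i])
        if i == last_idx:
            if end - t_i >= min_absence:
                status, departure = "departed_permanent", t_i
            break
        if gap_after[i] < np.timedelta64(min_absence):
            continue
        # exit event: find the re-detection and when (if ever) it is outer
        t_next = pd.Timestamp(times[i + 1])
        if t_next - t_i < excursion_max:
            excursions.append((t_i, t_next))
            continue
        later_outer = np.nonzero(outer[i + 1 :])[0]
        back = (
            pd.Timestamp(times[i + 1 + later_outer[0]])
            if len(later_outer)
            else t_next
        )
        status, departure, return_time = "departed_returned", t_i, back

    if status is None:
        t_last = pd.Timestamp(times[last_idx])
        if end - t_last > resident_gap_max:
            status = "lost"
        else:
            status = "short_excursion" if excursions else "resident"
    elif status == "departed_returned" and excursions:
        pass  # departures dominate the status; excursions stay counted

    return FateRecord(
        tag_id=str(tags[0]),
        status=status,
        departure_time=departure,
        return_time=return_time,
        n_excursions=len(excursions),
        excursions=tuple(excursions),
    )


def classify_all_fates(
    detections: pd.DataFrame,
    deployments: pd.DataFrame,
    study_end,
    all_tags: list[str] | None = None,
    **kwargs,
) -> list[FateRecord]:
    """Per-tag fate records; tags in ``all_tags`` with no detections → lost."""
    records = [
        classify_fate(group, deployments, study_end, **kwargs)
        for _, group in detections.groupby("tag_id", observed=True, sort=True)
    ]
    if all_tags is not None:
        seen = {r.tag_id for r in records}
        for tag in all_tags:
            if tag not in seen:
                records.append(FateRecord(tag_id=tag, status="lost"))
        records.sort(key=lambda r: r.tag_id)
    return records


def fates_frame(records: list[FateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tag_id": [r.tag_id for r in records],
            "status": [r.status for r in records],
            "departure_time": [r.departure_time for r in records],
            "return_time": [r.return_time for r in records],
            "n_excursions": [r.n_excursions for r in records],
        }
    )


# -- gate QC ----------------------------------------------------------------


def gate_consistency(
    detections: pd.DataFrame, deployments: pd.DataFrame
) -> pd.DataFrame:
    """Check that gate passages hit the two transects in the right order.

    Outward: no outer-transect detection may occur before the tag has ever
    been seen on the secondary transect.  Inward: after an absence of at
    least the exit threshold, the secondary transect must not be hit before
    the outer one.  Returns a frame of violations (possibly empty) with
    columns tag_id, timestamp, kind.
    """
    roles = deployments.set_index("receiver_id")["role"]
    need = {"outer_transect", "secondary_transect"}
    if not need <= set(roles.unique()):
        raise ValueError("deployments must include outer and secondary transects")
    rows = []
    for tag, grp in detections.groupby("tag_id", observed=True, sort=True):
        g = grp.sort_values("timestamp", kind="stable")
        r = g["receiver_id"].map(roles).to_numpy()
        ts = pd.to_datetime(g["timestamp"]).to_numpy()
        seen_secondary = False
        prev_t = None
        last_since_gap: str | None = None
        for i in range(len(g)):
            if prev_t is not None and ts[i] - prev_t >= np.timedelta64(MIN_ABSENCE):
                last_since_gap = None  # re-entry begins
            if r[i] == "secondary_transect":
                # first detection after an absence should be outer, not
                # secondary (re-entries come through the outer gate)
                if last_since_gap is None and prev_t is not None and seen_secondary:
                    rows.append(
                        {
                            "tag_id": tag,
                            "timestamp": pd.Timestamp(ts[i]),
                            "kind": "secondary_before_outer_on_return",
                        }
                    )
                seen_secondary = True
                last_since_gap = "secondary"
            elif r[i] == "outer_transect":
                if not seen_secondary:
                    rows.append(
                        {
                            "tag_id": tag,
                            "timestamp": pd.Timestamp(ts[i]),
                            "kind": "outer_without_prior_secondary",
                        }
                    )
                    seen_secondary = True  # report once per tag
                last_since_gap = "outer"
            prev_t = ts[i]
    return pd.DataFrame(rows, columns=["tag_id", "timestamp", "kind"])


# -- cohorts ----------------------------------------------------------------


def select_array_cohort(
    fates: list[FateRecord],
    position_avgs: pd.DataFrame,
    window: tuple = ("2017-05-01", "2017-11-30"),
) -> set[str]:
    """Tags present during the array window.

    Included: at least one position average inside the window, and not
    permanently departed before the window opened.
    """
    start, end = _utc(window[0]), _utc(window[1])
    pa = position_avgs.copy()
    per = pd.to_datetime(pa["period_start"])
    if per.dt.tz is None:
        per = per.dt.tz_localize("UTC")
    inside = pa.loc[(per >= start) & (per <= end), "tag_id"].unique()
    departed_before = {
        r.tag_id
        for r in fates
        if r.status == "departed_permanent"
        and r.departure_time is not None
        and _utc(r.departure_time) < start
    }
    return set(inside) - departed_before
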