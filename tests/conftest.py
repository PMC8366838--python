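import datetime as dt

import numpy as np
import pandas as pd
import pytest

from fjordtrace.config import SimulationConfig
from fjordtrace.fjord import build_default_geometry

UTC = dt.timezone.utc


def brute_force_hull(points: np.ndarray) -> np.ndarray:
    """All-triples hull oracle: a point is interior iff it lies strictly
    inside some triangle of three other points; everything else is on the
    hull.  O(n^4); for small n only."""
    pts = np.unique(np.asarray(points, float), axis=0)
    n = len(pts)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        p = pts[i]
        for a in range(n):
            if not keep[i]:
                break
            for b in range(a + 1, n):
                if not keep[i]:
                    break
                for c in range(b + 1, n):
                    if i in (a, b, c):
                        continue
                    if _strictly_inside(p, pts[a], pts[b], pts[c]):
                        keep[i] = False
                        break
    return pts[keep]


def _strictly_inside(p, a, b, c) -> bool:
    def cross(o, u, v):
        return (u[0] - o[0]) * (v[1] - o[1]) - (u[1] - o[1]) * (v[0] - o[0])

    d1, d2, d3 = cross(a, b, p), cross(b, c, p), cross(c, a, p)
    return (d1 > 0 and d2 > 0 and d3 > 0) or (d1 < 0 and d2 < 0 and d3 < 0)


@pytest.fixture(scope="session")
def geometry():
    return build_default_geometry(0)


@pytest.fixture(scope="session")
def short_config():
    """One simulated month with the array active throughout."""
    start = dt.datetime(2017, 6, 1, tzinfo=UTC)
    return SimulationConfig(
        n_fish=20,
        seed=7,
        study_start=start,
        study_end=start + dt.timedelta(days=30),
        array_start=start,
        array_end=start + dt.timedelta(days=30),
    )


@pytest.fixture()
def toy_receivers():
    t0 = pd.Timestamp("2016-11-01")
    t1 = pd.Timestamp("2018-06-01")
    return pd.DataFrame(
        {
            "receiver_id": ["OT1", "ST1", "IT1", "AR1"],
            "easting": [478200.0, 478700.0, 482500.0, 484000.0],
            "northing": [6490000.0] * 4,
            "role": ["outer_transect", "secondary_transect", "internal_transect", "array"],
            "active_from": [t0] * 4,
            "active_to": [t1] * 4,
        }
    )


def make_detections(rows):
    """rows: list of (timestamp str, receiver_id, tag_id)."""
    return pd.DataFrame(
        {
            "timestamp": pd.to_datetime([r[0] for r in rows]),
            "receiver_id": [r[1] for r in rows],
            "tag_id": [r[2] for r in rows],
        }
    )
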