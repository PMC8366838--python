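"""Synthetic fjord study generator.

Produces every input the downstream analysis consumes — receiver layout,
fish, movement tracks, acoustic detections, SNP genotypes with reference
panels, and isotope run sheets — with the statistical structure the
analysis assumes:

* residents follow a discrete-time mean-reverting (AR(1)) walk around a
  per-fish home center, clipped to the fjord basin;
* emigrants (Bernoulli per ecotype: 0.42 North Sea, 0.07 Fjord by default)
  swim down the channel past the receiver gates and fall silent, optionally
  returning months later; some residents make one short (<2 d) excursion;
* tags ping at i.i.d. Uniform(30, 90) s gaps and are detected per receiver
  with a logistic decay in distance truncated at the 130 m maximum range;
* genotypes are Hardy–Weinberg draws from per-locus ecotype frequencies
  separated by a configurable differential;
* muscle δ15N/δ13C follow a linear along-fjord baseline plus ecotype
  offsets, measured in duplicate on a run sheet with interleaved Gel-A
  standards and a linear instrument drift.

All draws flow from per-purpose child streams of the one config seed, so
identical (config, seed) gives bit-identical outputs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import SimulationConfig
from .fjord import (
    HALF_WIDTH_M,
    ORIGIN_EASTING,
    ORIGIN_NORTHING,
    FjordGeometry,
    build_default_geometry,
)
from .genepop import write_genepop
from .genetics import ReferencePanel, SnpGenotype

__all__ = [
    "TrueFish",
    "Track",
    "simulate_fish",
    "simulate_tracks",
    "simulate_detections",
    "simulate_study",
    "simulate_genotypes",
    "simulate_isotopes",
    "write_study",
]

#: Gel-A internal laboratory standard, known values (‰)
GELA_D15N = 5.4
GELA_D13C = -21.8

# stream ids so each random purpose has an independent child generator
_FISH, _TRACK, _DETECT, _GENO, _ISO = range(5)


def _rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream, index]))


@dataclass(frozen=True)
class TrueFish:
    """Latent truth for one tagged individual."""

    tag_id: str
    ecotype: str  # "FJ" | "NS"
    length_cm: float
    home_center: tuple[float, float]  # UTM easting/northing
    home_sd_m: float
    emigrates: bool
    departure_time: dt.datetime | None
    return_time: dt.datetime | None = None
    excursion_start: dt.datetime | None = None
    excursion_hours: float = 0.0

    def __post_init__(self) -> None:
        if not 33.0 <= self.length_cm <= 70.0:
            raise ValueError("length_cm outside the tagging window [33, 70]")


@dataclass(frozen=True)
class Track:
    """1-min (configurable) position series; NaN rows mean 'outside the fjord'."""

    tag_id: str
    t0: dt.datetime
    step_s: float
    xy: np.ndarray  # (n, 2) UTM, NaN when absent

    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.t0, periods=len(self.xy), freq=pd.Timedelta(seconds=self.step_s)
        )


# -- fish -------------------------------------------------------------------

_LENGTHS = {"NS": (44.4, 6.0, 36.0, 63.0), "FJ": (50.0, 8.0, 33.0, 70.0)}


def simulate_fish(
    geometry: FjordGeometry, config: SimulationConfig
) -> list[TrueFish]:
    """Draw the tagged cohort: ecotypes, sizes, home sites, and fates."""
    rng = _rng(config.seed, _FISH)
    horizon_s = (config.study_end - config.study_start).total_seconds()
    margin_s = min(7 * 86400.0, horizon_s / 5.0)

    # home sites sit near a moored receiver (fish are sedentary and the
    # basin interior is only observable near receivers), away from the gates
    interior = [
        r
        for r in geometry.receivers
        if r.role in ("internal_transect", "array")
    ]
    weights = np.array(
        [3.0 if r.role == "internal_transect" else 1.0 for r in interior]
    )
    weights /= weights.sum()

    fish: list[TrueFish] = []
    for i in range(config.n_fish):
        ecotype = "NS" if rng.random() < config.p_northsea else "FJ"
        mean, sd, lo, hi = _LENGTHS[ecotype]
        length = float(np.clip(rng.normal(mean, sd), lo, hi))
        anchor = interior[rng.choice(len(interior), p=weights)]
        home = (
            float(
                np.clip(
                    anchor.easting + rng.normal(0.0, 120.0),
                    ORIGIN_EASTING + 150.0,
                    ORIGIN_EASTING + 8_900.0,
                )
            ),
            float(
                np.clip(
                    anchor.northing + rng.normal(0.0, 70.0),
                    ORIGIN_NORTHING - HALF_WIDTH_M + 20,
                    ORIGIN_NORTHING + HALF_WIDTH_M - 20,
                )
            ),
        )
        home_sd = float(
            config.home_sd_median_m * np.exp(rng.normal(0.0, config.home_sd_logsd))
        )
        emigrates = rng.random() < config.emigration_prob[ecotype]
        departure = return_time = None
        excursion_start = None
        excursion_hours = 0.0
        if emigrates:
            dep_s = rng.uniform(margin_s, horizon_s - margin_s)
            departure = config.study_start + dt.timedelta(seconds=dep_s)
            if rng.random() < 0.08:  # rare prolonged absence with return
                back_s = dep_s + rng.uniform(60, 150) * 86400.0
                if back_s < horizon_s - margin_s / 2:
                    return_time = config.study_start + dt.timedelta(seconds=back_s)
        elif rng.random() < config.excursion_prob:
            exc_s = rng.uniform(margin_s, max(margin_s + 1.0, horizon_s - 2 * 86400.0 - margin_s))
            excursion_start = config.study_start + dt.timedelta(seconds=exc_s)
            excursion_hours = float(rng.uniform(8.0, 40.0))
        fish.append(
            TrueFish(
                tag_id=f"F{i + 1:04d}",
                ecotype=ecotype,
                length_cm=length,
                home_center=home,
                home_sd_m=home_sd,
                emigrates=emigrates,
                departure_time=departure,
                return_time=return_time,
                excursion_start=excursion_start,
                excursion_hours=excursion_hours,
            )
        )
    return fish


# -- tracks -----------------------------------------------------------------


def _ou_series(
    rng: np.random.Generator, n: int, center: float, sd: float, phi: float
) -> np.ndarray:
    """Stationary AR(1) (discrete Ornstein-Uhlenbeck) series around center."""
    if sd <= 0.0 or n == 0:
        return np.full(n, center)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - phi * phi), size=n)
    eps[0] = rng.normal(0.0, sd)  # start in the stationary distribution
    dev = lfilter([1.0], [1.0, -phi], eps)
    return center + dev


def _transit_out(
    u: np.ndarray, lat: np.ndarray, i0: int, speed: float, step: float, side: float
) -> int:
    """Overwrite from index i0 with a down-channel run past the outlet.

    Returns the first index at which the fish is outside (u < -50 m); from
    there positions are the caller's responsibility (NaN or a later return).
    """
    n = len(u)
    if i0 >= n:
        return n
    u0 = u[i0]
    k = np.arange(n - i0)
    uu = u0 - speed * step * k
    lat_target = side * 90.0
    blend = np.exp(-k * step / 1800.0)
    ll = lat[i0] * blend + lat_target * (1.0 - blend)
    u[i0:] = uu
    lat[i0:] = ll
    out = np.nonzero(uu < -50.0)[0]
    return i0 + int(out[0]) if len(out) else n


def _transit_in(
    u: np.ndarray,
    lat: np.ndarray,
    i_back: int,
    home_u: float,
    home_lat: float,
    speed: float,
    step: float,
    side: float,
) -> int:
    """Overwrite from i_back with an up-channel run from the outlet to home.

    Returns the first index at which the fish is back at its home center.
    """
    n = len(u)
    if i_back >= n:
        return n
    k = np.arange(n - i_back)
    uu = -50.0 + speed * step * k
    arrived = np.nonzero(uu >= home_u)[0]
    i_home = i_back + int(arrived[0]) if len(arrived) else n
    uu = np.minimum(uu, home_u)
    frac = np.clip(uu / max(home_u, 1.0), 0.0, 1.0)
    ll = side * 90.0 * (1.0 - frac) + home_lat * frac
    u[i_back:] = uu
    lat[i_back:] = ll
    return i_home


def _build_track(
    fish: TrueFish, geometry: FjordGeometry, config: SimulationConfig, index: int
) -> Track:
    rng = _rng(config.seed, _TRACK, index)
    step = config.track_step_s
    n = int((config.study_end - config.study_start).total_seconds() // step)
    phi = float(np.exp(-step / config.reversion_tau_s))

    home_u = fish.home_center[0] - ORIGIN_EASTING
    home_lat = fish.home_center[1] - ORIGIN_NORTHING
    u = _ou_series(rng, n, home_u, fish.home_sd_m, phi)
    lat = _ou_series(rng, n, home_lat, fish.home_sd_m / 2.0, phi)
    np.clip(u, 50.0, 8_950.0, out=u)
    np.clip(lat, -HALF_WIDTH_M + 10, HALF_WIDTH_M - 10, out=lat)
    side = 1.0 if home_lat >= 0 else -1.0
    absent = np.zeros(n, dtype=bool)

    def idx(ts: dt.datetime) -> int:
        return int((ts - config.study_start).total_seconds() // step)

    if fish.emigrates and fish.departure_time is not None:
        i_out = _transit_out(
            u, lat, idx(fish.departure_time), config.emigrant_speed_ms, step, side
        )
        absent[i_out:] = True
        if fish.return_time is not None:
            i_back = idx(fish.return_time)
            if i_back < n:
                i_home = _transit_in(
                    u, lat, i_back, home_u, home_lat,
                    config.emigrant_speed_ms, step, side,
                )
                absent[i_back:] = False
                # resume residency after the return leg
                m = n - i_home
                if m > 0:
                    u[i_home:] = np.clip(
                        _ou_series(rng, m, home_u, fish.home_sd_m, phi), 50.0, 8_950.0
                    )
                    lat[i_home:] = np.clip(
                        _ou_series(rng, m, home_lat, fish.home_sd_m / 2.0, phi),
                        -HALF_WIDTH_M + 10,
                        HALF_WIDTH_M - 10,
                    )
    elif fish.excursion_start is not None:
        i_exc = idx(fish.excursion_start)
        exc_speed = 0.4  # out-and-back trips are faster, directed swimming
        i_out = _transit_out(u, lat, i_exc, exc_speed, step, side)
        i_back = i_out + int(fish.excursion_hours * 3600.0 // step)
        absent[i_out:] = True
        if i_back < n:
            i_home = _transit_in(
                u, lat, i_back, home_u, home_lat, exc_speed, step, side
            )
            absent[i_back:] = False
            m = n - i_home
            if m > 0:
                u[i_home:] = np.clip(
                    _ou_series(rng, m, home_u, fish.home_sd_m, phi), 50.0, 8_950.0
                )
                lat[i_home:] = np.clip(
                    _ou_series(rng, m, home_lat, fish.home_sd_m / 2.0, phi),
                    -HALF_WIDTH_M + 10,
                    HALF_WIDTH_M - 10,
                )

    xy = np.column_stack([ORIGIN_EASTING + u, ORIGIN_NORTHING + lat])
    xy[absent] = np.nan
    return Track(tag_id=fish.tag_id, t0=config.study_start, step_s=step, xy=xy)


def simulate_tracks(
    geometry: FjordGeometry,
    config: SimulationConfig,
    fish: list[TrueFish] | None = None,
) -> list[Track]:
    """Movement tracks for the whole cohort (see module docstring)."""
    if config.n_fish <= 0:
        raise ValueError("n_fish must be positive")
    if fish is None:
        fish = simulate_fish(geometry, config)
    return [_build_track(f, geometry, config, i) for i, f in enumerate(fish)]


# -- detections -------------------------------------------------------------


def detection_probability(
    distance_m: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    """Logistic range decay, truncated to zero beyond the maximum range."""
    d = np.asarray(distance_m, dtype=float)
    p = 1.0 / (1.0 + np.exp((d - config.detect_halfrange_m) / config.detect_scale_m))
    return np.where(d > config.max_detect_range_m, 0.0, p)


def _detect_one(
    track: Track,
    geometry: FjordGeometry,
    config: SimulationConfig,
    index: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(transmission times [s since study start], receiver indices) for one fish."""
    rng = _rng(config.seed, _DETECT, index)
    horizon = len(track.xy) * track.step_s
    lo, hi = config.transmit_interval_s
    mean_gap = 0.5 * (lo + hi)
    n_draw = int(horizon / mean_gap * 1.05) + 16
    gaps = rng.uniform(lo, hi, size=n_draw)
    tt = np.cumsum(gaps)
    while tt[-1] < horizon:  # pragma: no cover - generous initial draw
        more = rng.uniform(lo, hi, size=n_draw // 4 + 16)
        tt = np.concatenate([tt, tt[-1] + np.cumsum(more)])
    tt = tt[tt < horizon]
    pos = track.xy[(tt // track.step_s).astype(np.int64)]
    ok = ~np.isnan(pos[:, 0])
    tt, pos = tt[ok], pos[ok]
    if len(tt) == 0:
        return np.empty(0), np.empty(0, dtype=np.int64)

    coords = geometry.receiver_coords
    # candidate receivers: within detection reach of the fish's bounding box
    margin = config.max_detect_range_m + 1.0
    lo_xy = pos.min(axis=0) - margin
    hi_xy = pos.max(axis=0) + margin
    cand = np.nonzero(
        (coords[:, 0] >= lo_xy[0])
        & (coords[:, 0] <= hi_xy[0])
        & (coords[:, 1] >= lo_xy[1])
        & (coords[:, 1] <= hi_xy[1])
    )[0]
    if len(cand) == 0:
        return np.empty(0), np.empty(0, dtype=np.int64)

    start = config.study_start
    act_from = np.array(
        [
            (geometry.receivers[c].active_from - start).total_seconds()
            for c in cand
        ]
    )
    act_to = np.array(
        [(geometry.receivers[c].active_to - start).total_seconds() for c in cand]
    )
    # chunk so the (transmissions x candidates) matrices stay small
    chunk = max(1, 4_000_000 // max(1, len(cand)))
    out_t: list[np.ndarray] = []
    out_r: list[np.ndarray] = []
    for s in range(0, len(tt), chunk):
        tts = tt[s : s + chunk]
        ps = pos[s : s + chunk]
        d = np.hypot(
            ps[:, 0][:, None] - coords[cand, 0][None, :],
            ps[:, 1][:, None] - coords[cand, 1][None, :],
        )
        p = detection_probability(d, config)
        active = (tts[:, None] >= act_from[None, :]) & (tts[:, None] < act_to[None, :])
        hit = (rng.random(size=p.shape) < p) & active
        ti, ri = np.nonzero(hit)
        out_t.append(tts[ti])
        out_r.append(cand[ri])
    return np.concatenate(out_t), np.concatenate(out_r)


def _assemble_detections(
    times: list[np.ndarray],
    recs: list[np.ndarray],
    tag_ids: list[str],
    geometry: FjordGeometry,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Build the time-sorted detection frame from per-fish arrays."""
    tt = np.concatenate(times) if times else np.empty(0)
    ri = np.concatenate(recs) if recs else np.empty(0, dtype=np.int64)
    tag_codes = np.repeat(
        np.arange(len(times), dtype=np.int64),
        [len(t) for t in times],
    )
    order = np.argsort(tt, kind="stable")
    tt, ri, tag_codes = tt[order], ri[order], tag_codes[order]
    start = pd.Timestamp(config.study_start)
    if start.tzinfo is not None:
        start = start.tz_convert("UTC").tz_localize(None)
    stamps = start.to_datetime64() + (tt * 1e6).astype("timedelta64[us]")
    rec_ids = pd.Categorical.from_codes(
        ri, categories=[r.receiver_id for r in geometry.receivers]
    )
    tags = pd.Categorical.from_codes(tag_codes, categories=tag_ids)
    return pd.DataFrame(
        {"timestamp": stamps, "receiver_id": rec_ids, "tag_id": tags}
    )


def simulate_detections(
    tracks: list[Track], geometry: FjordGeometry, config: SimulationConfig
) -> pd.DataFrame:
    """Acoustic detection log for a set of tracks, sorted by time.

    Columns: ``timestamp`` (naive UTC), ``receiver_id``, ``tag_id``.
    """
    if not tracks:
        raise ValueError("tracks must be non-empty")
    times: list[np.ndarray] = []
    recs: list[np.ndarray] = []
    for i, track in enumerate(tracks):
        tt, ri = _detect_one(track, geometry, config, i)
        times.append(tt)
        recs.append(ri)
    return _assemble_detections(
        times, recs, [t.tag_id for t in tracks], geometry, config
    )


def simulate_study(
    geometry: FjordGeometry | None, config: SimulationConfig
) -> tuple[list[TrueFish], pd.DataFrame]:
    """Fish plus their detection log, streaming tracks one fish at a time.

    Equivalent to ``simulate_detections(simulate_tracks(...))`` but never
    holds more than one track in memory, which is what makes the large
    classification experiments feasible.
    """
    if geometry is None:
        geometry = build_default_geometry(config.seed, config)
    fish = simulate_fish(geometry, config)
    times: list[np.ndarray] = []
    recs: list[np.ndarray] = []
    for i, f in enumerate(fish):
        track = _build_track(f, geometry, config, i)
        tt, ri = _detect_one(track, geometry, config, i)
        times.append(tt)
        recs.append(ri)
    df = _assemble_detections(
        times, recs, [f.tag_id for f in fish], geometry, config
    )
    return fish, df


# -- genotypes --------------------------------------------------------------


def simulate_genotypes(
    config: SimulationConfig, fish: list[TrueFish] | None = None
) -> tuple[ReferencePanel, dict[str, list[SnpGenotype]], list[SnpGenotype], list[str]]:
    """Reference panels plus study genotypes with known true origins.

    Per locus, the Fjord allele-1 frequency is Uniform(0.2, 0.8) and the
    North Sea frequency sits ``allele_freq_differential`` away (random side,
    flipped if it would leave [0.01, 0.99]).  Reference panels are
    Hardy–Weinberg samples of ``ref_sample_size`` gene copies per
    population; study individuals are Hardy–Weinberg draws from their true
    origin, with independent per-call missingness.

    Returns ``(panel, reference_individuals, study_genotypes, true_origins)``.
    """
    if config.n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = _rng(config.seed, _GENO)
    diff = config.allele_freq_differential
    p_fj = rng.uniform(0.2, 0.8, size=config.n_loci)
    sign = rng.choice([-1.0, 1.0], size=config.n_loci)
    p_ns = p_fj + sign * diff
    flip = (p_ns < 0.01) | (p_ns > 0.99)
    p_ns = np.where(flip, p_fj - sign * diff, p_ns)
    p_ns = np.clip(p_ns, 0.0, 1.0)
    freqs = {"FJ": p_fj, "NS": p_ns}
    loci = tuple(f"SNP{j + 1:02d}" for j in range(config.n_loci))

    def draw_individual(
        pop: str, ind_id: str, missing_rate: float
    ) -> SnpGenotype:
        p = freqs[pop]
        a = (rng.random(config.n_loci) < p).astype(int)
        b = (rng.random(config.n_loci) < p).astype(int)
        miss = rng.random(config.n_loci) < missing_rate
        calls: list[tuple[str, str] | None] = []
        for j in range(config.n_loci):
            if miss[j]:
                calls.append(None)
            else:
                x, y = sorted((a[j], b[j]))
                calls.append((f"{1 + x:02d}", f"{1 + y:02d}"))
        return SnpGenotype(individual_id=ind_id, calls=tuple(calls))

    n_ref_ind = config.ref_sample_size // 2
    reference = {
        pop: [
            draw_individual(pop, f"{pop}ref{i + 1:03d}", 0.0)
            for i in range(n_ref_ind)
        ]
        for pop in ("FJ", "NS")
    }

    if fish is not None:
        origins = [f.ecotype for f in fish]
        ids = [f.tag_id for f in fish]
    else:
        origins = [
            "NS" if rng.random() < config.p_northsea else "FJ"
            for _ in range(config.n_fish)
        ]
        ids = [f"F{i + 1:04d}" for i in range(config.n_fish)]
    study = [
        draw_individual(pop, ind_id, config.missing_rate)
        for pop, ind_id in zip(origins, ids)
    ]

    counts: dict[str, list[dict[str, int]]] = {
        pop: [dict() for _ in loci] for pop in ("FJ", "NS")
    }
    for pop, block in reference.items():
        for g in block:
            for li, call in enumerate(g.calls):
                if call is None:
                    continue
                for allele in call:
                    counts[pop][li][allele] = counts[pop][li].get(allele, 0) + 1
    panel = ReferencePanel(loci=loci, populations=("FJ", "NS"), counts=counts)
    panel.register_alleles(study)
    return panel, reference, study, origins


# -- isotopes ---------------------------------------------------------------


def simulate_isotopes(
    fish: list[TrueFish],
    mean_distances_km: dict[str, float],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw duplicate run sheet with interleaved Gel-A standards, plus truth.

    True values: δ15N = intercept + slope·distance + offset·1[Fjord] +
    N(0, isotope_sd), same pattern for δ13C.  Each fish is measured twice;
    a standard is inserted before every 5 samples and one closes the sheet;
    every raw value is perturbed by a per-sheet offset plus a linear drift
    in run position.  Run position is 1-based and counts standards and
    samples alike.

    Returns ``(run_sheet, truth)`` where truth has one row per fish.
    """
    for f in fish:
        if f.tag_id not in mean_distances_km:
            raise KeyError(f"no mean distance for fish {f.tag_id}")
    rng = _rng(config.seed, _ISO)
    offset_n = float(rng.normal(0.0, config.sheet_offset_sd))
    offset_c = float(rng.normal(0.0, config.sheet_offset_sd))

    truth_rows = []
    for f in fish:
        d = mean_distances_km[f.tag_id]
        is_fj = 1.0 if f.ecotype == "FJ" else 0.0
        n15 = (
            config.d15n_intercept
            + config.d15n_slope_per_km * d
            + config.ecotype_offset_n * is_fj
            + rng.normal(0.0, config.isotope_sd)
        )
        c13 = (
            config.d13c_intercept
            + config.d13c_slope_per_km * d
            + config.ecotype_offset_c * is_fj
            + rng.normal(0.0, config.isotope_sd)
        )
        truth_rows.append(
            {
                "tag_id": f.tag_id,
                "ecotype": f.ecotype,
                "distance_km": d,
                "d15N_true": n15,
                "d13C_true": c13,
            }
        )
    truth = pd.DataFrame(truth_rows)

    rows = []
    run = 0
    since_standard = 5  # force a standard first

    def add_standard() -> None:
        nonlocal run, since_standard
        run += 1
        rows.append(
            {
                "run_number": run,
                "sample_id": "",
                "is_standard": True,
                "replicate": 0,
                "d15N_raw": GELA_D15N + offset_n + config.drift_per_run * run,
                "d13C_raw": GELA_D13C + offset_c + config.drift_per_run * run,
            }
        )
        since_standard = 0

    for row in truth_rows:
        for rep in (1, 2):
            if since_standard >= 5:
                add_standard()
            run += 1
            since_standard += 1
            rows.append(
                {
                    "run_number": run,
                    "sample_id": row["tag_id"],
                    "is_standard": False,
                    "replicate": rep,
                    "d15N_raw": row["d15N_true"]
                    + offset_n
                    + config.drift_per_run * run,
                    "d13C_raw": row["d13C_true"]
                    + offset_c
                    + config.drift_per_run * run,
                }
            )
    add_standard()
    return pd.DataFrame(rows), truth


# -- writers ----------------------------------------------------------------


def write_study(out_dir: str | Path, config: SimulationConfig) -> dict[str, Path]:
    """Run the full generator and write every pipeline input to ``out_dir``.

    Files: receivers.csv, detections.csv, fish.csv, genotypes.gen (GENEPOP),
    isotopes.csv, truth.csv (latent values, for tests and QC only).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geometry = build_default_geometry(config.seed, config)
    fish, detections = simulate_study(geometry, config)
    panel, reference, study, origins = simulate_genotypes(config, fish)
    distances = {
        f.tag_id: float(geometry.distance_to_outlet_km(np.array([f.home_center]))[0])
        for f in fish
    }
    iso, truth = simulate_isotopes(fish, distances, config)

    paths = {
        "receivers": out / "receivers.csv",
        "detections": out / "detections.csv",
        "fish": out / "fish.csv",
        "genotypes": out / "genotypes.gen",
        "isotopes": out / "isotopes.csv",
        "truth": out / "truth.csv",
    }
    geometry.receivers_frame().to_csv(paths["receivers"], index=False)
    det = detections.copy()
    det["timestamp"] = det["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    det.to_csv(paths["detections"], index=False)
    pd.DataFrame(
        {
            "tag_id": [f.tag_id for f in fish],
            "length_cm": [f.length_cm for f in fish],
            "release_easting": [f.home_center[0] for f in fish],
            "release_northing": [f.home_center[1] for f in fish],
            "true_ecotype": [f.ecotype for f in fish],
        }
    ).to_csv(paths["fish"], index=False)
    write_genepop(
        paths["genotypes"], panel.loci, reference, study, title="simulated cod panel"
    )
    iso.to_csv(paths["isotopes"], index=False)
    truth_full = truth.merge(
        pd.DataFrame(
            {
                "tag_id": [f.tag_id for f in fish],
                "home_sd_m": [f.home_sd_m for f in fish],
                "emigrates": [f.emigrates for f in fish],
                "departure_time": [f.departure_time for f in fish],
                "return_time": [f.return_time for f in fish],
            }
        ),
        on="tag_id",
    )
    truth_full.to_csv(paths["truth"], index=False)
    return paths
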