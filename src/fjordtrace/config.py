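"""Configuration objects for the simulator and the end-to-end pipeline.

Defaults describe the study system the package targets: a ~9 km Norwegian
fjord instrumented with receiver gates and a dense array, 72 tagged cod
split ~43/57 between the oceanic "North Sea" (NS) and resident "Fjord" (FJ)
ecotypes, tags pinging every 30–90 s, ecotype-specific emigration
probabilities of 0.42 (NS) and 0.07 (FJ), and muscle δ13C/δ15N values with
a shared along-fjord baseline gradient plus ecotype offsets.
"""

from __future__ import annotations

import datetime as dt
import tomllib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any

__all__ = ["SimulationConfig", "RunConfig", "load_toml"]


def _parse_utc(value: str | dt.datetime) -> dt.datetime:
    if isinstance(value, dt.datetime):
        ts = value
    else:
        ts = dt.datetime.fromisoformat(str(value))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=dt.timezone.utc)
    return ts.astimezone(dt.timezone.utc)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic fjord study.

    Probabilities are per-individual over the whole study horizon; lengths
    in meters unless suffixed otherwise; isotope quantities in per mil (‰).
    """

    n_fish: int = 72
    p_northsea: float = 0.43
    #: per-ecotype probability of leaving the fjord for good during the study
    emigration_prob: dict[str, float] = field(
        default_factory=lambda: {"NS": 0.42, "FJ": 0.07}
    )
    #: probability of one short (<2 d) out-and-back excursion past the gates
    excursion_prob: float = 0.08
    transmit_interval_s: tuple[float, float] = (30.0, 90.0)
    max_detect_range_m: float = 130.0
    detect_halfrange_m: float = 65.0
    #: logistic scale of the detection-range decay; default gives p<0.01 at 130 m
    detect_scale_m: float = 14.0
    track_step_s: float = 60.0
    #: median and log-sd of the per-fish lognormal movement scale
    home_sd_median_m: float = 110.0
    home_sd_logsd: float = 0.5
    #: mean-reversion time scale of the movement walk
    reversion_tau_s: float = 3600.0
    #: along-axis swimming speed of departing fish
    emigrant_speed_ms: float = 0.15

    n_loci: int = 27
    ref_sample_size: int = 200
    allele_freq_differential: float = 0.3
    missing_rate: float = 0.01

    d15n_intercept: float = 15.0
    d13c_intercept: float = -18.5
    d15n_slope_per_km: float = -0.135
    d13c_slope_per_km: float = -0.038
    ecotype_offset_n: float = 0.389
    ecotype_offset_c: float = 0.626
    isotope_sd: float = 0.55
    drift_per_run: float = 0.01
    #: per-run-sheet constant offset sd (daily instrument offset)
    sheet_offset_sd: float = 0.2

    study_start: dt.datetime = field(
        default_factory=lambda: _parse_utc("2016-11-01")
    )
    study_end: dt.datetime = field(default_factory=lambda: _parse_utc("2018-06-01"))
    array_start: dt.datetime = field(default_factory=lambda: _parse_utc("2017-05-01"))
    array_end: dt.datetime = field(default_factory=lambda: _parse_utc("2017-11-30"))

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish <= 0:
            raise ValueError("n_fish must be positive")
        for name in ("p_northsea", "excursion_prob", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for pop, p in self.emigration_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"emigration_prob[{pop!r}] must be in [0, 1]")
        lo, hi = self.transmit_interval_s
        if not lo < hi:
            raise ValueError("transmit_interval_s must satisfy min < max")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0.0 <= self.allele_freq_differential <= 1.0:
            raise ValueError("allele_freq_differential must be in [0, 1]")
        if self.isotope_sd < 0:
            raise ValueError("isotope_sd must be >= 0")
        if not self.study_start < self.study_end:
            raise ValueError("study_start must precede study_end")

    def with_(self, **kwargs: Any) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "SimulationConfig":
        kwargs: dict[str, Any] = {}
        names = {f.name for f in fields(cls)}
        for key, value in raw.items():
            if key not in names:
                raise KeyError(f"unknown simulation option {key!r}")
            if key in {"study_start", "study_end", "array_start", "array_end"}:
                value = _parse_utc(value)
            elif key == "transmit_interval_s":
                value = (float(value[0]), float(value[1]))
            elif key == "emigration_prob":
                value = {str(k): float(v) for k, v in value.items()}
            kwargs[key] = value
        return cls(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline run: input locations (or a simulation), thresholds."""

    out_dir: Path
    simulation: SimulationConfig | None = None
    detections_csv: Path | None = None
    receivers_csv: Path | None = None
    fish_csv: Path | None = None
    genepop_path: Path | None = None
    isotopes_csv: Path | None = None

    assignment_threshold: float = 80.0
    min_loci: int = 20
    window_start: dt.datetime = field(default_factory=lambda: _parse_utc("2017-05-01"))
    window_end: dt.datetime = field(default_factory=lambda: _parse_utc("2017-11-30"))
    keep_fraction: float = 0.95
    min_positions: int = 5
    ellipse_vertices: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.window_start < self.window_end:
            raise ValueError("window start must precede window end")
        if self.simulation is None:
            for name in ("detections_csv", "receivers_csv", "fish_csv"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(
                        f"{name} must exist for a non-simulated run: {p}"
                    )

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        raw = load_toml(path)
        sim = raw.pop("simulation", None)
        run = raw.pop("run", {})
        kwargs: dict[str, Any] = {}
        if sim is not None:
            kwargs["simulation"] = SimulationConfig.from_dict(sim)
        for key in ("window_start", "window_end"):
            if key in run:
                run[key] = _parse_utc(run[key])
        for key in (
            "out_dir",
            "detections_csv",
            "receivers_csv",
            "fish_csv",
            "genepop_path",
            "isotopes_csv",
        ):
            if key in run:
                run[key] = Path(run[key])
        kwargs.update(run)
        return cls(**kwargs)


def load_toml(path: str | Path) -> dict[str, Any]:
    with open(path, "rb") as fh:
        return tomllib.load(fh)
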