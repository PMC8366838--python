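"""End-to-end orchestration: simulate → assign → telemetry → home range →
isotopes → niche → models → summaries.

Each stage writes its row-level CSV into the run directory before the next
starts, so a failing stage (reported by name) leaves partial outputs for
inspection.  Summary percentages are integer-rounded half-up, and every
percentage in a summary equals its numerator/denominator recomputed from
the row-level files.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, SimulationConfig
from .fjord import FjordGeometry, ReceiverDeployment, build_default_geometry
from .genepop import read_genepop
from .genetics import assign_all
from .home_range import home_ranges
from .isotope_lab import collapse_duplicates, drift_correct, standards_qc
from .models import (
    GammaRandomInterceptModel,
    drop_insignificant_interactions,
    model_table,
)
from .niche import niche_table, plot_niche_biplot, residualize
from .telemetry import (
    classify_all_fates,
    daily_positions,
    fates_frame,
    position_averages,
    select_array_cohort,
)

log = logging.getLogger("fjordtrace")

__all__ = ["run_pipeline", "PipelineError", "percent", "fates_summary", "cohort_summary"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def percent(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half-up (42.5 → 43)."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator in percentage")
    frac = Decimal(numerator) * 100 / Decimal(denominator)
    return int(frac.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def fates_summary(fates: pd.DataFrame, ecotypes: pd.Series) -> pd.DataFrame:
    """Departure counts and integer percentages per ecotype.

    ``ecotypes`` maps tag_id → ecotype label; the denominator per row is
    the number of tagged fish of that ecotype.  ``departed`` counts both
    permanent and prolonged (returned) departures.
    """
    df = fates.copy()
    df["ecotype"] = df["tag_id"].map(ecotypes)
    rows = []
    for eco, grp in df.groupby("ecotype", sort=True):
        n = len(grp)
        permanent = int((grp["status"] == "departed_permanent").sum())
        returned = int((grp["status"] == "departed_returned").sum())
        rows.append(
            {
                "ecotype": eco,
                "n": n,
                "departed": permanent + returned,
                "departed_pct": percent(permanent + returned, n),
                "departed_permanent": permanent,
                "departed_permanent_pct": percent(permanent, n),
                "departed_returned": returned,
                "short_excursion": int((grp["status"] == "short_excursion").sum()),
                "lost": int((grp["status"] == "lost").sum()),
                "resident": int((grp["status"] == "resident").sum()),
            }
        )
    return pd.DataFrame(rows)


def cohort_summary(
    fish: pd.DataFrame, cohort_tags: set[str], ecotype_col: str = "ecotype"
) -> pd.DataFrame:
    """Tagged-cohort composition, one row per ecotype plus a total row."""
    total = len(fish)
    rows = []
    for eco, grp in fish.groupby(ecotype_col, sort=True):
        in_cohort = grp[grp["tag_id"].isin(cohort_tags)]
        rows.append(
            {
                "ecotype": eco,
                "n": len(grp),
                "pct_of_tagged": percent(len(grp), total),
                "mean_length_cm": float(grp["length_cm"].mean()),
                "n_array_cohort": len(in_cohort),
                "mean_length_array_cm": float(in_cohort["length_cm"].mean())
                if len(in_cohort)
                else np.nan,
            }
        )
    rows.append(
        {
            "ecotype": "all",
            "n": total,
            "pct_of_tagged": 100,
            "mean_length_cm": float(fish["length_cm"].mean()),
            "n_array_cohort": len(cohort_tags & set(fish["tag_id"])),
            "mean_length_array_cm": float(
                fish.loc[fish["tag_id"].isin(cohort_tags), "length_cm"].mean()
            )
            if cohort_tags
            else np.nan,
        }
    )
    return pd.DataFrame(rows)


def _geometry_from_files(receivers: pd.DataFrame) -> FjordGeometry:
    deps = []
    for _, r in receivers.iterrows():
        deps.append(
            ReceiverDeployment(
                receiver_id=str(r["receiver_id"]),
                easting=float(r["easting"]),
                northing=float(r["northing"]),
                role=str(r["role"]),
                active_from=pd.Timestamp(r["active_from"]).to_pydatetime(),
                active_to=pd.Timestamp(r["active_to"]).to_pydatetime(),
            )
        )
    # default straight axis spanning the receiver extent (head → outlet)
    east = receivers["easting"]
    north_mid = float(receivers["northing"].mean())
    axis = np.array(
        [[float(east.max()) + 200.0, north_mid], [float(east.min()) - 200.0, north_mid]]
    )
    return FjordGeometry(axis=axis, receivers=tuple(deps))


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns the map of written outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    t_start = dt.datetime.now(dt.timezone.utc)

    def stage(name):
        def wrap(fn):
            try:
                log.info("stage %s", name)
                return fn()
            except Exception as exc:  # noqa: BLE001 - report the stage
                raise PipelineError(name, exc) from exc

        return wrap

    # -- inputs ------------------------------------------------------------
    if config.simulation is not None:
        from .simulate import write_study

        sim = config.simulation
        paths = stage("simulate")(lambda: write_study(out / "inputs", sim))
        detections_csv = paths["detections"]
        receivers_csv = paths["receivers"]
        fish_csv = paths["fish"]
        genepop_path = paths["genotypes"]
        isotopes_csv = paths["isotopes"]
        study_end = sim.study_end
        geometry = build_default_geometry(sim.seed, sim)
    else:
        detections_csv = config.detections_csv
        receivers_csv = config.receivers_csv
        fish_csv = config.fish_csv
        genepop_path = config.genepop_path
        isotopes_csv = config.isotopes_csv
        geometry = None
        study_end = None

    receivers = pd.read_csv(receivers_csv, parse_dates=["active_from", "active_to"])
    detections = pd.read_csv(detections_csv, parse_dates=["timestamp"])
    fish = pd.read_csv(fish_csv)
    if geometry is None:
        geometry = _geometry_from_files(receivers)
    if study_end is None:
        study_end = pd.Timestamp(detections["timestamp"].max()).to_pydatetime()

    # -- genetic assignment --------------------------------------------------
    if genepop_path is not None:
        def _assign():
            panel, study = read_genepop(genepop_path)
            report = assign_all(
                study,
                panel,
                threshold=config.assignment_threshold,
                min_loci=min(config.min_loci, len(panel.loci)),
            )
            p = out / "assignments.csv"
            report.to_csv(p, index=False)
            return report, p

        report, outputs["assignments"] = stage("assign")(_assign)
        labels = report.set_index("individual_id")["label"]
        fish["ecotype"] = fish["tag_id"].map(labels)
        unassigned = fish["ecotype"].isin(["unassigned"]) | fish["ecotype"].isna()
        if unassigned.any():
            log.info("dropping %d unassigned fish", int(unassigned.sum()))
            fish = fish[~unassigned]
    elif "true_ecotype" in fish.columns:
        fish["ecotype"] = fish["true_ecotype"]
    else:
        raise PipelineError("assign", ValueError("no genotypes and no ecotype column"))
    detections = detections[detections["tag_id"].isin(set(fish["tag_id"]))]

    # -- telemetry -----------------------------------------------------------
    def _telemetry():
        pos = position_averages(detections, receivers, geometry)
        fates = fates_frame(
            classify_all_fates(
                detections, receivers, study_end, all_tags=list(fish["tag_id"])
            )
        )
        pos.to_csv(out / "positions.csv", index=False)
        fates.to_csv(out / "fates.csv", index=False)
        return pos, fates

    positions, fates = stage("telemetry")(_telemetry)
    outputs["positions"] = out / "positions.csv"
    outputs["fates"] = out / "fates.csv"

    ecotypes = fish.set_index("tag_id")["ecotype"]
    fsum = fates_summary(fates, ecotypes)
    fsum.to_csv(out / "fates_summary.csv", index=False)
    outputs["fates_summary"] = out / "fates_summary.csv"

    # detections are read as naive UTC; keep window bounds naive to match
    window = (
        pd.Timestamp(config.window_start).tz_localize(None),
        pd.Timestamp(config.window_end).tz_localize(None),
    )
    cohort = select_array_cohort(
        classify_all_fates(detections, receivers, study_end), positions, window
    )
    csum = cohort_summary(fish, cohort)
    csum.to_csv(out / "cohort_summary.csv", index=False)
    outputs["cohort_summary"] = out / "cohort_summary.csv"

    # -- home ranges ---------------------------------------------------------
    def _homerange():
        per = pd.to_datetime(positions["period_start"])
        mask = (
            positions["tag_id"].isin(cohort)
            & (per >= pd.Timestamp(window[0]))
            & (per <= pd.Timestamp(window[1]))
        )
        hr = home_ranges(
            positions[mask],
            keep_fraction=config.keep_fraction,
            min_points=config.min_positions,
        )
        hr.to_csv(out / "homeranges.csv", index=False)
        if len(hr):
            stats = pd.DataFrame(
                [
                    {
                        "n": len(hr),
                        "mean_ha": hr["area_ha"].mean(),
                        "sd_ha": hr["area_ha"].std(ddof=1),
                        "median_ha": hr["area_ha"].median(),
                        "min_ha": hr["area_ha"].min(),
                        "max_ha": hr["area_ha"].max(),
                    }
                ]
            )
        else:
            stats = pd.DataFrame()
        stats.to_csv(out / "homerange_stats.csv", index=False)
        return hr

    hr = stage("home_range")(_homerange)
    outputs["homeranges"] = out / "homeranges.csv"
    outputs["homerange_stats"] = out / "homerange_stats.csv"

    # -- isotopes + niche ----------------------------------------------------
    niche_ok = isotopes_csv is not None
    if niche_ok:
        def _isotopes():
            raw = pd.read_csv(isotopes_csv)
            corrected = drift_correct(raw)
            collapsed = collapse_duplicates(corrected)
            collapsed.to_csv(out / "corrected_isotopes.csv", index=False)
            standards_qc(corrected).to_csv(out / "standards_qc.csv", index=False)
            return collapsed

        corrected = stage("isotopes")(_isotopes)
        outputs["corrected_isotopes"] = out / "corrected_isotopes.csv"

        def _niche():
            daily = daily_positions(positions)
            per = pd.to_datetime(daily["date"])
            in_win = daily[
                daily["tag_id"].isin(cohort)
                & (per >= pd.Timestamp(window[0]))
                & (per <= pd.Timestamp(window[1]))
            ]
            mean_dist = (
                in_win.groupby("tag_id")["distance_km"].mean().rename("distance_km")
            )
            meta = fish.set_index("tag_id")
            dist = pd.DataFrame(
                {
                    "sample_id": mean_dist.index,
                    "distance_km": mean_dist.to_numpy(),
                }
            )
            dist["ecotype"] = dist["sample_id"].map(meta["ecotype"])
            if "length_cm" in meta.columns:
                dist["length_cm"] = dist["sample_id"].map(meta["length_cm"])
            residuals = residualize(corrected, dist)
            summary, overlaps = niche_table(
                residuals, n_vertices=config.ellipse_vertices
            )
            summary.to_csv(out / "niche_summary.csv", index=False)
            overlaps.to_csv(out / "overlap.csv", index=False)
            plot_niche_biplot(residuals, out / "niche_biplot.png")
            return residuals

        residuals = stage("niche")(_niche)
        outputs["niche_summary"] = out / "niche_summary.csv"
        outputs["overlap"] = out / "overlap.csv"

    # -- models --------------------------------------------------------------
    def _models():
        fits = {}
        meta = fish.set_index("tag_id")
        hr_data = hr[~hr["degenerate"] & (hr["area_ha"] > 0)].copy()
        hr_data["log_area"] = np.log(hr_data["area_ha"])
        hr_data["is_ns"] = (
            hr_data["tag_id"].map(meta["ecotype"]) == "NS"
        ).astype(float)
        if "length_cm" in meta.columns:
            hr_data["length_cm"] = hr_data["tag_id"].map(meta["length_cm"])
            if len(hr_data) > 5 and hr_data["is_ns"].nunique() > 1:
                fits["homerange_log"] = drop_insignificant_interactions(
                    "log_area ~ is_ns * length_cm", hr_data
                )
        if niche_ok:
            iso = residuals.copy()
            iso["is_fj"] = (iso["ecotype"] == "FJ").astype(float)
            for el, col in (("d15N", "d15N"), ("d13C", "d13C")):
                if iso["is_fj"].nunique() > 1 and len(iso) > 6:
                    fits[f"isotope_{el}"] = drop_insignificant_interactions(
                        f"{col} ~ is_fj * distance_km", iso
                    )
        daily = daily_positions(positions)
        per = pd.to_datetime(daily["date"])
        dd = daily[
            daily["tag_id"].isin(cohort)
            & (per >= pd.Timestamp(window[0]))
            & (per <= pd.Timestamp(window[1]))
        ].copy()
        dd["ecotype"] = dd["tag_id"].map(meta["ecotype"])
        dd["is_ns"] = (dd["ecotype"] == "NS").astype(float)
        dd["time_days"] = (
            pd.to_datetime(dd["date"]) - pd.Timestamp(window[0])
        ).dt.total_seconds() / 86400.0
        dd = dd[dd["distance_km"] > 0]
        if dd["tag_id"].nunique() >= 2 and dd["is_ns"].nunique() > 1:
            glmm = GammaRandomInterceptModel.from_dataframe(
                dd,
                response="distance_km",
                terms=["is_ns", "time_days", "is_ns:time_days"],
                group="tag_id",
            ).fit()
            fits["distance_glmm"] = glmm
        if fits:
            model_table(fits).to_csv(out / "model_tables.csv", index=False)
        return fits

    stage("models")(_models)
    outputs["model_tables"] = out / "model_tables.csv"

    # -- run log -------------------------------------------------------------
    run_log = {
        "started_utc": t_start.isoformat(),
        "finished_utc": dt.datetime.now(dt.timezone.utc).isoformat(),
        "fjordtrace_version": __version__,
        "seed": config.seed,
        "window": [str(window[0]), str(window[1])],
        "n_fish": int(len(fish)),
        "n_detections": int(len(detections)),
        "simulated": config.simulation is not None,
    }
    (out / "run.log").write_text(json.dumps(run_log, indent=2, default=str) + "\n")
    outputs["run_log"] = out / "run.log"
    return outputs
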