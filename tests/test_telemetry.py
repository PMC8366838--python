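import datetime as dt

import numpy as np
import pandas as pd
import pytest

from fjordtrace.fjord import build_default_geometry
from fjordtrace.telemetry import (
    classify_fate,
    daily_positions,
    distance_to_outlet,
    gate_consistency,
    position_average,
    position_averages,
    select_array_cohort,
    FateRecord,
)

from conftest import make_detections

STUDY_END = dt.datetime(2018, 6, 1, tzinfo=dt.timezone.utc)


class TestPositionAverage:
    def test_count_weighted_mean(self, toy_receivers):
        rec = toy_receivers.copy()
        rec.loc[0, ["easting", "northing"]] = (480000.0, 6490000.0)
        rec.loc[1, ["easting", "northing"]] = (480100.0, 6490000.0)
        det = make_detections(
            [("2017-05-01 10:01", "OT1", "F1")] * 3
            + [("2017-05-01 10:21", "ST1", "F1")]
        )
        res = position_average(det, rec)
        assert res["easting"] == pytest.approx(480025.0)
        assert res["northing"] == pytest.approx(6490000.0)
        assert res["n_detections"] == 4
        assert res["period_start"] == pd.Timestamp("2017-05-01 10:00")

    def test_single_receiver_returns_its_coordinates(self, toy_receivers):
        det = make_detections([("2017-05-01 10:05", "AR1", "F1")] * 7)
        res = position_average(det, toy_receivers)
        assert (res["easting"], res["northing"]) == (484000.0, 6490000.0)

    def test_equal_counts_give_midpoint(self, toy_receivers):
        det = make_detections(
            [("2017-05-01 10:05", "IT1", "F1")] * 2
            + [("2017-05-01 10:25", "AR1", "F1")] * 2
        )
        res = position_average(det, toy_receivers)
        assert res["easting"] == pytest.approx((482500.0 + 484000.0) / 2)

    def test_empty_input_yields_no_record(self, toy_receivers):
        assert position_average(make_detections([]), toy_receivers) is None

    def test_mixed_periods_rejected(self, toy_receivers):
        det = make_detections(
            [("2017-05-01 10:05", "AR1", "F1"), ("2017-05-01 10:35", "AR1", "F1")]
        )
        with pytest.raises(ValueError):
            position_average(det, toy_receivers)

    def test_result_is_convex_combination(self, toy_receivers):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(1, 30))
            recs = rng.choice(toy_receivers["receiver_id"], size=n)
            det = make_detections(
                [("2017-05-01 10:05", r, "F1") for r in recs]
            )
            res = position_average(det, toy_receivers)
            used = toy_receivers[toy_receivers["receiver_id"].isin(set(recs))]
            assert used["easting"].min() - 1e-9 <= res["easting"]
            assert res["easting"] <= used["easting"].max() + 1e-9

    def test_detection_order_is_irrelevant(self, toy_receivers):
        rows = (
            [("2017-05-01 10:01", "OT1", "F1")] * 2
            + [("2017-05-01 10:11", "IT1", "F1")] * 3
            + [("2017-05-01 10:21", "AR1", "F1")]
        )
        a = position_average(make_detections(rows), toy_receivers)
        b = position_average(make_detections(rows[::-1]), toy_receivers)
        assert a == b

    def test_batch_matches_single_period_operation(self, toy_receivers):
        rows = (
            [("2017-05-01 10:01", "OT1", "F1")] * 3
            + [("2017-05-01 10:31", "IT1", "F1")] * 2
            + [("2017-05-01 10:40", "AR1", "F2")]
        )
        batch = position_averages(make_detections(rows), toy_receivers)
        assert len(batch) == 3
        one = position_average(make_detections(rows[:3]), toy_receivers)
        got = batch[
            (batch["tag_id"] == "F1")
            & (batch["period_start"] == pd.Timestamp("2017-05-01 10:00"))
        ].iloc[0]
        assert got["easting"] == one["easting"]
        assert got["n_detections"] == one["n_detections"]


class TestDailyPositions:
    def test_single_average_passes_through(self):
        pa = pd.DataFrame(
            {
                "tag_id": ["F1"],
                "period_start": pd.to_datetime(["2017-05-01 10:00"]),
                "easting": [1.0],
                "northing": [2.0],
                "distance_km": [2.0],
            }
        )
        out = daily_positions(pa)
        assert len(out) == 1
        assert out.loc[0, "distance_km"] == 2.0

    def test_two_averages_give_arithmetic_mean(self):
        pa = pd.DataFrame(
            {
                "tag_id": ["F1", "F1"],
                "period_start": pd.to_datetime(
                    ["2017-05-01 10:00", "2017-05-01 22:30"]
                ),
                "easting": [0.0, 10.0],
                "northing": [0.0, 0.0],
                "distance_km": [2.0, 4.0],
            }
        )
        out = daily_positions(pa)
        assert len(out) == 1
        assert out.loc[0, "distance_km"] == pytest.approx(3.0)
        assert out.loc[0, "easting"] == pytest.approx(5.0)


class TestDistanceToOutlet:
    def test_axis_endpoints(self, geometry):
        head, outlet = geometry.axis[0], geometry.axis[-1]
        assert distance_to_outlet(outlet, geometry) == pytest.approx(0.0)
        assert distance_to_outlet(head, geometry) == pytest.approx(9.0)

    def test_lateral_offset_ignored(self, geometry):
        p = geometry.axis[-1] + np.array([1000.0, 100.0])
        assert distance_to_outlet(p, geometry) == pytest.approx(1.0)


def _fate(rows, toy_receivers, **kw):
    return classify_fate(make_detections(rows), toy_receivers, STUDY_END, **kw)


class TestClassifyFate:
    def test_last_outer_detection_is_permanent_departure(self, toy_receivers):
        rec = _fate(
            [
                ("2017-01-01 10:00", "AR1", "F1"),
                ("2017-02-01 09:00", "ST1", "F1"),
                ("2017-02-01 10:00", "OT1", "F1"),
            ],
            toy_receivers,
        )
        assert rec.status == "departed_permanent"
        assert rec.departure_time == pd.Timestamp("2017-02-01 10:00", tz="UTC")

    def test_redetection_within_six_hours_is_an_excursion(self, toy_receivers):
        rec = _fate(
            [
                ("2017-02-01 10:00", "OT1", "F1"),
                ("2017-02-01 16:00", "OT1", "F1"),
                ("2017-02-01 17:00", "AR1", "F1"),
                ("2018-05-30 10:00", "AR1", "F1"),
            ],
            toy_receivers,
        )
        assert rec.status == "short_excursion"
        assert rec.n_excursions == 1

    def test_december_exit_april_return_is_prolonged(self, toy_receivers):
        rec = _fate(
            [
                ("2016-12-10 10:00", "ST1", "F1"),
                ("2016-12-10 11:00", "OT1", "F1"),
                ("2017-04-15 08:00", "OT1", "F1"),
                ("2017-04-15 09:00", "ST1", "F1"),
                ("2018-05-30 10:00", "AR1", "F1"),
            ],
            toy_receivers,
        )
        assert rec.status == "departed_returned"
        assert rec.departure_time == pd.Timestamp("2016-12-10 11:00", tz="UTC")
        assert rec.return_time == pd.Timestamp("2017-04-15 08:00", tz="UTC")
        assert rec.return_time - rec.departure_time >= pd.Timedelta(hours=48)

    def test_silence_away_from_the_gate_is_lost(self, toy_receivers):
        rec = _fate(
            [
                ("2017-01-01 10:00", "AR1", "F1"),
                ("2017-03-01 10:00", "IT1", "F1"),
            ],
            toy_receivers,
        )
        assert rec.status == "lost"

    def test_detected_until_study_end_is_resident(self, toy_receivers):
        rec = _fate(
            [
                ("2017-01-01 10:00", "AR1", "F1"),
                ("2018-05-30 10:00", "AR1", "F1"),
            ],
            toy_receivers,
        )
        assert rec.status == "resident"

    def test_gate_dwelling_fish_is_not_an_emigrant(self, toy_receivers):
        """Minute-scale gaps between outer-transect pings are residence,
        not exits."""
        rows = [
            (f"2018-05-30 {h:02d}:{m:02d}", "OT1", "F1")
            for h in range(10, 14)
            for m in (0, 30)
        ]
        rows.append(("2018-05-30 15:00", "AR1", "F1"))
        rows.append(("2018-05-31 23:00", "AR1", "F1"))
        rec = _fate(rows, toy_receivers)
        assert rec.status == "resident"
        assert rec.n_excursions == 0

    def test_empty_or_multi_tag_input_rejected(self, toy_receivers):
        with pytest.raises(ValueError):
            _fate([], toy_receivers)
        with pytest.raises(ValueError):
            _fate(
                [
                    ("2017-01-01 10:00", "AR1", "F1"),
                    ("2017-01-01 10:01", "AR1", "F2"),
                ],
                toy_receivers,
            )


class TestGateConsistency:
    def test_compliant_passage_has_no_violations(self, toy_receivers):
        det = make_detections(
            [
                ("2017-01-01 10:00", "AR1", "F1"),
                ("2017-02-01 09:00", "ST1", "F1"),
                ("2017-02-01 10:00", "OT1", "F1"),
            ]
        )
        assert len(gate_consistency(det, toy_receivers)) == 0

    def test_outer_without_prior_secondary_is_flagged(self, toy_receivers):
        det = make_detections(
            [
                ("2017-01-01 10:00", "AR1", "F1"),
                ("2017-02-01 10:00", "OT1", "F1"),
            ]
        )
        qc = gate_consistency(det, toy_receivers)
        assert len(qc) == 1
        assert qc.loc[0, "kind"] == "outer_without_prior_secondary"

    def test_simulated_passages_are_consistent(self, short_config):
        from fjordtrace.simulate import simulate_study

        cfg = short_config.with_(n_fish=40, seed=13,
                                 emigration_prob={"NS": 0.5, "FJ": 0.5})
        g = build_default_geometry(cfg.seed, cfg)
        fish, det = simulate_study(g, cfg)
        qc = gate_consistency(det, g.receivers_frame())
        # departing fish pass the secondary gate before the outer gate
        assert len(qc) == 0


class TestCohortSelection:
    def test_early_permanent_departure_excluded(self):
        fates = [
            FateRecord("F1", "departed_permanent",
                       departure_time=pd.Timestamp("2016-12-10", tz="UTC")),
            FateRecord("F2", "resident"),
        ]
        pa = pd.DataFrame(
            {
                "tag_id": ["F1", "F2"],
                "period_start": pd.to_datetime(
                    ["2016-12-01 10:00", "2017-10-15 10:00"]
                ),
                "easting": [0.0, 0.0],
                "northing": [0.0, 0.0],
            }
        )
        cohort = select_array_cohort(fates, pa)
        assert cohort == {"F2"}

    def test_simulated_presence_recovered_exactly(self, short_config):
        from fjordtrace.simulate import simulate_study
        from fjordtrace.telemetry import classify_all_fates, position_averages

        cfg = short_config.with_(n_fish=25, seed=21)
        g = build_default_geometry(cfg.seed, cfg)
        fish, det = simulate_study(g, cfg)
        rec = g.receivers_frame()
        pos = position_averages(det, rec)
        fates = classify_all_fates(det, rec, cfg.study_end,
                                   all_tags=[f.tag_id for f in fish])
        window = (cfg.study_start, cfg.study_end)
        cohort = select_array_cohort(fates, pos, window)
        # truth: every fish that was present (detected) inside the window
        expected = {
            f.tag_id
            for f in fish
            if not (f.emigrates and f.departure_time <= cfg.study_start)
        } & set(det["tag_id"].unique())
        assert cohort == expected
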