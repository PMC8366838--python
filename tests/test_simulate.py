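import datetime as dt

import numpy as np
import pytest

from fjordtrace.config import SimulationConfig
from fjordtrace.fjord import (
    HALF_WIDTH_M,
    ORIGIN_EASTING,
    ORIGIN_NORTHING,
    FjordGeometry,
    ReceiverDeployment,
    build_default_geometry,
)
from fjordtrace.simulate import (
    GELA_D13C,
    GELA_D15N,
    detection_probability,
    simulate_detections,
    simulate_fish,
    simulate_genotypes,
    simulate_isotopes,
    simulate_study,
    simulate_tracks,
)

UTC = dt.timezone.utc


class TestGeometry:
    def test_default_layout_counts_and_length(self):
        g = build_default_geometry(1)
        assert len(g.receivers) == 52
        assert g.length_km == pytest.approx(9.0)
        roles = [r.role for r in g.receivers]
        assert roles.count("outer_transect") == 2
        assert roles.count("secondary_transect") == 2
        assert roles.count("internal_transect") == 6
        assert roles.count("array") == 42

    def test_every_receiver_on_the_axis_span(self):
        g = build_default_geometry(5)
        d = g.distance_to_outlet_km(g.receiver_coords)
        assert np.all((d >= 0.0) & (d <= 9.0))

    def test_layout_is_seed_independent(self):
        a = build_default_geometry(1).receivers_frame()
        b = build_default_geometry(2).receivers_frame()
        assert a.equals(b)

    def test_gate_transects_500m_apart(self):
        g = build_default_geometry(0)
        outer = np.mean(
            [r.easting for r in g.receivers if r.role == "outer_transect"]
        )
        secondary = np.mean(
            [r.easting for r in g.receivers if r.role == "secondary_transect"]
        )
        assert abs(secondary - outer) == pytest.approx(500.0)


class TestTracks:
    def test_zero_movement_scale_pins_fish_to_home(self, short_config):
        cfg = short_config.with_(home_sd_median_m=0.0, excursion_prob=0.0,
                                 emigration_prob={"NS": 0.0, "FJ": 0.0})
        g = build_default_geometry(cfg.seed, cfg)
        fish = simulate_fish(g, cfg)
        tracks = simulate_tracks(g, cfg, fish)
        for f, tr in zip(fish, tracks):
            assert np.allclose(tr.xy[:, 0], f.home_center[0])
            assert np.allclose(tr.xy[:, 1], f.home_center[1])

    def test_same_seed_gives_identical_trajectories(self, short_config):
        g = build_default_geometry(short_config.seed, short_config)
        t1 = simulate_tracks(g, short_config)
        t2 = simulate_tracks(g, short_config)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.xy, b.xy, equal_nan=True)

    def test_rejects_nonpositive_cohort(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_fish=0)

    def test_emigrant_fraction_matches_config(self):
        """Bernoulli fates at n=10,000 land within 3 SE of 0.42 / 0.07."""
        cfg = SimulationConfig(n_fish=10_000, seed=1, p_northsea=0.43)
        g = build_default_geometry(cfg.seed, cfg)
        fish = simulate_fish(g, cfg)
        for eco, p in (("NS", 0.42), ("FJ", 0.07)):
            sub = [f for f in fish if f.ecotype == eco]
            frac = np.mean([f.emigrates for f in sub])
            se = np.sqrt(p * (1 - p) / len(sub))
            assert abs(frac - p) <= 3 * se

    def test_tracks_stay_inside_the_fjord(self, short_config):
        g = build_default_geometry(short_config.seed, short_config)
        for tr in simulate_tracks(g, short_config):
            xy = tr.xy[~np.isnan(tr.xy[:, 0])]
            u = xy[:, 0] - ORIGIN_EASTING
            lat = xy[:, 1] - ORIGIN_NORTHING
            assert np.all((u >= -100.0) & (u <= 9_050.0))
            assert np.all(np.abs(lat) <= HALF_WIDTH_M)


class TestDetections:
    def test_probability_monotone_and_truncated(self, short_config):
        d = np.linspace(0.0, 200.0, 101)
        p = detection_probability(d, short_config)
        assert np.all(np.diff(p) <= 0)
        assert p[0] > 0.5
        assert detection_probability(np.array([0.0]), short_config)[0] > 0.99
        assert np.all(detection_probability(np.array([131.0, 10_000.0]), short_config) == 0)
        # logistic scale keeps the decay below 1% already at max range
        at_max = 1.0 / (1.0 + np.exp(
            (short_config.max_detect_range_m - short_config.detect_halfrange_m)
            / short_config.detect_scale_m
        ))
        assert at_max < 0.01

    def test_far_fish_yields_no_detections(self, short_config):
        """A fish ~8 km from every receiver is never logged."""
        full = (short_config.study_start, short_config.study_end)
        receivers = tuple(
            ReceiverDeployment(f"R{i}", ORIGIN_EASTING + 200.0,
                               ORIGIN_NORTHING + s * 90.0, role, *full)
            for i, (s, role) in enumerate(
                [(-1, "outer_transect"), (1, "secondary_transect")]
            )
        )
        axis = np.array(
            [[ORIGIN_EASTING + 9000.0, ORIGIN_NORTHING], [ORIGIN_EASTING, ORIGIN_NORTHING]]
        )
        g = FjordGeometry(axis=axis, receivers=receivers)
        cfg = short_config.with_(n_fish=3, home_sd_median_m=10.0,
                                 emigration_prob={"NS": 0.0, "FJ": 0.0},
                                 excursion_prob=0.0)
        fish = simulate_fish(build_default_geometry(cfg.seed, cfg), cfg)
        far = [
            type(f)(**{**f.__dict__,
                       "home_center": (ORIGIN_EASTING + 8_500.0, ORIGIN_NORTHING)})
            for f in fish
        ]
        det = simulate_detections(simulate_tracks(g, cfg, far), g, cfg)
        assert len(det) == 0

    def test_transmission_rate_near_one_per_minute(self, short_config):
        """30–90 s uniform gaps average 60 s; a fish parked on a receiver
        logs close to 60 detections per hour."""
        cfg = short_config.with_(n_fish=5, home_sd_median_m=0.0,
                                 excursion_prob=0.0,
                                 emigration_prob={"NS": 0.0, "FJ": 0.0},
                                 study_end=short_config.study_start + dt.timedelta(hours=10))
        g = build_default_geometry(cfg.seed, cfg)
        fish = simulate_fish(g, cfg)
        # park each fish exactly on its nearest receiver
        coords = g.receiver_coords
        parked = []
        for f in fish:
            j = np.argmin(np.hypot(coords[:, 0] - f.home_center[0],
                                   coords[:, 1] - f.home_center[1]))
            parked.append(
                type(f)(**{**f.__dict__, "home_center": tuple(coords[j])})
            )
        det = simulate_detections(simulate_tracks(g, cfg, parked), g, cfg)
        per_fish_hour = det.groupby("tag_id", observed=True).size() / 10.0
        # nearest receiver co-located: p(0) ≈ 0.99, so ≈ 59/h ± gap noise
        assert np.all(per_fish_hour.to_numpy() > 45)
        assert np.all(per_fish_hour.to_numpy() < 75)

    def test_detection_counts_decay_with_distance(self, short_config):
        counts = []
        cfg = short_config.with_(n_fish=1, home_sd_median_m=0.0,
                                 excursion_prob=0.0,
                                 emigration_prob={"NS": 0.0, "FJ": 0.0},
                                 study_end=short_config.study_start + dt.timedelta(hours=20))
        g = build_default_geometry(cfg.seed, cfg)
        base = simulate_fish(g, cfg)[0]
        j = np.argmin(np.hypot(
            g.receiver_coords[:, 0] - base.home_center[0],
            g.receiver_coords[:, 1] - base.home_center[1]))
        anchor = g.receiver_coords[j]
        anchor_id = g.receivers[j].receiver_id
        for offset in (0.0, 40.0, 65.0, 90.0, 120.0):
            f = type(base)(**{**base.__dict__,
                              "home_center": (anchor[0], anchor[1] + offset)})
            det = simulate_detections(simulate_tracks(g, cfg, [f]), g, cfg)
            at_anchor = int((det["receiver_id"] == anchor_id).sum())
            counts.append(at_anchor)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_study_stream_equals_tracks_then_detections(self, short_config):
        cfg = short_config.with_(n_fish=6)
        g = build_default_geometry(cfg.seed, cfg)
        fish, det_stream = simulate_study(g, cfg)
        det_two_step = simulate_detections(
            simulate_tracks(g, cfg, fish), g, cfg
        )
        assert det_stream.equals(det_two_step)


class TestGenotypes:
    def test_rejects_bad_differential(self):
        with pytest.raises(ValueError):
            SimulationConfig(allele_freq_differential=1.5)

    def test_reference_frequencies_separated_by_differential(self):
        cfg = SimulationConfig(n_fish=10, seed=9, n_loci=40,
                               allele_freq_differential=0.4,
                               ref_sample_size=20_000)
        panel, _, _, _ = simulate_genotypes(cfg)
        diffs = []
        for li in range(len(panel.loci)):
            freq = {}
            for pop in panel.populations:
                c = panel.counts[pop][li]
                tot = sum(c.values())
                freq[pop] = c.get("02", 0) / tot
            diffs.append(abs(freq["FJ"] - freq["NS"]))
        se = np.sqrt(0.25 / 20_000)  # generous binomial bound per pop
        assert np.mean(diffs) == pytest.approx(0.4, abs=6 * se)

    def test_true_origin_splits_follow_p_northsea(self):
        cfg = SimulationConfig(n_fish=8_000, seed=2, p_northsea=0.43, n_loci=2)
        _, _, _, origins = simulate_genotypes(cfg)
        frac = np.mean([o == "NS" for o in origins])
        assert abs(frac - 0.43) <= 3 * np.sqrt(0.43 * 0.57 / 8_000)

    def test_missingness_rate(self):
        cfg = SimulationConfig(n_fish=2_000, seed=3, missing_rate=0.1)
        _, _, study, _ = simulate_genotypes(cfg)
        miss = np.mean([c is None for g in study for c in g.calls])
        assert miss == pytest.approx(0.1, abs=0.01)


class TestIsotopes:
    def _fish(self, cfg):
        g = build_default_geometry(cfg.seed, cfg)
        fish = simulate_fish(g, cfg)
        dist = {f.tag_id: float((f.home_center[0] - ORIGIN_EASTING) / 1000.0)
                for f in fish}
        return fish, dist

    def test_noiseless_standards_hit_known_values(self, short_config):
        cfg = short_config.with_(drift_per_run=0.0, isotope_sd=0.0,
                                 sheet_offset_sd=0.0)
        fish, dist = self._fish(cfg)
        sheet, _ = simulate_isotopes(fish, dist, cfg)
        std = sheet[sheet["is_standard"]]
        assert np.allclose(std["d15N_raw"], GELA_D15N)
        assert np.allclose(std["d13C_raw"], GELA_D13C)

    def test_noiseless_duplicates_identical(self, short_config):
        cfg = short_config.with_(drift_per_run=0.0, isotope_sd=0.0,
                                 sheet_offset_sd=0.0)
        fish, dist = self._fish(cfg)
        sheet, truth = simulate_isotopes(fish, dist, cfg)
        samples = sheet[~sheet["is_standard"]]
        spread = samples.groupby("sample_id")[["d15N_raw", "d13C_raw"]].agg(
            lambda s: s.max() - s.min()
        )
        assert np.allclose(spread.to_numpy(), 0.0)

    def test_standard_cadence_two_or_three_per_ten_samples(self, short_config):
        fish, dist = self._fish(short_config)
        sheet, _ = simulate_isotopes(fish, dist, short_config)
        flags = sheet.sort_values("run_number")["is_standard"].to_numpy()
        sample_pos = np.nonzero(~flags)[0]
        # within any window of 10 consecutive samples, 2-3 standards appear
        for s in range(0, len(sample_pos) - 10, 10):
            lo, hi = sample_pos[s], sample_pos[s + 10]
            n_std = int(flags[lo:hi].sum())
            assert 2 <= n_std <= 3

    def test_run_numbers_strictly_increase(self, short_config):
        fish, dist = self._fish(short_config)
        sheet, _ = simulate_isotopes(fish, dist, short_config)
        assert (np.diff(sheet["run_number"].to_numpy()) > 0).all()

    def test_missing_distance_raises(self, short_config):
        fish, dist = self._fish(short_config)
        dist.pop(fish[0].tag_id)
        with pytest.raises(KeyError):
            simulate_isotopes(fish, dist, short_config)


def test_full_study_determinism(short_config):
    cfg = short_config.with_(n_fish=8)
    g = build_default_geometry(cfg.seed, cfg)
    f1, d1 = simulate_study(g, cfg)
    f2, d2 = simulate_study(g, cfg)
    assert d1.equals(d2)
    assert [x.home_center for x in f1] == [x.home_center for x in f2]
    p1, r1, s1, o1 = simulate_genotypes(cfg)
    p2, r2, s2, o2 = simulate_genotypes(cfg)
    assert p1.counts == p2.counts and s1 == s2 and o1 == o2
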