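"""Hourly singer metrics, states and covariates."""

from datetime import date

import numpy as np
import pytest

from songtrack.geo import GeoPoint, LocalXY, destination_point, haversine_km, to_geo
from songtrack.localization import LocalizedTrack, smooth
from songtrack.movement import (
    HourlySingerRecord,
    build_covariates,
    classify_state,
    day_of_season,
    epoch_speeds_kmh,
    hourly_mean_position,
    hourly_singer_table,
    nearest_neighbour,
    radius_filter,
    reference_distance,
    subsample_first_half_hour,
)
from songtrack.synthetic_data import DASAR_Y


def _track(xy_km, epochs=None, origin=DASAR_Y, track_id="t"):
    pts = [to_geo(LocalXY(x, y, origin)) for x, y in xy_km]
    eps = np.arange(len(pts)) * 60.0 if epochs is None else np.asarray(epochs, float)
    return LocalizedTrack(
        track_id=track_id,
        epochs=eps,
        lats=np.array([p.lat for p in pts]),
        lons=np.array([p.lon for p in pts]),
    )


class TestSubsample:
    def test_minute_rule(self):
        t = _track([[0, 0]] * 3, epochs=[10 * 60, 29 * 60, 31 * 60])
        np.testing.assert_array_equal(subsample_first_half_hour(t), [True, True, False])

    def test_late_half_hour_contributes_nothing(self):
        t = _track([[0, 0]] * 5, epochs=[(31 + i) * 60 for i in range(5)])
        assert not subsample_first_half_hour(t).any()

    def test_uniform_track_retains_half(self):
        t = _track([[0, 0]] * 120, epochs=np.arange(120) * 60.0)
        assert subsample_first_half_hour(t).mean() == pytest.approx(0.5)


class TestHourlyMeanPosition:
    def test_symmetric_pair_gives_midpoint(self):
        t = _track([[-1.0, 0.0], [1.0, 0.0]])
        [(h, pos, n)] = hourly_mean_position(t)
        assert n == 2
        assert haversine_km(pos, DASAR_Y) * 1000 < 1.5

    def test_single_point_is_itself(self):
        t = _track([[0.5, 0.5]])
        [(h, pos, n)] = hourly_mean_position(t)
        assert haversine_km(pos, to_geo(LocalXY(0.5, 0.5, DASAR_Y))) * 1000 < 0.01

    def test_noisy_stationary_mean_close_to_truth(self):
        rng = np.random.default_rng(20)
        sigma = 0.15
        xy = rng.normal(0, sigma, (30, 2))
        t = _track(xy)
        [(h, pos, n)] = hourly_mean_position(t)
        se = sigma / np.sqrt(30)
        assert haversine_km(pos, DASAR_Y) < 3 * se * np.sqrt(2) + 0.01


class TestClassifyState:
    def _uniform_track(self, step_km, n=61):
        return _track([[i * step_km, 0.0] for i in range(n)])

    def test_50m_per_minute_is_travelling(self):
        states = classify_state(self._uniform_track(0.050))
        assert set(states.values()) == {"travelling"}  # 3.0 km/h

    def test_30m_per_minute_is_stationary(self):
        states = classify_state(self._uniform_track(0.030))
        assert set(states.values()) == {"stationary"}  # 1.8 km/h

    def test_exactly_2kmh_is_stationary(self):
        # 2.0 km/h does not strictly exceed the threshold
        states = classify_state(self._uniform_track(2.0 / 60))
        assert set(states.values()) == {"stationary"}

    def test_half_half_mix_is_both(self):
        xy = [[0.0, 0.0]]
        x = 0.0
        for i in range(60):
            x += 0.050 if i % 2 else 0.010
            xy.append([x, 0.0])
        states = classify_state(_track(xy), baseline=1)
        assert set(states.values()) == {"both"}

    def test_min_epochs_floor(self):
        assert classify_state(self._uniform_track(0.05, n=4), baseline=1) == {}

    def test_baseline_invariant_for_uniform_motion(self):
        t = self._uniform_track(0.050)
        assert classify_state(t, baseline=1) == classify_state(t, baseline=10)


class TestScriptedStateRecovery:
    def test_80_percent_travel_hour_recovered_across_seeds(self):
        """An hour scripted 80% travelling classifies as travelling in
        nearly all seeds, despite realistic position noise."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            # 48 min travel at 3.5 km/h then drift, plus 150 m position noise
            xy = []
            x = 0.0
            for i in range(61):
                xy.append([x, 0.0])
                x += (3.5 / 60.0) if i < 48 else 0.005
            noisy = np.asarray(xy) + rng.normal(0, 0.15, (61, 2))
            t = smooth(_track(noisy.tolist()))
            states = classify_state(t, baseline=10)
            hits += states.get(0.0) == "travelling"
        assert hits >= 0.95 * n_seeds


class TestNearestNeighbour:
    def test_two_singers_symmetric(self):
        p = {"a": DASAR_Y, "b": destination_point(DASAR_Y, 90.0, 1.0)}
        d = nearest_neighbour(p)
        assert d["a"] == pytest.approx(1.0, abs=1e-6)
        assert d["b"] == pytest.approx(1.0, abs=1e-6)

    def test_three_collinear(self):
        p = {
            "a": DASAR_Y,
            "b": destination_point(DASAR_Y, 90.0, 1.0),
            "c": destination_point(DASAR_Y, 90.0, 3.0),
        }
        d = nearest_neighbour(p)
        assert d["a"] == pytest.approx(1.0, abs=1e-6)
        assert d["b"] == pytest.approx(1.0, abs=1e-6)
        assert d["c"] == pytest.approx(2.0, abs=1e-6)

    def test_alone_is_missing(self):
        assert nearest_neighbour({"a": DASAR_Y})["a"] is None

    def test_matches_brute_force(self):
        rng = np.random.default_rng(21)
        pts = {
            f"s{i}": to_geo(LocalXY(x, y, DASAR_Y))
            for i, (x, y) in enumerate(rng.uniform(-4, 4, (8, 2)))
        }
        d = nearest_neighbour(pts)
        for i in pts:
            brute = min(haversine_km(pts[i], pts[j]) for j in pts if j != i)
            assert d[i] == pytest.approx(brute)
            assert all(
                d[i] <= haversine_km(pts[i], pts[j]) + 1e-12 for j in pts if j != i
            )


class TestReferenceDistance:
    def test_stationary_singer(self):
        t = _track([[2.0, 0.0]] * 10)
        d = reference_distance(t, DASAR_Y)
        assert d[0.0] == pytest.approx(2.0, abs=0.01)

    def test_linear_approach_median(self):
        xs = np.linspace(1.0, 3.0, 31)
        t = _track([[x, 0.0] for x in xs])
        d = reference_distance(t, DASAR_Y)
        assert d[0.0] == pytest.approx(2.0, abs=0.02)


class TestRadiusFilter:
    def _rec(self, dist_km):
        return HourlySingerRecord(
            track_id="t",
            date=date(2020, 4, 5),
            hour=3,
            mean_position=destination_point(DASAR_Y, 228.0, dist_km),
        )

    def test_boundary(self):
        kept = radius_filter([self._rec(5.9), self._rec(6.1)], DASAR_Y)
        assert len(kept) == 1

    def test_all_offshore_empty(self):
        assert radius_filter([self._rec(8.0), self._rec(12.0)], DASAR_Y) == []

    def test_count_matches_brute_force(self):
        rng = np.random.default_rng(22)
        dists = rng.uniform(0, 12, 50)
        recs = [self._rec(d) for d in dists]
        kept = radius_filter(recs, DASAR_Y)
        assert len(kept) == int((dists <= 6.0 + 1e-9).sum())


class TestCovariates:
    def _rec(self, d, hour=5, state="stationary"):
        return HourlySingerRecord(
            track_id="t", date=d, hour=hour, mean_position=DASAR_Y, state=state
        )

    @pytest.mark.parametrize(
        "d,expected",
        [
            (date(2019, 12, 1), 1),
            (date(2019, 12, 15), 15),
            (date(2020, 2, 1), 63),  # 31 (Dec) + 31 (Jan) + 1
            (date(2020, 4, 30), 152),
        ],
    )
    def test_day_of_season(self, d, expected):
        assert day_of_season(d) == expected

    def test_columns_and_one_hot(self):
        df = build_covariates(
            [
                self._rec(date(2019, 12, 1), state="stationary"),
                self._rec(date(2020, 2, 10), state="travelling"),
                self._rec(date(2020, 4, 5), state="both"),
            ]
        )
        assert list(df["day_season"]) == [1, 72, 127]
        assert list(df["time_season"]) == ["early", "peak", "late"]
        assert list(df["year"]) == [2020, 2020, 2020]
        onehot = df[["state_stationary", "state_travelling", "state_both"]].to_numpy()
        np.testing.assert_array_equal(onehot.sum(axis=1), [1, 1, 1])

    def test_out_of_season_flagged(self):
        df = build_covariates([self._rec(date(2020, 7, 1))])
        assert not df["in_season"].iloc[0]

    def test_stateless_record_has_na_binaries(self):
        df = build_covariates([self._rec(date(2020, 2, 1), state=None)])
        assert df["state_stationary"].isna().all()


class TestHourlySingerTable:
    def test_states_partition_and_dnn(self, slope_bathy):
        rng = np.random.default_rng(23)
        from songtrack.synthetic_data import shore_frame

        origin, along, offshore = shore_frame()
        tracks = []
        for i, d0 in enumerate((1.5, 3.0)):
            base = offshore * d0 - offshore * 0.5
            xy = [base + along * (0.01 * rng.normal()) for _ in range(120)]
            t = _track([list(p) for p in xy], origin=origin, track_id=f"w{i}")
            tracks.append(smooth(t))
        recs = hourly_singer_table(tracks, DASAR_Y, bathy=slope_bathy, radius_km=6.0)
        by_hour = {}
        for r in recs:
            assert r.state in (None, "stationary", "travelling", "both")
            assert r.d_shore_km is not None and r.d_shore_km >= 0
            by_hour.setdefault((r.date, r.hour), []).append(r)
        for key, rs in by_hour.items():
            if len(rs) >= 2:
                for r in rs:
                    assert r.d_nn_km is not None and r.d_nn_km > 0
        # d_shore close to construction (1.5 and 3.0 km)
        d_by_track = {}
        for r in recs:
            d_by_track.setdefault(r.track_id, []).append(r.d_shore_km)
        assert np.mean(d_by_track["w0"]) == pytest.approx(1.5, abs=0.3)
        assert np.mean(d_by_track["w1"]) == pytest.approx(3.0, abs=0.3)
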