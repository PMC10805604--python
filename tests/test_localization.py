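"""Track matching, triangulation and track post-processing."""

import math
from dataclasses import replace

import numpy as np
import pytest

from songtrack.geo import GeoPoint, LocalXY, destination_point, haversine_km, initial_bearing_deg, to_geo
from songtrack.localization import (
    AzimuthalTrack,
    LocalizedTrack,
    TriangulationError,
    localize_triplet,
    match_tracks,
    merge_split_tracks,
    pair_score,
    qc_positions,
    remove_outliers,
    smooth,
    triangulate,
)
from songtrack.synthetic_data import DASAR_X, DASAR_Y, DASAR_Z


def grid_search_triangulate(bearings, center, half_km=0.3, cell_km=0.01):
    """Brute-force least-squares position on a 10-m grid around ``center``."""
    origin = bearings[0][0]
    from songtrack.geo import to_local

    c = to_local(center, origin)
    xs = np.arange(c.x - half_km, c.x + half_km + cell_km / 2, cell_km)
    ys = np.arange(c.y - half_km, c.y + half_km + cell_km / 2, cell_km)
    X, Y = np.meshgrid(xs, ys)
    cost = np.zeros_like(X)
    for sensor, az in bearings:
        q = to_local(sensor, origin)
        pred = np.degrees(np.arctan2(X - q.x, Y - q.y)) % 360.0
        d = (az - pred + 180.0) % 360.0 - 180.0
        cost += np.radians(d) ** 2
    k = np.unravel_index(np.argmin(cost), cost.shape)
    return to_geo(LocalXY(float(X[k]), float(Y[k]), origin))


def bearings_to(target, noise_deg=0.0, rng=None):
    out = []
    for s in (DASAR_X, DASAR_Y, DASAR_Z):
        az = initial_bearing_deg(s, target)
        if noise_deg and rng is not None:
            az += rng.normal(0, noise_deg)
        out.append((s, az % 360.0))
    return out


class TestTriangulate:
    def test_exact_recovery(self):
        target = destination_point(DASAR_Y, 250.0, 2.5)
        est, rms = triangulate(bearings_to(target))
        assert haversine_km(est, target) * 1000 < 5.0
        assert rms < 0.01

    def test_parallel_bearings_flagged(self):
        brs = [(DASAR_X, 90.0), (DASAR_Y, 90.0), (DASAR_Z, 90.0)]
        with pytest.raises(TriangulationError):
            triangulate(brs)

    def test_grid_search_oracle_and_rmse(self):
        # targets in the broadside sector (endfire geometry is degenerate
        # by design and flagged, not solved)
        rng = np.random.default_rng(10)
        errs, offsets = [], []
        for _ in range(100):
            target = destination_point(
                DASAR_Y, rng.uniform(170, 290), rng.uniform(1.0, 4.0)
            )
            brs = bearings_to(target, noise_deg=2.0, rng=rng)
            est, _ = triangulate(brs)
            oracle = grid_search_triangulate(brs, est)
            offsets.append(haversine_km(est, oracle) * 1000)
            errs.append(haversine_km(est, target) * 1000)
        assert np.sqrt(np.mean(np.array(errs) ** 2)) < 250.0
        # GN solution sits within one 10-m grid cell of the brute-force argmin
        assert max(offsets) <= 10.0 * math.sqrt(2) + 1e-6

    def test_two_bearing_minimum(self):
        target = destination_point(DASAR_Y, 260.0, 3.0)
        est, _ = triangulate(bearings_to(target)[:2])
        assert haversine_km(est, target) * 1000 < 5.0
        with pytest.raises(ValueError):
            triangulate(bearings_to(target)[:1])


class TestPairScore:
    def test_same_singer_good_geometry_high_score(self, sensors):
        # singer broadside of the X-Y pair at 3 km, drifting alongshore,
        # bearings with von Mises kappa=200 noise
        rng = np.random.default_rng(7)
        eps = np.arange(0, 7200, 60.0)
        azx, azy = [], []
        for e in eps:
            p = destination_point(
                destination_point(DASAR_Y, 228.0, 3.0), 318.0, 0.3 * e / 3600
            )
            azx.append(initial_bearing_deg(DASAR_X, p) + math.degrees(rng.vonmises(0, 200)))
            azy.append(initial_bearing_deg(DASAR_Y, p) + math.degrees(rng.vonmises(0, 200)))
        a = AzimuthalTrack("X", eps, np.asarray(azx))
        b = AzimuthalTrack("Y", eps, np.asarray(azy))
        s, n = pair_score(a, b, sensors)
        assert n == len(eps)
        assert s > 0.8

    def test_diverging_bearings_score_zero(self, sensors):
        # rays pointing away from each other never intersect forward
        eps = np.arange(0, 600, 60.0)
        a = AzimuthalTrack("X", eps, np.full(len(eps), 0.0))  # due north from X
        b = AzimuthalTrack("Y", eps, np.full(len(eps), 180.0))  # due south from Y
        s, n = pair_score(a, b, sensors, smooth_window=1)
        assert s == 0.0 and n == len(eps)

    def test_disjoint_time_ranges(self, sensors):
        a = AzimuthalTrack("X", np.arange(0, 300, 60.0), np.full(5, 100.0))
        b = AzimuthalTrack("Y", np.arange(600, 900, 60.0), np.full(5, 200.0))
        assert pair_score(a, b, sensors) == (0.0, 0)

    def test_same_sensor_rejected(self, sensors):
        a = AzimuthalTrack("X", np.arange(0, 300, 60.0), np.full(5, 100.0))
        with pytest.raises(ValueError):
            pair_score(a, a, sensors)


class TestMatchTracks:
    def test_three_singers_matched_correctly(self, small_scene):
        cfg, truth, bearings = small_scene
        trips = match_tracks(bearings, cfg.sensors)
        assert len(trips) == 3
        for tr in trips:
            assert len({t.track_id.split(":")[1] for t in tr}) == 1

    def test_two_sensor_singer_not_emitted(self, small_scene):
        cfg, truth, bearings = small_scene
        pruned = {
            "X": bearings["X"],
            "Y": bearings["Y"],
            "Z": bearings["Z"][1:],  # singer 0 invisible on Z
        }
        dropped = bearings["Z"][0].track_id.split(":")[1]
        trips = match_tracks(pruned, cfg.sensors)
        emitted = {tr[0].track_id.split(":")[1] for tr in trips}
        assert dropped not in emitted

    def test_empty_input(self, sensors):
        assert match_tracks({"X": [], "Y": [], "Z": []}, sensors) == []


def _track(xy_km, origin=DASAR_Y, epochs=None):
    pts = [to_geo(LocalXY(x, y, origin)) for x, y in xy_km]
    eps = np.arange(len(pts)) * 60.0 if epochs is None else np.asarray(epochs)
    return LocalizedTrack(
        track_id="t",
        epochs=eps,
        lats=np.array([p.lat for p in pts]),
        lons=np.array([p.lon for p in pts]),
    )


class TestRemoveOutliers:
    def test_planted_far_point_removed(self):
        rng = np.random.default_rng(11)
        xy = rng.normal(0, 0.05, (100, 2)).tolist()
        xy.append([5.0, 5.0])
        track = _track(xy)
        out = remove_outliers(track)
        # the far point is gone; at most the quantile tail of clean points goes
        assert max(abs(out.lats - DASAR_Y.lat)) < 0.01
        assert len(out) >= 95

    def test_coincident_points_kept(self):
        track = _track([[1.0, 1.0]] * 10)
        assert len(remove_outliers(track)) == 10

    def test_short_track_unchanged(self):
        track = _track([[0, 0], [0.1, 0]])
        assert remove_outliers(track) is track

    def test_clean_removal_fraction_bounded(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            track = _track(rng.normal(0, 0.2, (80, 2)))
            out = remove_outliers(track)
            assert len(out) >= 0.95 * 80 - 1


class TestSmooth:
    def test_constant_track_unchanged(self):
        track = _track([[1.0, 2.0]] * 9)
        out = smooth(track)
        np.testing.assert_allclose(out.smoothed_lats, track.lats)
        np.testing.assert_allclose(out.smoothed_lons, track.lons)

    def test_linear_track_interior_unchanged(self):
        track = _track([[0.1 * i, 0.05 * i] for i in range(11)])
        out = smooth(track)
        np.testing.assert_allclose(out.smoothed_lats[2:-2], track.lats[2:-2], rtol=1e-9)

    def test_variance_reduction_one_fifth(self):
        # white positional noise: 5-point mean cuts interior variance ~5x
        rng = np.random.default_rng(13)
        n_tracks, n_pts = 10_000, 15
        noise = rng.normal(0, 1.0, (n_tracks, n_pts))
        sm = np.stack(
            [np.convolve(row, np.ones(5) / 5, mode="valid") for row in noise]
        )
        ratio = sm.var() / noise.var()
        assert ratio == pytest.approx(0.2, abs=0.02)
        # and the library smoother agrees with the convolution oracle
        track = _track([[x, 0.0] for x in noise[0]])
        out = smooth(track)
        lat_mid = out.smoothed_lats[2:-2]
        conv = np.convolve(track.lats, np.ones(5) / 5, mode="valid")
        np.testing.assert_allclose(lat_mid, conv, rtol=1e-12)


class TestMergeSplitTracks:
    def test_surfacing_gap_merged(self):
        a = _track([[0, 0]] * 10)
        b = _track([[0.05, 0]] * 10, epochs=np.arange(10) * 60.0 + 600 + 240)
        merged = merge_split_tracks([a, b])
        assert len(merged) == 1
        assert len(merged[0]) == 20

    def test_concurrent_tracks_never_merged(self):
        a = _track([[0, 0]] * 10)
        b = _track([[0.5, 0]] * 10)  # same epochs, 500 m apart
        assert len(merge_split_tracks([a, b])) == 2

    def test_long_gap_not_merged(self):
        a = _track([[0, 0]] * 10)
        b = _track([[0.05, 0]] * 10, epochs=np.arange(10) * 60.0 + 600 + 1800)
        assert len(merge_split_tracks([a, b])) == 2

    def test_fast_bridge_not_merged(self):
        a = _track([[0, 0]] * 10)
        b = _track([[2.0, 0]] * 10, epochs=np.arange(10) * 60.0 + 600 + 240)
        # 2 km in 4 min = 30 km/h
        assert len(merge_split_tracks([a, b])) == 2

    def test_transitive_closure(self):
        a = _track([[0, 0]] * 5)
        b = _track([[0.05, 0]] * 5, epochs=np.arange(5) * 60.0 + 300 + 120)
        c = _track([[0.10, 0]] * 5, epochs=np.arange(5) * 60.0 + 720 + 120)
        assert len(merge_split_tracks([a, b, c])) == 1


class TestQcPositions:
    def test_land_and_mirage_dropped(self, slope_bathy, sensors):
        from songtrack.synthetic_data import shore_frame

        origin, along, offshore = shore_frame()
        good = offshore * 2.0 - offshore * 0.5
        land = -offshore * 3.0
        xy = [list(good), list(land)]
        track = _track(xy, origin=origin)
        out = qc_positions([track], slope_bathy, sensors)
        assert len(out) == 1 and len(out[0]) == 1

    def test_clean_offshore_track_unchanged(self, slope_bathy, sensors, small_scene):
        cfg, truth, _ = small_scene
        sub = truth[truth.singer == "whale-00"].head(20)
        track = LocalizedTrack(
            "w0", sub.epoch.to_numpy(), sub.lat.to_numpy(), sub.lon.to_numpy()
        )
        out = qc_positions([track], slope_bathy, sensors)
        assert len(out) == 1 and len(out[0]) == 20


class TestLocalizeTriplet:
    def test_noise_free_recovery(self, sensors):
        target = destination_point(DASAR_Y, 240.0, 3.0)
        eps = np.arange(0, 600, 60.0)
        tracks = tuple(
            AzimuthalTrack(s, eps, np.full(len(eps), initial_bearing_deg(p, target)))
            for s, p in sensors.items()
        )
        out = localize_triplet(tracks, sensors, track_id="fix")
        assert len(out) == len(eps)
        for la, lo in zip(out.lats, out.lons):
            assert haversine_km(GeoPoint(la, lo), target) * 1000 < 5.0
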