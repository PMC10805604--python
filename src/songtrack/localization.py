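"""Cross-sensor track association and three-bearing triangulation.

Each singer traced on a vector sensor yields an azimuthal track: a 60-s
series of arrival bearings. Tracks from different sensors are paired by a
displacement-consistency score (bearing pairs that keep intersecting at a
slowly moving point score high), matched one-to-one by greedy assignment,
and — for singers visible on all three sensors — triangulated per epoch by
least squares on wrapped angular residuals. Post-processing drops
nearest-neighbour-distance outliers beyond the 95% within-track quantile,
smooths coordinates with a five-step running average, merges track
fragments split by surfacing gaps, and removes physically impossible
positions (on land, or far beyond the array).

The pairwise score formula is this package's own definition (kept behind
one function so an alternative can be swapped in): it encodes the stated
behaviour that high scores mean "same singer".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geo import GeoPoint, LocalXY, haversine_km, to_geo, to_local

__all__ = [
    "AzimuthalTrack",
    "PairScoreMatrix",
    "LocalizedTrack",
    "TriangulationError",
    "pair_score",
    "score_matrix",
    "match_tracks",
    "triangulate",
    "localize_triplet",
    "remove_outliers",
    "smooth",
    "merge_split_tracks",
    "qc_positions",
]


@dataclass
class AzimuthalTrack:
    """Bearing time series for one traced source at one sensor.

    ``epochs`` are seconds (or POSIX seconds), strictly increasing on the
    60-s epoch raster; missing epochs are surfacing or masking gaps.
    Azimuths are degrees clockwise from true north in [0, 360).
    """

    sensor: str
    epochs: np.ndarray
    azimuths: np.ndarray
    track_id: str = ""

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.azimuths = np.asarray(self.azimuths, dtype=float) % 360.0
        if len(self.epochs) != len(self.azimuths):
            raise ValueError("epochs and azimuths length mismatch")
        if len(self.epochs) > 1 and np.any(np.diff(self.epochs) <= 0):
            raise ValueError("epochs must be strictly increasing")


@dataclass
class PairScoreMatrix:
    """Median pair scores and overlaps for all track pairs of two sensors."""

    sensor_a: str
    sensor_b: str
    scores: np.ndarray  # (n_a, n_b) in [0, 1]
    overlaps: np.ndarray  # (n_a, n_b) ints

    def to_frame(self, rows=None, cols=None) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=rows, columns=cols)


@dataclass
class LocalizedTrack:
    """Georeferenced 60-s positions for one singer (raw and smoothed)."""

    track_id: str
    epochs: np.ndarray
    lats: np.ndarray
    lons: np.ndarray
    residuals_deg: np.ndarray | None = None
    smoothed_lats: np.ndarray | None = None
    smoothed_lons: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)

    def __len__(self) -> int:
        return len(self.epochs)

    def points(self) -> list[GeoPoint]:
        return [GeoPoint(la, lo) for la, lo in zip(self.lats, self.lons)]

    def best_lats(self) -> np.ndarray:
        return self.smoothed_lats if self.smoothed_lats is not None else self.lats

    def best_lons(self) -> np.ndarray:
        return self.smoothed_lons if self.smoothed_lons is not None else self.lons


class TriangulationError(ValueError):
    """Raised for degenerate (near-parallel) bearing geometry."""


def _wrap(a):
    """Wrap angle difference(s) to (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)


def _unit(az_deg):
    th = np.radians(az_deg)
    return np.sin(th), np.cos(th)


def _ray_intersection(s1, az1, s2, az2):
    """Forward intersection of two bearing rays in local XY; None if absent."""
    u1x, u1y = _unit(az1)
    u2x, u2y = _unit(az2)
    det = u2x * u1y - u1x * u2y
    if abs(det) < 1e-9:
        return None
    dx, dy = s2[0] - s1[0], s2[1] - s1[1]
    t1 = (u2x * dy - u2y * dx) / det
    t2 = (u1x * dy - u1y * dx) / det
    if t1 <= 0 or t2 <= 0:
        return None
    return (s1[0] + t1 * u1x, s1[1] + t1 * u1y)


def _circular_smooth(az_deg: np.ndarray, window: int) -> np.ndarray:
    """Centered running circular mean of an azimuth series."""
    if window <= 1:
        return np.asarray(az_deg, dtype=float)
    th = np.radians(az_deg)
    s = pd.Series(np.sin(th)).rolling(window, center=True, min_periods=1).mean()
    c = pd.Series(np.cos(th)).rolling(window, center=True, min_periods=1).mean()
    return np.degrees(np.arctan2(s.to_numpy(), c.to_numpy())) % 360.0


def pair_score(
    a: AzimuthalTrack,
    b: AzimuthalTrack,
    sensors: dict[str, GeoPoint],
    max_range_km: float = 30.0,
    disp_scale_m: float = 200.0,
    smooth_window: int = 5,
) -> tuple[float, int]:
    """Median displacement-consistency score of two tracks, plus overlap.

    Bearings are first smoothed with a centered circular running mean over
    ``smooth_window`` epochs (suppressing per-epoch bearing noise, which
    would otherwise dominate the intersection displacement at km ranges).
    Per common epoch the two bearings are intersected: score 1 if the
    intersection lies within ``max_range_km`` of both sensors and moved
    less than ``disp_scale_m`` since the previous common epoch, partial
    credit exp(-d^2 / (2 s^2)) for larger displacements d, and 0 where the
    rays do not intersect forward. Returns (median score over common
    epochs, number of common epochs); (0.0, 0) without temporal overlap.

    A high score means the two tracks plausibly arise from one singer; the
    converse does not hold when both sources are stationary (the ghost
    intersection of two stationary singers is itself stationary), which is
    why :func:`match_tracks` verifies candidates with the three-bearing
    triangulation residual.
    """
    if a.sensor == b.sensor:
        raise ValueError("pair_score requires tracks from different sensors")
    common, ia, ib = np.intersect1d(a.epochs, b.epochs, return_indices=True)
    if common.size == 0:
        return 0.0, 0
    origin = sensors[a.sensor]
    qa = to_local(sensors[a.sensor], origin)
    qb = to_local(sensors[b.sensor], origin)
    sa, sb = (qa.x, qa.y), (qb.x, qb.y)
    az_a = _circular_smooth(a.azimuths, smooth_window)[ia]
    az_b = _circular_smooth(b.azimuths, smooth_window)[ib]
    scores = np.zeros(common.size)
    prev = None
    s_km = disp_scale_m / 1000.0
    for k in range(common.size):
        pt = _ray_intersection(sa, az_a[k], sb, az_b[k])
        if pt is None:
            prev = None
            continue
        r1 = math.hypot(pt[0] - sa[0], pt[1] - sa[1])
        r2 = math.hypot(pt[0] - sb[0], pt[1] - sb[1])
        if r1 > max_range_km or r2 > max_range_km:
            prev = pt
            continue
        if prev is None:
            scores[k] = 1.0
        else:
            d = math.hypot(pt[0] - prev[0], pt[1] - prev[1])
            scores[k] = 1.0 if d < s_km else math.exp(-(d**2) / (2 * s_km**2))
        prev = pt
    return float(np.median(scores)), int(common.size)


def score_matrix(
    tracks_a: list[AzimuthalTrack],
    tracks_b: list[AzimuthalTrack],
    sensors: dict[str, GeoPoint],
    **kw,
) -> PairScoreMatrix:
    """All cross-track pair scores between two sensors (confusion matrix)."""
    scores = np.zeros((len(tracks_a), len(tracks_b)))
    overlaps = np.zeros((len(tracks_a), len(tracks_b)), dtype=int)
    for i, ta in enumerate(tracks_a):
        for j, tb in enumerate(tracks_b):
            scores[i, j], overlaps[i, j] = pair_score(ta, tb, sensors, **kw)
    sa = tracks_a[0].sensor if tracks_a else ""
    sb = tracks_b[0].sensor if tracks_b else ""
    return PairScoreMatrix(sensor_a=sa, sensor_b=sb, scores=scores, overlaps=overlaps)


def _triplet_residual(
    trip: tuple[AzimuthalTrack, ...],
    sensors: dict[str, GeoPoint],
    min_overlap: int,
    n_sample: int = 25,
    max_range_km: float = 30.0,
    smooth_window: int = 5,
) -> tuple[float, int]:
    """Median per-epoch triangulation RMS residual (deg) of a candidate
    triplet over up to ``n_sample`` evenly spaced common epochs.

    Bearings are circularly smoothed over ``smooth_window`` epochs first,
    which drops the residual floor of a true triplet (noise-dominated)
    well below the structural misfit of a mismatched one. Epochs whose
    least-squares position falls beyond ``max_range_km`` of every sensor
    count as misfits: three nearly parallel bearings to *different*
    sources can co-intersect at long range with a deceptively small
    angular residual (angular misfit shrinks with range), so a
    range-unconstrained residual would favour such ghost solutions.
    """
    a, b, c = trip
    common = np.intersect1d(np.intersect1d(a.epochs, b.epochs), c.epochs)
    if common.size < min_overlap:
        return math.inf, int(common.size)
    sel = common[np.linspace(0, common.size - 1, min(n_sample, common.size)).astype(int)]
    maps = [
        dict(zip(t.epochs, _circular_smooth(t.azimuths, smooth_window))) for t in trip
    ]
    res = []
    for e in sel:
        brs = [(sensors[t.sensor], m[e]) for t, m in zip(trip, maps)]
        try:
            pt, rms = triangulate(brs)
        except TriangulationError:
            res.append(90.0)
            continue
        if min(haversine_km(pt, s) for s, _ in brs) > max_range_km:
            res.append(90.0)
        else:
            res.append(rms)
    return float(np.median(res)), int(common.size)


def match_tracks(
    tracks_by_sensor: dict[str, list[AzimuthalTrack]],
    sensors: dict[str, GeoPoint],
    min_overlap: int = 5,
    min_score: float = 0.0,
    max_residual_deg: float = 8.0,
    **kw,
) -> list[tuple[AzimuthalTrack, AzimuthalTrack, AzimuthalTrack]]:
    """Match tracks across three sensors into consistent triplets.

    Candidate triplets must overlap for at least ``min_overlap`` common
    epochs, have at least one pairwise score >= ``min_score`` (off by
    default: the displacement score jitters badly for near-endfire pair
    geometry, so it serves as diagnostics rather than as a gate), and —
    the decisive consistency check — a median three-bearing triangulation
    RMS residual <= ``max_residual_deg`` (three bearings to one physical
    source nearly co-intersect; mismatched bearings do not). The one-to-one
    assignment minimizes total capped residual globally (a mismatched
    triplet steals tracks from two others, so greedy ordering can cascade
    a single ambiguity into several errors); scenes too large for the
    exact search fall back to greedy ascending-residual assignment. A
    singer visible on only two sensors is never emitted.
    """
    ids = sorted(tracks_by_sensor)
    if len(ids) < 3:
        return []
    s1, s2, s3 = ids[:3]
    t1, t2, t3 = (tracks_by_sensor[s] for s in (s1, s2, s3))
    if not (t1 and t2 and t3):
        return []
    m12 = score_matrix(t1, t2, sensors, **kw)
    m23 = score_matrix(t2, t3, sensors, **kw)
    m13 = score_matrix(t1, t3, sensors, **kw)
    n1, n2, n3 = len(t1), len(t2), len(t3)
    big = 90.0
    R = np.full((n1, n2, n3), big)
    for i in range(n1):
        for j in range(n2):
            for k in range(n3):
                if (
                    min(m12.overlaps[i, j], m23.overlaps[j, k], m13.overlaps[i, k])
                    < min_overlap
                ):
                    continue
                if min_score > 0 and (
                    max(m12.scores[i, j], m23.scores[j, k], m13.scores[i, k]) < min_score
                ):
                    continue
                r, _ = _triplet_residual((t1[i], t2[j], t3[k]), sensors, min_overlap)
                R[i, j, k] = min(r, big)

    chosen: list[tuple[int, int, int]]
    if max(n1, n2, n3) <= 7:
        chosen = _assign_global(R, cap=max_residual_deg)
    else:
        chosen = _assign_greedy(R, cap=max_residual_deg)
    return [(t1[i], t2[j], t3[k]) for i, j, k in chosen if R[i, j, k] <= max_residual_deg]


def _assign_global(R: np.ndarray, cap: float) -> list[tuple[int, int, int]]:
    """Exact three-way assignment minimizing total capped residual.

    Enumerates injections of axis 0 into axis 1 and solves the remaining
    axis-2 assignment with the Hungarian algorithm; capping residuals at
    ``cap`` makes every impossible triplet equally expensive so one bad
    cell cannot distort the optimum.
    """
    import itertools

    from scipy.optimize import linear_sum_assignment

    n1, n2, n3 = R.shape
    Rc = np.minimum(R, cap)
    best, best_cost = [], math.inf
    for perm in itertools.permutations(range(n2), min(n1, n2)):
        rows = range(len(perm))
        C = np.array([[Rc[i, perm[i], k] for k in range(n3)] for i in rows])
        ri, ck = linear_sum_assignment(C)
        cost = float(C[ri, ck].sum())
        if cost < best_cost:
            best_cost = cost
            best = [(int(i), int(perm[i]), int(k)) for i, k in zip(ri, ck)]
    return best


def _assign_greedy(R: np.ndarray, cap: float) -> list[tuple[int, int, int]]:
    order = np.argsort(R, axis=None)
    used_i, used_j, used_k = set(), set(), set()
    out = []
    for flat in order:
        i, j, k = np.unravel_index(flat, R.shape)
        if R[i, j, k] > cap:
            break
        if i in used_i or j in used_j or k in used_k:
            continue
        used_i.add(i)
        used_j.add(j)
        used_k.add(k)
        out.append((int(i), int(j), int(k)))
    return out


def triangulate(
    bearings: list[tuple[GeoPoint, float]],
    prior: LocalXY | None = None,
    max_iter: int = 50,
    tol_km: float = 1e-6,
    max_condition: float = 1e6,
) -> tuple[GeoPoint, float]:
    """Least-squares position from >= 2 bearings (Gauss-Newton).

    Minimizes the sum of squared wrapped differences between observed
    azimuths and sensor-to-candidate bearings, in a local planar frame.
    Starts from ``prior`` or the best pairwise ray intersection. Returns the
    position and the RMS angular misfit in degrees. Raises
    :class:`TriangulationError` when the geometry is degenerate
    (near-parallel bearings, normal-matrix condition number > 1e6).
    """
    if len(bearings) < 2:
        raise ValueError("need at least two bearings")
    origin = bearings[0][0]
    sx, sy, obs = [], [], []
    for sensor, az in bearings:
        q = to_local(sensor, origin)
        sx.append(q.x)
        sy.append(q.y)
        obs.append(az % 360.0)
    sx, sy, obs = np.asarray(sx), np.asarray(sy), np.asarray(obs)

    def residuals(x, y):
        pred = np.degrees(np.arctan2(x - sx, y - sy)) % 360.0
        return np.radians(_wrap(obs - pred))

    # initial guess: prior, else pairwise intersection with smallest misfit
    if prior is not None:
        pq = prior if prior.origin == origin else to_local(to_geo(prior), origin)
        x, y = pq.x, pq.y
    else:
        best, best_cost = None, np.inf
        n = len(obs)
        for i in range(n):
            for j in range(i + 1, n):
                pt = _ray_intersection((sx[i], sy[i]), obs[i], (sx[j], sy[j]), obs[j])
                if pt is None:
                    continue
                cost = float(np.sum(residuals(*pt) ** 2))
                if cost < best_cost:
                    best, best_cost = pt, cost
        if best is None:
            raise TriangulationError("no forward bearing intersection (parallel geometry)")
        x, y = best

    for _ in range(max_iter):
        dx, dy = x - sx, y - sy
        r2 = dx**2 + dy**2
        if np.any(r2 < 1e-12):
            raise TriangulationError("candidate coincides with a sensor")
        # d(bearing)/dx = dy/r^2, d(bearing)/dy = -dx/r^2 (radians)
        J = np.column_stack([dy / r2, -dx / r2])
        res = residuals(x, y)
        JtJ = J.T @ J
        cond = np.linalg.cond(JtJ)
        if not np.isfinite(cond) or cond > max_condition:
            raise TriangulationError(f"ill-conditioned bearing geometry (cond={cond:.2g})")
        step = np.linalg.solve(JtJ, J.T @ res)
        x += step[0]
        y += step[1]
        if math.hypot(*step) < tol_km:
            break

    rms = float(np.degrees(np.sqrt(np.mean(residuals(x, y) ** 2))))
    return to_geo(LocalXY(x, y, origin)), rms


def localize_triplet(
    triplet: tuple[AzimuthalTrack, ...],
    sensors: dict[str, GeoPoint],
    track_id: str = "",
    smooth_bearings: int = 5,
) -> LocalizedTrack:
    """Triangulate one matched triplet at every common 60-s epoch.

    Bearings are circularly smoothed over ``smooth_bearings`` epochs before
    triangulation (traced ridge azimuths are serially noisy at the bin
    scale; the smoothing matches the five-step position averaging applied
    downstream). Epochs with degenerate geometry are skipped (flagged by
    omission); each epoch's solution seeds the next as prior.
    """
    a, b, c = triplet
    common = np.intersect1d(np.intersect1d(a.epochs, b.epochs), c.epochs)
    lats, lons, eps, res = [], [], [], []
    prior = None
    lookup = [
        (t, dict(zip(t.epochs, _circular_smooth(t.azimuths, smooth_bearings))))
        for t in (a, b, c)
    ]
    origin = sensors[a.sensor]
    for e in common:
        brs = [(sensors[t.sensor], azmap[e]) for t, azmap in lookup]
        try:
            pt, rms = triangulate(brs, prior=prior)
            prior = to_local(pt, brs[0][0])
        except (TriangulationError, ValueError):
            # degenerate geometry or runaway far-field solution: skip epoch
            prior = None
            continue
        eps.append(e)
        lats.append(pt.lat)
        lons.append(pt.lon)
        res.append(rms)
    return LocalizedTrack(
        track_id=track_id or a.track_id,
        epochs=np.asarray(eps),
        lats=np.asarray(lats),
        lons=np.asarray(lons),
        residuals_deg=np.asarray(res),
    )


def _nn_distances_km(track: LocalizedTrack) -> np.ndarray:
    """Per-point distance to the nearest other point of the same track."""
    origin = GeoPoint(float(np.mean(track.lats)), float(np.mean(track.lons)))
    xy = np.array(
        [(q.x, q.y) for q in (to_local(p, origin) for p in track.points())]
    )
    d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    return np.sqrt(d2.min(axis=1))


def remove_outliers(track: LocalizedTrack, quantile: float = 0.95) -> LocalizedTrack:
    """Drop positions whose nearest-neighbour distance exceeds the
    within-track 95% quantile (single pass); tracks with fewer than three
    points are returned unchanged."""
    if len(track) < 3:
        return track
    nn = _nn_distances_km(track)
    thresh = float(np.quantile(nn, quantile))
    keep = nn <= thresh
    return replace(
        track,
        epochs=track.epochs[keep],
        lats=track.lats[keep],
        lons=track.lons[keep],
        residuals_deg=None if track.residuals_deg is None else track.residuals_deg[keep],
        smoothed_lats=None,
        smoothed_lons=None,
    )


def smooth(track: LocalizedTrack, window: int = 5) -> LocalizedTrack:
    """Centered running average of coordinates over ``window`` consecutive
    steps, truncated at the ends; epochs are preserved."""
    if len(track) == 0:
        return track
    la = pd.Series(track.lats).rolling(window, center=True, min_periods=1).mean().to_numpy()
    lo = pd.Series(track.lons).rolling(window, center=True, min_periods=1).mean().to_numpy()
    return replace(track, smoothed_lats=la, smoothed_lons=lo)


def merge_split_tracks(
    tracks: list[LocalizedTrack],
    gap_max_s: float = 600.0,
    max_bridge_speed_kmh: float = 6.0,
) -> list[LocalizedTrack]:
    """Re-join track fragments belonging to one singer.

    Two fragments merge when they do not overlap in time, the end-to-start
    gap is at most ``gap_max_s`` (10 min covers surfacing interruptions),
    and the implied bridging speed is at most ``max_bridge_speed_kmh``;
    merging is closed transitively.
    """
    tracks = [t for t in tracks if len(t) > 0]
    n = len(tracks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def mergeable(t1: LocalizedTrack, t2: LocalizedTrack) -> bool:
        if t1.epochs[0] > t2.epochs[0]:
            t1, t2 = t2, t1
        if t2.epochs[0] <= t1.epochs[-1]:  # concurrent
            return False
        gap = t2.epochs[0] - t1.epochs[-1]
        if gap > gap_max_s:
            return False
        d = haversine_km(
            GeoPoint(t1.lats[-1], t1.lons[-1]), GeoPoint(t2.lats[0], t2.lons[0])
        )
        return d / (gap / 3600.0) <= max_bridge_speed_kmh

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) != find(j) and mergeable(tracks[i], tracks[j]):
                parent[find(j)] = find(i)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        members.sort(key=lambda i: tracks[i].epochs[0])
        first = tracks[members[0]]
        if len(members) == 1:
            out.append(first)
            continue
        eps = np.concatenate([tracks[i].epochs for i in members])
        lats = np.concatenate([tracks[i].lats for i in members])
        lons = np.concatenate([tracks[i].lons for i in members])
        res = (
            np.concatenate([tracks[i].residuals_deg for i in members])
            if all(tracks[i].residuals_deg is not None for i in members)
            else None
        )
        out.append(
            LocalizedTrack(
                track_id=first.track_id,
                epochs=eps,
                lats=lats,
                lons=lons,
                residuals_deg=res,
            )
        )
    out.sort(key=lambda t: t.epochs[0])
    return out


def qc_positions(
    tracks: list[LocalizedTrack],
    bathy,
    sensors: dict[str, GeoPoint],
    max_sensor_range_km: float = 30.0,
) -> list[LocalizedTrack]:
    """Drop physically implausible epochs: positions on land (depth <= 0 or
    outside the bathymetry grid) or beyond ``max_sensor_range_km`` of the
    nearest sensor. Tracks left empty are removed."""
    from .geo import depth_at as _depth_at

    out = []
    for t in tracks:
        keep = np.ones(len(t), dtype=bool)
        for i, p in enumerate(t.points()):
            try:
                if _depth_at(bathy, p) <= 0:
                    keep[i] = False
                    continue
            except ValueError:
                keep[i] = False
                continue
            if min(haversine_km(p, s) for s in sensors.values()) > max_sensor_range_km:
                keep[i] = False
        if keep.any():
            out.append(
                replace(
                    t,
                    epochs=t.epochs[keep],
                    lats=t.lats[keep],
                    lons=t.lons[keep],
                    residuals_deg=None
                    if t.residuals_deg is None
                    else t.residuals_deg[keep],
                    smoothed_lats=None,
                    smoothed_lons=None,
                )
            )
    return out
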