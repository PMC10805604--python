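"""Ground-truthed synthetic inputs for every pipeline stage.

The generators emulate the study geometry and behaviours with known truth:
singers alternating stationary and travelling bouts (or following a
scripted diel distance-to-shore curve) in a coastal strip monitored by
three in-line vector sensors about 3 km apart; per-sensor bearings with
von Mises noise and surfacing gaps; plane-wave three-channel audio; diel
band-limited soundscape files on a 30 s / 5 min duty cycle; and a
linear-slope bathymetry whose shoreline runs parallel to the sensor line.

Default sensor positions are the three printed vector-sensor deployments
(X, Y, Z), so synthetic inter-sensor distances match the field geometry.
The coastline is modelled as the straight line parallel to the X-Z axis
passing 0.5 km inshore of sensor Y (the deployments sat 350-510 m off the
beach), which makes true distance-to-shore an analytic plane distance.
Movement defaults straddle the 2 km/h state threshold: stationary drift
0-0.5 km/h, travel 2.5-6 km/h, so state recovery is non-trivial but
identifiable. All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .geo import (
    BathymetryGrid,
    GeoPoint,
    haversine_km,
    initial_bearing_deg,
    to_geo,
    to_local,
    LocalXY,
)
from .localization import AzimuthalTrack
from .soundscape import RecordingFile, bandpass
from .vector_field import C_SEAWATER, RHO_SEAWATER, VectorFrame

__all__ = [
    "DASAR_X",
    "DASAR_Y",
    "DASAR_Z",
    "default_sensors",
    "SceneConfig",
    "simulate_scene",
    "render_bearings",
    "render_vector_audio",
    "render_soundscape",
    "synth_bathymetry",
    "shore_frame",
]

# Printed vector-sensor deployment positions (deg N, deg W as negative lon)
DASAR_X = GeoPoint(20.808, -156.627)
DASAR_Y = GeoPoint(20.829, -156.646)
DASAR_Z = GeoPoint(20.851, -156.668)


def default_sensors() -> dict[str, GeoPoint]:
    return {"X": DASAR_X, "Y": DASAR_Y, "Z": DASAR_Z}


def shore_frame(sensors: dict[str, GeoPoint] | None = None, shore_offset_km: float = 0.5):
    """Coastline geometry of the synthetic world.

    Returns (origin, alongshore unit vector, offshore unit vector) in the
    local frame centred on the middle sensor. The coastline is the line
    through ``origin - offshore * shore_offset_km`` parallel to the sensor
    axis; offshore points seaward (away from land, toward lower longitudes
    here on a west-facing coast).
    """
    sensors = sensors or default_sensors()
    ids = sorted(sensors)
    first, mid, last = sensors[ids[0]], sensors[ids[1]], sensors[ids[2]]
    q = to_local(last, mid)
    p = to_local(first, mid)
    along = np.array([q.x - p.x, q.y - p.y])
    along = along / np.linalg.norm(along)
    offshore = np.array([-along[1], along[0]])
    # pick the seaward sign: away from the island, i.e. westward (negative x)
    if offshore[0] > 0:
        offshore = -offshore
    return mid, along, offshore


@dataclass
class SceneConfig:
    """Configuration of a synthetic singer scene; ``seed`` is mandatory."""

    seed: int
    n_singers: int = 3
    duration_h: float = 8.0
    epoch_s: float = 60.0
    sensors: dict[str, GeoPoint] = dc_field(default_factory=default_sensors)
    extent_alongshore_km: float = 8.0
    d_shore_range_km: tuple[float, float] = (1.0, 5.0)
    shore_offset_km: float = 0.5
    stationary_dwell_min: float = 40.0
    travel_dwell_min: float = 15.0
    stationary_speed_kmh: tuple[float, float] = (0.0, 0.5)
    travel_speed_kmh: tuple[float, float] = (2.5, 6.0)
    p_travel: float = 0.35
    surfacing_period_min: float = 15.0
    surfacing_gap_min: float = 2.0
    kappa: float = 200.0
    audible_radius_km: float = 30.0
    diel_d_shore_by_hour: dict[int, float] | None = None
    travel_frac_by_hour: dict[int, float] | None = None
    speed_thresh_kmh: float = 2.0
    min_spacing_km: float = 1.2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if min(self.travel_speed_kmh) <= 0:
            raise ValueError("speeds must be positive")


def _scene_rng(cfg: SceneConfig) -> np.random.Generator:
    return np.random.default_rng(cfg.seed)


def simulate_scene(cfg: SceneConfig) -> pd.DataFrame:
    """Simulate true singer positions per 60-s epoch.

    Returns a truth table with one row per (epoch, singer): epoch seconds,
    singer id, local x/y (km, frame centred on the middle sensor), lat,
    lon, true d_shore (km), true state by the 2 km/h rule, and an
    ``audible`` flag that is False during scripted surfacing gaps.

    Without a diel script, singers alternate stationary and travelling
    bouts (exponential dwell times, uniform speeds/headings). With
    ``diel_d_shore_by_hour`` set, each singer relaxes its offshore
    coordinate toward the hour's target distance-to-shore at travel speed,
    which reproduces the scripted curve once targets are reached. With
    ``travel_frac_by_hour`` set, each singer instead travels for a scripted
    contiguous fraction of each hour's epochs (start offset randomized per
    singer-hour) and drifts otherwise, giving exactly controlled true state
    proportions. Singers repel each other below ``min_spacing_km``,
    emulating the spacing that singing males maintain on the breeding
    ground.
    """
    rng = _scene_rng(cfg)
    origin, along, offshore = shore_frame(cfg.sensors, cfg.shore_offset_km)
    shore_base = -offshore * cfg.shore_offset_km  # a point on the coastline
    n_epochs = int(round(cfg.duration_h * 3600.0 / cfg.epoch_s))
    dt_h = cfg.epoch_s / 3600.0
    n = cfg.n_singers

    # initial placement: rejection-sample to respect minimum spacing
    pos = np.zeros((n, 2))
    for s in range(n):
        for _ in range(1000):
            u0 = rng.uniform(-cfg.extent_alongshore_km / 2, cfg.extent_alongshore_km / 2)
            if cfg.diel_d_shore_by_hour is not None:
                v0 = cfg.diel_d_shore_by_hour[0]
            else:
                v0 = rng.uniform(*cfg.d_shore_range_km)
            cand = shore_base + along * u0 + offshore * v0
            if all(
                np.linalg.norm(cand - pos[j]) >= cfg.min_spacing_km for j in range(s)
            ):
                pos[s] = cand
                break
        else:
            pos[s] = cand  # crowded scene: accept the last candidate

    travelling = rng.random(n) < cfg.p_travel
    dwell_left = np.array(
        [
            rng.exponential(cfg.travel_dwell_min if travelling[s] else cfg.stationary_dwell_min)
            for s in range(n)
        ]
    )
    heading = rng.uniform(0, 2 * math.pi, n)
    speed = np.array(
        [
            rng.uniform(*(cfg.travel_speed_kmh if travelling[s] else cfg.stationary_speed_kmh))
            for s in range(n)
        ]
    )

    eph = max(1, int(round(3600.0 / cfg.epoch_s)))  # epochs per hour
    trav_off = np.zeros(n, dtype=int)
    trav_len = np.zeros(n, dtype=int)
    trav_heading = rng.uniform(0, 2 * math.pi, n)
    trav_speed = np.array([rng.uniform(*cfg.travel_speed_kmh) for _ in range(n)])

    rows = []
    for k in range(n_epochs):
        t = k * cfg.epoch_s
        hour = int(t // 3600)
        if cfg.travel_frac_by_hour is not None and k % eph == 0:
            frac = cfg.travel_frac_by_hour.get(hour % 24, 0.0)
            for s in range(n):
                trav_len[s] = int(round(frac * eph))
                trav_off[s] = rng.integers(0, max(1, eph - trav_len[s] + 1))
                trav_heading[s] = rng.uniform(0, 2 * math.pi)
                trav_speed[s] = rng.uniform(*cfg.travel_speed_kmh)
        new_pos = pos.copy()
        for s in range(n):
            if cfg.travel_frac_by_hour is not None:
                in_travel = trav_off[s] <= (k % eph) < trav_off[s] + trav_len[s]
                if in_travel:
                    step = trav_speed[s] * dt_h
                    hd = trav_heading[s]
                else:
                    step = rng.uniform(*cfg.stationary_speed_kmh) * dt_h
                    hd = rng.uniform(0, 2 * math.pi)
                cand = pos[s] + step * np.array([math.sin(hd), math.cos(hd)])
                v = float(cand @ offshore) + cfg.shore_offset_km
                lo, hi = cfg.d_shore_range_km
                if not lo <= v <= hi:
                    hd = -hd + math.pi
                    trav_heading[s] = hd
                    cand = pos[s] + step * np.array([math.sin(hd), math.cos(hd)])
            elif cfg.diel_d_shore_by_hour is not None:
                target = cfg.diel_d_shore_by_hour.get(
                    hour % 24, list(cfg.diel_d_shore_by_hour.values())[-1]
                )
                v = float(pos[s] @ offshore) + cfg.shore_offset_km
                dv = target - v
                vmax = max(cfg.travel_speed_kmh) * dt_h
                step_off = float(np.clip(dv, -vmax, vmax))
                step_along = rng.normal(0.0, 0.1 * dt_h)
                cand = pos[s] + offshore * step_off + along * step_along
            else:
                dwell_left[s] -= cfg.epoch_s / 60.0
                if dwell_left[s] <= 0:
                    travelling[s] = not travelling[s]
                    dwell_left[s] = rng.exponential(
                        cfg.travel_dwell_min if travelling[s] else cfg.stationary_dwell_min
                    )
                    heading[s] = rng.uniform(0, 2 * math.pi)
                    speed[s] = rng.uniform(
                        *(cfg.travel_speed_kmh if travelling[s] else cfg.stationary_speed_kmh)
                    )
                step = speed[s] * dt_h
                cand = pos[s] + step * np.array([math.sin(heading[s]), math.cos(heading[s])])
                # reflect off the coastal strip boundaries
                v = float(cand @ offshore) + cfg.shore_offset_km
                lo, hi = cfg.d_shore_range_km
                if not lo <= v <= hi:
                    heading[s] = -heading[s] + math.pi  # reflect offshore component
                    cand = pos[s] + step * np.array(
                        [math.sin(heading[s]), math.cos(heading[s])]
                    )
            # spacing repulsion: step directly away from a too-close neighbour
            others = [j for j in range(n) if j != s]
            if others:
                d = [float(np.linalg.norm(cand - pos[j])) for j in others]
                jmin = others[int(np.argmin(d))]
                if min(d) < cfg.min_spacing_km:
                    away = cand - pos[jmin]
                    nrm = np.linalg.norm(away)
                    away = (
                        away / nrm
                        if nrm > 1e-9
                        else np.array([math.sin(heading[s]), math.cos(heading[s])])
                    )
                    cand = cand + away * max(cfg.travel_speed_kmh) * dt_h
            new_pos[s] = cand

        for s in range(n):
            speed_kmh = float(np.linalg.norm(new_pos[s] - pos[s])) / dt_h
            state = "travelling" if speed_kmh > cfg.speed_thresh_kmh else "stationary"
            phase = (t / 60.0) % cfg.surfacing_period_min
            audible = phase >= cfg.surfacing_gap_min
            d_shore = float(new_pos[s] @ offshore) + cfg.shore_offset_km
            g = to_geo(LocalXY(float(new_pos[s][0]), float(new_pos[s][1]), origin))
            rows.append(
                {
                    "epoch": t,
                    "singer": f"whale-{s:02d}",
                    "x_km": float(new_pos[s][0]),
                    "y_km": float(new_pos[s][1]),
                    "lat": g.lat,
                    "lon": g.lon,
                    "d_shore_km": d_shore,
                    "state": state,
                    "audible": audible,
                }
            )
        pos = new_pos
    df = pd.DataFrame(rows)
    return df.sort_values(["singer", "epoch"]).reset_index(drop=True)


def render_bearings(truth: pd.DataFrame, cfg: SceneConfig) -> dict[str, list[AzimuthalTrack]]:
    """Observed azimuthal tracks: true bearing + von Mises(kappa) noise.

    Epochs during surfacing gaps are omitted, as are epochs beyond the
    audibility radius. Returns {sensor id: [one track per audible singer]}.
    """
    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2**31))
    out: dict[str, list[AzimuthalTrack]] = {s: [] for s in cfg.sensors}
    for sid, grp in truth.groupby("singer", sort=True):
        grp = grp[grp["audible"]]
        if grp.empty:
            continue
        for sname, spos in cfg.sensors.items():
            eps, azs = [], []
            for _, row in grp.iterrows():
                p = GeoPoint(row["lat"], row["lon"])
                if haversine_km(spos, p) > cfg.audible_radius_km:
                    continue
                true_az = initial_bearing_deg(spos, p)
                noisy = true_az + math.degrees(rng.vonmises(0.0, cfg.kappa))
                eps.append(row["epoch"])
                azs.append(noisy % 360.0)
            if eps:
                out[sname].append(
                    AzimuthalTrack(
                        sensor=sname,
                        epochs=np.asarray(eps),
                        azimuths=np.asarray(azs),
                        track_id=f"{sname}:{sid}",
                    )
                )
    return out


def render_vector_audio(
    truth: pd.DataFrame,
    cfg: SceneConfig,
    sensor: str,
    duration_s: float = 60.0,
    fs: float = 1000.0,
    snr_db: float = 20.0,
    amplitude_upa: float = 1e5,
) -> VectorFrame:
    """Plane-wave three-channel audio for one sensor.

    Each singer contributes tonal upsweeps (0.1-1 kHz song-like units);
    particle velocity follows the plane-wave relations
    vx = p sin(theta)/(rho c), vy = p cos(theta)/(rho c) with theta the
    arrival azimuth, plus isotropic Gaussian noise on all channels at the
    requested SNR. Limited to <= 3 singers for tractability.
    """
    singers = sorted(truth["singer"].unique())
    if len(singers) > 3:
        raise ValueError("render_vector_audio supports at most 3 singers")
    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2**31, size=2)[1])
    spos = cfg.sensors[sensor]
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    p = np.zeros(n)
    vx = np.zeros(n)
    vy = np.zeros(n)
    rc = RHO_SEAWATER * C_SEAWATER
    for i, sid in enumerate(singers):
        row = truth[truth["singer"] == sid].iloc[0]
        theta = math.radians(initial_bearing_deg(spos, GeoPoint(row["lat"], row["lon"])))
        # repeated 2-s upsweep units in disjoint 100-Hz slots per singer
        # (0.1-1 kHz song range); disjoint slots keep per-bin intensities
        # single-source so each singer forms its own azimuth ridge
        f0 = 150.0 + 150.0 * i
        unit = (t % 2.0) / 2.0
        inst_f = f0 + 100.0 * unit
        phase = 2 * np.pi * np.cumsum(inst_f) / fs
        pi_sig = amplitude_upa * np.sin(phase)
        p += pi_sig
        vx += pi_sig * math.sin(theta) / rc
        vy += pi_sig * math.cos(theta) / rc
    sig_rms = amplitude_upa / math.sqrt(2)
    noise_rms = sig_rms * 10 ** (-snr_db / 20)
    p += rng.normal(0, noise_rms, n)
    vx += rng.normal(0, noise_rms / rc, n)
    vy += rng.normal(0, noise_rms / rc, n)
    return VectorFrame(p=p, vx=vx, vy=vy, fs=fs, sensor=spos, orientation_offset=0.0)


def render_soundscape(
    diel_profile: dict[str, np.ndarray],
    bands: dict[str, tuple[float, float]],
    days: int = 1,
    seed: int = 0,
    fs: float = 8000.0,
    file_s: float = 30.0,
    cycle_s: float = 300.0,
    t0: datetime | None = None,
    sensitivity: float = -193.5,
    site: str = "synthetic",
) -> list[RecordingFile]:
    """Duty-cycled synthetic soundscape recordings.

    ``diel_profile[band]`` is a 24-vector of target RMS SPL (dB re 1 uPa)
    per hour for each named band in ``bands``; every 30-s file contains the
    sum of independent Gaussian noises band-passed to each band and scaled
    so the band RMS follows the hour's profile. Counts are synthesized by
    inverting the calibration so the full chain (counts -> uPa -> SPL) is
    exercised.
    """
    rng = np.random.default_rng(seed)
    t0 = t0 or datetime(2020, 2, 1)
    n = int(round(file_s * fs))
    files = []
    files_per_day = int(round(86400.0 / cycle_s))
    for day in range(days):
        for k in range(files_per_day):
            ts = t0 + timedelta(days=day, seconds=k * cycle_s)
            hour = ts.hour
            upa = np.zeros(n)
            for name, (lo, hi) in bands.items():
                target_db = float(diel_profile[name][hour])
                noise = rng.normal(0.0, 1.0, n)
                shaped = bandpass(noise, fs, lo, hi)
                rms = np.sqrt(np.mean(shaped**2))
                upa += shaped * (10 ** (target_db / 20) / rms)
            counts = upa * 10 ** (sensitivity / 20) / (2.0 / 2**15)
            files.append(
                RecordingFile(
                    samples=counts,
                    fs=fs,
                    t0=ts,
                    sensitivity=sensitivity,
                    gain=0.0,
                    adc_fullscale_volts=2.0,
                    bits=16,
                    site=site,
                )
            )
    return files


def synth_bathymetry(
    slope_m_per_km: float = 50.0,
    extent_km: float = 12.0,
    cell_km: float = 0.1,
    sensors: dict[str, GeoPoint] | None = None,
    shore_offset_km: float = 0.5,
) -> BathymetryGrid:
    """Linear-slope bathymetry consistent with the synthetic coastline.

    depth = slope * (signed distance offshore of the coastline), so depth
    is negative (land) inshore and the 0-m isobath is exactly the scene's
    coastline; ``dist_to_isobath`` at 0 m then equals the analytic d_shore
    of the truth tables to within a cell width.
    """
    if slope_m_per_km <= 0:
        raise ValueError("slope must be positive")
    sensors = sensors or default_sensors()
    origin, along, offshore = shore_frame(sensors, shore_offset_km)
    half = extent_km / 2
    # axis-aligned lat/lon grid covering the strip
    corners = []
    for du in (-half, half):
        for dv in (-half, half):
            xy = along * du + offshore * dv
            corners.append(to_geo(LocalXY(float(xy[0]), float(xy[1]), origin)))
    lats = np.array([c.lat for c in corners])
    lons = np.array([c.lon for c in corners])
    km_per_deg = 2 * math.pi * 6371.0088 / 360.0
    dlat = cell_km / km_per_deg
    dlon = cell_km / (km_per_deg * math.cos(math.radians(origin.lat)))
    lat_ax = np.arange(lats.min(), lats.max() + dlat, dlat)
    lon_ax = np.arange(lons.min(), lons.max() + dlon, dlon)
    # signed offshore distance of every node, vectorized equirectangular
    lat2, lon2 = np.meshgrid(lat_ax, lon_ax, indexing="ij")
    x = (lon2 - origin.lon) * km_per_deg * math.cos(math.radians(origin.lat))
    y = (lat2 - origin.lat) * km_per_deg
    v = x * offshore[0] + y * offshore[1] + shore_offset_km
    depth = slope_m_per_km * v
    return BathymetryGrid(lat_ax, lon_ax, depth)
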