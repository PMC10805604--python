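"""Land-station theodolite and binocular-reticle survey geometry.

A shore observer on a hill of known height fixes whale pods either with a
surveyor's theodolite (vertical depression + horizontal angle) or, when a
theodolite fix is impossible, with a compass bearing and a count of
binocular reticles below the horizon. Both reduce to the same spherical
ray geometry: given eye height h above sea level and a depression angle
below the local horizontal, the line of sight meets the sea surface at a
ground range obtained from the triangle (earth centre, eye, target) on a
sphere of radius R (optionally inflated by a refraction coefficient k to
R/(1-k)). The position follows from the destination-point formula along
the fix azimuth.

Scan post-processing applies the survey's inclusion and rounding rules:
pods beyond 10 km are excluded, timestamps are rounded to the full hour
with an era-dependent rule (first survey era floors; second era rounds up
from minute 30), duplicate pod records within a scan are rejected, and
hourly medians of pod counts, shore distance and depth are produced pooled
and per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd

from .geo import (
    EARTH_RADIUS_KM,
    BathymetryGrid,
    GeoPoint,
    depth_at,
    destination_point,
    dist_to_isobath,
)

__all__ = [
    "Station",
    "PodSighting",
    "horizon_dip_deg",
    "horizon_distance_km",
    "range_from_depression",
    "depression_for_range",
    "theodolite_fix",
    "reticle_fix",
    "filter_and_round",
    "hourly_pod_medians",
]


@dataclass(frozen=True)
class Station:
    """Shore observation station."""

    position: GeoPoint
    eye_height_m: float
    reference_azimuth_deg: float = 0.0
    refraction_k: float = 0.0

    def __post_init__(self) -> None:
        if self.eye_height_m <= 0:
            raise ValueError("eye height must be positive")

    @property
    def effective_radius_km(self) -> float:
        return EARTH_RADIUS_KM / (1.0 - self.refraction_k)


@dataclass
class PodSighting:
    """One land-survey pod detection."""

    timestamp: datetime
    fix_kind: str  # "theodolite" | "reticle"
    pod_class: str  # "calf" | "non-calf"
    size_class: str  # "1" | "2" | "3+"
    position: GeoPoint
    d_station_km: float
    era: int = 1
    scan_id: str = ""
    pod_id: str = ""
    d_shore_km: float | None = None
    depth_m: float | None = None
    hour: int | None = None


def horizon_dip_deg(station: Station) -> float:
    """Angular dip of the visible sea horizon below the local horizontal."""
    R = station.effective_radius_km * 1000.0
    return math.degrees(math.acos(R / (R + station.eye_height_m)))


def horizon_distance_km(station: Station) -> float:
    """Great-circle distance from the station foot to the visible horizon."""
    R = station.effective_radius_km
    return R * math.acos(R / (R + station.eye_height_m / 1000.0))


def range_from_depression(station: Station, depression_deg: float) -> float:
    """Ground range (km) where a sight line at ``depression_deg`` below the
    horizontal meets the sea surface (spherical earth, eye-height corrected).

    In the triangle (earth centre O, eye E, sea-level target P):
    |OE| = R + h, |OP| = R, angle at E (from nadir) = 90 deg - depression;
    the near intersection has an obtuse angle at P, giving central angle
    gamma = asin((R+h) cos(depression) / R) - 90 deg + depression and ground
    range R * gamma. Raises for angles above the visible horizon dip.
    """
    dip = horizon_dip_deg(station)
    if depression_deg < dip - 1e-12:
        raise ValueError(
            f"depression {depression_deg:.4f} deg is above the visible horizon "
            f"(dip {dip:.4f} deg): target not on the sea surface"
        )
    R = station.effective_radius_km
    h = station.eye_height_m / 1000.0
    s = (R + h) * math.cos(math.radians(depression_deg)) / R
    s = min(1.0, s)
    gamma = math.radians(depression_deg) + math.asin(s) - math.pi / 2
    return R * gamma


def depression_for_range(station: Station, range_km: float) -> float:
    """Inverse of :func:`range_from_depression` (degrees below horizontal)."""
    if range_km <= 0:
        raise ValueError("range must be positive")
    R = station.effective_radius_km
    h = station.eye_height_m / 1000.0
    gamma = range_km / R
    # angle at eye between nadir and sight line, from the planar triangle
    x = R * math.sin(gamma)
    y = (R + h) - R * math.cos(gamma)
    return 90.0 - math.degrees(math.atan2(x, y))


def theodolite_fix(
    station: Station, vertical_angle_deg: float, horizontal_angle_deg: float
) -> tuple[GeoPoint, float]:
    """Convert a theodolite fix (depression below horizontal, horizontal
    angle from the station's reference azimuth) into a position and a
    station distance in km."""
    rng = range_from_depression(station, vertical_angle_deg)
    az = (station.reference_azimuth_deg + horizontal_angle_deg) % 360.0
    return destination_point(station.position, az, rng), rng


def reticle_fix(
    station: Station,
    compass_bearing_deg: float,
    reticles: float,
    reticle_angle_deg: float,
) -> tuple[GeoPoint, float]:
    """Convert a binocular 'non-fix' (compass bearing + reticles measured
    down from the horizon) into a position and station distance.

    Total depression = horizon dip + reticles * reticle_angle_deg; zero
    reticles place the target on the visible horizon.
    """
    if reticles < 0:
        raise ValueError("reticle count must be non-negative")
    dip = horizon_dip_deg(station)
    if reticles == 0 and dip == 0:
        raise ValueError("zero reticles with no horizon dip: range undefined")
    depression = dip + reticles * reticle_angle_deg
    rng = range_from_depression(station, depression)
    return destination_point(station.position, compass_bearing_deg % 360.0, rng), rng


def filter_and_round(
    sightings: list[PodSighting], max_range_km: float = 10.0
) -> list[PodSighting]:
    """Apply the survey inclusion and hour-rounding rules.

    Pods beyond ``max_range_km`` are dropped. Era-1 scans are floored to
    the hour; era-2 scans round up from minute 30 (minutes [30, 60) go to
    the next hour). A pod id recorded twice within one scan violates the
    no-double-count protocol and raises.
    """
    seen: set[tuple[str, str]] = set()
    for s in sightings:
        if s.scan_id and s.pod_id:
            key = (s.scan_id, s.pod_id)
            if key in seen:
                raise ValueError(f"pod {s.pod_id!r} recorded twice in scan {s.scan_id!r}")
            seen.add(key)
    out = []
    for s in sightings:
        if s.d_station_km > max_range_km:
            continue
        if s.era == 1:
            s.hour = s.timestamp.hour
        elif s.era == 2:
            s.hour = s.timestamp.hour + (1 if s.timestamp.minute >= 30 else 0)
        else:
            raise ValueError(f"unknown survey era {s.era}")
        out.append(s)
    return out


def _annotate(sightings: list[PodSighting], bathy: BathymetryGrid | None) -> None:
    if bathy is None:
        return
    for s in sightings:
        if s.depth_m is None:
            s.depth_m = depth_at(bathy, s.position)
        if s.d_shore_km is None:
            s.d_shore_km = dist_to_isobath(bathy, s.position, 0.0)


def hourly_pod_medians(
    sightings: list[PodSighting],
    bathy: BathymetryGrid | None = None,
    min_scans_per_day: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hourly medians of pod count, shore distance and depth.

    Survey days with fewer than ``min_scans_per_day`` completed scans are
    excluded. Returns (hourly, summary): ``hourly`` has one row per hour
    pooled over the dataset and per year (column ``year``, with "all" for
    the pooled rows); ``summary`` holds the first-vs-last-scan-hour
    differences of each median.
    """
    if not sightings:
        return pd.DataFrame(), pd.DataFrame()
    if any(s.hour is None for s in sightings):
        raise ValueError("run filter_and_round before hourly_pod_medians")
    _annotate(sightings, bathy)
    df = pd.DataFrame(
        {
            "date": [s.timestamp.date() for s in sightings],
            "year": [s.timestamp.year for s in sightings],
            "hour": [s.hour for s in sightings],
            "scan_id": [s.scan_id for s in sightings],
            "d_shore_km": [s.d_shore_km for s in sightings],
            "depth_m": [s.depth_m for s in sightings],
        }
    )
    scans_per_day = df.groupby("date")["scan_id"].nunique()
    good_days = scans_per_day[scans_per_day >= min_scans_per_day].index
    df = df[df["date"].isin(good_days)]
    if df.empty:
        return pd.DataFrame(), pd.DataFrame()

    def _hourly(sub: pd.DataFrame, label) -> pd.DataFrame:
        counts = sub.groupby(["date", "hour"]).size().rename("n_pods").reset_index()
        rows = []
        for h, grp in sub.groupby("hour"):
            rows.append(
                {
                    "year": label,
                    "hour": int(h),
                    "median_n_pods": float(counts[counts["hour"] == h]["n_pods"].median()),
                    "median_d_shore_km": float(grp["d_shore_km"].median())
                    if grp["d_shore_km"].notna().any()
                    else np.nan,
                    "median_depth_m": float(grp["depth_m"].median())
                    if grp["depth_m"].notna().any()
                    else np.nan,
                }
            )
        return pd.DataFrame(rows).sort_values("hour")

    parts = [_hourly(df, "all")] + [
        _hourly(g, str(y)) for y, g in df.groupby("year")
    ]
    hourly = pd.concat(parts, ignore_index=True)

    summaries = []
    for label, grp in hourly.groupby("year"):
        first = grp.iloc[grp["hour"].argmin()]
        last = grp.iloc[grp["hour"].argmax()]
        summaries.append(
            {
                "year": label,
                "first_hour": int(first["hour"]),
                "last_hour": int(last["hour"]),
                "diff_n_pods": last["median_n_pods"] - first["median_n_pods"],
                "diff_d_shore_km": last["median_d_shore_km"] - first["median_d_shore_km"],
                "diff_depth_m": last["median_depth_m"] - first["median_depth_m"],
            }
        )
    return hourly, pd.DataFrame(summaries)
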