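"""File readers and writers for the pipeline's tabular and audio formats.

WAV audio is read with :mod:`scipy.io.wavfile` (PCM-16/24/32); sensor and
station metadata come from small YAML files; azimuthal and localized tracks
travel as tidy CSV so externally (manually) traced tracks are first-class
inputs.
"""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .geo import GeoPoint
from .localization import AzimuthalTrack, LocalizedTrack
from .soundscape import RecordingFile

__all__ = [
    "read_wav_recording",
    "write_wav",
    "load_sensors_yaml",
    "load_station_yaml",
    "read_azimuthal_tracks_csv",
    "write_azimuthal_tracks_csv",
    "read_localized_tracks_csv",
    "write_localized_tracks_csv",
]


def read_wav_recording(path, meta: dict, t0: datetime | None = None) -> RecordingFile:
    """Read a PCM WAV file into a calibrated :class:`RecordingFile`.

    ``meta`` carries sensitivity (dB re 1 V/uPa), gain (dB),
    adc_fullscale_volts and optionally site; sample width is taken from the
    file.
    """
    fs, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    bits = {np.dtype("int16"): 16, np.dtype("int32"): 32}.get(data.dtype, 16)
    return RecordingFile(
        samples=np.asarray(data),
        fs=float(fs),
        t0=t0 or datetime(1970, 1, 1),
        sensitivity=float(meta["sensitivity"]),
        gain=float(meta.get("gain", 0.0)),
        adc_fullscale_volts=float(meta.get("adc_fullscale_volts", 2.0)),
        bits=bits,
        site=str(meta.get("site", "")),
    )


def write_wav(path, samples: np.ndarray, fs: float) -> None:
    """Write int16 PCM WAV (clipping values to the 16-bit range)."""
    s = np.clip(np.asarray(samples), -32768, 32767).astype(np.int16)
    wavfile.write(path, int(fs), s)


def load_sensors_yaml(path) -> dict[str, GeoPoint]:
    """Sensor table: mapping of id -> {lat, lon, [depth_m, orientation]}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {str(k): GeoPoint(float(v["lat"]), float(v["lon"])) for k, v in raw.items()}


def load_station_yaml(path):
    """Shore station: {lat, lon, eye_height_m, [reference_azimuth_deg,
    refraction_k]}."""
    from .shore_survey import Station

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return Station(
        position=GeoPoint(float(raw["lat"]), float(raw["lon"])),
        eye_height_m=float(raw["eye_height_m"]),
        reference_azimuth_deg=float(raw.get("reference_azimuth_deg", 0.0)),
        refraction_k=float(raw.get("refraction_k", 0.0)),
    )


def read_azimuthal_tracks_csv(path) -> dict[str, list[AzimuthalTrack]]:
    """CSV columns: track_id, sensor, epoch_s, azimuth_deg."""
    df = pd.read_csv(path)
    out: dict[str, list[AzimuthalTrack]] = {}
    for (sensor, tid), grp in df.groupby(["sensor", "track_id"]):
        grp = grp.sort_values("epoch_s")
        out.setdefault(str(sensor), []).append(
            AzimuthalTrack(
                sensor=str(sensor),
                epochs=grp["epoch_s"].to_numpy(float),
                azimuths=grp["azimuth_deg"].to_numpy(float),
                track_id=str(tid),
            )
        )
    return out


def write_azimuthal_tracks_csv(path, tracks_by_sensor: dict[str, list[AzimuthalTrack]]) -> None:
    rows = []
    for sensor, tracks in tracks_by_sensor.items():
        for t in tracks:
            for e, a in zip(t.epochs, t.azimuths):
                rows.append(
                    {"track_id": t.track_id, "sensor": sensor, "epoch_s": e, "azimuth_deg": a}
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_localized_tracks_csv(path) -> list[LocalizedTrack]:
    """CSV columns: track_id, epoch_s, lat, lon [, residual_deg]."""
    df = pd.read_csv(path)
    out = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("epoch_s")
        out.append(
            LocalizedTrack(
                track_id=str(tid),
                epochs=grp["epoch_s"].to_numpy(float),
                lats=grp["lat"].to_numpy(float),
                lons=grp["lon"].to_numpy(float),
                residuals_deg=grp["residual_deg"].to_numpy(float)
                if "residual_deg" in grp
                else None,
            )
        )
    return out


def write_localized_tracks_csv(path, tracks: list[LocalizedTrack]) -> None:
    rows = []
    for t in tracks:
        res = t.residuals_deg if t.residuals_deg is not None else [np.nan] * len(t)
        for e, la, lo, r in zip(t.epochs, t.lats, t.lons, res):
            rows.append(
                {"track_id": t.track_id, "epoch_s": e, "lat": la, "lon": lo, "residual_deg": r}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
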