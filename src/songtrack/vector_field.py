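"""Acoustic vector-sensor directional processing.

A vector sensor records pressure p(t) plus two orthogonal horizontal
particle-velocity channels (vx east, vy north). Per STFT bin the active
acoustic intensity

    Ix = Re{ conj(P) Vx },   Iy = Re{ conj(P) Vy }

points along the propagation direction, so the direction of arrival (from
the sensor toward the source) is atan2(Ix, Iy) in degrees clockwise from
true north after correcting for the sensor's mounting orientation. The
normalized transport velocity

    NTV = |<I>| / (c <E>),   E = |P|^2 / (2 rho c^2) + rho |V|^2 / 2

is 1 for a single plane wave and near 0 for diffuse or opposing fields, and
is used to gate azimuth estimates before binning them into azimuthal
histogram displays (AHDs): one azimuth histogram per 60-s epoch, in which a
continuously singing whale appears as a ridge over time. ``trace_tracks``
is an automated ridge-follower standing in for an analyst tracing those
ridges; externally traced track tables are equally accepted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .geo import GeoPoint

__all__ = ["VectorFrame", "Azigram", "AHD", "azigram", "ahd", "trace_tracks"]

RHO_SEAWATER = 1026.0  # kg m^-3
C_SEAWATER = 1500.0  # m s^-1


@dataclass
class VectorFrame:
    """Calibrated pressure + particle-velocity channels from one sensor.

    ``orientation_offset`` rotates raw sensor axes onto true north (degrees,
    added to the raw azimuth estimate).
    """

    p: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    fs: float
    sensor: GeoPoint | None = None
    orientation_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (len(self.p) == len(self.vx) == len(self.vy)):
            raise ValueError("p, vx, vy must have equal length")


@dataclass
class Azigram:
    """Per-STFT-bin azimuth (deg cw from north, [0, 360)) and NTV in [0, 1]."""

    times: np.ndarray
    freqs: np.ndarray
    azimuth: np.ndarray  # (n_freqs, n_times)
    ntv: np.ndarray  # (n_freqs, n_times)


@dataclass
class AHD:
    """Azimuthal histogram display: azimuth counts per fixed-length epoch."""

    epoch_starts: np.ndarray  # seconds
    bin_edges: np.ndarray  # degrees, 0..360
    counts: np.ndarray  # (n_epochs, n_bins) ints
    epoch_s: float = 60.0


def azigram(
    frame: VectorFrame,
    nfft: int = 1024,
    overlap: float = 0.5,
    avg_frames: int = 8,
    rho: float = RHO_SEAWATER,
    c: float = C_SEAWATER,
) -> Azigram:
    """Azigram of a vector-sensor record (Hann window, default 50% overlap).

    Active intensity and energy density are block-averaged over
    ``avg_frames`` consecutive STFT frames before forming NTV and azimuth:
    the instantaneous intensity of a *diffuse* field in a single bin is
    O(1) relative to its energy, so only the averaged transport ratio
    separates directional sources (NTV -> 1) from isotropic noise
    (NTV -> ~M^-1/2 for M averaged frames). NTV is bounded by 1 (AM-GM);
    values exceeding 1 + 1e-6 indicate a numerical inconsistency and raise
    rather than being silently clipped.
    """
    noverlap = int(nfft * overlap)
    kw = dict(fs=frame.fs, window="hann", nperseg=nfft, noverlap=noverlap, boundary=None)
    f, t, P = signal.stft(frame.p, **kw)
    _, _, Vx = signal.stft(frame.vx, **kw)
    _, _, Vy = signal.stft(frame.vy, **kw)

    ix = np.real(np.conj(P) * Vx)
    iy = np.real(np.conj(P) * Vy)
    energy = np.abs(P) ** 2 / (2 * rho * c**2) + rho * (np.abs(Vx) ** 2 + np.abs(Vy) ** 2) / 2
    if avg_frames > 1 and ix.shape[1] > 1:
        avg_frames = min(avg_frames, ix.shape[1])
        nblk = ix.shape[1] // avg_frames
        keep = nblk * avg_frames

        def blocks(a):
            return a[:, :keep].reshape(a.shape[0], nblk, avg_frames).mean(axis=2)

        ix, iy, energy = blocks(ix), blocks(iy), blocks(energy)
        t = t[:keep].reshape(nblk, avg_frames).mean(axis=1)
    inten = np.hypot(ix, iy)
    with np.errstate(invalid="ignore", divide="ignore"):
        ntv = inten / (c * energy)
    ntv = np.where(energy > 0, ntv, 0.0)
    if np.any(ntv > 1 + 1e-6):
        raise ValueError(
            f"NTV {np.max(ntv):.6f} exceeds 1: pressure/velocity channels are "
            "not in consistent units"
        )
    ntv = np.clip(ntv, 0.0, 1.0)
    az = (np.degrees(np.arctan2(ix, iy)) + frame.orientation_offset) % 360.0
    return Azigram(times=t, freqs=f, azimuth=az, ntv=ntv)


def ahd(
    az: Azigram,
    ntv_threshold: float = 0.75,
    bin_deg: float = 2.0,
    epoch_s: float = 60.0,
    f_lo: float = 0.0,
    f_hi: float = np.inf,
) -> AHD:
    """Bin NTV-gated azimuths into per-epoch histograms.

    Only time-frequency bins with NTV >= ``ntv_threshold`` (default 0.75)
    and frequency within [f_lo, f_hi] contribute; counts per epoch therefore
    sum to the number of gated bins in that epoch.
    """
    if not 0.0 <= ntv_threshold <= 1.0:
        raise ValueError("ntv_threshold must be in [0, 1]")
    edges = np.arange(0.0, 360.0 + bin_deg / 2, bin_deg)
    fmask = (az.freqs >= f_lo) & (az.freqs <= f_hi)
    t_end = az.times[-1] if len(az.times) else 0.0
    starts = np.arange(0.0, t_end + 1e-9, epoch_s)
    counts = np.zeros((len(starts), len(edges) - 1), dtype=int)
    epoch_idx = np.minimum((az.times / epoch_s).astype(int), len(starts) - 1)
    for k in range(len(starts)):
        tmask = epoch_idx == k
        if not tmask.any():
            continue
        sel = az.ntv[np.ix_(fmask, tmask)] >= ntv_threshold
        vals = az.azimuth[np.ix_(fmask, tmask)][sel]
        counts[k], _ = np.histogram(vals, bins=edges)
    return AHD(epoch_starts=starts, bin_edges=edges, counts=counts, epoch_s=epoch_s)


def _circ_diff(a: float, b: float) -> float:
    return (a - b + 180.0) % 360.0 - 180.0


def trace_tracks(
    display: AHD,
    max_step_deg: float = 5.0,
    gap_max: int = 5,
    min_count: int | None = None,
    min_length: int = 5,
) -> list["AzimuthalTrack"]:
    """Automated ridge-following over an AHD.

    Per-epoch peaks (prominence above ``min_count``, default 5x the median
    non-zero bin count or 5, whichever is larger) are linked across epochs
    when the azimuth moves by at most ``max_step_deg`` per epoch; gaps of up
    to ``gap_max`` epochs (surfacings) are bridged. Where two candidate
    peaks compete for one track the nearer is taken and the other starts a
    new track, mirroring conservative manual tracing that splits crossing
    tracks. Tracks shorter than ``min_length`` epochs are discarded.
    """
    from .localization import AzimuthalTrack

    centers = 0.5 * (display.bin_edges[:-1] + display.bin_edges[1:])
    if min_count is None:
        # ridge bins carry the bulk of an epoch's counts; peaks below ~30%
        # of a typical epoch maximum are treated as background
        epoch_max = display.counts.max(axis=1)
        min_count = max(5, int(0.3 * np.median(epoch_max)))

    # active tracks: list of dict(last_epoch, last_az, epochs[], azs[])
    active: list[dict] = []
    done: list[dict] = []
    for k, row in enumerate(display.counts):
        # circular peak detection: pad the histogram row
        ext = np.concatenate([row[-3:], row, row[:3]])
        pk, _ = signal.find_peaks(ext, height=min_count)
        pk = pk - 3
        peaks = sorted({centers[p % len(centers)] for p in pk})
        # drop exhausted tracks
        still = []
        for tr in active:
            if k - tr["last_epoch"] > gap_max:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        # greedy nearest association, one peak per track
        used = set()
        for tr in sorted(active, key=lambda t: t["last_epoch"], reverse=True):
            best, bestd = None, None
            for az in peaks:
                if az in used:
                    continue
                gap = k - tr["last_epoch"]
                d = abs(_circ_diff(az, tr["last_az"]))
                if d <= max_step_deg * gap and (bestd is None or d < bestd):
                    best, bestd = az, d
            if best is not None:
                used.add(best)
                tr["epochs"].append(k)
                tr["azs"].append(best)
                tr["last_epoch"] = k
                tr["last_az"] = best
        for az in peaks:
            if az not in used:
                active.append(
                    {"last_epoch": k, "last_az": az, "epochs": [k], "azs": [az]}
                )
    done.extend(active)

    tracks = []
    for i, tr in enumerate(t for t in done if len(t["epochs"]) >= min_length):
        epochs = display.epoch_starts[np.asarray(tr["epochs"], dtype=int)]
        tracks.append(
            AzimuthalTrack(
                sensor="",
                epochs=np.asarray(epochs, dtype=float),
                azimuths=np.asarray(tr["azs"], dtype=float),
                track_id=f"ahd-{i}",
            )
        )
    return tracks
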