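"""Duty-cycled hydrophone (EAR-style) soundscape metrics.

Processing chain for bottom-moored omnidirectional recorders sampling on a
duty cycle (by default 30 s of audio every 5 min): instrument calibration
from 16-bit counts to micropascals, anti-aliased downsampling, 1-octave band
splitting, per-file root-mean-square sound pressure level

    RMS SPL = 20 log10( sqrt( (1/T) * integral p(t)^2 dt ) )   [dB re 1 uPa]

hourly medians per site/band (the median suppresses intermittent
high-intensity transients such as passing vessels), min/max/delta-dB
summaries per month or season, and long-time spectral averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "RecordingFile",
    "BandLevelRecord",
    "DeltaDbSummary",
    "counts_to_micropascal",
    "downsample",
    "rms_spl",
    "octave_bands",
    "band_label",
    "bandpass",
    "hourly_median",
    "delta_db",
    "spectral_average",
]

_SEASONS = {12: "early", 1: "early", 2: "peak", 3: "peak", 4: "late"}


@dataclass
class RecordingFile:
    """One duty-cycle audio file with its calibration metadata.

    ``samples`` are raw integer ADC counts; ``sensitivity`` is the hydrophone
    sensitivity in dB re 1 V/uPa (a large negative number, e.g. -193.5),
    ``gain`` any additional amplifier gain in dB, and ``adc_fullscale_volts``
    the voltage mapped to full-scale counts.
    """

    samples: np.ndarray
    fs: float
    t0: datetime
    sensitivity: float
    gain: float = 0.0
    adc_fullscale_volts: float = 2.0
    bits: int = 16
    site: str = ""

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


def counts_to_micropascal(rec: RecordingFile) -> np.ndarray:
    """Convert raw ADC counts to a pressure series in micropascals.

    counts -> volts via the ADC full-scale mapping, gain removed, then volts
    -> uPa through the hydrophone sensitivity (dB re 1 V/uPa).
    """
    if rec.sensitivity is None:
        raise ValueError("hydrophone sensitivity required for calibration")
    counts = np.asarray(rec.samples, dtype=float)
    volts = counts * (rec.adc_fullscale_volts / 2 ** (rec.bits - 1)) * 10 ** (-rec.gain / 20)
    return volts / 10 ** (rec.sensitivity / 20)


def downsample(p: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Anti-aliased downsampling to ``target_fs`` (polyphase resampling).

    A zero-phase low-pass at 0.45 * target_fs precedes the rate change so
    energy above the new Nyquist is strongly attenuated; non-integer rate
    ratios are handled by polyphase resampling.
    """
    if target_fs > fs:
        raise ValueError("target_fs must not exceed fs")
    if target_fs == fs:
        return np.asarray(p, dtype=float)
    sos = signal.butter(8, 0.45 * target_fs, btype="low", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, np.asarray(p, dtype=float))
    from fractions import Fraction

    frac = Fraction(target_fs / fs).limit_denominator(1000)
    return signal.resample_poly(filtered, frac.numerator, frac.denominator)


def rms_spl(p: np.ndarray, T: float | None = None) -> float:
    """RMS sound pressure level of a calibrated series, dB re 1 uPa.

    ``T`` is accepted for interface symmetry but the discrete mean square
    already normalises by duration. An all-zero series has no defined level
    and returns ``-inf`` (treated as missing downstream).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty pressure series")
    ms = float(np.mean(p**2))
    if ms == 0.0:
        return -math.inf
    return 10.0 * math.log10(ms)


def octave_bands(fullband_nyquist: float, floor_hz: float = 20.0) -> list[tuple[float, float]]:
    """1-octave band edges (lo, hi) Hz, halving downward from the Nyquist.

    Bands are (ny/2, ny), (ny/4, ny/2), ... until the lower edge would fall
    below ``floor_hz``; every band satisfies hi = 2 * lo. For a 25 kHz
    recording (12.5 kHz Nyquist) the third band is 1.5625-3.125 kHz,
    displayed as "1.56-3.12 kHz".
    """
    if fullband_nyquist <= 0:
        raise ValueError("nyquist must be positive")
    bands = []
    hi = float(fullband_nyquist)
    while hi / 2 >= floor_hz:
        bands.append((hi / 2, hi))
        hi /= 2
    return bands


def band_label(lo: float, hi: float) -> str:
    """Display label for a band, edges truncated to 2 decimals in kHz."""

    def t(v: float) -> str:
        return f"{math.floor(v / 10) / 100:.2f}"

    return f"{t(lo)}-{t(hi)} kHz"


def bandpass(p: np.ndarray, fs: float, lo: float, hi: float, order: int = 8) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, flat passband)."""
    nyq = fs / 2
    hi = min(hi, nyq * 0.999999)
    if lo <= 0:
        sos = signal.butter(order, hi, btype="low", fs=fs, output="sos")
    else:
        sos = signal.butter(order, [lo, hi], btype="band", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(p, dtype=float))


@dataclass(frozen=True)
class BandLevelRecord:
    """Median band level for one site-date-hour."""

    site: str
    date: object  # datetime.date
    hour: int
    band: str
    spl_db: float
    n_files: int


def hourly_median(
    levels: Iterable[tuple[datetime, float]],
    site: str = "",
    band: str = "",
) -> list[BandLevelRecord]:
    """Median per-file level for each hour of each day.

    ``levels`` are (timestamp, dB) pairs for one site and band; -inf entries
    (silent files) are dropped as missing, and hours with no valid file emit
    no record.
    """
    rows = [(ts, v) for ts, v in levels if np.isfinite(v)]
    if not rows:
        return []
    df = pd.DataFrame(rows, columns=["t", "db"])
    df["date"] = df["t"].map(lambda t: t.date())
    df["hour"] = df["t"].map(lambda t: t.hour)
    out = []
    for (date, hour), grp in df.groupby(["date", "hour"], sort=True):
        out.append(
            BandLevelRecord(
                site=site,
                date=date,
                hour=int(hour),
                band=band,
                spl_db=float(grp["db"].median()),
                n_files=len(grp),
            )
        )
    return out


@dataclass(frozen=True)
class DeltaDbSummary:
    """Min/max spread of hourly medians over a period; delta = min - max <= 0."""

    period: str
    min_db: float
    max_db: float

    @property
    def delta_db(self) -> float:
        return self.min_db - self.max_db


def delta_db(records: Sequence[BandLevelRecord], period: str = "month") -> list[DeltaDbSummary]:
    """Min, max and their (negative) difference per month or per season.

    ``period``: "month" groups by calendar year-month; "season" pools
    December-April into one breeding season labelled by its peak year
    (December belongs to the following year's season).
    """
    if not records:
        return []

    def key(r: BandLevelRecord) -> str:
        if period == "month":
            return f"{r.date.year}-{r.date.month:02d}"
        if period == "season":
            return str(r.date.year + 1 if r.date.month == 12 else r.date.year)
        raise ValueError(f"unknown period {period!r}")

    df = pd.DataFrame({"k": [key(r) for r in records], "db": [r.spl_db for r in records]})
    return [
        DeltaDbSummary(period=k, min_db=float(g.min()), max_db=float(g.max()))
        for k, g in df.groupby("k")["db"]
    ]


def spectral_average(
    p: np.ndarray, fs: float, win_s: float = 1.0, avg_s: float = 60.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Long-time spectral average: Welch PSD per ``avg_s`` block.

    Returns (block start times s, frequencies Hz, dB matrix of shape
    blocks x freqs) in dB re 1 uPa^2/Hz. ``win_s`` sets the Welch segment
    length, so frequency resolution is 1/win_s Hz.
    """
    if avg_s < win_s:
        raise ValueError("avg_s must be >= win_s")
    p = np.asarray(p, dtype=float)
    nper = int(round(win_s * fs))
    nblock = int(round(avg_s * fs))
    nblocks = len(p) // nblock
    if nblocks == 0:
        raise ValueError("series shorter than one averaging block")
    rows = []
    for i in range(nblocks):
        f, pxx = signal.welch(p[i * nblock : (i + 1) * nblock], fs=fs, nperseg=nper)
        rows.append(pxx)
    mat = np.asarray(rows)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(mat)
    times = np.arange(nblocks) * avg_s
    return times, f, db
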