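"""Substrate-vibration metrics for impulsive (impact-hammer) and continuous
(vibratory-hammer) seabed-acceleration records.

All scalar levels are computed on the orientation-invariant vector magnitude
``m(t) = sqrt(x^2 + y^2 + z^2)`` of the triaxial acceleration, in µm s^-2.
Levels are expressed in dB re 1 µm s^-2 (amplitudes) or dB re
(1 µm s^-2)^2 s (exposure, i.e. time-integrated squared acceleration).

Impulsive metrics follow standard impulsive-noise metrology: the "90% energy
window" of a pulse is the interval between the 5% and 95% points of its
cumulative energy, and single-strike exposure (SEL_ss) integrates m^2 over
that window.  Cumulative exposure over a pile-driving event (SEL_cum) sums
single-strike exposures in the intensity domain.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

__all__ = [
    "TriaxialSeries",
    "StrikeEvent",
    "PulseMetrics",
    "EventSummary",
    "PsdResult",
    "SignalAbsentError",
    "amplitude_to_db",
    "db_to_amplitude",
    "detect_strikes",
    "pulse_metrics",
    "sel_cum",
    "vh_metrics",
    "ambient_level",
    "psd",
    "event_summary",
]

#: dB reference amplitude, 1 µm s^-2.
DB_REF = 1.0

_EPOCH = datetime(2021, 9, 11, tzinfo=timezone.utc)


class SignalAbsentError(ValueError):
    """Raised when a level is requested from an all-zero window."""


def amplitude_to_db(a: float | np.ndarray) -> float | np.ndarray:
    """Convert an acceleration amplitude (µm s^-2) to dB re 1 µm s^-2."""
    return 20.0 * np.log10(np.asarray(a) / DB_REF)


def db_to_amplitude(db: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`amplitude_to_db`."""
    return DB_REF * 10.0 ** (np.asarray(db) / 20.0)


@dataclass
class TriaxialSeries:
    """Timestamped three-axis seabed-acceleration record.

    Axes are one vertical and two horizontal channels in µm s^-2, sampled
    uniformly at ``fs`` Hz starting at ``start_time``.
    """

    fs: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    start_time: datetime = _EPOCH
    site: str = ""
    distance_m: Optional[float] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        n = len(self.x)
        if n < 2 or len(self.y) != n or len(self.z) != n:
            raise ValueError("axes must have equal length >= 2")
        for name, arr in (("x", self.x), ("y", self.y), ("z", self.z)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in axis {name}")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def duration(self) -> float:
        """Record length in seconds (n samples at fs)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds since record start."""
        return np.arange(self.n) / self.fs

    @property
    def magnitude(self) -> np.ndarray:
        """Vector magnitude sqrt(x^2 + y^2 + z^2)."""
        return np.sqrt(self.x**2 + self.y**2 + self.z**2)


@dataclass(frozen=True)
class StrikeEvent:
    """One detected impact-hammer strike: onset and its analysis window."""

    onset: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        t0, t1 = self.window
        if not (t0 < self.onset <= t1):
            raise ValueError(
                f"window must satisfy t_start < onset <= t_end, got {t0}, {self.onset}, {t1}"
            )


@dataclass(frozen=True)
class PulseMetrics:
    """Per-strike impulsive-vibration metrics.

    peak_level_db
        0-peak acceleration level, 20 log10(max m), dB re 1 µm s^-2.
    pulse_duration_s
        Time for the magnitude to rise from 5% to 90% of its maximum.
    rise_time_s
        Time from the 5% cumulative-energy point to the magnitude peak.
    sel_ss_db
        Single-strike exposure level over the 90% energy window,
        dB re (1 µm s^-2)^2 s.
    energy_window
        [t5, t95] cumulative-energy interval, seconds since record start.
    """

    peak_level_db: float
    pulse_duration_s: float
    rise_time_s: float
    sel_ss_db: float
    energy_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.pulse_duration_s < 0 or self.rise_time_s < 0:
            raise ValueError("durations must be >= 0")
        if not self.energy_window[0] < self.energy_window[1]:
            raise ValueError("energy window must satisfy t5 < t95")


@dataclass(frozen=True)
class EventSummary:
    """Per-event (strike train) summary statistics."""

    n_strikes: int
    ipi_mean_s: float
    ipi_sd_s: float
    sel_cum_db: float
    peak_level_db_mean: float
    peak_level_db_sd: float
    pulse_duration_s_mean: float
    pulse_duration_s_sd: float
    rise_time_s_mean: float
    rise_time_s_sd: float
    sel_ss_db_mean: float
    sel_ss_db_sd: float


@dataclass(frozen=True)
class PsdResult:
    """Welch power spectral densities per recording axis."""

    freqs: np.ndarray
    psd_x: np.ndarray
    psd_y: np.ndarray
    psd_z: np.ndarray
    segment_s: float
    overlap: float


# ---------------------------------------------------------------------------
# strike detection
# ---------------------------------------------------------------------------

def _envelope(m: np.ndarray, fs: float, smooth_s: float = 0.05) -> np.ndarray:
    """Short-window moving-RMS envelope of the magnitude trace."""
    win = max(1, int(round(smooth_s * fs)))
    return np.sqrt(uniform_filter1d(m * m, size=win, mode="nearest"))


def _ambient_rms(m: np.ndarray, fs: float, frame_s: float = 1.0,
                 quietest_fraction: float = 0.1) -> float:
    """Ambient RMS estimated from the lowest-energy fraction of 1-s frames."""
    nf = int(round(frame_s * fs))
    nframes = len(m) // nf
    if nframes < 1:
        raise ValueError("record too short to estimate ambient level")
    frame_power = (m[: nframes * nf] ** 2).reshape(nframes, nf).mean(axis=1)
    k = max(1, int(quietest_fraction * nframes))
    return float(np.sqrt(np.sort(frame_power)[:k].mean()))


def detect_strikes(
    series: TriaxialSeries,
    threshold_db_above_ambient: float = 12.0,
    min_separation_s: float = 1.0,
) -> list[StrikeEvent]:
    """Detect impact-hammer strikes in a triaxial record.

    Strikes are local maxima of the moving-RMS envelope of the vector
    magnitude that exceed the ambient level (estimated from the quietest 10%
    of 1-s frames) by ``threshold_db_above_ambient`` dB, separated by at
    least ``min_separation_s``.  Each event is assigned a window
    ``[onset - 0.5 s, onset + min(2 s, next onset - 0.25 s)]``.
    """
    if series.duration < 10.0:
        raise ValueError("record must be at least 10 s for strike detection")
    if threshold_db_above_ambient <= 0:
        raise ValueError("threshold must be positive")
    m = series.magnitude
    env = _envelope(m, series.fs)
    amb = _ambient_rms(m, series.fs)
    if amb == 0.0:
        # all-zero quiet frames: fall back to an absolute floor so pulses on
        # silence are still detectable
        amb = np.finfo(float).tiny
    thr = amb * 10.0 ** (threshold_db_above_ambient / 20.0)
    distance = max(1, int(round(min_separation_s * series.fs)))
    peaks, _ = sps.find_peaks(env, height=thr, distance=distance)
    # refine each onset from the envelope maximum back to the threshold
    # crossing (bounded at 0.5 s), which tracks the pulse front
    back = int(round(0.5 * series.fs))
    refined = []
    for p in peaks:
        j = p
        while j > 0 and j > p - back and env[j - 1] >= thr:
            j -= 1
        refined.append(j)
    onsets = np.asarray(refined) / series.fs
    events: list[StrikeEvent] = []
    for i, onset in enumerate(onsets):
        t0 = max(0.0, onset - 0.5)
        if t0 >= onset:  # peak in the very first sample
            continue
        if i + 1 < len(onsets):
            t1 = onset + min(2.0, onsets[i + 1] - onset - 0.25)
        else:
            t1 = onset + 2.0
        t1 = min(t1, series.duration - 1.0 / series.fs)
        if t1 <= onset:
            t1 = min(onset + 1.0 / series.fs, series.duration)
        events.append(StrikeEvent(onset=float(onset), window=(float(t0), float(t1))))
    return events


# ---------------------------------------------------------------------------
# pulse metrics
# ---------------------------------------------------------------------------

def _first_crossing_time(t: np.ndarray, m: np.ndarray, level: float) -> float:
    """Time of the first upward crossing of ``level``, linearly interpolated."""
    above = m >= level
    idx = int(np.argmax(above))
    if not above[idx]:
        raise ValueError("signal never reaches the requested level")
    if idx == 0 or m[idx] == m[idx - 1]:
        return float(t[idx])
    frac = (level - m[idx - 1]) / (m[idx] - m[idx - 1])
    return float(t[idx - 1] + frac * (t[idx] - t[idx - 1]))


def _energy_fraction_time(t: np.ndarray, e_cum: np.ndarray, fraction: float) -> float:
    """Time at which cumulative energy reaches ``fraction`` of its total."""
    target = fraction * e_cum[-1]
    idx = int(np.searchsorted(e_cum, target))
    if idx == 0:
        return float(t[0])
    d = e_cum[idx] - e_cum[idx - 1]
    frac = 0.0 if d == 0 else (target - e_cum[idx - 1]) / d
    return float(t[idx - 1] + frac * (t[idx] - t[idx - 1]))


def pulse_metrics(series: TriaxialSeries, event: StrikeEvent) -> PulseMetrics:
    """Compute the impulsive metrics of one strike.

    Pulse duration is the first-crossing interval from 5% to 90% of the
    maximum magnitude; rise time runs from the 5% cumulative-energy point to
    the magnitude peak; SEL_ss integrates m^2 (trapezoidal rule) over the
    5–95% cumulative-energy window, which by construction holds 90% of the
    pulse energy.
    """
    t0, t1 = event.window
    if t0 < 0 or t1 > series.duration:
        raise ValueError("event window extends outside the record")
    i0 = int(round(t0 * series.fs))
    i1 = int(round(t1 * series.fs)) + 1
    m = series.magnitude[i0:i1]
    t = np.arange(i0, i0 + len(m)) / series.fs
    peak = float(m.max())
    if peak == 0.0:
        raise SignalAbsentError("all-zero window: level undefined")
    peak_level_db = float(amplitude_to_db(peak))

    t05 = _first_crossing_time(t, m, 0.05 * peak)
    t90 = _first_crossing_time(t, m, 0.90 * peak)
    pulse_duration = t90 - t05

    dt = 1.0 / series.fs
    # cumulative trapezoidal energy of m^2
    e_inc = 0.5 * (m[1:] ** 2 + m[:-1] ** 2) * dt
    e_cum = np.concatenate([[0.0], np.cumsum(e_inc)])
    t5 = _energy_fraction_time(t, e_cum, 0.05)
    t95 = _energy_fraction_time(t, e_cum, 0.95)
    t_peak = float(t[int(np.argmax(m))])
    rise_time = max(0.0, t_peak - t5)
    energy_90 = 0.90 * e_cum[-1]
    sel_ss_db = float(10.0 * np.log10(energy_90))

    return PulseMetrics(
        peak_level_db=peak_level_db,
        pulse_duration_s=float(pulse_duration),
        rise_time_s=float(rise_time),
        sel_ss_db=sel_ss_db,
        energy_window=(t5, t95),
    )


def sel_cum(metrics: Sequence[PulseMetrics] | Sequence[float]) -> float:
    """Cumulative strike exposure level: 10 log10 of summed strike energies."""
    if len(metrics) == 0:
        raise ValueError("cannot accumulate an empty strike list")
    sels = np.array(
        [m.sel_ss_db if isinstance(m, PulseMetrics) else float(m) for m in metrics]
    )
    return float(10.0 * np.log10(np.sum(10.0 ** (sels / 10.0))))


def vh_metrics(series: TriaxialSeries) -> tuple[float, float]:
    """RMS level and exposure level of a continuous (vibratory) record.

    Both are evaluated inside the 5–95% cumulative-energy window of the
    vector magnitude: ``rms_level_db = 20 log10(RMS within the window)`` and
    ``sel_ss_db = 10 log10(energy within the window)``.
    """
    if series.duration < 1.0:
        raise ValueError("record must be at least 1 s")
    m = series.magnitude
    if np.all(m == 0.0):
        raise SignalAbsentError("all-zero record")
    t = series.times
    dt = 1.0 / series.fs
    e_inc = 0.5 * (m[1:] ** 2 + m[:-1] ** 2) * dt
    e_cum = np.concatenate([[0.0], np.cumsum(e_inc)])
    t5 = _energy_fraction_time(t, e_cum, 0.05)
    t95 = _energy_fraction_time(t, e_cum, 0.95)
    energy_90 = 0.90 * e_cum[-1]
    rms = np.sqrt(energy_90 / (t95 - t5))
    return float(amplitude_to_db(rms)), float(10.0 * np.log10(energy_90))


def ambient_level(series: TriaxialSeries) -> float:
    """RMS level (dB re 1 µm s^-2) of the vector magnitude over the record."""
    m = series.magnitude
    rms = float(np.sqrt(np.mean(m * m)))
    if rms == 0.0:
        raise SignalAbsentError("all-zero record")
    return float(amplitude_to_db(rms))


def psd(series: TriaxialSeries, segment_s: float = 1.0, overlap: float = 0.5) -> PsdResult:
    """Welch-averaged one-sided PSD per axis (Hann window, density scaling)."""
    nperseg = int(round(segment_s * series.fs))
    if nperseg < 8:
        raise ValueError("segment must contain at least 8 samples")
    if nperseg > series.n:
        raise ValueError("segment longer than record")
    noverlap = int(nperseg * overlap)
    out = {}
    for name in ("x", "y", "z"):
        f, p = sps.welch(
            getattr(series, name), fs=series.fs, window="hann",
            nperseg=nperseg, noverlap=noverlap, detrend="constant",
            scaling="density",
        )
        out[name] = p
    return PsdResult(freqs=f, psd_x=out["x"], psd_y=out["y"], psd_z=out["z"],
                     segment_s=segment_s, overlap=overlap)


def event_summary(series: TriaxialSeries, events: Sequence[StrikeEvent]) -> EventSummary:
    """Summarize a detected strike train: IPI statistics, SEL_cum, and
    per-metric means/SDs across strikes."""
    if len(events) == 0:
        raise ValueError("no strikes to summarize")
    metrics = [pulse_metrics(series, ev) for ev in events]
    onsets = np.array([ev.onset for ev in events])
    ipis = np.diff(onsets)
    def _ms(vals):
        v = np.asarray(vals)
        return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0
    pk_m, pk_s = _ms([m.peak_level_db for m in metrics])
    pd_m, pd_s = _ms([m.pulse_duration_s for m in metrics])
    rt_m, rt_s = _ms([m.rise_time_s for m in metrics])
    se_m, se_s = _ms([m.sel_ss_db for m in metrics])
    return EventSummary(
        n_strikes=len(events),
        ipi_mean_s=float(ipis.mean()) if len(ipis) else 0.0,
        ipi_sd_s=float(ipis.std(ddof=1)) if len(ipis) > 1 else 0.0,
        sel_cum_db=sel_cum(metrics),
        peak_level_db_mean=pk_m, peak_level_db_sd=pk_s,
        pulse_duration_s_mean=pd_m, pulse_duration_s_sd=pd_s,
        rise_time_s_mean=rt_m, rise_time_s_sd=rt_s,
        sel_ss_db_mean=se_m, sel_ss_db_sd=se_s,
    )
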