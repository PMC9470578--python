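"""Seeded synthetic geophone, biologging-tag, and annotation datasets.

The generator emulates the statistical structure of a coastal pile-driving
exposure experiment on scallops:

* impact-hammer (IH) strike trains — exponentially decaying 10-Hz sinusoid
  pulses over a Gaussian ambient floor, with truncated-normal inter-pulse
  intervals and per-strike peak levels normal in dB;
* vibratory-hammer (VH) signals — band-limited Gaussian noise whose
  vector-magnitude RMS is set exactly to the requested level;
* valve-angle tag records — a smooth 24-h diel cycle (nocturnal maximum),
  strike-triggered partial closures with exponential recovery, exposure-window
  depression, and a linear magnetometer forward model, plus a 25-Hz
  accelerometer stream carrying scaled strike pulses for synchronization;
* behavioral annotation tables — Poisson event streams per individual and
  treatment.

Every generator returns ground truth (exact strike onsets, closure events,
underlying circadian period) alongside the data so that downstream detectors
and estimators can be scored against it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .vibration import TriaxialSeries, db_to_amplitude, _EPOCH
from .tag import EXPOSURE_LABELS as EXPOSURE_LABELS_
from .tag import ExposureSchedule, TagRecord

__all__ = [
    "SimConfig",
    "GroundTruth",
    "gen_ih_train",
    "gen_vh_signal",
    "gen_tag_record",
    "gen_annotations",
    "gen_angle_observations",
]

_SQ3 = 1.0 / math.sqrt(3.0)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study conditions.

    Defaults reproduce the near-site field conditions: ambient floor
    ~54 dB re 1 µm s^-2, IH peaks ~110 dB centered at 10 Hz arriving every
    ~6.6 s, VH levels of 86 dB in the 10–100 Hz band, a daytime valve angle
    of ~7.3° depressed to ~5.5° during exposure, and strike-triggered
    closures answering about half of the strikes.
    """

    seed: int = 0
    fs_geo: float = 200.0
    fs_mag: float = 2.0
    fs_acc: float = 25.0
    ambient_rms_db: Optional[float] = 53.86
    ih_peak_db: float = 109.95
    ih_peak_sd_db: float = 1.25
    ih_center_freq: float = 10.0
    ih_decay_tau: float = 0.15
    ipi_mean: float = 6.63
    ipi_sd: float = 0.61
    ipi_floor: float = 0.5
    vh_rms_db: float = 86.00
    vh_band: tuple[float, float] = (10.0, 100.0)
    day_angle_mean: float = 7.34
    night_angle_mean: float = 9.5
    exposure_angle_mean: float = 5.52
    exposure_ramp_s: float = 60.0
    closure_prob: float = 0.51
    closure_depth: float = 2.2
    closure_recovery_tau: float = 5.0
    angle_noise_sd: float = 0.5
    sunset_hour: float = 19.0
    sunrise_hour: float = 6.5
    diel_transition_h: float = 1.0
    mag_offset_mv: float = 400.0
    mag_slope_mv_per_deg: float = 20.0
    mag_noise_sd_mv: float = 2.0
    acc_noise_sd: float = 0.01
    acc_pulse_amp: float = 1.0
    direction_cosines: tuple[float, float, float] = (_SQ3, _SQ3, _SQ3)

    def __post_init__(self) -> None:
        for name in ("fs_geo", "fs_mag", "fs_acc"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.closure_prob <= 1.0:
            raise ValueError("closure_prob must lie in [0, 1]")
        if self.night_angle_mean < self.day_angle_mean:
            raise ValueError("night_angle_mean must be >= day_angle_mean "
                             "(valve opening peaks at night)")
        if not self.ipi_mean > 0:
            raise ValueError("ipi_mean must be positive")
        f1, f2 = self.vh_band
        if not 0 < f1 < f2:
            raise ValueError(f"invalid vibratory band {self.vh_band}")
        csq = sum(c * c for c in self.direction_cosines)
        if abs(csq - 1.0) > 1e-9:
            raise ValueError("direction cosines must have unit norm")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Exact event lists underlying a generated record."""

    strike_times: np.ndarray
    closure_events: list[tuple[float, float, str]] = field(default_factory=list)
    circadian_period_h: Optional[float] = None
    angle_truth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.strike_times = np.asarray(self.strike_times, dtype=float)
        if len(self.strike_times) > 1 and np.any(np.diff(self.strike_times) <= 0):
            raise ValueError("strike times must be strictly increasing")


# ---------------------------------------------------------------------------
# waveform building blocks
# ---------------------------------------------------------------------------

def _pulse_waveform(fs: float, f0: float, tau: float) -> np.ndarray:
    """Exponentially decaying sinusoid, normalized to unit sampled peak."""
    T = tau * math.log(1e4)  # decay to 1e-4 of the envelope
    t = np.arange(int(round(T * fs))) / fs
    p = np.exp(-t / tau) * np.sin(2.0 * np.pi * f0 * t)
    return p / np.abs(p).max()


def _ambient_floor(cfg: SimConfig, n: int, fs: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Gaussian floor per axis; the vector-magnitude RMS of three iid axes
    with per-axis SD sigma is sqrt(3) sigma."""
    if cfg.ambient_rms_db is None:
        return np.zeros((3, n))
    sigma = db_to_amplitude(cfg.ambient_rms_db) * _SQ3
    return rng.normal(0.0, sigma, size=(3, n))


def _band_noise(n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with support exactly inside [f1, f2] (spectral
    synthesis), one axis, unit-free amplitude."""
    f1, f2 = band
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum = rng.normal(size=len(freqs)) + 1j * rng.normal(size=len(freqs))
    spectrum[(freqs < f1) | (freqs > f2)] = 0.0
    spectrum[0] = 0.0
    return np.fft.irfft(spectrum, n=n)


def _sample_ipis(rng: np.random.Generator, mean: float, sd: float,
                 floor: float, total: float) -> np.ndarray:
    """Truncated-normal inter-pulse intervals (rejection at the floor)
    whose cumulative sum just exceeds ``total``."""
    if sd >= mean:
        raise ValueError("ipi_sd must be smaller than ipi_mean "
                         "(truncation would be degenerate)")
    out: list[float] = []
    acc = 0.0
    while acc <= total:
        batch = rng.normal(mean, sd, size=max(16, int(total / mean) + 8))
        for v in batch:
            if v < floor:
                continue
            out.append(v)
            acc += v
            if acc > total:
                break
    return np.array(out)


# ---------------------------------------------------------------------------
# geophone records
# ---------------------------------------------------------------------------

def gen_ih_train(cfg: SimConfig, duration: float,
                 rng: Optional[np.random.Generator] = None,
                 site: str = "near") -> tuple[TriaxialSeries, GroundTruth]:
    """Impact-hammer strike train over the ambient floor.

    Strike onsets follow truncated-normal inter-pulse intervals; each strike
    is a decaying 10-Hz sinusoid whose vector-magnitude sampled peak equals a
    level drawn Normal(ih_peak_db, ih_peak_sd_db) in dB.  Onsets are snapped
    to the sample grid so the ground truth is exact.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if duration <= 2.0 * cfg.ipi_mean:
        raise ValueError("duration must exceed two mean inter-pulse intervals")
    rng = cfg.rng() if rng is None else rng
    fs = cfg.fs_geo
    n = int(round(duration * fs))
    axes = _ambient_floor(cfg, n, fs, rng)
    pulse = _pulse_waveform(fs, cfg.ih_center_freq, cfg.ih_decay_tau)

    ipis = _sample_ipis(rng, cfg.ipi_mean, cfg.ipi_sd, cfg.ipi_floor,
                        total=duration)
    onsets = np.cumsum(ipis)
    onsets = onsets[onsets < duration - len(pulse) / fs]
    onsets = np.round(onsets * fs) / fs  # snap to grid; truth stays exact
    peaks_db = rng.normal(cfg.ih_peak_db, cfg.ih_peak_sd_db, size=len(onsets))
    for t0, pk in zip(onsets, peaks_db):
        i0 = int(round(t0 * fs))
        amp = db_to_amplitude(pk)
        seg = amp * pulse
        for a, c in zip(axes, cfg.direction_cosines):
            a[i0:i0 + len(seg)] += c * seg
    series = TriaxialSeries(fs=fs, x=axes[0], y=axes[1], z=axes[2],
                            site=site)
    return series, GroundTruth(strike_times=onsets)


def gen_vh_signal(cfg: SimConfig, duration: float,
                  rng: Optional[np.random.Generator] = None,
                  site: str = "near") -> TriaxialSeries:
    """Continuous vibratory-hammer signal: band-limited Gaussian noise whose
    vector-magnitude RMS equals ``10^(vh_rms_db/20)`` µm s^-2 exactly,
    superposed on the ambient floor."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    f1, f2 = cfg.vh_band
    if f2 > cfg.fs_geo / 2.0:
        raise ValueError("vibratory band exceeds the geophone Nyquist frequency")
    rng = cfg.rng() if rng is None else rng
    fs = cfg.fs_geo
    n = int(round(duration * fs))
    vh = np.stack([c * _band_noise(n, fs, cfg.vh_band, rng)
                   for c in cfg.direction_cosines])
    # scale the three-axis field so its magnitude RMS is exact
    mag_rms = float(np.sqrt(np.mean(np.sum(vh**2, axis=0))))
    vh *= db_to_amplitude(cfg.vh_rms_db) / mag_rms
    axes = _ambient_floor(cfg, n, fs, rng) + vh
    return TriaxialSeries(fs=fs, x=axes[0], y=axes[1], z=axes[2], site=site)


# ---------------------------------------------------------------------------
# tag records
# ---------------------------------------------------------------------------

def _diel_fraction(cfg: SimConfig, t_s: np.ndarray) -> np.ndarray:
    """Nocturnality in [0, 1]: 0 by day, 1 at night, half-cosine transitions
    of width diel_transition_h starting at sunset/sunrise.  Period: 24 h
    exactly (the record starts at local midnight)."""
    h = (t_s / 3600.0) % 24.0
    hs = (h - cfg.sunset_hour) % 24.0
    night_len = (cfg.sunrise_hour - cfg.sunset_hour) % 24.0
    w = cfg.diel_transition_h
    return np.select(
        [hs < w, hs < night_len, hs < night_len + w],
        [0.5 * (1.0 - np.cos(np.pi * hs / w)),
         1.0,
         0.5 * (1.0 + np.cos(np.pi * (hs - night_len) / w))],
        default=0.0,
    )


def gen_tag_record(
    cfg: SimConfig,
    schedule: ExposureSchedule,
    days: int,
    rng: Optional[np.random.Generator] = None,
    include_acc: bool = True,
    individual: str = "tag-01",
    site: str = "near",
    start_time: datetime = _EPOCH,
) -> tuple[TagRecord, GroundTruth]:
    """Dual-rate tag record with a 24-h valve rhythm and exposure responses.

    The noiseless angle is a smooth diel cycle (``day_angle_mean`` by day,
    ``night_angle_mean`` at night, period exactly 24 h).  During scheduled
    exposure the level declines over a ~1-min half-cosine onset ramp to an
    exposure plateau (instant reopening at offset).  Each IH strike triggers
    a Bernoulli(closure_prob) partial closure of depth ``closure_depth``
    recovering exponentially with ``closure_recovery_tau``.

    ``exposure_angle_mean`` parameterizes the observable the study reports —
    the mean angle over exposure windows *including* ramp and
    strike-triggered transients — so each window's plateau is offset by the
    realized in-window depression, making the noiseless window mean equal
    the configured value exactly.

    The magnetometer stream is the linear forward model (mV = offset +
    slope * angle) of the noisy angle plus sensor noise; the accelerometer
    stream (optional, 25 Hz) carries scaled strike pulses and band noise
    during VH so strike synchronization is testable.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    span = days * 86400.0
    if schedule.intervals and schedule.span > span + 1e-9:
        raise ValueError("schedule extends beyond the record span")
    rng = cfg.rng() if rng is None else rng
    fs = cfg.fs_mag
    n = int(round(span * fs))
    t = np.arange(n) / fs

    base = (cfg.day_angle_mean
            + (cfg.night_angle_mean - cfg.day_angle_mean) * _diel_fraction(cfg, t))

    def _sl(iv):
        return slice(int(round(iv.start_s * fs)), int(round(iv.end_s * fs)))

    # strikes and closures inside IH windows
    strike_times: list[float] = []
    closure_times: list[float] = []
    for iv in schedule.by_label("IH"):
        ipis = _sample_ipis(rng, cfg.ipi_mean, cfg.ipi_sd, cfg.ipi_floor,
                            total=iv.duration)
        onsets = iv.start_s + np.cumsum(ipis)
        onsets = onsets[onsets < iv.end_s]
        strike_times.extend(onsets.tolist())
        hit = rng.random(len(onsets)) < cfg.closure_prob
        closure_times.extend(onsets[hit].tolist())

    # strike-triggered transient depressions (subtracted from the level)
    dips = np.zeros(n)
    tau = cfg.closure_recovery_tau
    klen = int(math.ceil(8.0 * tau * fs))
    for tc in closure_times:
        i0 = int(math.ceil(tc * fs))
        kk = min(klen, n - i0)
        if kk <= 0:
            continue
        offs = (np.arange(kk) + i0) / fs - tc
        dips[i0:i0 + kk] += cfg.closure_depth * np.exp(-offs / tau)

    # Exposure windows: half-cosine onset ramp to a plateau, with the
    # plateau offset by the realized in-window depression (ramp + dips) so
    # the noiseless window mean equals exposure_angle_mean exactly.
    for iv in schedule.by_label(*EXPOSURE_LABELS_):
        sl = _sl(iv)
        seg_len = sl.stop - sl.start
        if seg_len < 2:
            continue
        L0 = float(base[max(0, sl.start - 1)])
        R = min(cfg.exposure_ramp_s, iv.duration / 2.0)
        nr = min(int(round(R * fs)), seg_len)
        ramp = np.zeros(seg_len)
        if nr > 0:
            tt = np.arange(nr) / fs
            ramp[:nr] = 0.5 * (1.0 + np.cos(np.pi * tt / R))
        mean_dip = float(dips[sl].mean())
        # plateau Lc: mean(Lc + (L0-Lc)*ramp - dips) = exposure_angle_mean
        rbar = float(ramp.mean())
        Lc = (cfg.exposure_angle_mean + mean_dip - L0 * rbar) / (1.0 - rbar)
        base[sl] = Lc + (L0 - Lc) * ramp

    angle_truth = base - dips
    closure_events: list[tuple[float, float, str]] = []
    for tc in closure_times:
        i0 = min(n - 1, int(math.ceil(tc * fs)))
        floor = float(base[i0]) - cfg.closure_depth
        closure_events.append(
            (tc, cfg.closure_depth, "total" if floor <= 1.0 else "partial"))
    np.clip(angle_truth, 0.0, 90.0, out=angle_truth)

    noisy = np.clip(angle_truth + rng.normal(0.0, cfg.angle_noise_sd, n), 0.0, 90.0)
    mv = (cfg.mag_offset_mv + cfg.mag_slope_mv_per_deg * noisy
          + rng.normal(0.0, cfg.mag_noise_sd_mv, n))

    if include_acc:
        n_acc = int(round(span * cfg.fs_acc))
        acc = rng.normal(0.0, cfg.acc_noise_sd, size=(3, n_acc))
        pulse = _pulse_waveform(cfg.fs_acc, min(cfg.ih_center_freq,
                                                0.8 * cfg.fs_acc / 2.0),
                                cfg.ih_decay_tau)
        for tc in strike_times:
            i0 = int(round(tc * cfg.fs_acc))
            seg = cfg.acc_pulse_amp * pulse[: max(0, n_acc - i0)]
            for a, c in zip(acc, cfg.direction_cosines):
                a[i0:i0 + len(seg)] += c * seg
        vh_band_acc = (min(cfg.vh_band[0], 0.3 * cfg.fs_acc / 2.0),
                       0.9 * cfg.fs_acc / 2.0)
        for iv in schedule.by_label("VH"):
            i0 = int(round(iv.start_s * cfg.fs_acc))
            i1 = int(round(iv.end_s * cfg.fs_acc))
            seg = _band_noise(i1 - i0, cfg.fs_acc, vh_band_acc, rng)
            seg *= 0.3 * cfg.acc_pulse_amp / max(1e-12, np.sqrt(np.mean(seg**2)))
            for a, c in zip(acc, cfg.direction_cosines):
                a[i0:i1] += c * seg
        acc_time = np.arange(n_acc) / cfg.fs_acc
    else:
        n_acc = int(round(10.0 * cfg.fs_acc))
        acc = np.zeros((3, n_acc))
        acc_time = np.arange(n_acc) / cfg.fs_acc

    record = TagRecord(mag_time=t, mag_mv=mv, acc_time=acc_time,
                       acc_x=acc[0], acc_y=acc[1], acc_z=acc[2],
                       fs_mag=fs, fs_acc=cfg.fs_acc,
                       individual=individual, site=site, start_time=start_time)
    truth = GroundTruth(strike_times=np.array(strike_times),
                        closure_events=closure_events,
                        circadian_period_h=24.0,
                        angle_truth=angle_truth)
    return record, truth


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

def gen_annotations(
    design: pd.DataFrame,
    minutes: float | dict = 15.0,
    fish_flag_prob: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Poisson behavioral event streams.

    ``design`` has one row per (stage, site, treatment, behavior) with
    columns ``rate_per_min`` and ``n_individuals``; for each individual the
    event count is Poisson(rate x window) with uniform event times.  A
    fraction ``fish_flag_prob`` of partial closures carries the fish_nearby
    flag (candidates for removal downstream).
    """
    required = {"stage", "site", "treatment", "behavior", "rate_per_min",
                "n_individuals"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design missing columns: {sorted(missing)}")
    if (design["rate_per_min"] < 0).any():
        raise ValueError("rates must be >= 0")
    if not 0.0 <= fish_flag_prob <= 1.0:
        raise ValueError("fish_flag_prob must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for _, r in design.iterrows():
        w = minutes.get(r["treatment"]) if isinstance(minutes, dict) else minutes
        w = float(w)
        for i in range(int(r["n_individuals"])):
            subject = f"{r['site']}-{r['stage']}-{i:02d}"
            count = rng.poisson(r["rate_per_min"] * w)
            times = np.sort(rng.uniform(0.0, w * 60.0, size=count))
            for ts in times:
                flagged = (r["behavior"] == "partial_closure"
                           and rng.random() < fish_flag_prob)
                rows.append({"time_s": float(ts), "subject": subject,
                             "stage": r["stage"], "site": r["site"],
                             "treatment": r["treatment"],
                             "behavior": r["behavior"],
                             "fish_nearby": bool(flagged)})
    cols = ["time_s", "subject", "stage", "site", "treatment", "behavior",
            "fish_nearby"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# lightweight observation generator for the mixed-model ladder
# ---------------------------------------------------------------------------

def gen_angle_observations(
    n_individuals: int = 10,
    n_days: int = 9,
    sequences: Sequence[str] = ("IH1", "VH1", "IH2", "VH2"),
    baseline_angle: float = 7.34,
    effect_exposure: float = 0.0,
    effect_type: float = 0.0,
    effect_rep: float = 0.0,
    effect_day: float = 0.0,
    sd_individual: float = 0.15,
    sd_date: float = 0.05,
    sd_noise: float = 0.10,
    rng: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Long-format valve-angle observations for the mixed-model ladder.

    One row per individual x day x window (preexposure, each exposure
    sequence, postexposure).  Effects are additive on the log(angle + 0.1)
    scale: ``effect_exposure`` shifts all exposure windows, ``effect_type``
    additionally shifts IH windows, ``effect_rep`` shifts second repetitions,
    and ``effect_day`` scales linearly with day number.  Individual and date
    intercepts are Gaussian.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    mu = math.log(baseline_angle + 0.1)
    b_ind = rng.normal(0.0, sd_individual, n_individuals)
    rows = []
    for d in range(n_days):
        b_day = rng.normal(0.0, sd_date)
        for i in range(n_individuals):
            windows = ([("preexposure", "none", "none")]
                       + [("exposure", s[:2], s) for s in sequences]
                       + [("postexposure", "none", "none")])
            for phase, etype, seq in windows:
                y = mu + b_ind[i] + b_day + effect_day * d
                if phase == "exposure":
                    y += effect_exposure
                    if etype == "IH":
                        y += effect_type
                    if seq.endswith("2"):
                        y += effect_rep
                y += rng.normal(0.0, sd_noise)
                rows.append({"angle": max(0.0, math.exp(y) - 0.1),
                             "phase": phase, "exp_type": etype,
                             "sequence": seq, "day": f"d{d}", "day_num": d,
                             "individual": f"i{i:02d}"})
    return pd.DataFrame(rows)
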