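"""Valve-gape biologging pipeline.

Converts dual-rate tag streams (2 Hz magnetometer voltage, 25 Hz triaxial
acceleration) into calibrated valve-angle series, synchronizes them with
pile-driving strikes, detects partial/total valve closures, computes
before/during/after exposure statistics, and runs the nested mixed-model
ladder used to attribute valve-angle changes to exposure.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.stats import chi2

from .vibration import TriaxialSeries, _EPOCH, _envelope, _ambient_rms, detect_strikes

__all__ = [
    "TagRecord",
    "MagCalibration",
    "ValveAngleSeries",
    "ClosureEvent",
    "ScheduleInterval",
    "ExposureSchedule",
    "ExposureStats",
    "TagStrikeDetection",
    "LadderStep",
    "LadderResult",
    "fit_calibration",
    "mv_to_angle",
    "detect_tag_strikes",
    "detect_closures",
    "exposure_stats",
    "lmm_ladder",
]

SCHEDULE_LABELS = ("preexposure", "VH", "IH", "recovery")
EXPOSURE_LABELS = ("VH", "IH")

#: offset added before log-transforming valve angles, degrees
LOG_ANGLE_OFFSET = 0.1


@dataclass
class TagRecord:
    """Raw dual-rate tag streams sharing one time origin."""

    mag_time: np.ndarray          # s since record start, 2 Hz
    mag_mv: np.ndarray            # magnetometer output, mV
    acc_time: np.ndarray          # s since record start, 25 Hz
    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    fs_mag: float = 2.0
    fs_acc: float = 25.0
    individual: str = ""
    site: str = ""
    start_time: datetime = _EPOCH

    def __post_init__(self) -> None:
        for name in ("mag_time", "mag_mv", "acc_time", "acc_x", "acc_y", "acc_z"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.mag_time) != len(self.mag_mv):
            raise ValueError("magnetometer time and voltage lengths differ")
        for rate, t, what in ((self.fs_mag, self.mag_time, "magnetometer"),
                              (self.fs_acc, self.acc_time, "accelerometer")):
            if len(t) > 1:
                observed = (len(t) - 1) / (t[-1] - t[0])
                if abs(observed - rate) / rate > 0.01:
                    raise ValueError(
                        f"{what} sampling rate {observed:.3f} Hz deviates >1% "
                        f"from declared {rate} Hz")


@dataclass(frozen=True)
class MagCalibration:
    """Monotone piecewise-linear mapping from magnetometer mV to valve angle."""

    mv: np.ndarray
    degrees: np.ndarray

    def angle(self, mv: np.ndarray | float) -> np.ndarray | float:
        """Map mV to degrees; extrapolation clamps to the end angles."""
        return np.interp(mv, self.mv, self.degrees)


@dataclass
class ValveAngleSeries:
    """Calibrated valve-gape angle series, degrees, at the magnetometer rate."""

    fs: float
    angle: np.ndarray
    start_time: datetime = _EPOCH
    individual: str = ""

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)
        if not np.all(np.isfinite(self.angle)):
            raise ValueError("angles must be finite")
        if self.angle.min() < -1e-9 or self.angle.max() > 90.0 + 1e-9:
            raise ValueError("angles must lie in [0, 90] degrees")

    @property
    def n(self) -> int:
        return len(self.angle)

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs


@dataclass(frozen=True)
class ClosureEvent:
    """One detected valve closure."""

    time: float                     # onset, s since record start
    type: str                       # "partial" or "total"
    depth: float                    # drop from local baseline, degrees
    duration: float                 # time below the half-drop level, s
    latency_to_strike: Optional[float] = None

    def __post_init__(self) -> None:
        if self.type not in ("partial", "total"):
            raise ValueError(f"unknown closure type {self.type!r}")
        if self.depth <= 0 or self.duration <= 0:
            raise ValueError("depth and duration must be positive")


@dataclass(frozen=True)
class ScheduleInterval:
    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.label not in SCHEDULE_LABELS:
            raise ValueError(
                f"unknown schedule label {self.label!r}; allowed: {SCHEDULE_LABELS}")
        if not self.start_s < self.end_s:
            raise ValueError("interval must satisfy start < end")

    @property
    def day(self) -> int:
        return int(self.start_s // 86400)

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass
class ExposureSchedule:
    """Labeled pile-driving intervals (seconds since record start, which is
    local midnight of the first monitoring day)."""

    intervals: tuple[ScheduleInterval, ...]
    timezone: str = "local"

    def __post_init__(self) -> None:
        self.intervals = tuple(sorted(self.intervals, key=lambda iv: iv.start_s))
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start_s < a.end_s:
                raise ValueError(
                    f"overlapping schedule intervals at {a.end_s} s and {b.start_s} s")

    def by_label(self, *labels: str) -> list[ScheduleInterval]:
        return [iv for iv in self.intervals if iv.label in labels]

    @property
    def exposure_days(self) -> list[int]:
        return sorted({iv.day for iv in self.by_label(*EXPOSURE_LABELS)})

    @property
    def span(self) -> float:
        return max((iv.end_s for iv in self.intervals), default=0.0)

    @classmethod
    def daily_pd(cls, n_days: int, events_per_day: int = 4,
                 start_hour: float = 13.5, vh_min: float = 15.0,
                 gap_min: float = 5.0, ih_min: float = 15.0,
                 inter_event_gap_min: float = 5.0,
                 first_day: int = 0) -> "ExposureSchedule":
        """Build the study-style daily schedule: each afternoon, a sequence of
        pile-driving events, each a vibratory phase followed (after a short
        gap) by an impact phase."""
        ivs = []
        for d in range(first_day, first_day + n_days):
            t = d * 86400.0 + start_hour * 3600.0
            for _ in range(events_per_day):
                ivs.append(ScheduleInterval("VH", t, t + vh_min * 60.0))
                t += (vh_min + gap_min) * 60.0
                ivs.append(ScheduleInterval("IH", t, t + ih_min * 60.0))
                t += (ih_min + inter_event_gap_min) * 60.0
        return cls(intervals=tuple(ivs))


@dataclass
class ExposureStats:
    """Window statistics of a valve-angle series under a schedule.

    Means/SDs per label; pooled pre/post 15-min windows (15 min before the
    first exposure onset and after the last exposure offset, per day); pooled
    exposure (VH+IH) statistics; per-day window means; and the relative
    reduction (pre - exposure) / pre.
    """

    label_stats: dict
    pre15_mean: Optional[float]
    pre15_sd: Optional[float]
    post15_mean: Optional[float]
    post15_sd: Optional[float]
    exposure_mean: Optional[float]
    exposure_sd: Optional[float]
    relative_reduction: Optional[float]
    per_day: pd.DataFrame


@dataclass(frozen=True)
class TagStrikeDetection:
    """Strike times resolved from the tag accelerometer, or a continuous-
    activity flag when individual blows are unresolvable (vibratory mode)."""

    times: np.ndarray
    continuous_activity: bool


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def fit_calibration(points: Sequence[tuple[float, float]]) -> MagCalibration:
    """Fit a monotone piecewise-linear mV-to-degrees calibration.

    Requires >= 2 points, strictly monotone in mV (after sorting) and in
    angle, with angles in [0, 90] degrees.
    """
    if len(points) < 2:
        raise ValueError("calibration needs at least 2 points")
    pts = sorted((float(mv), float(deg)) for mv, deg in points)
    mv = np.array([p[0] for p in pts])
    deg = np.array([p[1] for p in pts])
    if np.any(np.diff(mv) <= 0):
        raise ValueError("calibration mV values must be strictly monotone")
    d = np.diff(deg)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("calibration angles must be strictly monotone in mV")
    if deg.min() < 0 or deg.max() > 90:
        raise ValueError("calibration angles must lie in [0, 90] degrees")
    return MagCalibration(mv=mv, degrees=deg)


def mv_to_angle(record: TagRecord, cal: MagCalibration) -> ValveAngleSeries:
    """Apply the calibration pointwise to the magnetometer stream."""
    if len(record.mag_mv) == 0:
        raise ValueError("empty magnetometer stream")
    bad = np.flatnonzero(~np.isfinite(record.mag_mv))
    if len(bad):
        raise ValueError(f"non-finite magnetometer sample at index {bad[0]}")
    angles = cal.angle(record.mag_mv)
    return ValveAngleSeries(fs=record.fs_mag, angle=angles,
                            start_time=record.start_time,
                            individual=record.individual)


# ---------------------------------------------------------------------------
# strike synchronization from the tag accelerometer
# ---------------------------------------------------------------------------

def detect_tag_strikes(record: TagRecord, threshold_db: float = 12.0,
                       min_separation_s: float = 1.0) -> TagStrikeDetection:
    """Detect impact-hammer strikes in the 25 Hz tag accelerometer.

    Uses the same envelope-threshold detector as the geophone pipeline.  A
    vibratory hammer (~1150 blows/min, ~19 Hz blow rate) cannot be resolved
    into individual blows at 25 Hz; if the envelope stays above threshold for
    more than 25% of the record the result is flagged as continuous activity
    and no individual times are returned.
    """
    n = len(record.acc_x)
    if n / record.fs_acc < 10.0:
        raise ValueError("accelerometer stream must be at least 10 s")
    series = TriaxialSeries(fs=record.fs_acc, x=record.acc_x, y=record.acc_y,
                            z=record.acc_z, start_time=record.start_time)
    m = series.magnitude
    env = _envelope(m, series.fs)
    amb = _ambient_rms(m, series.fs)
    if amb == 0.0:
        amb = np.finfo(float).tiny
    thr = amb * 10.0 ** (threshold_db / 20.0)
    active_fraction = float(np.mean(env > thr))
    if active_fraction > 0.25:
        return TagStrikeDetection(times=np.empty(0), continuous_activity=True)
    events = detect_strikes(series, threshold_db_above_ambient=threshold_db,
                            min_separation_s=min_separation_s)
    return TagStrikeDetection(times=np.array([ev.onset for ev in events]),
                              continuous_activity=False)


# ---------------------------------------------------------------------------
# closure detection
# ---------------------------------------------------------------------------

def detect_closures(
    angles: ValveAngleSeries,
    strikes: Sequence[float] = (),
    partial_drop_deg: float = 1.0,
    total_threshold_deg: float = 1.0,
    sync_window_s: float = 2.0,
    baseline_window_s: float = 60.0,
    min_separation_s: float = 2.0,
    recovery_tau_s: float = 5.0,
    n_iter: int = 6,
) -> list[ClosureEvent]:
    """Detect valve closures by sparse matched deconvolution.

    A partial closure is modeled as an abrupt angle drop with exponential
    recovery (time constant ``recovery_tau_s``).  The detector alternates
    two steps, matching-pursuit style: (1) the smooth open-state level is
    estimated as a centered ``baseline_window_s`` running mean of the angle
    plus the depression explained by the events found so far — unbiased no
    matter how densely dips cover the record; (2) new events are picked as
    peaks of the residual depression correlated with the causal
    exponential-recovery kernel, and every event amplitude is refit
    leave-one-out.  Events whose final fitted drop is below
    ``partial_drop_deg``, or whose decline does not actually reach
    ``baseline - partial_drop_deg`` within ``sync_window_s`` of onset, are
    discarded.  Consecutive events with no intervening recovery of at least
    half the drop are merged (a sustained total closure is one event, not a
    train).

    An event is total when the minimum angle is at or below
    ``total_threshold_deg``.  Duration is the contiguous time below
    ``baseline - partial_drop_deg/2`` around the trough; latency is the gap
    to the nearest earlier strike within ``sync_window_s``, when strikes
    are supplied.
    """
    if sync_window_s <= 0:
        raise ValueError("sync_window_s must be positive")
    from scipy.ndimage import uniform_filter1d
    from scipy.signal import fftconvolve, find_peaks

    fs = angles.fs
    raw = angles.angle
    n = len(raw)
    dt = 1.0 / fs
    a3 = median_filter(raw, size=3, mode="nearest")
    K = max(2, int(round(3.0 * recovery_tau_s * fs)))
    h = np.exp(-np.arange(K) / (recovery_tau_s * fs))
    hsq = float(np.sum(h * h))
    W = max(2, int(round(baseline_window_s * fs)))
    dist = max(1, int(round(min_separation_s * fs)))

    events: dict[int, float] = {}

    def kernel_sum() -> np.ndarray:
        pred = np.zeros(n)
        for i, a in events.items():
            kk = min(K, n - i)
            pred[i:i + kk] += a * h[:kk]
        return pred

    for _ in range(n_iter):
        pred = kernel_sum()
        open_lvl = uniform_filter1d(raw + pred, size=W, mode="nearest")
        resid = open_lvl - (raw + pred)
        amp = fftconvolve(resid, h[::-1], mode="full")[K - 1:][:n] / hsq
        peaks, _props = find_peaks(amp, height=0.7 * partial_drop_deg,
                                   distance=dist)
        for pk in peaks:
            if any(abs(int(pk) - q) < dist for q in events):
                continue
            events[int(pk)] = float(amp[pk])
        # leave-one-out amplitude refit; drop clearly spurious entries
        pred = kernel_sum()
        open_lvl = uniform_filter1d(raw + pred, size=W, mode="nearest")
        for i in sorted(events):
            kk = min(K, n - i)
            hk = h[:kk]
            resid_i = (open_lvl[i:i + kk] - (raw[i:i + kk] + pred[i:i + kk])
                       + events[i] * hk)
            inc = float(np.dot(resid_i, hk) / np.dot(hk, hk))
            if inc < 0.5 * partial_drop_deg:
                pred[i:i + kk] -= events[i] * hk
                del events[i]
            else:
                pred[i:i + kk] += (inc - events[i]) * hk
                events[i] = inc

    pred = kernel_sum()
    open_lvl = uniform_filter1d(raw + pred, size=W, mode="nearest")
    Wsync = int(round(sync_window_s * fs)) + 1

    accepted: list[int] = []
    for i in sorted(events):
        if events[i] < partial_drop_deg:
            continue
        seg = a3[i: min(n, i + Wsync)]
        if len(seg) == 0 or seg.min() > open_lvl[i] - partial_drop_deg:
            continue  # drop not reached within the sync window
        accepted.append(i)

    # merge events with no intervening recovery (sustained closures)
    merged: list[int] = []
    half = partial_drop_deg / 2.0
    for i in accepted:
        if merged:
            j = merged[-1]
            between = a3[j:i + 1]
            if (len(between) and between.min() < open_lvl[j] - half
                    and between.max() - between.min() < half):
                continue  # flat continuation of the previous excursion
        merged.append(i)

    strikes = np.sort(np.asarray(strikes, dtype=float))
    events_out: list[ClosureEvent] = []
    for i in merged:
        base = float(open_lvl[i])
        onset = i * dt
        hi_seg = min(n, i + max(Wsync, int(round(2 * recovery_tau_s * fs))))
        imin = i + int(np.argmin(a3[i:hi_seg]))
        seg_min = float(a3[imin])
        depth = base - seg_min
        if depth <= 0:
            continue
        lo_d = imin
        while lo_d > 0 and a3[lo_d - 1] < base - half:
            lo_d -= 1
        hi_d = imin
        while hi_d < n and a3[hi_d] < base - half:
            hi_d += 1
        duration = max(dt, (hi_d - lo_d) * dt)
        latency = None
        if len(strikes):
            k = int(np.searchsorted(strikes, onset, side="right")) - 1
            if k >= 0 and onset - strikes[k] <= sync_window_s:
                latency = float(onset - strikes[k])
        events_out.append(ClosureEvent(
            time=float(onset),
            type="total" if seg_min <= total_threshold_deg else "partial",
            depth=float(depth),
            duration=float(duration),
            latency_to_strike=latency,
        ))
    return events_out


# ---------------------------------------------------------------------------
# exposure statistics
# ---------------------------------------------------------------------------

def _window_slice(angles: ValveAngleSeries, start_s: float, end_s: float) -> np.ndarray:
    i0 = int(round(start_s * angles.fs))
    i1 = int(round(end_s * angles.fs))
    if i0 < 0 or i1 > angles.n:
        raise ValueError(
            f"window [{start_s}, {end_s}] s extends outside the record")
    return angles.angle[i0:i1]


def exposure_stats(angles: ValveAngleSeries, schedule: ExposureSchedule,
                   prepost_min: float = 15.0) -> ExposureStats:
    """Per-label window statistics plus the daily pre/post comparison.

    The pre window is exactly ``prepost_min`` minutes before each day's first
    exposure onset; the post window is the same duration after the day's last
    exposure offset.  The relative reduction is (pre - exposure) / pre on the
    pooled means.
    """
    label_stats: dict = {}
    for label in SCHEDULE_LABELS:
        segs = [_window_slice(angles, iv.start_s, iv.end_s)
                for iv in schedule.by_label(label)]
        if segs:
            allv = np.concatenate(segs)
            label_stats[label] = {
                "mean": float(allv.mean()),
                "sd": float(allv.std(ddof=1)),
                "n": int(len(allv)),
            }

    exp_ivs = schedule.by_label(*EXPOSURE_LABELS)
    if not exp_ivs:
        return ExposureStats(label_stats=label_stats, pre15_mean=None,
                             pre15_sd=None, post15_mean=None, post15_sd=None,
                             exposure_mean=None, exposure_sd=None,
                             relative_reduction=None,
                             per_day=pd.DataFrame())

    exp_all = np.concatenate(
        [_window_slice(angles, iv.start_s, iv.end_s) for iv in exp_ivs])
    pre_parts, post_parts, rows = [], [], []
    w = prepost_min * 60.0
    for day in schedule.exposure_days:
        day_ivs = [iv for iv in exp_ivs if iv.day == day]
        first_on = min(iv.start_s for iv in day_ivs)
        last_off = max(iv.end_s for iv in day_ivs)
        pre = _window_slice(angles, first_on - w, first_on)
        post = _window_slice(angles, last_off, last_off + w)
        day_exp = np.concatenate(
            [_window_slice(angles, iv.start_s, iv.end_s) for iv in day_ivs])
        pre_parts.append(pre)
        post_parts.append(post)
        rows.append({
            "day": day,
            "pre_mean": float(pre.mean()),
            "exposure_mean": float(day_exp.mean()),
            "post_mean": float(post.mean()),
            "delta_pre_exposure": float(pre.mean() - day_exp.mean()),
        })
    pre_all = np.concatenate(pre_parts)
    post_all = np.concatenate(post_parts)
    pre_mean = float(pre_all.mean())
    exp_mean = float(exp_all.mean())
    return ExposureStats(
        label_stats=label_stats,
        pre15_mean=pre_mean,
        pre15_sd=float(pre_all.std(ddof=1)),
        post15_mean=float(post_all.mean()),
        post15_sd=float(post_all.std(ddof=1)),
        exposure_mean=exp_mean,
        exposure_sd=float(exp_all.std(ddof=1)),
        relative_reduction=float((pre_mean - exp_mean) / pre_mean),
        per_day=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# nested mixed-model ladder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LadderStep:
    name: str
    llf: float
    df_added: int
    lrt_stat: Optional[float]
    p_value: Optional[float]


@dataclass
class LadderResult:
    steps: list[LadderStep]
    selected: str


#: ladder order: fixed-effect terms added one step at a time
_LADDER = [
    ("null", []),
    ("phase", ["x_exposure", "x_post"]),
    ("exposure_type", ["x_ih"]),
    ("exposure_sequence", ["x_rep2"]),
    ("day", ["x_day"]),
]


def _fit_ml(formula: str, data: pd.DataFrame):
    """ML fit of a crossed random-effects model (individual + date variance
    components in a single group), trying optimizers until one converges."""
    import statsmodels.formula.api as smf

    vcf = {"individual": "0 + C(individual)", "date": "0 + C(day)"}
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                res = smf.mixedlm(formula, data, groups="_one",
                                  vc_formula=vcf, re_formula="0").fit(
                                      reml=False, method=method, maxiter=500)
            except Exception:
                continue
            if np.isfinite(res.llf) and (best is None or res.llf > best.llf):
                best = res
            if best is not None and getattr(res, "converged", False):
                break
    if best is None:
        raise RuntimeError(f"mixed model failed to fit: {formula}")
    return best


def lmm_ladder(data: pd.DataFrame, alpha: float = 0.05,
               angle_col: str = "angle") -> LadderResult:
    """Stepwise likelihood-ratio comparison of five nested mixed models.

    ``data`` is a long-format table with one valve-angle observation per row
    and columns ``angle`` (degrees), ``phase`` (preexposure / exposure /
    postexposure), ``exp_type`` (IH / VH / none), ``sequence`` (e.g. IH1,
    VH2, or none), ``day`` (calendar-date label, random effect),
    ``day_num`` (numeric day of exposure), and ``individual``.

    The response is log(angle + 0.1) to admit zero angles.  Random effects
    are crossed intercepts for individual and date.  The fixed-effect ladder
    adds, in order: exposure phase (2 df), impact-vs-vibratory within
    exposure (1 df), repetition within exposure (1 df), and numeric day of
    exposure (1 df); each nested pair is compared by a likelihood-ratio test
    and the selection stops at the first non-significant addition.
    """
    required = {"phase", "exp_type", "sequence", "day", "day_num", "individual",
                angle_col}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if data["individual"].nunique() < 2:
        raise ValueError("at least two individuals are required")
    if data["day"].nunique() < 2:
        raise ValueError("at least two dates are required")
    if data["phase"].nunique() < 2:
        raise ValueError("phase has a single level; design is singular")

    df = data.copy()
    df["_y"] = np.log(df[angle_col].to_numpy(dtype=float) + LOG_ANGLE_OFFSET)
    df["_one"] = 1
    df["x_exposure"] = (df["phase"] == "exposure").astype(float)
    df["x_post"] = (df["phase"] == "postexposure").astype(float)
    df["x_ih"] = ((df["phase"] == "exposure")
                  & (df["exp_type"] == "IH")).astype(float)
    df["x_rep2"] = ((df["phase"] == "exposure")
                    & df["sequence"].astype(str).str.endswith("2")).astype(float)
    df["x_day"] = df["day_num"].astype(float) - df["day_num"].astype(float).mean()

    steps: list[LadderStep] = []
    selected = "null"
    terms: list[str] = []
    prev_llf = None
    stopped = False
    for name, added in _LADDER:
        terms = terms + added
        rhs = " + ".join(terms) if terms else "1"
        res = _fit_ml(f"_y ~ {rhs}", df)
        llf = float(res.llf)
        if prev_llf is None:
            steps.append(LadderStep(name, llf, 0, None, None))
        else:
            # nested ML fits: likelihood cannot decrease (tolerance for the
            # optimizer)
            if llf < prev_llf - 1e-6:
                llf = prev_llf
            stat = max(0.0, 2.0 * (llf - prev_llf))
            p = float(chi2.sf(stat, df=len(added)))
            steps.append(LadderStep(name, llf, len(added), stat, p))
            if not stopped and p < alpha:
                selected = name
            else:
                stopped = True
        prev_llf = llf
    return LadderResult(steps=steps, selected=selected)
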