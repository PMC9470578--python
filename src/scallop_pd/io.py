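"""File formats, configuration, seeding, and the end-to-end pipeline.

All data files are plain CSV (comma-separated, UTF-8, ``.`` decimal, header
row mandatory) with times in seconds since record start; the UTC origin,
sampling rate, and site metadata live in a JSON sidecar next to each data
file (``<name>.meta.json``), which avoids timezone ambiguity inside data
files.  Schedules and run configurations are YAML.
"""
from __future__ import annotations

import dataclasses
import json
import zlib
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import behavior, circadian, synthetic, tag as tag_mod, vibration
from .tag import (ExposureSchedule, ScheduleInterval, TagRecord,
                  ValveAngleSeries)
from .vibration import TriaxialSeries

__all__ = [
    "ValidationError",
    "write_triaxial_csv", "read_triaxial_csv",
    "write_tag_csv", "read_tag_csv",
    "write_valve_csv", "read_valve_csv",
    "write_annotations_csv", "read_annotations_csv",
    "write_calibration_csv", "read_calibration_csv",
    "write_schedule_yaml", "read_schedule_yaml",
    "write_ground_truth", "read_ground_truth",
    "child_seed", "RunConfig", "run_pipeline",
]

_FLOAT_FMT = "%.10g"


class ValidationError(ValueError):
    """Malformed file or configuration."""


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _write_meta(path: Path, meta: dict) -> None:
    _meta_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def _read_meta(path: Path) -> dict:
    mp = _meta_path(path)
    if not mp.exists():
        raise ValidationError(f"missing metadata sidecar {mp}")
    return json.loads(mp.read_text())


def _check_monotone_time(t: np.ndarray, path: Path) -> None:
    bad = np.flatnonzero(np.diff(t) <= 0)
    if len(bad):
        # +2: header line plus 1-based indexing of the later row
        raise ValidationError(
            f"{path}: time reversal at line {int(bad[0]) + 3}")


def _check_rate(t: np.ndarray, fs: float, path: Path) -> None:
    if len(t) > 1:
        observed = (len(t) - 1) / (t[-1] - t[0])
        if abs(observed - fs) / fs > 0.01:
            raise ValidationError(
                f"{path}: observed rate {observed:.4f} Hz deviates >1% from "
                f"declared {fs} Hz")


# ---------------------------------------------------------------------------
# triaxial series
# ---------------------------------------------------------------------------

def write_triaxial_csv(series: TriaxialSeries, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_s": series.times, "x": series.x, "y": series.y,
                       "z": series.z})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    _write_meta(path, {"start_time": series.start_time.isoformat(),
                       "fs": series.fs, "site": series.site,
                       "distance_m": series.distance_m})


def read_triaxial_csv(path: str | Path) -> TriaxialSeries:
    path = Path(path)
    meta = _read_meta(path)
    df = pd.read_csv(path)
    for col in ("time_s", "x", "y", "z"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy()
    _check_monotone_time(t, path)
    _check_rate(t, meta["fs"], path)
    return TriaxialSeries(fs=meta["fs"], x=df["x"].to_numpy(),
                          y=df["y"].to_numpy(), z=df["z"].to_numpy(),
                          start_time=datetime.fromisoformat(meta["start_time"]),
                          site=meta.get("site", ""),
                          distance_m=meta.get("distance_m"))


# ---------------------------------------------------------------------------
# tag records
# ---------------------------------------------------------------------------

def write_tag_csv(record: TagRecord, mag_path: str | Path,
                  acc_path: str | Path) -> None:
    mag_path, acc_path = Path(mag_path), Path(acc_path)
    pd.DataFrame({"time_s": record.mag_time, "mv": record.mag_mv}).to_csv(
        mag_path, index=False, float_format=_FLOAT_FMT)
    pd.DataFrame({"time_s": record.acc_time, "x": record.acc_x,
                  "y": record.acc_y, "z": record.acc_z}).to_csv(
        acc_path, index=False, float_format=_FLOAT_FMT)
    meta = {"start_time": record.start_time.isoformat(),
            "fs_mag": record.fs_mag, "fs_acc": record.fs_acc,
            "individual": record.individual, "site": record.site}
    _write_meta(mag_path, meta)
    _write_meta(acc_path, meta)


def read_tag_csv(mag_path: str | Path, acc_path: str | Path) -> TagRecord:
    mag_path, acc_path = Path(mag_path), Path(acc_path)
    meta = _read_meta(mag_path)
    mag = pd.read_csv(mag_path)
    acc = pd.read_csv(acc_path)
    for col in ("time_s", "mv"):
        if col not in mag.columns:
            raise ValidationError(f"{mag_path}: missing column {col!r}")
    for col in ("time_s", "x", "y", "z"):
        if col not in acc.columns:
            raise ValidationError(f"{acc_path}: missing column {col!r}")
    tm = mag["time_s"].to_numpy()
    ta = acc["time_s"].to_numpy()
    _check_monotone_time(tm, mag_path)
    _check_monotone_time(ta, acc_path)
    _check_rate(tm, meta["fs_mag"], mag_path)
    _check_rate(ta, meta["fs_acc"], acc_path)
    return TagRecord(mag_time=tm, mag_mv=mag["mv"].to_numpy(),
                     acc_time=ta, acc_x=acc["x"].to_numpy(),
                     acc_y=acc["y"].to_numpy(), acc_z=acc["z"].to_numpy(),
                     fs_mag=meta["fs_mag"], fs_acc=meta["fs_acc"],
                     individual=meta.get("individual", ""),
                     site=meta.get("site", ""),
                     start_time=datetime.fromisoformat(meta["start_time"]))


# ---------------------------------------------------------------------------
# valve-angle series
# ---------------------------------------------------------------------------

def write_valve_csv(angles: ValveAngleSeries, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": angles.times, "angle_deg": angles.angle}).to_csv(
        path, index=False, float_format=_FLOAT_FMT)
    _write_meta(path, {"start_time": angles.start_time.isoformat(),
                       "fs": angles.fs, "individual": angles.individual})


def read_valve_csv(path: str | Path) -> ValveAngleSeries:
    path = Path(path)
    meta = _read_meta(path)
    df = pd.read_csv(path)
    for col in ("time_s", "angle_deg"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy()
    _check_monotone_time(t, path)
    _check_rate(t, meta["fs"], path)
    return ValveAngleSeries(fs=meta["fs"], angle=df["angle_deg"].to_numpy(),
                            start_time=datetime.fromisoformat(meta["start_time"]),
                            individual=meta.get("individual", ""))


# ---------------------------------------------------------------------------
# annotations, calibration, schedule, ground truth
# ---------------------------------------------------------------------------

_ANN_WRITE_COLS = ["time_s", "subject", "stage", "site", "treatment",
                   "behavior", "modifier"]


def write_annotations_csv(table: pd.DataFrame, path: str | Path) -> None:
    """BORIS-style export: the fish_nearby flag is carried in ``modifier``."""
    out = table.copy()
    out["modifier"] = np.where(out["fish_nearby"].astype(bool), "fish_nearby", "")
    out[_ANN_WRITE_COLS].to_csv(Path(path), index=False,
                                float_format=_FLOAT_FMT)


def read_annotations_csv(path: str | Path,
                         column_map: Optional[dict] = None) -> pd.DataFrame:
    """Read a BORIS-style annotation CSV; ``column_map`` renames incoming
    columns to the canonical schema before validation."""
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    missing = {"time_s", "subject", "stage", "site", "treatment",
               "behavior"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if "fish_nearby" not in df.columns:
        mod = df["modifier"].astype(str) if "modifier" in df.columns else ""
        df["fish_nearby"] = (pd.Series(mod, index=df.index)
                             .str.contains("fish_nearby", na=False))
    try:
        behavior.validate_annotations(df)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    return df.drop(columns=[c for c in ("modifier",) if c in df.columns])


def write_calibration_csv(cal: tag_mod.MagCalibration, path: str | Path) -> None:
    pd.DataFrame({"mv": cal.mv, "degrees": cal.degrees}).to_csv(
        Path(path), index=False, float_format=_FLOAT_FMT)


def read_calibration_csv(path: str | Path) -> tag_mod.MagCalibration:
    df = pd.read_csv(Path(path))
    for col in ("mv", "degrees"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    try:
        return tag_mod.fit_calibration(list(zip(df["mv"], df["degrees"])))
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_schedule_yaml(schedule: ExposureSchedule, path: str | Path) -> None:
    data = {"timezone": schedule.timezone,
            "intervals": [{"label": iv.label, "start_s": iv.start_s,
                           "end_s": iv.end_s} for iv in schedule.intervals]}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_schedule_yaml(path: str | Path) -> ExposureSchedule:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "intervals" not in data:
        raise ValidationError(f"{path}: schedule must define 'intervals'")
    try:
        ivs = tuple(ScheduleInterval(iv["label"], float(iv["start_s"]),
                                     float(iv["end_s"]))
                    for iv in data["intervals"])
        return ExposureSchedule(intervals=ivs,
                                timezone=data.get("timezone", "local"))
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_ground_truth(truth: synthetic.GroundTruth, path: str | Path) -> None:
    data = {"strike_times": [float(v) for v in truth.strike_times],
            "closure_events": [{"time": t, "depth_deg": d, "type": ty}
                               for t, d, ty in truth.closure_events],
            "circadian_period_h": truth.circadian_period_h}
    Path(path).write_text(json.dumps(data, indent=1))


def read_ground_truth(path: str | Path) -> synthetic.GroundTruth:
    data = json.loads(Path(path).read_text())
    return synthetic.GroundTruth(
        strike_times=np.array(data["strike_times"]),
        closure_events=[(e["time"], e["depth_deg"], e["type"])
                        for e in data["closure_events"]],
        circadian_period_h=data.get("circadian_period_h"))


# ---------------------------------------------------------------------------
# seeding and run configuration
# ---------------------------------------------------------------------------

def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed: the global seed is combined with
    the CRC-32 of the stage name through SeedSequence, so stages are
    independently reproducible.  Result fits in 31 bits."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


_RUN_KEYS = {"seed", "days", "sim", "schedule", "geophone", "thresholds",
             "annotations"}
_SCHED_KEYS = {"n_days", "events_per_day", "start_hour", "vh_min", "gap_min",
               "ih_min", "inter_event_gap_min", "first_day"}
_GEO_KEYS = {"ih_duration_s", "vh_duration_s", "ambient_duration_s"}
_THRESH_KEYS = {"threshold_db", "min_separation_s", "bin_minutes",
                "partial_drop_deg", "total_threshold_deg", "sync_window_s"}
_ANN_KEYS = {"minutes", "fish_flag_prob"}


@dataclasses.dataclass
class RunConfig:
    """Validated configuration for the end-to-end demo pipeline."""

    seed: int = 0
    days: int = 4
    sim: dict = dataclasses.field(default_factory=dict)
    schedule: dict = dataclasses.field(default_factory=dict)
    geophone: dict = dataclasses.field(default_factory=dict)
    thresholds: dict = dataclasses.field(default_factory=dict)
    annotations: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        sim_fields = {f.name for f in dataclasses.fields(synthetic.SimConfig)}
        for name, given, allowed in (
                ("sim", self.sim, sim_fields),
                ("schedule", self.schedule, _SCHED_KEYS),
                ("geophone", self.geophone, _GEO_KEYS),
                ("thresholds", self.thresholds, _THRESH_KEYS),
                ("annotations", self.annotations, _ANN_KEYS)):
            unknown = set(given) - allowed
            if unknown:
                raise ValidationError(
                    f"unknown {name} key(s): {sorted(unknown)}")
        if self.days < 3:
            raise ValidationError("days must be >= 3 (periodicity analysis "
                                  "needs three whole days)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        unknown = set(data) - _RUN_KEYS
        if unknown:
            raise ValidationError(f"{path}: unknown key(s): {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute simulate -> vibration -> tag -> circadian -> rates and return
    one structured report.  Identical config and seed give identical reports
    (no timestamps in the body)."""
    cfg = synthetic.SimConfig(seed=config.seed, **config.sim)
    thr = config.thresholds
    report: dict = {"seed": config.seed, "days": config.days,
                    "software_version": __import__("scallop_pd").__version__,
                    "parameters": {"sim": config.sim, "thresholds": thr}}

    # --- geophone stage -----------------------------------------------------
    geo = config.geophone
    rng = np.random.default_rng(child_seed(config.seed, "geophone"))
    ih_series, ih_truth = synthetic.gen_ih_train(
        cfg, float(geo.get("ih_duration_s", 300.0)), rng=rng)
    events = vibration.detect_strikes(
        ih_series, thr.get("threshold_db", 12.0), thr.get("min_separation_s", 1.0))
    summ = vibration.event_summary(ih_series, events)
    vh_series = synthetic.gen_vh_signal(
        cfg, float(geo.get("vh_duration_s", 60.0)), rng=rng)
    vh_rms_db, vh_sel_db = vibration.vh_metrics(vh_series)
    amb_axes = synthetic._ambient_floor(
        cfg, int(cfg.fs_geo * float(geo.get("ambient_duration_s", 30.0))),
        cfg.fs_geo, rng)
    amb_series = TriaxialSeries(fs=cfg.fs_geo, x=amb_axes[0], y=amb_axes[1],
                                z=amb_axes[2])
    report["vibration"] = {
        "n_strikes_true": int(len(ih_truth.strike_times)),
        "n_strikes_detected": summ.n_strikes,
        "ipi_mean_s": round(summ.ipi_mean_s, 4),
        "peak_level_db_mean": round(summ.peak_level_db_mean, 3),
        "sel_ss_db_mean": round(summ.sel_ss_db_mean, 3),
        "sel_cum_db": round(summ.sel_cum_db, 3),
        "vh_rms_db": round(vh_rms_db, 3),
        "vh_sel_db": round(vh_sel_db, 3),
        "ambient_db": round(vibration.ambient_level(amb_series), 3),
    }

    # --- tag stage ----------------------------------------------------------
    sched_kwargs = dict(config.schedule)
    sched_kwargs.setdefault("n_days", max(1, config.days - 1))
    schedule = ExposureSchedule.daily_pd(**sched_kwargs)
    rng_tag = np.random.default_rng(child_seed(config.seed, "tag"))
    record, truth = synthetic.gen_tag_record(cfg, schedule, config.days,
                                             rng=rng_tag, include_acc=False)
    cal = tag_mod.fit_calibration(
        [(cfg.mag_offset_mv + cfg.mag_slope_mv_per_deg * d, d)
         for d in (0.0, 10.0, 30.0, 60.0, 90.0)])
    angles = tag_mod.mv_to_angle(record, cal)
    stats = tag_mod.exposure_stats(angles, schedule)
    closures = tag_mod.detect_closures(
        angles, truth.strike_times,
        partial_drop_deg=thr.get("partial_drop_deg", 1.0),
        total_threshold_deg=thr.get("total_threshold_deg", 1.0),
        sync_window_s=thr.get("sync_window_s", 2.0))
    report["tag"] = {
        "pre15_mean_deg": round(stats.pre15_mean, 3),
        "exposure_mean_deg": round(stats.exposure_mean, 3),
        "post15_mean_deg": round(stats.post15_mean, 3),
        "relative_reduction": round(stats.relative_reduction, 4),
        "n_closures_true": len(truth.closure_events),
        "n_closures_detected": len(closures),
    }

    # --- circadian stage ----------------------------------------------------
    per = circadian.periodogram(angles, bin_minutes=thr.get("bin_minutes", 10.0))
    report["circadian"] = {
        "dominant_period_h": round(per.dominant_period_h, 3),
        "fisher_g": round(per.g, 5),
        "p_value": float(per.p_value),
    }

    # --- behavior stage -----------------------------------------------------
    ann_cfg = config.annotations
    design = _demo_design()
    table = synthetic.gen_annotations(
        design, minutes=float(ann_cfg.get("minutes", 15.0)),
        fish_flag_prob=float(ann_cfg.get("fish_flag_prob", 0.1)),
        seed=np.random.default_rng(child_seed(config.seed, "annotations")))
    filtered, removed = behavior.filter_annotations(table)
    rates = behavior.compute_rates(filtered,
                                   windows=float(ann_cfg.get("minutes", 15.0)))
    summary = behavior.rate_summary(rates)
    near_ih = summary[(summary["site"] == "near")
                      & (summary["treatment"] == "IH1")
                      & (summary["stage"] == "juvenile")]
    report["behavior"] = {
        "n_events": int(len(table)),
        "n_fish_removed": removed,
        "near_juvenile_IH1_closures_per_min": round(
            float(near_ih["partial_closure_per_min_mean"].iloc[0]), 3),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1,
                                                    sort_keys=True))
    return report


def _demo_design() -> pd.DataFrame:
    """Small two-site behavioral design with near-site impact-hammer
    elevation (rates in events/min)."""
    rows = []
    for site in ("near", "far"):
        for stage, n in (("juvenile", 6), ("subadult", 4), ("adult", 4)):
            for tr in behavior.TREATMENTS:
                if site == "near" and tr.startswith("IH"):
                    rate = {"juvenile": 5.1, "subadult": 1.5, "adult": 2.2}[stage]
                elif site == "near" and tr.startswith("VH"):
                    rate = 0.8
                else:
                    rate = 0.2
                rows.append({"stage": stage, "site": site, "treatment": tr,
                             "behavior": "partial_closure",
                             "rate_per_min": rate, "n_individuals": n})
                rows.append({"stage": stage, "site": site, "treatment": tr,
                             "behavior": "coughing",
                             "rate_per_min": 0.5 if site == "near" else 0.9,
                             "n_individuals": n})
    return pd.DataFrame(rows)
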