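"""Tag pipeline: calibration round trips, closure detection, exposure-window
statistics, strike synchronization, and the mixed-model ladder."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scallop_pd import synthetic, tag
from scallop_pd.synthetic import SimConfig, gen_angle_observations, gen_tag_record
from scallop_pd.tag import (
    ExposureSchedule, ScheduleInterval, ValveAngleSeries, detect_closures,
    detect_tag_strikes, exposure_stats, fit_calibration, lmm_ladder,
    mv_to_angle,
)


class TestCalibration:
    def test_linear_midpoint(self):
        cal = fit_calibration([(400.0, 0.0), (600.0, 10.0)])
        assert cal.angle(500.0) == pytest.approx(5.0)

    def test_extrapolation_clamps(self):
        cal = fit_calibration([(400.0, 0.0), (600.0, 10.0)])
        assert cal.angle(700.0) == pytest.approx(10.0)
        assert cal.angle(300.0) == pytest.approx(0.0)

    def test_rejects_non_monotone(self):
        with pytest.raises(ValueError):
            fit_calibration([(400.0, 0.0), (600.0, 10.0), (500.0, 20.0)])
        with pytest.raises(ValueError):
            fit_calibration([(400.0, 0.0), (400.0, 10.0)])
        with pytest.raises(ValueError):
            fit_calibration([(400.0, 0.0)])

    def test_rejects_out_of_range_angles(self):
        with pytest.raises(ValueError):
            fit_calibration([(400.0, -5.0), (600.0, 10.0)])

    def test_round_trip_through_generator(self, linear_cal):
        # noiseless tag: recovered angles match truth to < 0.1 degree
        cfg = SimConfig(seed=20, angle_noise_sd=0.0, mag_noise_sd_mv=0.0)
        sched = ExposureSchedule.daily_pd(n_days=1, events_per_day=2)
        rec, truth = gen_tag_record(cfg, sched, 1, include_acc=False)
        angles = mv_to_angle(rec, linear_cal)
        assert np.max(np.abs(angles.angle - truth.angle_truth)) < 0.1

    @given(mv=st.floats(350.0, 2300.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_mapping_stays_in_calibrated_range(self, linear_cal, mv):
        a = linear_cal.angle(mv)
        assert 0.0 <= a <= 90.0


class TestMvToAngle:
    def test_constant_voltage_constant_angle(self, linear_cal):
        rec = tag.TagRecord(mag_time=np.arange(20) / 2.0,
                            mag_mv=np.full(20, 500.0),
                            acc_time=np.arange(250) / 25.0,
                            acc_x=np.zeros(250), acc_y=np.zeros(250),
                            acc_z=np.zeros(250))
        angles = mv_to_angle(rec, linear_cal)
        assert np.allclose(angles.angle, 5.0)

    def test_nan_sample_rejected(self, linear_cal):
        mv = np.full(20, 500.0)
        mv[7] = np.nan
        rec = tag.TagRecord(mag_time=np.arange(20) / 2.0, mag_mv=mv,
                            acc_time=np.arange(250) / 25.0,
                            acc_x=np.zeros(250), acc_y=np.zeros(250),
                            acc_z=np.zeros(250))
        with pytest.raises(ValueError, match="index 7"):
            mv_to_angle(rec, linear_cal)


class TestScheduleValidation:
    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            ExposureSchedule(intervals=(
                ScheduleInterval("VH", 0.0, 100.0),
                ScheduleInterval("IH", 50.0, 150.0)))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            ScheduleInterval("lunch", 0.0, 100.0)


class TestDetectTagStrikes:
    def test_ih_strikes_recovered_from_accelerometer(self):
        cfg = SimConfig(seed=21)
        sched = ExposureSchedule(
            intervals=(ScheduleInterval("IH", 600.0, 1500.0),))
        rec, truth = gen_tag_record(cfg, sched, 1, include_acc=True)
        # analyze a window around the IH interval only (keeps the test fast)
        i0, i1 = int(500 * 25), int(1600 * 25)
        sub = tag.TagRecord(mag_time=rec.mag_time[:100], mag_mv=rec.mag_mv[:100],
                            acc_time=rec.acc_time[i0:i1] - 500.0,
                            acc_x=rec.acc_x[i0:i1], acc_y=rec.acc_y[i0:i1],
                            acc_z=rec.acc_z[i0:i1])
        det = detect_tag_strikes(sub)
        assert not det.continuous_activity
        got = det.times + 500.0
        for t in truth.strike_times:
            assert np.min(np.abs(got - t)) <= 0.08 + 1e-9

    def test_vibratory_phase_flagged_continuous(self):
        cfg = SimConfig(seed=22)
        sched = ExposureSchedule(
            intervals=(ScheduleInterval("VH", 0.0, 600.0),))
        rec, _ = gen_tag_record(cfg, sched, 1, include_acc=True)
        # window spans the vibratory phase plus quiet time (the detector
        # needs quiet frames to estimate the ambient floor)
        i1 = int(1200 * 25)
        sub = tag.TagRecord(mag_time=rec.mag_time[:100], mag_mv=rec.mag_mv[:100],
                            acc_time=rec.acc_time[:i1],
                            acc_x=rec.acc_x[:i1], acc_y=rec.acc_y[:i1],
                            acc_z=rec.acc_z[:i1])
        det = detect_tag_strikes(sub)
        assert det.continuous_activity
        assert len(det.times) == 0

    def test_quiet_stream_empty(self, rng):
        acc = rng.normal(0, 0.01, size=(3, 2500))
        rec = tag.TagRecord(mag_time=np.arange(20) / 2.0,
                            mag_mv=np.full(20, 500.0),
                            acc_time=np.arange(2500) / 25.0,
                            acc_x=acc[0], acc_y=acc[1], acc_z=acc[2])
        det = detect_tag_strikes(rec)
        assert not det.continuous_activity
        assert len(det.times) == 0


def _flat_series_with_dips(dips, n=7200, fs=2.0, level=7.0, noise=0.0, seed=0):
    """Flat angle trace with exponential-recovery dips at given (time, depth)."""
    rng = np.random.default_rng(seed)
    a = np.full(n, level)
    t = np.arange(n) / fs
    for tc, depth in dips:
        m = t >= tc
        a[m] -= depth * np.exp(-(t[m] - tc) / 5.0)
    if noise:
        a = a + rng.normal(0, noise, n)
    return ValveAngleSeries(fs=fs, angle=np.clip(a, 0, 90))


class TestDetectClosures:
    def test_single_closure_detected_with_latency(self):
        angles = _flat_series_with_dips([(1800.0, 3.0)], noise=0.3, seed=1)
        events = detect_closures(angles, strikes=[1799.5],
                                 partial_drop_deg=1.5)
        assert len(events) == 1
        ev = events[0]
        assert ev.type == "partial"
        assert ev.latency_to_strike is not None and ev.latency_to_strike < 1.0
        assert ev.depth == pytest.approx(3.0, abs=0.7)

    def test_flat_series_no_events(self):
        angles = ValveAngleSeries(fs=2.0, angle=np.full(7200, 7.0))
        assert detect_closures(angles) == []

    def test_total_closure_duration(self):
        # shells shut (0 deg) for 0.12 min = 7.2 s
        a = np.full(4800, 7.0)
        a[2400:2400 + 14] = 0.0
        angles = ValveAngleSeries(fs=2.0, angle=a)
        events = detect_closures(angles)
        assert len(events) == 1
        assert events[0].type == "total"
        assert events[0].duration == pytest.approx(7.2, abs=1.5)

    def test_invalid_sync_window_rejected(self):
        angles = ValveAngleSeries(fs=2.0, angle=np.full(1200, 7.0))
        with pytest.raises(ValueError):
            detect_closures(angles, sync_window_s=0.0)

    def test_recall_precision_on_default_conditions(self, linear_cal):
        """Pooled over two exposure days at default SNR: >= 0.95/0.95."""
        n_true = n_det = n_hit_true = n_hit_det = 0
        sched = ExposureSchedule.daily_pd(n_days=1, events_per_day=4)
        for seed in (0, 1):
            cfg = SimConfig(seed=seed)
            rec, truth = gen_tag_record(cfg, sched, 1, include_acc=False)
            angles = mv_to_angle(rec, linear_cal)
            events = detect_closures(angles, truth.strike_times)
            true_t = np.array([c[0] for c in truth.closure_events])
            det_t = np.array([e.time for e in events])
            n_true += len(true_t)
            n_det += len(det_t)
            n_hit_true += sum(np.any(np.abs(det_t - t) <= 2.5) for t in true_t)
            n_hit_det += sum(np.any(np.abs(true_t - t) <= 2.5) for t in det_t)
        assert n_hit_true / n_true >= 0.95
        assert n_hit_det / n_det >= 0.95

    def test_ih_closures_have_bounded_latency(self, linear_cal):
        cfg = SimConfig(seed=2)
        sched = ExposureSchedule.daily_pd(n_days=1, events_per_day=2)
        rec, truth = gen_tag_record(cfg, sched, 1, include_acc=False)
        events = detect_closures(mv_to_angle(rec, linear_cal),
                                 truth.strike_times, sync_window_s=2.0)
        with_latency = [e for e in events if e.latency_to_strike is not None]
        assert len(with_latency) >= 0.8 * len(events)
        assert all(0.0 <= e.latency_to_strike <= 2.0 for e in with_latency)


class TestExposureStats:
    def test_window_accounting_is_exact(self, linear_cal):
        cfg = SimConfig(seed=23)
        sched = ExposureSchedule.daily_pd(n_days=2, events_per_day=3)
        rec, _ = gen_tag_record(cfg, sched, 2, include_acc=False)
        angles = mv_to_angle(rec, linear_cal)
        st = exposure_stats(angles, sched)
        for label in ("VH", "IH"):
            expected = sum(iv.duration for iv in sched.by_label(label)) * angles.fs
            assert st.label_stats[label]["n"] == int(expected)

    def test_no_exposure_schedule_yields_absent_fields(self, linear_cal):
        cfg = SimConfig(seed=24)
        rec, _ = gen_tag_record(cfg, ExposureSchedule(intervals=()), 1,
                                include_acc=False)
        st = exposure_stats(mv_to_angle(rec, linear_cal),
                            ExposureSchedule(intervals=()))
        assert st.exposure_mean is None and st.pre15_mean is None

    def test_window_outside_record_rejected(self):
        angles = ValveAngleSeries(fs=2.0, angle=np.full(1200, 7.0))
        sched = ExposureSchedule(
            intervals=(ScheduleInterval("IH", 500.0, 900.0),))
        with pytest.raises(ValueError):
            exposure_stats(angles, sched)

    def test_relative_reduction_sign(self, linear_cal):
        cfg = SimConfig(seed=25)
        sched = ExposureSchedule.daily_pd(n_days=2, events_per_day=2)
        rec, _ = gen_tag_record(cfg, sched, 2, include_acc=False)
        st = exposure_stats(mv_to_angle(rec, linear_cal), sched)
        # ~25% angle reduction during exposure at the default means
        assert 0.15 < st.relative_reduction < 0.35


class TestLmmLadder:
    def test_exposure_effect_selects_phase_model(self):
        df = gen_angle_observations(effect_exposure=-0.28, rng=31)
        res = lmm_ladder(df)
        assert res.selected == "phase"
        assert res.steps[1].p_value < 0.001

    def test_pure_noise_retains_null(self):
        df = gen_angle_observations(effect_exposure=0.0, rng=32)
        assert lmm_ladder(df).selected == "null"

    def test_likelihood_never_decreases_along_ladder(self):
        df = gen_angle_observations(effect_exposure=-0.28, effect_type=-0.1,
                                    rng=33)
        res = lmm_ladder(df)
        llfs = [s.llf for s in res.steps]
        assert all(b >= a - 1e-6 for a, b in zip(llfs, llfs[1:]))

    def test_single_individual_rejected(self):
        df = gen_angle_observations(n_individuals=1, rng=34)
        with pytest.raises(ValueError):
            lmm_ladder(df)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            lmm_ladder(pd.DataFrame({"angle": [1.0, 2.0]}))
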