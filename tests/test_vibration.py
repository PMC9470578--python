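"""Vibration metrics: closed-form pulse oracles, SEL algebra, level chains,
PSDs, and the strike detector."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scallop_pd import synthetic, vibration
from scallop_pd.vibration import (
    PulseMetrics, SignalAbsentError, StrikeEvent, TriaxialSeries,
    ambient_level, db_to_amplitude, detect_strikes, event_summary, psd,
    pulse_metrics, sel_cum, vh_metrics,
)


def _mono_series(x, fs):
    """Put a scalar trace on the x axis (magnitude equals |x|)."""
    z = np.zeros_like(x)
    return TriaxialSeries(fs=fs, x=np.asarray(x, float), y=z, z=z.copy())


def _rect_pulse(fs=1000.0, amp=1000.0, width=1.0, pad=0.1):
    n_pad = int(pad * fs)
    x = np.concatenate([np.zeros(n_pad), np.full(int(width * fs), amp),
                        np.zeros(n_pad)])
    return _mono_series(x, fs)


class TestPulseMetrics:
    def test_rectangle_closed_form(self):
        # 1000 µm/s² for 1 s: peak 60 dB, 90%-energy SEL 10 log10(0.9e6)
        s = _rect_pulse()
        ev = StrikeEvent(onset=0.15, window=(0.0, 1.15))
        m = pulse_metrics(s, ev)
        assert m.peak_level_db == pytest.approx(60.0, abs=1e-9)
        assert m.sel_ss_db == pytest.approx(10 * np.log10(0.9e6), abs=0.02)
        # amplitude crossings at 5% and 90% coincide on the leading edge
        assert m.pulse_duration_s <= 2.0 / s.fs
        t5, t95 = m.energy_window
        assert t95 - t5 == pytest.approx(0.9, abs=2.0 / s.fs)

    def test_triangle_closed_form(self):
        # linear ramp 0 -> 1000 over 1 s then hard stop at fs=2000
        fs, amp = 2000.0, 1000.0
        x = np.concatenate([np.zeros(100), np.linspace(0, amp, int(fs)),
                            np.zeros(100)])
        s = _mono_series(x, fs)
        m = pulse_metrics(s, StrikeEvent(onset=0.5, window=(0.0, s.duration - 1/fs)))
        dt = 1.0 / fs
        # amplitude crossings: 0.05 and 0.90 of max on the ramp
        assert m.pulse_duration_s == pytest.approx(0.85, abs=2 * dt)
        # cumulative energy of t^2 grows as t^3
        t5_expected = 0.05 + 0.05 ** (1 / 3)  # ramp starts at 0.05 s
        assert m.energy_window[0] == pytest.approx(t5_expected, abs=2 * dt)
        assert m.energy_window[1] == pytest.approx(0.05 + 0.95 ** (1 / 3), abs=2 * dt)
        # rise time: 5% energy point to the peak (end of ramp)
        assert m.rise_time_s == pytest.approx(1.05 - t5_expected, abs=2 * dt)
        assert m.sel_ss_db == pytest.approx(10 * np.log10(0.9 * amp**2 / 3.0),
                                            abs=0.02)

    def test_field_scale_peak_level(self):
        amp = db_to_amplitude(109.95)
        s = _rect_pulse(amp=amp, width=0.1)
        m = pulse_metrics(s, StrikeEvent(onset=0.15, window=(0.0, 0.3)))
        assert m.peak_level_db == pytest.approx(109.95, abs=1e-9)

    def test_all_zero_window_signals_error(self):
        s = _mono_series(np.zeros(1000), 100.0)
        with pytest.raises(SignalAbsentError):
            pulse_metrics(s, StrikeEvent(onset=1.0, window=(0.5, 2.0)))


class TestSelCum:
    def test_identical_strikes_additivity(self):
        m = 94.39
        assert sel_cum([m] * 115) == pytest.approx(94.39 + 10 * np.log10(115),
                                                   abs=1e-9)

    def test_single_strike_identity(self):
        assert sel_cum([72.48]) == pytest.approx(72.48, abs=1e-12)

    def test_two_strikes_10db_apart(self):
        # quieter strike adds 10 log10(1.1) = 0.414 dB to the louder one
        assert sel_cum([80.0, 70.0]) == pytest.approx(
            80.0 + 10 * np.log10(1.1), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sel_cum([])

    @given(st.floats(40.0, 120.0), st.integers(1, 400))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_n_copies_property(self, sel_db, n):
        assert sel_cum([sel_db] * n) == pytest.approx(
            sel_db + 10 * np.log10(n), abs=1e-9)


class TestLevels:
    @given(st.floats(1e-3, 1e8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_db_round_trip(self, amp):
        level = vibration.amplitude_to_db(amp)
        assert db_to_amplitude(level) == pytest.approx(amp, rel=1e-9)

    def test_ambient_level_recovers_requested_rms(self, rng):
        cfg = synthetic.SimConfig(seed=3)
        axes = synthetic._ambient_floor(cfg, 6000, 200.0, rng)
        s = TriaxialSeries(fs=200.0, x=axes[0], y=axes[1], z=axes[2])
        assert ambient_level(s) == pytest.approx(53.86, abs=0.1)

    def test_doubling_amplitude_adds_6db(self, rng):
        x = rng.normal(0, 5.0, 4000)
        a = _mono_series(x, 200.0)
        b = _mono_series(2 * x, 200.0)
        assert ambient_level(b) - ambient_level(a) == pytest.approx(
            20 * np.log10(2), abs=1e-9)

    def test_unit_rms_is_zero_db(self):
        x = np.ones(400)
        assert ambient_level(_mono_series(x, 100.0)) == pytest.approx(0.0, abs=1e-9)

    def test_vh_unit_rms(self, rng):
        x = rng.choice([-1.0, 1.0], 2000)
        rms_db, _sel = vh_metrics(_mono_series(x, 200.0))
        assert rms_db == pytest.approx(0.0, abs=0.05)

    def test_vh_energy_rms_identity(self, rng):
        # stationary record: sel ~= rms + 10 log10(0.9 T)
        x = rng.normal(0, 30.0, 12000)
        s = _mono_series(x, 200.0)
        rms_db, sel_db = vh_metrics(s)
        assert sel_db == pytest.approx(rms_db + 10 * np.log10(0.9 * s.duration),
                                       abs=0.05)


class TestPsd:
    def test_white_noise_parseval(self, rng):
        x = rng.normal(0, 2.0, 40000)
        s = _mono_series(x, 200.0)
        r = psd(s, segment_s=1.0)
        df = r.freqs[1] - r.freqs[0]
        assert np.sum(r.psd_x) * df == pytest.approx(np.var(x), rel=0.05)

    def test_sinusoid_peak_at_10hz(self):
        t = np.arange(0, 60, 1 / 200.0)
        s = _mono_series(100 * np.sin(2 * np.pi * 10.0 * t), 200.0)
        r = psd(s, segment_s=2.0)
        df = r.freqs[1] - r.freqs[0]
        assert abs(r.freqs[np.argmax(r.psd_x)] - 10.0) <= df

    def test_segment_longer_than_record_rejected(self):
        s = _mono_series(np.ones(100), 100.0)
        with pytest.raises(ValueError):
            psd(s, segment_s=10.0)


class TestDetector:
    def test_recovers_all_strikes_and_ipi(self):
        cfg = synthetic.SimConfig(seed=7)
        series, truth = synthetic.gen_ih_train(cfg, 600.0)
        events = detect_strikes(series)
        det = np.array([e.onset for e in events])
        assert len(det) == len(truth.strike_times)
        assert np.all(np.abs(det - truth.strike_times) < 0.5)
        assert np.diff(det).mean() == pytest.approx(6.63, abs=0.3)

    def test_recall_precision_at_20db_snr(self):
        # peak 20 dB above the ambient floor, fixed (no per-strike spread)
        cfg = synthetic.SimConfig(seed=21, ih_peak_db=53.86 + 20.0,
                                  ih_peak_sd_db=0.0)
        series, truth = synthetic.gen_ih_train(cfg, 600.0)
        det = np.array([e.onset for e in detect_strikes(series)])
        matched_true = sum(np.any(np.abs(det - t) < 0.5)
                           for t in truth.strike_times)
        matched_det = sum(np.any(np.abs(truth.strike_times - t) < 0.5)
                          for t in det)
        assert matched_true / len(truth.strike_times) >= 0.99
        assert matched_det == len(det)  # precision 1.0

    def test_pure_ambient_gives_no_strikes(self, rng):
        x = rng.normal(0, 5.0, 6000)
        y = rng.normal(0, 5.0, 6000)
        z = rng.normal(0, 5.0, 6000)
        s = TriaxialSeries(fs=200.0, x=x, y=y, z=z)
        assert detect_strikes(s) == []

    def test_min_separation_merges_close_pulses(self):
        fs = 200.0
        x = np.zeros(4000)
        for t0 in (10.0, 10.3):
            i = int(t0 * fs)
            x[i:i + 20] = 1000.0
        s = _mono_series(x + 0.001 * np.ones_like(x), fs)
        events = detect_strikes(s, min_separation_s=1.0)
        assert len(events) == 1

    def test_short_record_rejected(self):
        s = _mono_series(np.ones(100), 100.0)
        with pytest.raises(ValueError):
            detect_strikes(s)

    def test_event_summary_consistency(self):
        cfg = synthetic.SimConfig(seed=9)
        series, _ = synthetic.gen_ih_train(cfg, 300.0)
        events = detect_strikes(series)
        summ = event_summary(series, events)
        assert summ.n_strikes == len(events)
        # SEL_cum dominates every single-strike SEL
        assert summ.sel_cum_db >= summ.sel_ss_db_mean
        assert summ.peak_level_db_mean == pytest.approx(109.95, abs=1.5)
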