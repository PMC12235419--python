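"""Tests for the detrending, smoothing and extremum analysis pipeline."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lucirhythm.model_core import ModelParams, closed_form_eff
from lucirhythm.rhythm_metrics import (
    Extremum,
    TimeSeries,
    amplitude_half_swing,
    average_series,
    centered_moving_average,
    detect_extrema,
    filter_extrema,
    phase_difference,
    phase_since_last_peak,
    relative_series,
    rhythm_report,
    smooth,
    smoothing_attenuation,
    window_mean,
)

STEP = 1.0 / 3.0


def cosine_series(t0=0.0, t1=140.0, period=26.0, amplitude=0.25, mean=1.0,
                  phase_h=0.0):
    t = np.arange(t0, t1 + 1e-9, STEP)
    v = mean * (1 - amplitude * np.cos(2 * np.pi * (t - phase_h) / period))
    return TimeSeries(t, v)


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        ts = TimeSeries(np.arange(0, 40, STEP), np.full(120, 3.7))
        ma = centered_moving_average(ts)
        assert np.allclose(ma.values, 3.7)
        assert ma.times[0] == pytest.approx(ts.times[0] + 13.0)
        assert ma.times[-1] == pytest.approx(ts.times[-1] - 13.0)

    def test_one_period_cosine_nearly_cancelled(self):
        ts = cosine_series()
        ma = centered_moving_average(ts, 26.0)
        # 79-sample discrete mean leaks ~1.27% of a 26-h cosine
        assert np.max(np.abs(ma.values - 1.0)) <= 0.013 * 0.25 + 1e-9

    def test_tracks_equilibrating_amount(self):
        p = ModelParams(gamma=0.07)
        t = np.arange(0, 140 + 1e-9, STEP)
        traj = closed_form_eff(p, t)
        ma = centered_moving_average(TimeSeries(t, traj.x))
        at_106 = ma.values[np.argmin(np.abs(ma.times - 106.0))]
        assert at_106 == pytest.approx(14.28, abs=0.01)

    def test_short_series_rejected(self):
        ts = TimeSeries(np.arange(0, 20, STEP), np.ones(60))
        with pytest.raises(ValueError):
            centered_moving_average(ts, 26.0)


class TestRelativeSeries:
    def test_constant_series_gives_unity(self):
        ts = TimeSeries(np.arange(0, 60, STEP), np.full(180, 42.0))
        rel = relative_series(ts)
        assert np.allclose(rel.values, 1.0)

    @given(c=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, c):
        ts = cosine_series(t1=80.0)
        scaled = TimeSeries(ts.times, c * ts.values)
        a, b = relative_series(ts), relative_series(scaled)
        assert np.allclose(a.values, b.values, rtol=1e-12)

    def test_zero_moving_average_rejected(self):
        t = np.arange(0, 40, STEP)
        v = np.zeros_like(t)
        with pytest.raises(ValueError):
            relative_series(TimeSeries(t, v))


class TestSmooth:
    def test_constant_unchanged(self):
        ts = TimeSeries(np.arange(0, 30, STEP), np.full(90, 5.0))
        assert np.allclose(smooth(ts).values, 5.0)

    def test_cosine_attenuation_and_zero_phase(self):
        ts = cosine_series(phase_h=0.0)  # troughs at 26k, peaks at 13 + 26k
        sm = smooth(ts, 7.0)
        att = smoothing_attenuation(21, 26.0)
        assert att == pytest.approx(0.885, abs=0.001)
        amp = (sm.values.max() - sm.values.min()) / 2
        assert amp == pytest.approx(0.25 * att, abs=0.001)
        peaks = [e for e in detect_extrema(sm) if e.kind == "peak"]
        assert min(abs(e.time % 26 - 13.0) for e in peaks) < 0.05

    def test_even_sample_window_rejected(self):
        ts = cosine_series(t1=40.0)
        with pytest.raises(ValueError):
            smooth(ts, 20 * STEP)  # 20 samples: even


class TestExtrema:
    def test_cosine_extrema_refined(self):
        ts = cosine_series(t0=13.0, t1=130.0)
        ext = detect_extrema(ts)
        troughs = [e.time for e in ext if e.kind == "trough"]
        peaks = [e.time for e in ext if e.kind == "peak"]
        assert np.allclose(troughs, [26, 52, 78, 104], atol=0.05)
        assert np.allclose(peaks, [39, 65, 91, 117], atol=0.05)

    @pytest.mark.parametrize("period", [20.0, 23.5, 26.0, 30.0])
    def test_refinement_accuracy_off_grid(self, period):
        ts = cosine_series(t1=3 * period, period=period, phase_h=0.37)
        ext = detect_extrema(ts)
        assert len(ext) >= 4
        for e in ext:
            # the series 1 - A*cos(2*pi*(t - phase_h)/P) troughs at phase_h
            target = 0.37 + (period / 2 if e.kind == "peak" else 0.0)
            assert min(abs(e.time - target - k * period)
                       for k in range(-1, 5)) < 0.05

    def test_alternation(self):
        ts = cosine_series(t1=120.0, phase_h=5.0)
        ext = detect_extrema(ts)
        kinds = [e.kind for e in ext]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_plateau_broken_at_midpoint(self):
        ts = TimeSeries(np.arange(7.0), [0, 1, 2, 2, 2, 1, 0])
        ext = detect_extrema(ts)
        assert len(ext) == 1
        assert ext[0].kind == "peak" and ext[0].plateau
        assert ext[0].time == pytest.approx(3.0)

    def test_filter_drops_jitter_pairs(self):
        base = cosine_series(t0=5.0, t1=120.0)
        wiggle = 0.01 * np.sin(2 * np.pi * base.times / 2.5)
        ext = detect_extrema(TimeSeries(base.times, base.values + wiggle))
        kept = filter_extrema(ext, min_swing=0.05)
        assert len(kept) < len(ext)
        assert all(a.kind != b.kind for a, b in zip(kept, kept[1:]))
        troughs = [e.time for e in kept if e.kind == "trough"]
        # the wiggle legitimately jitters the surviving extremum times
        assert np.allclose(troughs, [26, 52, 78, 104], atol=1.0)


class TestAmplitudeAndPhase:
    def test_half_swing(self):
        tr = Extremum(78.0, 0.75, "trough")
        pk = Extremum(91.0, 1.25, "peak")
        assert amplitude_half_swing(tr, pk) == pytest.approx(0.25)

    def test_half_swing_rejects_mislabeled(self):
        with pytest.raises(ValueError):
            amplitude_half_swing(Extremum(0, 1.0, "peak"), Extremum(1, 2.0, "peak"))
        with pytest.raises(ValueError):
            amplitude_half_swing(Extremum(0, 2.0, "trough"), Extremum(1, 1.0, "peak"))

    @pytest.mark.parametrize("peak_times, expected", [
        ([39.0, 65.0, 91.0], 19.0),
        ([18.3, 44.3, 70.3], 13.7),
        ([84.0], 0.0),
    ])
    def test_phase_since_last_peak(self, peak_times, expected):
        ext = [Extremum(t, 1.2, "peak") for t in peak_times]
        assert phase_since_last_peak(ext, 84.0) == pytest.approx(expected)

    def test_phase_requires_earlier_peak(self):
        with pytest.raises(ValueError):
            phase_since_last_peak([Extremum(90.0, 1.0, "peak")], 84.0)

    def test_phase_difference_wraps(self):
        a, b = _mk_report(1.0), _mk_report(25.0)
        assert phase_difference(a, b) == pytest.approx(2.0)  # wrapped into (-13, 13]
        assert phase_difference(b, a) == pytest.approx(-2.0)
        assert phase_difference(a, a) == 0.0


def _mk_report(phase):
    from lucirhythm.rhythm_metrics import RhythmReport, ExtremumList
    return RhythmReport(window_mean=1.0, relative_amplitude=0.2,
                        phase_at_ref=phase, extrema=ExtremumList(),
                        valid_range=(16.3, 123.7), t_ref=84.0, period=26.0)


class TestWindowMean:
    def test_constant(self):
        ts = TimeSeries(np.arange(0, 140, STEP), np.full(420, 2.5))
        assert window_mean(ts) == pytest.approx(2.5)

    def test_equilibrated_amount(self):
        p = ModelParams(gamma=0.07)
        t = np.arange(0, 140 + 1e-9, STEP)
        ts = TimeSeries(t, closed_form_eff(p, t).x)
        assert window_mean(ts) == pytest.approx(14.28, abs=0.01)

    def test_window_outside_series_rejected(self):
        ts = TimeSeries(np.arange(0, 50, STEP), np.ones(150))
        with pytest.raises(ValueError):
            window_mean(ts, 93.0, 119.0)


class TestAveragingAndReport:
    def test_average_series(self):
        t = np.arange(0, 30, STEP)
        a = TimeSeries(t, np.ones_like(t))
        b = TimeSeries(t, 3 * np.ones_like(t))
        assert np.allclose(average_series([a, b]).values, 2.0)
        with pytest.raises(ValueError):
            average_series([a, TimeSeries(t + 0.1, np.ones_like(t))])

    def test_report_on_modulated_equilibrium(self):
        """Full pipeline on an efficiency-modulated trace recovers the
        smoothing-attenuated amplitude and the 19-h phase."""
        p = ModelParams(gamma=0.07, A_eff=0.25)
        t = np.arange(0, 140 + 1e-9, STEP)
        traj = closed_form_eff(p, t)
        rep = rhythm_report(TimeSeries(t, traj.L))
        assert rep.relative_amplitude == pytest.approx(0.25 * 0.885, abs=0.005)
        assert rep.phase_at_ref == pytest.approx(19.0, abs=0.05)
        assert rep.trough.time == pytest.approx(78.0, abs=0.1)
        assert rep.peak.time == pytest.approx(91.0, abs=0.1)
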