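"""Rhythm-property extraction from bioluminescence time series.

The pipeline turns a raw luminescence trace sampled every 20 min into the
three properties used to compare reporters of different stability:

1. **Relative values** — the trace divided by its centred 26-h moving
   average at each time point.  This detrends slow drifts (reporter
   accumulation, the gradual decay of an unstable reporter) and removes
   the absolute intensity scale, leaving a dimensionless rhythm readout.
2. **Relative amplitude** — half the difference between a designated
   trough of the relative series and the immediately following peak,
   measured after a light symmetric smoothing.
3. **Phase** — the time elapsed since the most recent peak (or trough),
   evaluated at a fixed reference time.

All windowed operations are *centred and symmetric*, hence zero-phase:
they attenuate the rhythm's amplitude by a known Dirichlet-kernel factor
but never shift its extrema.  Extremum times are refined below the 20-min
grid by a local quadratic fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "Extremum",
    "ExtremumList",
    "RhythmReport",
    "centered_moving_average",
    "relative_series",
    "smooth",
    "smoothing_attenuation",
    "detect_extrema",
    "filter_extrema",
    "amplitude_half_swing",
    "phase_since_last_peak",
    "phase_since_last_trough",
    "window_mean",
    "phase_difference",
    "rhythm_report",
    "average_series",
]

_GRID_RTOL = 1e-6


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled intensity series (times in hours)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise ValueError("times and values must be 1-d arrays of equal length")
        if len(t) < 2:
            raise ValueError("a time series needs at least two samples")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=_GRID_RTOL, atol=1e-9):
            raise ValueError("times must be on a uniform grid")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Extremum:
    """A detected local extremum with sub-sample refined time."""

    time: float
    value: float
    kind: str  # "peak" | "trough"
    plateau: bool = False  # True if broken from a run of equal samples

    def __post_init__(self) -> None:
        if self.kind not in ("peak", "trough"):
            raise ValueError(f"kind must be 'peak' or 'trough', got {self.kind!r}")


class ExtremumList(list):
    """Time-ordered extrema with alternating kinds."""

    def peaks(self) -> list[Extremum]:
        return [e for e in self if e.kind == "peak"]

    def troughs(self) -> list[Extremum]:
        return [e for e in self if e.kind == "trough"]


@dataclass
class RhythmReport:
    """Rhythm properties of one (possibly replicate-averaged) series."""

    window_mean: float
    relative_amplitude: float | None
    phase_at_ref: float | None
    extrema: ExtremumList
    valid_range: tuple[float, float]
    t_ref: float
    period: float
    trough: Extremum | None = None
    peak: Extremum | None = None

    def to_row(self) -> dict:
        return {
            "window_mean": self.window_mean,
            "relative_amplitude": self.relative_amplitude,
            "phase_at_ref": self.phase_at_ref,
            "t_ref": self.t_ref,
            "valid_start": self.valid_range[0],
            "valid_end": self.valid_range[1],
        }


def _window_intervals(window_h: float, step: float) -> int:
    n = window_h / step
    n_round = int(round(n))
    if abs(n - n_round) > 1e-6 or n_round < 1:
        raise ValueError(
            f"window of {window_h} h is not a positive integer multiple of the "
            f"{step:.4g}-h sample step")
    return n_round


def centered_moving_average(ts: TimeSeries, window_h: float = 26.0) -> TimeSeries:
    """Centred moving average over one full period (endpoint-inclusive).

    The window spans ``window_h`` hours symmetrically around each point,
    i.e. ``window_h/step + 1`` samples (79 at 20-min sampling for 26 h).
    Only points with a complete window are returned — no padding — so the
    output loses ``window_h/2`` hours at each end.
    """
    n = _window_intervals(window_h, ts.step) + 1
    if n % 2 == 0:
        raise ValueError("window must span an even number of sample intervals "
                         "so the sample count is odd (centred window)")
    if len(ts) < n:
        raise ValueError(f"series of {len(ts)} samples is shorter than the "
                         f"{n}-sample window")
    half = (n - 1) // 2
    avg = np.convolve(ts.values, np.full(n, 1.0 / n), mode="valid")
    return TimeSeries(ts.times[half:len(ts) - half], avg)


def relative_series(ts: TimeSeries, window_h: float = 26.0) -> TimeSeries:
    """Series divided by its centred one-period moving average.

    Defined only where the full moving-average window fits; invariant to
    rescaling of the input (``relative_series(c·ts) == relative_series(ts)``).
    """
    ma = centered_moving_average(ts, window_h)
    if np.any(ma.values == 0.0):
        raise ValueError("moving average hits zero; relative values undefined")
    half = (len(ts) - len(ma)) // 2
    return TimeSeries(ma.times, ts.values[half:len(ts) - half] / ma.values)


def smooth(ts: TimeSeries, window_h: float = 7.0) -> TimeSeries:
    """Light centred moving-average smoothing before extremum detection.

    Uses ``round(window_h/step)`` samples, which must be odd (21 samples
    for the 7-h default at 20-min sampling).  A symmetric filter is
    zero-phase: a 26-h cosine keeps its extremum times exactly and its
    amplitude is multiplied by the attenuation factor
    :func:`smoothing_attenuation` (≈0.885 for the default).
    """
    m = int(round(window_h / ts.step))
    if m % 2 == 0:
        raise ValueError(f"smoothing window of {m} samples is even; a centred "
                         "window needs an odd sample count")
    if len(ts) < m:
        raise ValueError("series shorter than the smoothing window")
    half = (m - 1) // 2
    sm = np.convolve(ts.values, np.full(m, 1.0 / m), mode="valid")
    return TimeSeries(ts.times[half:len(ts) - half], sm)


def smoothing_attenuation(n_samples: int, period_h: float, step_h: float = 1.0 / 3.0) -> float:
    """Amplitude attenuation of an ``n``-sample centred mean at a given period.

    The Dirichlet kernel of a discrete boxcar: sin(nθ/2)/(n·sin(θ/2)) with
    θ = 2π·step/period.
    """
    theta = 2.0 * np.pi * step_h / period_h
    return float(np.sin(n_samples * theta / 2.0) / (n_samples * np.sin(theta / 2.0)))


def _refine_quadratic(ts: TimeSeries, i: int) -> tuple[float, float]:
    """Vertex of a quadratic fit through the 5 samples centred on index i.

    Falls back to the raw sample when too close to the boundary or when
    the fit degenerates; the vertex is clamped to the fitted window.
    """
    if i < 2 or i > len(ts) - 3:
        return float(ts.times[i]), float(ts.values[i])
    tt = ts.times[i - 2:i + 3]
    vv = ts.values[i - 2:i + 3]
    tc = tt - tt[2]  # centre for conditioning
    a, b, c = np.polyfit(tc, vv, 2)
    if a == 0.0:
        return float(ts.times[i]), float(ts.values[i])
    t_vertex = -b / (2.0 * a)
    t_vertex = float(np.clip(t_vertex, tc[1], tc[3]))
    v_vertex = float(a * t_vertex**2 + b * t_vertex + c)
    return float(t_vertex + tt[2]), v_vertex


def detect_extrema(ts: TimeSeries) -> ExtremumList:
    """Detect interior local extrema with sub-sample quadratic refinement.

    Candidates are sign changes of the discrete first difference; each is
    refined by a 5-point quadratic vertex fit.  A plateau of equal samples
    bounded by opposite slopes is broken at its midpoint and flagged.
    Output kinds alternate by construction.
    """
    if len(ts) < 5:
        raise ValueError("need at least 5 samples to detect extrema")
    d = np.diff(ts.values)
    signs = np.sign(d)
    nz = np.nonzero(signs)[0]
    out = ExtremumList()
    if len(nz) == 0:
        return out
    prev_idx = nz[0]
    prev_sign = signs[prev_idx]
    for j in nz[1:]:
        s = signs[j]
        if s != prev_sign:
            kind = "peak" if prev_sign > 0 else "trough"
            if j - prev_idx > 1:
                # equal samples at indices prev_idx+1 .. j
                mid = (prev_idx + 1 + j) // 2
                out.append(Extremum(float(ts.times[mid]), float(ts.values[mid]),
                                    kind, plateau=True))
            else:
                t_ref, v_ref = _refine_quadratic(ts, j)
                out.append(Extremum(t_ref, v_ref, kind))
        prev_idx, prev_sign = j, s
    return out


def filter_extrema(extrema: ExtremumList, min_swing: float) -> ExtremumList:
    """Drop jitter extrema whose adjacent swing is below ``min_swing``.

    Residual noise on a smoothed series produces spurious extremum pairs
    with near-equal values straddling the true extrema.  This repeatedly
    removes the adjacent pair with the smallest absolute value difference
    until every remaining swing is at least ``min_swing``; removing an
    adjacent pair preserves alternation.
    """
    ext = list(extrema)
    while len(ext) >= 2:
        swings = [abs(ext[i + 1].value - ext[i].value) for i in range(len(ext) - 1)]
        i = int(np.argmin(swings))
        if swings[i] >= min_swing:
            break
        del ext[i:i + 2]
    return ExtremumList(ext)


def amplitude_half_swing(trough: Extremum, peak: Extremum) -> float:
    """Relative amplitude: half the trough-to-peak swing."""
    if trough.kind != "trough" or peak.kind != "peak":
        raise ValueError("arguments must be a trough and a peak, in that order")
    amp = (peak.value - trough.value) / 2.0
    if amp < 0:
        raise ValueError("negative amplitude: extrema appear mislabeled")
    return amp


def _phase_since_last(extrema: ExtremumList, kind: str, t_ref: float) -> float:
    times = [e.time for e in extrema if e.kind == kind and e.time <= t_ref + 1e-9]
    if not times:
        raise ValueError(f"no {kind} at or before t_ref = {t_ref} h")
    return float(t_ref - max(times))


def phase_since_last_peak(extrema: ExtremumList, t_ref: float = 84.0) -> float:
    """Phase convention for simulations: hours since the latest peak ≤ t_ref."""
    return _phase_since_last(extrema, "peak", t_ref)


def phase_since_last_trough(extrema: ExtremumList, t_ref: float) -> float:
    """Trough-marker phase: hours since the latest trough ≤ t_ref.

    Used for experiment-style records where the reference time is itself
    a trough of the stable reporter, so its own phase reads 0.
    """
    return _phase_since_last(extrema, "trough", t_ref)


def window_mean(ts: TimeSeries, t0: float = 93.0, t1: float = 119.0) -> float:
    """Arithmetic mean of the samples with t0 ≤ t ≤ t1 (endpoints included)."""
    eps = ts.step * 1e-6
    if t0 < ts.times[0] - eps or t1 > ts.times[-1] + eps:
        raise ValueError(f"window [{t0}, {t1}] extends outside the series "
                         f"[{ts.times[0]:g}, {ts.times[-1]:g}]")
    mask = (ts.times >= t0 - eps) & (ts.times <= t1 + eps)
    return float(ts.values[mask].mean())


def phase_difference(report_a: RhythmReport, report_b: RhythmReport) -> float:
    """Phase difference a − b in hours, wrapped to (−period/2, period/2]."""
    if report_a.t_ref != report_b.t_ref:
        raise ValueError("phase difference requires a common reference time")
    if report_a.phase_at_ref is None or report_b.phase_at_ref is None:
        raise ValueError("both reports need a defined phase")
    period = report_a.period
    diff = report_a.phase_at_ref - report_b.phase_at_ref
    wrapped = (diff + period / 2.0) % period - period / 2.0
    if wrapped == -period / 2.0:
        wrapped = period / 2.0
    return float(wrapped)


def average_series(series: list[TimeSeries]) -> TimeSeries:
    """Pointwise mean of series sharing one time grid (replicate averaging)."""
    if not series:
        raise ValueError("no series to average")
    t0 = series[0].times
    for s in series[1:]:
        if len(s) != len(t0) or not np.allclose(s.times, t0, rtol=_GRID_RTOL, atol=1e-9):
            raise ValueError("all series must share the same time grid")
    return TimeSeries(t0, np.mean([s.values for s in series], axis=0))


def rhythm_report(ts: TimeSeries, ma_window_h: float = 26.0,
                  smooth_window_h: float = 7.0, t_ref: float = 84.0,
                  mean_window: tuple[float, float] = (93.0, 119.0),
                  trough_ordinal: int = 3, period: float = 26.0,
                  phase_marker: str = "peak", min_swing: float = 0.0) -> RhythmReport:
    """Run the full analysis pipeline on one raw luminescence series.

    Computes the raw-intensity window mean, then the relative series, its
    smoothed version, detects extrema, measures the amplitude between the
    ``trough_ordinal``-th trough of the valid region and the immediately
    following peak, and the phase at ``t_ref`` (since the last peak, or
    the last trough if ``phase_marker='trough'``).  A positive
    ``min_swing`` drops noise-jitter extrema (see :func:`filter_extrema`).
    """
    wm = window_mean(ts, *mean_window)
    rel = relative_series(ts, ma_window_h)
    sm = smooth(rel, smooth_window_h)
    extrema = detect_extrema(sm)
    if min_swing > 0:
        extrema = filter_extrema(extrema, min_swing)
    troughs = [e for e in extrema if e.kind == "trough"]
    if trough_ordinal < 1 or trough_ordinal > len(troughs):
        raise ValueError(f"series has {len(troughs)} troughs in the valid "
                         f"region; cannot take trough #{trough_ordinal}")
    trough = troughs[trough_ordinal - 1]
    following = [e for e in extrema if e.kind == "peak" and e.time > trough.time]
    if not following:
        raise ValueError("no peak follows the designated trough")
    peak = following[0]
    amp = amplitude_half_swing(trough, peak)
    if phase_marker == "peak":
        phase = phase_since_last_peak(extrema, t_ref)
    elif phase_marker == "trough":
        phase = phase_since_last_trough(extrema, t_ref)
    else:
        raise ValueError("phase_marker must be 'peak' or 'trough'")
    return RhythmReport(
        window_mean=wm, relative_amplitude=amp, phase_at_ref=phase,
        extrema=extrema, valid_range=(float(sm.times[0]), float(sm.times[-1])),
        t_ref=t_ref, period=period, trough=trough, peak=peak)
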