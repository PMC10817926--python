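"""Beat fiducial detection on preprocessed ABP: foot, systolic peak, dicrotic notch.

The detector labels, for every complete beat, the diastolic foot (pressure
minimum before the upstroke), the systolic peak, and the dicrotic notch (the
incisura on the downstroke marking aortic valve closure), each with sample
index, time and pressure.  Beats whose notch search fails are kept with the
notch fields set to None and flagged, so pressure-based features survive
heavily damped waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import DetectorConfig
from .waveform import WaveformSegment


class InsufficientBeatsError(ValueError):
    """Fewer complete beats than the detector (or a feature) requires."""


@dataclass
class BeatFiducials:
    foot_idx: int
    peak_idx: int
    notch_idx: int | None
    next_foot_idx: int
    foot_time_s: float
    peak_time_s: float
    notch_time_s: float | None
    foot_p_mmhg: float      # diastolic blood pressure
    peak_p_mmhg: float      # systolic blood pressure
    notch_p_mmhg: float | None
    notch_flagged: bool = False

    @property
    def period_s(self) -> float:
        return self.next_foot_time_s - self.foot_time_s

    @property
    def next_foot_time_s(self) -> float:
        # indices and times share one clock; recover dt from any two fields
        dt = (self.peak_time_s - self.foot_time_s) / max(self.peak_idx - self.foot_idx, 1)
        return self.foot_time_s + (self.next_foot_idx - self.foot_idx) * dt

    @property
    def pulse_pressure_mmhg(self) -> float:
        return self.peak_p_mmhg - self.foot_p_mmhg


def detect_beats(seg: WaveformSegment, cfg: DetectorConfig | None = None) -> list:
    """Detect per-beat fiducials in a preprocessed ABP segment.

    Systolic peaks are local maxima with prominence at least
    ``prominence_frac`` of the segment's median pulse amplitude and inter-peak
    distance at least ``min_peak_distance_s``.  Each beat's foot is the
    minimum between consecutive peaks (the first beat's foot precedes its
    peak); the notch is the deepest pressure local minimum in the window
    [peak + 0.1, peak + 0.5] beat periods, falling back to the maximal-
    curvature inflection when no local minimum exists.  Partial beats at the
    segment edges are dropped.

    Raises
    ------
    InsufficientBeatsError
        If fewer than ``cfg.min_beats`` complete beats are found.
    """
    cfg = cfg or DetectorConfig()
    x = seg.samples
    fs = seg.sample_rate_hz
    if seg.duration_s < 2.0:
        raise InsufficientBeatsError("segment shorter than 2 s")
    dist = max(int(round(cfg.min_peak_distance_s * fs)), 1)
    # first pass: unconstrained-prominence peaks to estimate the pulse amplitude
    cand, props = signal.find_peaks(x, distance=dist, prominence=1e-9)
    if cand.size < cfg.min_beats + 1:
        raise InsufficientBeatsError(
            f"insufficient beats: {cand.size} candidate peaks")
    med_amp = float(np.median(props["prominences"]))
    keep = props["prominences"] >= cfg.prominence_frac * med_amp
    peaks = cand[keep]
    if peaks.size < cfg.min_beats + 1:
        raise InsufficientBeatsError(
            f"insufficient beats: {peaks.size} prominent peaks")

    # feet: minimum between consecutive peaks, plus the minimum before peak 0
    feet = np.empty(peaks.size, dtype=int)
    first_lo = max(peaks[0] - int(1.2 * np.median(np.diff(peaks))), 0)
    feet[0] = first_lo + int(np.argmin(x[first_lo:peaks[0]])) if peaks[0] > first_lo else 0
    for i in range(1, peaks.size):
        lo, hi = peaks[i - 1], peaks[i]
        feet[i] = lo + int(np.argmin(x[lo:hi]))

    beats = []
    t0 = seg.start_time_s
    for i in range(peaks.size - 1):
        foot, peak, nxt = feet[i], peaks[i], feet[i + 1]
        if not (foot < peak < nxt):
            continue
        period = (nxt - foot) / fs
        notch_idx = _find_notch(x, peak, nxt, period, fs, cfg)
        flagged = notch_idx is None
        beats.append(BeatFiducials(
            foot_idx=int(foot), peak_idx=int(peak),
            notch_idx=None if flagged else int(notch_idx),
            next_foot_idx=int(nxt),
            foot_time_s=t0 + foot / fs, peak_time_s=t0 + peak / fs,
            notch_time_s=None if flagged else t0 + notch_idx / fs,
            foot_p_mmhg=_valley_height(x, foot), peak_p_mmhg=_vertex_height(x, peak),
            notch_p_mmhg=None if flagged else _vertex_height(x, notch_idx),
            notch_flagged=flagged,
        ))
    if len(beats) < cfg.min_beats:
        raise InsufficientBeatsError(f"insufficient beats: {len(beats)} complete")
    return beats


def _vertex_height(x, idx: int) -> float:
    """Sub-sample extremum height by parabolic interpolation through the
    sample and its two neighbours (removes sampling-phase error in pressures)."""
    if idx <= 0 or idx >= x.size - 1:
        return float(x[idx])
    y0, y1, y2 = x[idx - 1], x[idx], x[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(y1)
    delta = 0.5 * (y0 - y2) / denom
    if abs(delta) > 1:
        return float(y1)
    return float(y1 - 0.25 * (y0 - y2) * delta)


def _valley_height(x, idx: int, half: int = 8) -> float:
    """Foot pressure via a least-squares parabola over +/-``half`` samples;
    averages residual filter ripple across the broad diastolic valley."""
    lo, hi = max(idx - half, 0), min(idx + half + 1, x.size)
    if hi - lo < 5:
        return _vertex_height(x, idx)
    s = np.arange(lo, hi) - idx
    coef = np.polyfit(s, x[lo:hi], 2)
    a, b, c = coef
    if a <= 0:
        return _vertex_height(x, idx)
    vx = -b / (2 * a)
    if abs(vx) > half:
        return _vertex_height(x, idx)
    return float(c - b * b / (4 * a))


def _find_notch(x, peak, next_foot, period, fs, cfg):
    lo = peak + int(round(cfg.notch_window_frac[0] * period * fs))
    hi = peak + int(round(cfg.notch_window_frac[1] * period * fs))
    lo = max(lo, peak + 1)
    hi = min(hi, next_foot)
    if hi - lo < 3:
        return None
    w = x[lo:hi]
    minima, _ = signal.find_peaks(-w)
    if minima.size:
        # deepest local pressure minimum in the window
        return lo + int(minima[np.argmin(w[minima])])
    # fallback: inflection with maximal second derivative (most convex point)
    d2 = np.gradient(np.gradient(w))
    if d2.size < 3:
        return None
    inner = slice(1, d2.size - 1)
    idx = 1 + int(np.argmax(d2[inner]))
    if d2[idx] <= 0:
        return None
    return lo + idx


def beat_quality_filter(beats: list, seg: WaveformSegment | None = None,
                        cfg: DetectorConfig | None = None) -> list:
    """Drop implausible beats: period outside bounds, pulse pressure below
    5 mmHg, or period > 1.5x the median (missed-detection guard).  Order is
    preserved; the list may come back shorter."""
    cfg = cfg or DetectorConfig()
    if not beats:
        return []
    periods = np.array([b.period_s for b in beats])
    med = float(np.median(periods))
    out = []
    for b, T in zip(beats, periods):
        if not (cfg.period_bounds_s[0] <= T <= cfg.period_bounds_s[1]):
            continue
        if b.pulse_pressure_mmhg < cfg.min_pulse_pressure_mmhg:
            continue
        if T > cfg.missed_beat_period_factor * med:
            continue
        out.append(b)
    return out


def beats_to_frame(beats: list, bolus_id: str = ""):
    """Fiducials as a tidy table (one row per beat) for export or plotting."""
    import pandas as pd

    rows = []
    for i, b in enumerate(beats):
        rows.append({
            "bolus_id": bolus_id, "beat": i,
            "foot_idx": b.foot_idx, "peak_idx": b.peak_idx,
            "notch_idx": b.notch_idx, "next_foot_idx": b.next_foot_idx,
            "foot_time_s": b.foot_time_s, "peak_time_s": b.peak_time_s,
            "notch_time_s": b.notch_time_s,
            "foot_p_mmhg": b.foot_p_mmhg, "peak_p_mmhg": b.peak_p_mmhg,
            "notch_p_mmhg": b.notch_p_mmhg, "notch_flagged": b.notch_flagged,
        })
    return pd.DataFrame(rows)
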