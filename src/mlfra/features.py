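"""The 50-feature pre-bolus vector and the pulse pressure variation comparator.

Twenty-five per-beat physiologic features are computed from each beat's
fiducials and samples; their median and sample standard deviation over all
quality-filtered beats in the 60 s pre-bolus window give the 50-entry feature
vector.  The registry below is the single source of truth for base-feature
names and canonical order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .beats import BeatFiducials, InsufficientBeatsError
from .waveform import WaveformSegment

#: canonical order of the 25 per-beat base features
FEATURE_REGISTRY = (
    "sbp",                 # 1  systolic pressure, mmHg
    "dbp",                 # 2  diastolic pressure, mmHg
    "notch_p",             # 3  dicrotic notch pressure, mmHg
    "pp",                  # 4  pulse pressure, mmHg
    "map",                 # 5  beat mean pressure, mmHg
    "period_s",            # 6  beat period, s
    "hr_inst",             # 7  instantaneous heart rate, bpm
    "rise_time_s",         # 8  systolic rise time (foot -> peak), s
    "systolic_dur_s",      # 9  systolic phase duration (foot -> notch), s
    "diastolic_dur_s",     # 10 diastolic phase duration (notch -> next foot), s
    "sys_dia_ratio",       # 11 systolic:diastolic duration ratio
    "dpdt_max",            # 12 max dP/dt, mmHg/s
    "dpdt_min",            # 13 min dP/dt, mmHg/s
    "systolic_area",       # 14 area above DBP, foot -> notch, mmHg*s
    "diastolic_area",      # 15 area above DBP, notch -> next foot, mmHg*s
    "beat_area",           # 16 area above DBP, whole beat, mmHg*s
    "systolic_area_frac",  # 17 (14)/(16)
    "notch_rel_height",    # 18 (notch - DBP) / pulse pressure
    "peak_notch_amp",      # 19 peak-to-notch amplitude, mmHg
    "decay_tau_s",         # 20 diastolic decay time constant, s
    "peak_notch_time_s",   # 21 peak-to-notch time, s
    "pressure_sd",         # 22 within-beat pressure SD, mmHg
    "pressure_skew",       # 23 within-beat pressure skewness
    "pulse_width_half_s",  # 24 pulse width at half amplitude, s
    "decay_slope",         # 25 mean diastolic decay slope, mmHg/s
)

#: base features that require a detected dicrotic notch
NOTCH_FEATURES = frozenset({
    "notch_p", "systolic_dur_s", "diastolic_dur_s", "sys_dia_ratio",
    "systolic_area", "diastolic_area", "systolic_area_frac",
    "notch_rel_height", "peak_notch_amp", "decay_tau_s", "peak_notch_time_s",
    "decay_slope",
})

#: canonical order of the 50 aggregate feature names
FEATURE_NAMES = tuple(f"{base}_{stat}" for base in FEATURE_REGISTRY
                      for stat in ("median", "sd"))


def fit_exponential_decay(t: np.ndarray, y: np.ndarray):
    """Fit y = A*exp(-t/tau) + C by the integral linearisation (one lstsq).

    Exact on noise-free exponentials; returns (tau, A, C).  Falls back to
    NaN tau for degenerate segments.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.size < 4:
        return np.nan, np.nan, np.nan
    t = t - t[0]
    # cumulative trapezoid of y
    s = np.concatenate([[0.0], np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(t))])
    # y(t) = a*S(t) + b*t + c  with a = -1/tau
    m = np.column_stack([s, t, np.ones_like(t)])
    try:
        coef, *_ = np.linalg.lstsq(m, y, rcond=None)
    except np.linalg.LinAlgError:
        return np.nan, np.nan, np.nan
    a = coef[0]
    if a >= 0:
        return np.nan, np.nan, np.nan
    tau = -1.0 / a
    # with tau known, A and C are linear
    e = np.exp(-t / tau)
    m2 = np.column_stack([e, np.ones_like(t)])
    (amp, c), *_ = np.linalg.lstsq(m2, y, rcond=None)
    return float(tau), float(amp), float(c)


def compute_beat_features(beat: BeatFiducials, seg: WaveformSegment) -> dict:
    """The 25 per-beat base features; notch-dependent entries are None for
    notch-flagged beats."""
    fs = seg.sample_rate_hz
    x = seg.samples
    f, p, nf = beat.foot_idx, beat.peak_idx, beat.next_foot_idx
    period = (nf - f) / fs
    if period <= 0:
        raise ValueError("degenerate beat with non-positive period")
    w = x[f:nf + 1]
    dbp, sbp = beat.foot_p_mmhg, beat.peak_p_mmhg
    pp = sbp - dbp
    dp = np.gradient(w) * fs
    out = {
        "sbp": sbp, "dbp": dbp, "pp": pp,
        "map": float(np.mean(w)),
        "period_s": period, "hr_inst": 60.0 / period,
        "rise_time_s": (p - f) / fs,
        "dpdt_max": float(dp.max()), "dpdt_min": float(dp.min()),
        "beat_area": float(np.trapezoid(w - dbp, dx=1.0 / fs)),
        "pressure_sd": float(np.std(w, ddof=1)),
        "pressure_skew": float(stats.skew(w)),
        "pulse_width_half_s": _half_width(w, p - f, dbp + 0.5 * pp, fs),
    }
    if beat.notch_flagged or beat.notch_idx is None:
        for name in NOTCH_FEATURES:
            out[name] = None
    else:
        n = beat.notch_idx
        notch_p = beat.notch_p_mmhg
        sys_dur = (n - f) / fs
        dia_dur = (nf - n) / fs
        sys_area = float(np.trapezoid(x[f:n + 1] - dbp, dx=1.0 / fs))
        dia_area = float(np.trapezoid(x[n:nf + 1] - dbp, dx=1.0 / fs))
        # fit the monotone decay run: from the dicrotic crest (post-notch
        # maximum) down to the diastolic minimum
        sub = x[n:nf + 1]
        start = int(np.argmax(sub))
        stop = start + int(np.argmin(sub[start:]))
        if stop - start >= 4:
            tdec = np.arange(stop - start + 1) / fs
            tau, _, _ = fit_exponential_decay(tdec, sub[start:stop + 1])
        else:
            tau = np.nan
        out.update({
            "notch_p": notch_p,
            "systolic_dur_s": sys_dur,
            "diastolic_dur_s": dia_dur,
            "sys_dia_ratio": sys_dur / dia_dur if dia_dur > 0 else None,
            "systolic_area": sys_area,
            "diastolic_area": dia_area,
            "systolic_area_frac": sys_area / out["beat_area"] if out["beat_area"] > 0 else None,
            "notch_rel_height": (notch_p - dbp) / pp if pp > 0 else None,
            "peak_notch_amp": sbp - notch_p,
            "decay_tau_s": tau if np.isfinite(tau) else None,
            "peak_notch_time_s": (n - p) / fs,
            "decay_slope": float((x[nf] - x[n]) / dia_dur) if dia_dur > 0 else None,
        })
    return out


def _half_width(w, peak_off, level, fs):
    """Duration of the contiguous span around the peak with pressure >= level."""
    above = w >= level
    if not above[peak_off]:
        return 0.0
    lo = peak_off
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak_off
    while hi < w.size - 1 and above[hi + 1]:
        hi += 1
    return (hi - lo + 1) / fs


@dataclass
class FeatureVector:
    """The 50 engineered pre-bolus features plus the PPV comparator."""

    bolus_id: str
    pig_id: str
    values: dict            # feature name -> value (NaN where unimputed)
    ppv_pct: float
    n_beats_used: int
    imputed: list = field(default_factory=list)  # names imputed downstream


def aggregate_features(beats: list, seg: WaveformSegment,
                       bolus_id: str = "", pig_id: str = "",
                       ppv_pct: float | None = None) -> FeatureVector:
    """Median and sample SD (ddof=1) of each base feature across beats.

    Nulls from notch-flagged beats are skipped; a base feature with fewer than
    3 non-null beats yields NaN aggregates, flagged for training-cohort median
    imputation downstream (never test-cohort statistics).
    """
    if len(beats) < 3:
        raise InsufficientBeatsError(f"insufficient beats: {len(beats)} < 3")
    per_beat = [compute_beat_features(b, seg) for b in beats]
    values, flagged = {}, []
    for base in FEATURE_REGISTRY:
        col = np.array([fb[base] for fb in per_beat
                        if fb[base] is not None], dtype=float)
        if col.size < 3:
            values[f"{base}_median"] = np.nan
            values[f"{base}_sd"] = np.nan
            flagged += [f"{base}_median", f"{base}_sd"]
        else:
            values[f"{base}_median"] = float(np.median(col))
            values[f"{base}_sd"] = float(np.std(col, ddof=1))
    if ppv_pct is None:
        ppv_pct = compute_ppv(beats)
    return FeatureVector(bolus_id=bolus_id, pig_id=pig_id, values=values,
                         ppv_pct=ppv_pct, n_beats_used=len(beats),
                         imputed=flagged)


def compute_ppv(beats: list) -> float:
    """Pulse pressure variation over the window, percent.

    PPV% = 100 * (PPmax - PPmin) / ((PPmax + PPmin) / 2), with the extreme
    pulse pressures taken over all quality-filtered beats in the window.
    """
    pps = [b.pulse_pressure_mmhg for b in beats]
    if len(pps) < 3:
        raise InsufficientBeatsError("insufficient beats for PPV (< 3)")
    pmax, pmin = max(pps), min(pps)
    denom = 0.5 * (pmax + pmin)
    if denom == 0:
        raise ValueError("PPV undefined: mean extreme pulse pressure is zero")
    return 100.0 * (pmax - pmin) / denom


def classify_ppv(ppv_pct: float, threshold_pct: float = 12.0) -> str:
    """PPV-based prediction: FR iff PPV >= threshold (boundary inclusive)."""
    if not np.isfinite(ppv_pct):
        raise ValueError("ppv_pct must be finite")
    return "FR" if ppv_pct >= threshold_pct else "NR"


def feature_frame(vectors: list):
    """Feature table: one row per bolus, ids + 50 features + ppv_pct + n_beats_used."""
    import pandas as pd

    rows = []
    for v in vectors:
        row = {"bolus_id": v.bolus_id, "pig_id": v.pig_id}
        row.update({name: v.values[name] for name in FEATURE_NAMES})
        row["ppv_pct"] = v.ppv_pct
        row["n_beats_used"] = v.n_beats_used
        rows.append(row)
    return pd.DataFrame(rows, columns=["bolus_id", "pig_id", *FEATURE_NAMES,
                                       "ppv_pct", "n_beats_used"])


def impute_with_train_medians(train_df, df):
    """Fill NaN feature cells with the training-cohort median of each column
    (leakage-safe: test rows never contribute statistics)."""
    med = train_df[list(FEATURE_NAMES)].median()
    out = df.copy()
    out[list(FEATURE_NAMES)] = out[list(FEATURE_NAMES)].fillna(med)
    return out
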