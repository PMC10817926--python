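"""Stroke-volume derivation and fluid-responsiveness labeling.

Stroke volume is the median cardiac output divided by the median heart rate
over the 60 s window; a bolus is fluid responsive (FR) when SV rises by at
least 15%, and falls in the grey zone when the change lies in [10%, 20%].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .waveform import WaveformSegment

FR_THRESHOLD_PCT = 15.0
GREY_ZONE_PCT = (10.0, 20.0)


@dataclass
class BolusRecord:
    bolus_id: str
    pig_id: str
    injury_model: str
    sv_pre_ml: float
    sv_post_ml: float
    delta_sv_pct: float
    label: str        # "FR" or "NR"
    sv_zone: str      # "below" (<10%), "grey" (10-20%), "above" (>20%)


def compute_sv(co_seg: WaveformSegment, hr_seg: WaveformSegment) -> float:
    """SV (ml/beat) = median CO (L/min) / median HR (bpm) * 1000."""
    co = float(np.median(co_seg.samples))
    hr = float(np.median(hr_seg.samples))
    if hr <= 0:
        raise ValueError("median heart rate must be positive")
    return co / hr * 1000.0


def label_bolus(sv_pre_ml: float, sv_post_ml: float,
                fr_threshold_pct: float = FR_THRESHOLD_PCT,
                grey_zone_pct: tuple = GREY_ZONE_PCT):
    """Return (delta_sv_pct, label, sv_zone); FR iff delta >= threshold
    (inclusive), grey zone is the closed interval [10, 20]."""
    if sv_pre_ml <= 0:
        raise ValueError("sv_pre_ml must be positive")
    delta = 100.0 * (sv_post_ml - sv_pre_ml) / sv_pre_ml
    label = "FR" if delta >= fr_threshold_pct else "NR"
    lo, hi = grey_zone_pct
    if delta < lo:
        zone = "below"
    elif delta <= hi:
        zone = "grey"
    else:
        zone = "above"
    return delta, label, zone


def label_simulated_bolus(bolus, fr_threshold_pct: float = FR_THRESHOLD_PCT,
                          grey_zone_pct: tuple = GREY_ZONE_PCT) -> BolusRecord:
    """Label one simulated bolus from its CO and HR channels."""
    sv_pre = compute_sv(bolus.co_pre, bolus.hr_pre)
    sv_post = compute_sv(bolus.co_post, bolus.hr_post)
    delta, label, zone = label_bolus(sv_pre, sv_post, fr_threshold_pct, grey_zone_pct)
    return BolusRecord(
        bolus_id=bolus.bolus_id, pig_id=bolus.pig_id,
        injury_model=bolus.injury_model,
        sv_pre_ml=sv_pre, sv_post_ml=sv_post,
        delta_sv_pct=delta, label=label, sv_zone=zone,
    )
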