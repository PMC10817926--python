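"""Seeded synthetic hemodynamics: multi-pig cohorts of fluid-bolus events.

The simulator emulates the structure of a large-animal fluid-challenge study:
pigs drawn from three circulatory-shock archetypes (HEM: hemorrhagic, IRI:
ischemia-reperfusion, EPACC: ischemia-reperfusion with intermittent partial
aortic occlusion), each contributing several boluses with 60 s of arterial
blood pressure (ABP), cardiac output (CO) and heart rate (HR) recorded before
and after the bolus.

A latent per-bolus *preload reserve* r in [0, 1] drives everything:

* the respiratory modulation depth of per-beat stroke volume (hence pulse
  pressure variation, PPV) is ``delta_max * r`` times a pig-level gain,
* the true bolus response is ``delta_sv_pct = g(r) + eps`` with g linear and
  eps Gaussian label noise,
* secondary variability channels — dicrotic-notch timing and diastolic decay
  constant — are modulated by r through *independent* pig-level gains.

Because each observable variability channel reads r through its own noisy
gain, any single channel (PPV included) is an imperfect univariate proxy,
while a multivariate model can average the channels and recover r better.
This is the planted mechanism that lets a learned classifier outperform PPV.

Beats are synthesized foot-to-foot from a template exposing every fiducial a
detector must find: raised-cosine systolic upstroke, curvature-matched
raised-cosine fall to a dicrotic shoulder, a symmetric notch dip (exact local
minimum at the planted notch time), and an exponential diastolic decay with
time constant tau = resistance x compliance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulatorConfig
from .waveform import WaveformSegment, save_segment

INJURY_MODELS = ("HEM", "IRI", "EPACC")

# cohort composition mirrors the three-model study design (13/13/32 pigs of 58)
_INJURY_WEIGHTS = {"HEM": 13 / 58, "IRI": 13 / 58, "EPACC": 32 / 58}

# per-archetype parameter ranges: (sv_ml, hr_bpm, compliance ml/mmHg, tau_s, dbp)
# heart rates reflect anesthetized animals under continuous vasopressor support
_ARCHETYPES = {
    # hemorrhage: low stroke volume, relative tachycardia
    "HEM": {"sv": (25, 45), "hr": (80, 95), "c": (0.9, 1.4), "tau": (0.8, 1.4), "dbp": (48, 62)},
    # ischemia-reperfusion: broader SV, moderate rates
    "IRI": {"sv": (35, 60), "hr": (66, 89), "c": (1.1, 1.8), "tau": (1.0, 1.6), "dbp": (55, 70)},
    # aortic-occlusion support: higher resistance (longer decay), higher DBP
    "EPACC": {"sv": (30, 55), "hr": (72, 94), "c": (0.8, 1.3), "tau": (1.2, 1.8), "dbp": (60, 78)},
}


@dataclass
class PigProfile:
    pig_id: str
    injury_model: str
    baseline_sv_ml: float
    baseline_hr_bpm: float
    vascular_compliance: float      # ml/mmHg
    vascular_resistance: float      # mmHg*s/ml; tau = R*C
    preload_reserve: float          # pig-level anchor in [0, 1]
    resp_rate_bpm: float
    noise_sd_mmhg: float
    baseline_dbp_mmhg: float
    channel_gains: tuple = (1.0, 1.0, 1.0)  # PP, notch-timing, tau modulation gains

    def __post_init__(self):
        if not (60 <= self.baseline_hr_bpm <= 180):
            raise ValueError("baseline_hr_bpm outside [60, 180]")
        if not (10 <= self.resp_rate_bpm <= 25):
            raise ValueError("resp_rate_bpm outside [10, 25]")
        if not (0 <= self.preload_reserve <= 1):
            raise ValueError("preload_reserve outside [0, 1]")


@dataclass
class SimulatedBolus:
    bolus_id: str
    pig_id: str
    injury_model: str
    true_delta_sv_pct: float
    preload_reserve: float          # effective per-bolus reserve
    true_fiducials_pre: list = field(default_factory=list)  # (foot, peak, notch) times s
    abp_pre: WaveformSegment | None = None
    abp_post: WaveformSegment | None = None
    co_pre: WaveformSegment | None = None
    co_post: WaveformSegment | None = None
    hr_pre: WaveformSegment | None = None
    hr_post: WaveformSegment | None = None


def _rng(seed: int, *key) -> np.random.Generator:
    """Counter-based substream: stable per (pig, bolus) regardless of cohort size."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _injury_assignment(n_pigs: int) -> list:
    """Deterministic largest-remainder allocation of pigs to injury models."""
    quotas = {m: n_pigs * w for m, w in _INJURY_WEIGHTS.items()}
    counts = {m: int(np.floor(q)) for m, q in quotas.items()}
    short = n_pigs - sum(counts.values())
    for m in sorted(quotas, key=lambda m: quotas[m] - counts[m], reverse=True)[:short]:
        counts[m] += 1
    out = []
    for m in INJURY_MODELS:
        out.extend([m] * counts[m])
    return out


def _draw_profile(pig_idx: int, injury_model: str, seed: int,
                  cfg: SimulatorConfig) -> PigProfile:
    rng = _rng(seed, 0, pig_idx)
    a = _ARCHETYPES[injury_model]
    compliance = rng.uniform(*a["c"])
    tau = rng.uniform(*a["tau"])
    gains = np.clip(rng.lognormal(0.0, cfg.channel_gain_sd, size=3), 0.3, 2.0)
    return PigProfile(
        pig_id=f"pig{pig_idx:03d}",
        injury_model=injury_model,
        baseline_sv_ml=rng.uniform(*a["sv"]),
        baseline_hr_bpm=rng.uniform(*a["hr"]),
        vascular_compliance=compliance,
        vascular_resistance=tau / compliance,
        preload_reserve=rng.uniform(0.0, 1.0),
        resp_rate_bpm=rng.uniform(12, 22),
        noise_sd_mmhg=cfg.noise_sd_mmhg,
        baseline_dbp_mmhg=rng.uniform(*a["dbp"]),
        channel_gains=tuple(gains),
    )


def _reserve_map(u: np.ndarray | float, target: float) -> np.ndarray | float:
    """Piecewise-linear map of a uniform draw so P(r >= 0.5) = target exactly."""
    u = np.asarray(u, dtype=float)
    lo = 1.0 - target
    r = np.where(u < lo, u * 0.5 / lo, 0.5 + (u - lo) * 0.5 / target)
    return r


def synthesize_abp(profile: PigProfile, sv_ml: float, depth_pp: float,
                   depth_notch: float, depth_tau: float, resp_phase: float,
                   rng: np.random.Generator, cfg: SimulatorConfig,
                   noise_sd: float | None = None):
    """Render one ABP segment beat-by-beat; returns (segment, fiducials).

    ``depth_*`` are the respiratory modulation depths (dimensionless) of the
    pulse-pressure, notch-timing and decay-constant channels. Fiducials are
    the exact planted (foot, peak, notch) times in seconds.
    """
    rate = cfg.sample_rate_hz
    dur = cfg.segment_duration_s
    n = int(round(dur * rate))
    dbp = profile.baseline_dbp_mmhg
    tau0 = profile.vascular_resistance * profile.vascular_compliance
    f_resp = profile.resp_rate_bpm / 60.0
    period0 = 60.0 / profile.baseline_hr_bpm
    noise_sd = profile.noise_sd_mmhg if noise_sd is None else noise_sd

    t = np.arange(n) / rate
    abp = np.full(n, dbp)
    fiducials = []

    t_foot = 0.0
    # render one beat past the window so the last in-window beat is complete
    while t_foot < dur + 2 * period0:
        T = period0 * (1.0 + cfg.hr_jitter_frac * rng.standard_normal())
        resp = np.sin(2 * np.pi * f_resp * t_foot + resp_phase)
        sv_i = sv_ml * (1.0 + depth_pp * resp)
        if noise_sd > 0 and rng.random() < cfg.spike_rate_per_min * period0 / 60.0:
            sv_i *= 1.0 + rng.uniform(*cfg.spike_frac_range)
        pp = max(sv_i / profile.vascular_compliance, 5.0)
        sbp = dbp + pp
        tau = tau0 * (1.0 + cfg.tau_mod_frac * depth_tau * resp)

        # end-diastolic valley: a symmetric cosine bowl centred on the foot,
        # wide enough (>= 90 ms) that band-limiting does not displace the
        # pressure minimum from the planted foot time
        t_v = min(max(0.14 * T, 0.090), 0.22 * T)
        h = max(0.15 * pp, 5.0)
        t_r = cfg.rise_time_frac * T
        shoulder = dbp + cfg.notch_level_frac * pp
        # curvature-matched systolic fall so the peak is locally symmetric
        t_b = t_r * np.sqrt((sbp - shoulder) / (pp - h)) if pp > h else t_r
        nu = cfg.notch_delay_frac * (1.0 + cfg.notch_timing_mod_frac * depth_notch * resp)
        w = max(nu * T - t_b, 0.090 - t_b, 0.03 * T)
        d = max(cfg.notch_depth_frac * pp, 3.0)
        t_p = t_foot + t_v + t_r
        t_n = t_p + t_b + w
        t_next = t_foot + T
        t_dec_end = t_next - t_v
        # mirror the fall+dip shape past the notch (the dicrotic wave), so the
        # notch minimum is locally symmetric; leave room for the decay
        s_mir = min(cfg.notch_mirror_max_s, w + cfg.notch_mirror_fall_frac * t_b,
                    (t_dec_end - t_n) - max(0.07, 0.10 * T),
                    0.285 - t_b - w)   # dicrotic crest stays inside the refractory
        s_mir = max(s_mir, 0.5 * w)
        t_dw = t_n + s_mir

        def f_fall_dip(tt):
            return np.where(
                tt < t_p + t_b,
                shoulder + (sbp - shoulder) * 0.5 * (
                    1 + np.cos(np.pi * np.clip(tt - t_p, 0, t_b) / t_b)),
                shoulder - d * 0.5 * (
                    1 - np.cos(np.pi * np.clip(tt - (t_p + t_b), 0, w) / w)))

        v_m = float(f_fall_dip(np.array([2 * t_n - t_dw]))[0])
        delta = t_dec_end - t_dw
        e = np.exp(-delta / tau)
        p_inf = ((dbp + h) - v_m * e) / (1.0 - e)

        i0 = max(int(np.ceil(t_foot * rate)), 0)
        i1 = min(int(np.ceil(t_next * rate)), n)
        if i0 < i1:
            tb = t[i0:i1]
            seg = np.empty_like(tb)
            m_v1 = tb < t_foot + t_v
            m_up = (tb >= t_foot + t_v) & (tb < t_p)
            m_sys = (tb >= t_p) & (tb < t_n)
            m_mir = (tb >= t_n) & (tb < t_dw)
            m_dec = (tb >= t_dw) & (tb < t_dec_end)
            m_v2 = tb >= t_dec_end
            seg[m_v1] = dbp + h * 0.5 * (1 - np.cos(np.pi * (tb[m_v1] - t_foot) / t_v))
            seg[m_up] = dbp + h + (pp - h) * 0.5 * (
                1 - np.cos(np.pi * (tb[m_up] - (t_foot + t_v)) / t_r))
            seg[m_sys] = f_fall_dip(tb[m_sys])
            seg[m_mir] = f_fall_dip(2 * t_n - tb[m_mir])
            seg[m_dec] = p_inf + (v_m - p_inf) * np.exp(-(tb[m_dec] - t_dw) / tau)
            seg[m_v2] = dbp + h * 0.5 * (1 - np.cos(np.pi * (t_next - tb[m_v2]) / t_v))
            abp[i0:i1] = seg
        if t_n < dur:
            fiducials.append((t_foot, t_p, t_n))
        t_foot = t_next
        if t_foot >= dur:
            break

    drift_phase = rng.uniform(0, 2 * np.pi)
    if cfg.drift_amplitude_mmhg > 0 and noise_sd > 0:
        abp = abp + cfg.drift_amplitude_mmhg * np.sin(
            2 * np.pi * t / cfg.drift_period_s + drift_phase)
    if noise_sd > 0:
        abp = abp + rng.normal(0.0, noise_sd, size=n)
    abp = np.clip(abp, 0.5, 299.5)
    seg = WaveformSegment(abp, rate, 0.0, "ABP")
    return seg, fiducials


def _aux_channels(profile: PigProfile, sv_ml: float, depth_pp: float,
                  resp_phase: float, rng: np.random.Generator,
                  cfg: SimulatorConfig, noisy: bool):
    """CO (L/min) and HR (bpm) channels at the auxiliary rate."""
    n = int(round(cfg.segment_duration_s * cfg.aux_rate_hz))
    t = np.arange(n) / cfg.aux_rate_hz
    f_resp = profile.resp_rate_bpm / 60.0
    sv_t = sv_ml * (1.0 + depth_pp * np.sin(2 * np.pi * f_resp * t + resp_phase))
    co = sv_t * profile.baseline_hr_bpm / 1000.0
    hr = np.full(n, profile.baseline_hr_bpm)
    if noisy:
        co = co + rng.normal(0.0, 0.15, size=n)
        hr = hr + rng.normal(0.0, 1.0, size=n)
    co = np.clip(co, 0.05, None)
    hr = np.clip(hr, 20.0, None)
    return (WaveformSegment(co, cfg.aux_rate_hz, 0.0, "CO"),
            WaveformSegment(hr, cfg.aux_rate_hz, 0.0, "HR"))


def simulate_bolus(profile: PigProfile, pig_idx: int, bolus_idx: int, seed: int,
                   cfg: SimulatorConfig) -> SimulatedBolus:
    """Simulate one fluid challenge (pre and post 60 s windows) for a pig."""
    rng = _rng(seed, 1, pig_idx, bolus_idx)
    # per-bolus latent reserve: pig anchor + wrapped Gaussian jitter keeps the
    # marginal uniform, then the prevalence map sets P(r >= 0.5) = target
    u = (profile.preload_reserve
         + rng.normal(0.0, cfg.reserve_within_pig_sd)) % 1.0
    r = float(_reserve_map(u, cfg.fr_prevalence_target))
    g = cfg.g_low_pct + (cfg.g_high_pct - cfg.g_low_pct) * r
    eps = rng.normal(0.0, cfg.label_noise_sd_pct)
    true_delta = g + eps

    jit = rng.lognormal(0.0, cfg.channel_gain_bolus_sd, size=3)
    g_pp, g_notch, g_tau = np.asarray(profile.channel_gains) * jit
    depth_pp = min(cfg.delta_max * r * g_pp, 0.45)
    depth_notch = min(cfg.delta_max * r * g_notch, 0.45)
    depth_tau = min(cfg.delta_max * r * g_tau, 0.45)

    sv_pre = profile.baseline_sv_ml
    sv_post = sv_pre * (1.0 + true_delta / 100.0)
    phase_pre = rng.uniform(0, 2 * np.pi)
    phase_post = rng.uniform(0, 2 * np.pi)

    abp_pre, fids = synthesize_abp(profile, sv_pre, depth_pp, depth_notch,
                                   depth_tau, phase_pre, rng, cfg)
    # post-bolus modulation shrinks as reserve is spent (qualitative only)
    shrink = 0.6
    abp_post, _ = synthesize_abp(profile, sv_post, depth_pp * shrink,
                                 depth_notch * shrink, depth_tau * shrink,
                                 phase_post, rng, cfg)
    noisy = profile.noise_sd_mmhg > 0
    co_pre, hr_pre = _aux_channels(profile, sv_pre, depth_pp, phase_pre, rng, cfg, noisy)
    co_post, hr_post = _aux_channels(profile, sv_post, depth_pp * shrink,
                                     phase_post, rng, cfg, noisy)
    return SimulatedBolus(
        bolus_id=f"{profile.pig_id}_b{bolus_idx:02d}",
        pig_id=profile.pig_id,
        injury_model=profile.injury_model,
        true_delta_sv_pct=true_delta,
        preload_reserve=r,
        true_fiducials_pre=fids,
        abp_pre=abp_pre, abp_post=abp_post,
        co_pre=co_pre, co_post=co_post,
        hr_pre=hr_pre, hr_post=hr_post,
    )


def make_profiles(n_pigs: int, seed: int, cfg: SimulatorConfig) -> list:
    if n_pigs < 2:
        raise ValueError("n_pigs must be >= 2")
    assignment = _injury_assignment(n_pigs)
    return [_draw_profile(i, assignment[i], seed, cfg) for i in range(n_pigs)]


def iter_cohort(n_pigs: int, boluses_per_pig: int, fr_prevalence_target: float,
                seed: int, cfg: SimulatorConfig | None = None, profiles=None):
    """Yield SimulatedBolus objects one at a time (constant memory)."""
    if boluses_per_pig < 1:
        raise ValueError("boluses_per_pig must be >= 1")
    if not (0 < fr_prevalence_target < 1):
        raise ValueError("fr_prevalence_target must lie in (0, 1)")
    cfg = cfg or SimulatorConfig()
    cfg.fr_prevalence_target = fr_prevalence_target
    if profiles is None:
        profiles = make_profiles(n_pigs, seed, cfg)
    for i, prof in enumerate(profiles):
        for b in range(boluses_per_pig):
            yield simulate_bolus(prof, i, b, seed, cfg)


def simulate_cohort(n_pigs: int, boluses_per_pig: int,
                    fr_prevalence_target: float = 0.5, seed: int = 0,
                    cfg: SimulatorConfig | None = None):
    """Simulate a full cohort; returns (list of SimulatedBolus, list of PigProfile).

    Deterministic given ``seed``; per-pig and per-bolus substreams are derived
    by counter-based seed splitting, so enlarging the cohort never reshuffles
    earlier pigs.
    """
    if n_pigs < 2:
        raise ValueError("n_pigs must be >= 2")
    if not (0 < fr_prevalence_target < 1):
        raise ValueError("fr_prevalence_target must lie in (0, 1)")
    cfg = cfg or SimulatorConfig()
    cfg.fr_prevalence_target = fr_prevalence_target
    profiles = make_profiles(n_pigs, seed, cfg)
    boluses = list(iter_cohort(n_pigs, boluses_per_pig, fr_prevalence_target,
                               seed, cfg, profiles))
    return boluses, profiles


_SEGMENT_KEYS = ("abp_pre", "abp_post", "co_pre", "co_post", "hr_pre", "hr_post")


def write_cohort(boluses, directory) -> Path:
    """Write a cohort as a manifest plus per-segment delimited-text files.

    The manifest (``manifest.csv``) has one row per bolus with pig id, injury
    model, the six segment file references with their rates, and the planted
    ``true_delta_sv_pct`` (ground truth, for testing only).  Returns the
    manifest path.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {directory}: {exc}") from exc
    rows = []
    for b in boluses:
        row = {"pig_id": b.pig_id, "bolus_id": b.bolus_id,
               "injury_model": b.injury_model,
               "true_delta_sv_pct": b.true_delta_sv_pct}
        for key in _SEGMENT_KEYS:
            seg = getattr(b, key)
            fname = f"{b.bolus_id}_{key}.csv"
            try:
                save_segment(seg, directory / fname)
            except OSError as exc:
                raise OSError(f"cannot write segment file {directory / fname}: {exc}") from exc
            row[f"{key}_file"] = fname
            row[f"{key}_rate_hz"] = seg.sample_rate_hz
        rows.append(row)
    cols = ["pig_id", "bolus_id", "injury_model", "true_delta_sv_pct"]
    for key in _SEGMENT_KEYS:
        cols += [f"{key}_file", f"{key}_rate_hz"]
    manifest = pd.DataFrame(rows, columns=cols)
    mpath = directory / "manifest.csv"
    manifest.to_csv(mpath, index=False)
    return mpath
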