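"""Run configuration: every numeric constant of the pipeline, in one place.

The configuration round-trips losslessly through YAML so that a run can be
reproduced exactly from its config file.  CLI flags override the config file,
which overrides the built-in defaults below.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class SimulatorConfig:
    """Synthetic cohort generation parameters (study-design scale defaults)."""

    n_pigs: int = 58
    boluses_per_pig: int = 7          # 58 * 7 = 406 ~ the 394-bolus scale
    fr_prevalence_target: float = 0.5
    sample_rate_hz: float = 1000.0
    segment_duration_s: float = 60.0
    aux_rate_hz: float = 100.0        # CO / HR channel sampling rate
    # respiratory stroke-volume modulation: depth = delta_max * preload reserve
    delta_max: float = 0.15
    # linear dose-response g(r): delta-SV% from -5 (r=0) to +35 (r=1)
    g_low_pct: float = -5.0
    g_high_pct: float = 35.0
    label_noise_sd_pct: float = 4.0   # epsilon on the true delta-SV%
    # within-pig spread of per-bolus preload reserve around the pig anchor
    reserve_within_pig_sd: float = 0.15
    # pig-level multiplicative gain noise on each variability channel
    # (pulse-pressure, notch-timing, decay-constant); this is what makes PPV an
    # imperfect univariate proxy while the multivariate ensemble stays informative
    channel_gain_sd: float = 0.8
    # bolus-level multiplicative jitter of the same gains (breath-to-breath /
    # ventilator-setting variability between challenges)
    channel_gain_bolus_sd: float = 0.3
    noise_sd_mmhg: float = 1.0
    hr_jitter_frac: float = 0.005     # per-beat period jitter (relative SD)
    # occasional single-beat stroke-volume surges (sigh breaths, ectopy-like
    # events); these perturb extreme-value statistics such as PPV far more
    # than the robust median/SD beat aggregates
    spike_rate_per_min: float = 3.0
    spike_frac_range: tuple = (0.10, 0.30)
    drift_amplitude_mmhg: float = 2.0
    drift_period_s: float = 25.0
    # beat template shape (fractions of the beat period)
    rise_time_frac: float = 0.18
    notch_delay_frac: float = 0.27    # notch time after peak, fraction of period
    notch_level_frac: float = 0.45    # dicrotic shoulder height above DBP, x PP
    notch_depth_frac: float = 0.15    # notch dip depth, x PP
    notch_timing_mod_frac: float = 0.35
    tau_mod_frac: float = 0.5
    # dicrotic-wave mirror extent past the notch (keeps the notch minimum
    # locally symmetric under band-limiting without creating a spurious peak)
    notch_mirror_max_s: float = 0.095
    notch_mirror_fall_frac: float = 0.5


@dataclass
class PreprocessConfig:
    source_rate_hz: float = 1000.0
    target_rate_hz: float = 100.0
    savgol_window: int = 19
    savgol_polyorder: int = 2
    qc_pressure_low_mmhg: float = 0.0
    qc_pressure_high_mmhg: float = 300.0
    qc_flatline_duration_s: float = 2.0
    qc_flatline_range_mmhg: float = 1.0
    qc_min_pulse_pressure_mmhg: float = 5.0


@dataclass
class DetectorConfig:
    min_peak_distance_s: float = 0.3       # refractory, <= 200 bpm
    prominence_frac: float = 0.25          # of the median pulse amplitude
    notch_window_frac: tuple = (0.1, 0.5)  # of beat period, after the peak
    min_beats: int = 3
    # beat quality filter
    period_bounds_s: tuple = (0.3, 1.5)
    min_pulse_pressure_mmhg: float = 5.0
    missed_beat_period_factor: float = 1.5


@dataclass
class SelectionConfig:
    alpha: float = 0.1
    corr_threshold: float = 0.9
    n_keep: int = 10
    consensus_min_frequency: float = 0.5
    retain_if_discriminative: bool = True  # p < alpha; False gives literal p > alpha
    n_permutations: int = 10


@dataclass
class SplitConfig:
    n_splits: int = 29
    target_prevalence: float = 0.5
    n_candidates: int = 200
    injury_mix_weight: float = 0.25
    k_folds: int = 5


@dataclass
class ThresholdConfig:
    fr_delta_sv_pct: float = 15.0
    grey_zone_pct: tuple = (10.0, 20.0)
    ppv_threshold_pct: float = 12.0
    decision_threshold: float = 0.5


@dataclass
class ModelConfig:
    algorithm: str = "RF"
    grids: dict = field(default_factory=lambda: default_grids())


def default_grids() -> dict:
    """Hyperparameter grids per algorithm, ordered small-capacity first so the
    tuning tie-break (first best) prefers the least complex configuration."""
    return {
        "RF": [
            {"n_estimators": n, "max_depth": d, "min_samples_leaf": leaf}
            for leaf in (5, 1)
            for d in (6, None)
            for n in (100, 300)
        ],
        "LR": [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)],
        "SVM": [
            {"C": c, "gamma": g}
            for c in (0.1, 1.0, 10.0)
            for g in ("scale", 0.1, 0.01)
        ],
        "GBM": [
            {"n_estimators": n, "learning_rate": lr, "max_depth": d}
            for d in (2, 3)
            for lr in (0.05, 0.1)
            for n in (100, 200)
        ],
    }


@dataclass
class RunConfig:
    """Top-level configuration for an end-to-end pipeline run."""

    seed: int = 0
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    write_waveforms: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        # YAML round-trips lists, not tuples
        return json.loads(json.dumps(d))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        sub = {
            "simulator": SimulatorConfig,
            "preprocess": PreprocessConfig,
            "detector": DetectorConfig,
            "selection": SelectionConfig,
            "split": SplitConfig,
            "thresholds": ThresholdConfig,
            "model": ModelConfig,
        }
        for f in fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if f.name in sub and isinstance(v, dict):
                klass = sub[f.name]
                v = klass(**{k: _tupleize(klass, k, x) for k, x in v.items()})
            kwargs[f.name] = v
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Short stable digest recorded in every output artifact."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _tupleize(klass, name, value):
    """Restore tuple-typed fields lost to YAML/JSON list coercion."""
    for f in fields(klass):
        if f.name == name and f.type == "tuple" and isinstance(value, list):
            return tuple(value)
    return value
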