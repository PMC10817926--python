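import dataclasses

import numpy as np
import pytest

from mlfra.beats import BeatFiducials, detect_beats
from mlfra.features import (FEATURE_NAMES, FEATURE_REGISTRY, NOTCH_FEATURES,
                            aggregate_features, classify_ppv,
                            compute_beat_features, compute_ppv,
                            fit_exponential_decay)
from mlfra.preprocess import preprocess_abp
from mlfra.waveform import WaveformSegment


def _toy_beat(pp_values=None):
    """Synthetic beats over a triangular-ish waveform for hand-checkable math."""
    fs = 100.0
    beats = []
    x = []
    idx = 0
    pps = pp_values if pp_values is not None else [40.0] * 5
    for pp in pps:
        up = np.linspace(80, 80 + pp, 20)
        down = np.linspace(80 + pp, 80, 31)[1:-1]
        beat = np.concatenate([up, down])   # 49 samples, foot-to-foot
        notch_idx = idx + 30
        beats.append(BeatFiducials(
            foot_idx=idx, peak_idx=idx + 19, notch_idx=notch_idx,
            next_foot_idx=idx + 49,
            foot_time_s=idx / fs, peak_time_s=(idx + 19) / fs,
            notch_time_s=notch_idx / fs,
            foot_p_mmhg=80.0, peak_p_mmhg=80.0 + pp,
            notch_p_mmhg=float(beat[30]), notch_flagged=False))
        x.append(beat)
        idx += 49
    x.append([80.0])
    samples = np.concatenate([np.asarray(c, float) for c in x])
    return beats, WaveformSegment(samples, fs)


class TestBeatFeatures:
    def test_registry_size_and_names(self):
        assert len(FEATURE_REGISTRY) == 25
        assert len(FEATURE_NAMES) == 50
        assert len(set(FEATURE_NAMES)) == 50

    def test_definitional_bounds(self):
        beats, seg = _toy_beat()
        f = compute_beat_features(beats[0], seg)
        assert f["pp"] == pytest.approx(40.0)
        assert 80.0 < f["map"] < 120.0
        assert f["sbp"] == pytest.approx(120.0)
        assert f["dbp"] == pytest.approx(80.0)
        assert f["hr_inst"] == pytest.approx(60.0 / f["period_s"])

    def test_symmetric_triangle_skew_near_zero(self):
        fs = 100.0
        up = np.linspace(80, 120, 26)
        down = np.linspace(120, 80, 26)[1:]
        x = np.concatenate([up, down, [80.0]])
        seg = WaveformSegment(x, fs)
        beat = BeatFiducials(0, 25, 35, 50, 0.0, 0.25, 0.35, 80.0, 120.0,
                             float(x[35]), False)
        f = compute_beat_features(beat, seg)
        assert abs(f["pressure_skew"]) < 0.15

    def test_planted_tau_recovered(self):
        t = np.arange(0, 0.6, 0.01)
        y = 25.0 * np.exp(-t / 0.5) + 60.0
        tau, amp, c = fit_exponential_decay(t, y)
        assert tau == pytest.approx(0.5, abs=0.01)
        assert c == pytest.approx(60.0, abs=0.1)

    def test_notch_flagged_beat_yields_nulls(self):
        beats, seg = _toy_beat()
        flagged = dataclasses.replace(beats[0], notch_idx=None,
                                      notch_time_s=None, notch_p_mmhg=None,
                                      notch_flagged=True)
        f = compute_beat_features(flagged, seg)
        for name in NOTCH_FEATURES:
            assert f[name] is None
        assert f["pp"] == pytest.approx(40.0)


class TestAggregation:
    def test_vector_has_exactly_50_features(self, clean_bolus):
        bolus, _, _ = clean_bolus
        seg = preprocess_abp(bolus.abp_pre)
        vec = aggregate_features(detect_beats(seg), seg)
        assert list(vec.values) == list(FEATURE_NAMES)
        assert len(vec.values) == 50
        finite = [v for v in vec.values.values() if np.isfinite(v)]
        assert len(finite) == 50

    def test_identical_beats_zero_sd(self):
        beats, seg = _toy_beat([40.0] * 6)
        vec = aggregate_features(beats, seg)
        for base in FEATURE_REGISTRY:
            sd = vec.values[f"{base}_sd"]
            if np.isfinite(sd):
                assert sd == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_median_and_sd(self):
        beats, seg = _toy_beat([38.0, 40.0, 42.0])
        vec = aggregate_features(beats, seg)
        assert vec.values["sbp_median"] == pytest.approx(120.0)
        assert vec.values["sbp_sd"] == pytest.approx(2.0)   # sample SD of 118/120/122
        assert vec.values["pp_median"] == pytest.approx(40.0)

    def test_too_few_beats_rejected(self):
        beats, seg = _toy_beat([40.0, 41.0])
        from mlfra.beats import InsufficientBeatsError
        with pytest.raises(InsufficientBeatsError):
            aggregate_features(beats[:2], seg)


class TestPPV:
    def test_constant_pulse_pressure_zero(self):
        beats, _ = _toy_beat([40.0] * 5)
        assert compute_ppv(beats) == pytest.approx(0.0)

    def test_hand_formula(self):
        beats, _ = _toy_beat([40.0, 44.0, 48.0, 52.0])
        assert compute_ppv(beats) == pytest.approx(100 * 12 / 46, abs=0.01)

    def test_additive_and_multiplicative_invariance(self):
        beats, _ = _toy_beat([40.0, 44.0, 48.0, 52.0])
        base = compute_ppv(beats)
        shifted = [dataclasses.replace(b, foot_p_mmhg=b.foot_p_mmhg + 13,
                                       peak_p_mmhg=b.peak_p_mmhg + 13)
                   for b in beats]
        scaled = [dataclasses.replace(b, foot_p_mmhg=b.foot_p_mmhg * 2.5,
                                      peak_p_mmhg=b.peak_p_mmhg * 2.5)
                  for b in beats]
        assert compute_ppv(shifted) == pytest.approx(base, abs=1e-9)
        assert compute_ppv(scaled) == pytest.approx(base, abs=1e-9)

    @pytest.mark.parametrize("ppv,expected", [(12.0, "FR"), (11.99, "NR"), (0.0, "NR")])
    def test_threshold_boundary_inclusive(self, ppv, expected):
        assert classify_ppv(ppv) == expected

    def test_sd_features_track_ppv(self, small_table):
        """With clean respiratory modulation, pulse-pressure SD and PPV rank
        boluses almost identically (both read the same modulation depth)."""
        from scipy.stats import spearmanr

        from conftest import clean_sim_config
        from mlfra.config import RunConfig
        from mlfra.pipeline import extract_cohort
        from mlfra.simulate import iter_cohort
        cfg = RunConfig(seed=5)
        sim = clean_sim_config(noise_sd_mmhg=1.0, drift_amplitude_mmhg=2.0)
        table = extract_cohort(iter_cohort(10, 3, 0.5, 5, sim), cfg)
        rho = spearmanr(table["pp_sd"], table["ppv_pct"]).statistic
        assert rho > 0.8
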