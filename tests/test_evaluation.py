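import numpy as np
import pandas as pd
import pytest

from mlfra.evaluation import (aggregate_splits, calibration_curve,
                              confusion_metrics, error_analysis,
                              evaluate_holdout, ks_shift_fraction)


def brute_force_auroc(scores, labels):
    """Pairwise Mann-Whitney probability-of-correct-ranking oracle."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUROC:
    def test_matches_pairwise_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 51))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)   # induce ties
            rep = evaluate_holdout(s, y)
            assert rep.auroc == pytest.approx(brute_force_auroc(s, y), abs=1e-12)

    def test_perfect_separation(self):
        y = np.array([0] * 10 + [1] * 10)
        s = np.concatenate([np.linspace(0, 0.4, 10), np.linspace(0.6, 1, 10)])
        rep = evaluate_holdout(s, y)
        assert rep.auroc == 1.0
        row = rep.thresholds[rep.thresholds.threshold == 0.5].iloc[0]
        assert row["accuracy"] == 1.0

    def test_random_scores_near_half(self, rng):
        y = rng.integers(0, 2, 2000)
        s = rng.random(2000)
        assert evaluate_holdout(s, y).auroc == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_holdout(np.array([0.2, 0.8]), np.array([1, 1]))


class TestThresholdSweep:
    def test_degenerate_endpoints(self, rng):
        y = rng.integers(0, 2, 200)
        s = rng.random(200) * 0.98  # strictly below 1
        rep = evaluate_holdout(s, y)
        at0 = rep.thresholds[rep.thresholds.threshold == 0.0].iloc[0]
        at1 = rep.thresholds[rep.thresholds.threshold == 1.0].iloc[0]
        assert at0["recall"] == 1.0 and at0["specificity"] == 0.0
        assert at0["accuracy"] == pytest.approx(y.mean())
        assert at1["recall"] == 0.0 and at1["specificity"] == 1.0
        assert at1["accuracy"] == pytest.approx(1 - y.mean())
        assert np.isnan(at1["precision"])   # no positive calls -> undefined

    def test_confusion_metrics_hand_case(self):
        y = np.array([1, 1, 0, 0])
        s = np.array([0.9, 0.4, 0.6, 0.1])
        m = confusion_metrics(s, y, 0.5)
        assert m["accuracy"] == 0.5
        assert m["precision"] == 0.5
        assert m["recall"] == 0.5
        assert m["specificity"] == 0.5


class TestCalibration:
    def test_single_bin_observed_fraction(self):
        p = np.full(200, 0.55)
        y = np.array([1] * 110 + [0] * 90)
        bins = calibration_curve(p, y)
        occupied = bins[bins["count"] > 0]
        assert len(occupied) == 1
        assert occupied.iloc[0]["observed_fr_fraction"] == pytest.approx(0.55)

    def test_true_bernoulli_probabilities_calibrated(self, rng):
        p = rng.random(5000)
        y = (rng.random(5000) < p).astype(int)
        bins = calibration_curve(p, y)
        occ = bins[bins["count"] > 0]
        err = (occ["observed_fr_fraction"] - occ["mean_predicted"]).abs()
        assert err.max() < 0.05

    def test_counts_conserved(self, rng):
        p = rng.random(777)
        y = rng.integers(0, 2, 777)
        assert calibration_curve(p, y)["count"].sum() == 777

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            calibration_curve(np.array([0.5, 1.2]), np.array([0, 1]))


class TestAggregation:
    def _report(self, rng, auroc_shift=0.0):
        y = np.array([0, 1] * 25)
        s = np.clip(rng.random(50) * 0.5 + y * 0.3 + auroc_shift, 0, 1)
        return evaluate_holdout(s, y)

    def test_identical_reports_zero_ci(self, rng):
        rep = self._report(rng)
        agg = aggregate_splits([rep, rep, rep])
        assert (agg["metrics"]["ci95_half_width"] < 1e-12).all()

    def test_mean_of_two(self, rng):
        r1, r2 = self._report(rng), self._report(rng, 0.1)
        agg = aggregate_splits([r1, r2])
        row = agg["metrics"].set_index("metric").loc["auroc"]
        assert row["mean"] == pytest.approx((r1.auroc + r2.auroc) / 2)

    def test_ci_matches_closed_form(self, rng):
        reps = [self._report(rng, shift) for shift in rng.normal(0, 0.05, 29)]
        agg = aggregate_splits(reps)
        vals = np.array([r.auroc for r in reps])
        expect = 1.96 * vals.std(ddof=1) / np.sqrt(29)
        row = agg["metrics"].set_index("metric").loc["auroc"]
        assert row["ci95_half_width"] == pytest.approx(expect)


class TestErrorAnalysis:
    def test_perfect_collinearity(self):
        df = pd.DataFrame({"split_id": [1, 2, 3, 4],
                           "auroc": [0.9, 0.8, 0.7, 0.6],
                           "grey_fraction": [0.1, 0.2, 0.3, 0.4]})
        res = error_analysis(df).set_index("driver")
        assert res.loc["grey_fraction", "pearson_r"] == pytest.approx(-1.0)

    def test_zero_variance_driver_undefined(self):
        df = pd.DataFrame({"split_id": [1, 2, 3],
                           "auroc": [0.7, 0.8, 0.9],
                           "flat": [0.5, 0.5, 0.5]})
        res = error_analysis(df).set_index("driver")
        assert np.isnan(res.loc["flat", "pearson_r"])

    def test_shift_fraction_null_near_alpha(self, rng):
        from mlfra.features import FEATURE_NAMES
        n = 120
        cols = {c: rng.normal(size=n) for c in FEATURE_NAMES}
        df = pd.DataFrame(cols)
        frac = ks_shift_fraction(df.iloc[:60], df.iloc[60:], alpha=0.1)
        assert frac <= 0.25   # identical distributions: ~alpha of 50 features
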