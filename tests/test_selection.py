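import numpy as np
import pandas as pd
import pytest

from mlfra.features import FEATURE_NAMES
from mlfra.selection import (KSStatisticalSelector, MutualInfoSelector,
                             PermutationImportanceSelector, RFESelector,
                             SelectionResult, consensus_features)


def planted_dataset(rng, n_per_class=60, n_noise=19, gap_sd=3.0):
    """One informative feature (class means ``gap_sd`` SDs apart) + noise."""
    y = np.array(["FR"] * n_per_class + ["NR"] * n_per_class)
    signal = np.concatenate([rng.normal(gap_sd, 1, n_per_class),
                             rng.normal(0, 1, n_per_class)])
    noise = rng.normal(0, 1, (2 * n_per_class, n_noise))
    X = pd.DataFrame(np.column_stack([signal, noise]),
                     columns=["signal"] + [f"noise{i}" for i in range(n_noise)])
    return X, y


class TestStatisticalSelector:
    def test_separated_feature_retained(self, rng):
        X, y = planted_dataset(rng, n_per_class=100)
        sel = KSStatisticalSelector().fit(X, y)
        assert "signal" in sel.retained_features_

    def test_duplicate_feature_pruned(self, rng):
        X, y = planted_dataset(rng, n_per_class=80, n_noise=3)
        X["copy"] = X["signal"]
        sel = KSStatisticalSelector().fit(X, y)
        kept = sel.retained_features_
        assert ("signal" in kept) != ("copy" in kept)  # exactly one survives

    def test_no_retained_pair_highly_correlated(self, rng):
        X, y = planted_dataset(rng, n_per_class=80, n_noise=10)
        X["half_copy"] = X["signal"] + rng.normal(0, 0.05, len(X))
        sel = KSStatisticalSelector(corr_threshold=0.9).fit(X, y)
        kept = sel.retained_features_
        if len(kept) > 1:
            corr = np.abs(np.corrcoef(X[kept].to_numpy(), rowvar=False))
            np.fill_diagonal(corr, 0)
            assert corr.max() < 0.9

    def test_single_class_rejected(self, rng):
        X, _ = planted_dataset(rng)
        with pytest.raises(ValueError):
            KSStatisticalSelector().fit(X, np.array(["FR"] * len(X)))

    def test_literal_direction_flag(self, rng):
        X, y = planted_dataset(rng, n_per_class=100)
        sel = KSStatisticalSelector(retain_if_discriminative=False).fit(X, y)
        assert "signal" not in sel.retained_features_

    def test_type_one_rate_near_alpha(self, rng):
        """A pure-noise feature is retained at rate ~ alpha (quick version;
        the full 1000-trial calibration runs in the acceptance suite)."""
        hits = 0
        n = 300
        for _ in range(n):
            a = rng.normal(size=100)
            b = rng.normal(size=100)
            from scipy.stats import ks_2samp
            hits += ks_2samp(a, b).pvalue < 0.1
        assert abs(hits / n - 0.1) < 0.05


@pytest.mark.parametrize("selector_cls", [RFESelector, PermutationImportanceSelector,
                                          MutualInfoSelector])
class TestModelBasedSelectors:
    def test_exactly_ten_retained(self, selector_cls, rng):
        X, y = planted_dataset(rng, n_per_class=40, n_noise=49)
        sel = selector_cls(n_keep=10, random_state=0).fit(X, y)
        assert len(sel.retained_features_) == 10

    def test_planted_feature_found(self, selector_cls, rng):
        X, y = planted_dataset(rng, n_per_class=60, n_noise=20, gap_sd=4.0)
        sel = selector_cls(n_keep=5, random_state=0).fit(X, y)
        assert "signal" in sel.retained_features_

    def test_n_keep_exceeding_features_rejected(self, selector_cls, rng):
        X, y = planted_dataset(rng, n_per_class=20, n_noise=4)
        with pytest.raises(ValueError):
            selector_cls(n_keep=10).fit(X, y)


class TestSelectorEdgeCases:
    def test_rfe_identity_when_keeping_all(self, rng):
        X, y = planted_dataset(rng, n_per_class=30, n_noise=7)
        sel = RFESelector(n_keep=8, random_state=0).fit(X, y)
        assert sel.retained_features_ == list(X.columns)

    def test_permutation_null_importances_near_zero(self, rng):
        X, y = planted_dataset(rng, n_per_class=50, n_noise=9)
        y_perm = rng.permutation(y)
        sel = PermutationImportanceSelector(n_keep=5, random_state=0).fit(X, y_perm)
        assert np.abs(sel.importances_).max() < 0.15

    def test_mutual_info_independent_feature_near_zero(self, rng):
        X, y = planted_dataset(rng, n_per_class=100, n_noise=2)
        sel = MutualInfoSelector(n_keep=3, random_state=0).fit(X, y)
        assert sel.scores_["noise0"] < 0.05

    def test_mutual_info_label_copy_ranked_first(self, rng):
        y = np.array(["FR", "NR"] * 80)
        X = pd.DataFrame({
            "leak": (y == "FR").astype(float) + rng.normal(0, 0.01, 160),
            "junk": rng.normal(size=160),
        })
        sel = MutualInfoSelector(n_keep=1, random_state=0).fit(X, y)
        assert sel.retained_features_ == ["leak"]


class TestConsensus:
    def _result(self, names, split_id=0, method="rfe"):
        return SelectionResult(method=method, split_id=split_id,
                               retained=list(names))

    def test_boundary_inclusive_at_half(self):
        results = [self._result(["a"]) for _ in range(58)] + \
                  [self._result(["b"]) for _ in range(58)]
        for r in results[:58]:
            r.retained.append("c")   # c in 58/116 trials
        kept = consensus_features(results, 0.5)
        assert "a" in kept and "b" in kept and "c" in kept

    def test_below_half_dropped(self):
        results = ([self._result(["a", "c"]) for _ in range(57)]
                   + [self._result(["a"]) for _ in range(59)])
        kept = consensus_features(results, 0.5)
        assert "a" in kept and "c" not in kept   # 57/116 < 0.5

    def test_trial_count_bookkeeping(self):
        results = [self._result(["x"], split_id=s, method=m)
                   for s in range(1, 30)
                   for m in ("statistical", "rfe", "permutation", "mutual_info")]
        assert len(results) == 116

    def test_ordering_frequency_then_registry(self):
        f1, f2 = FEATURE_NAMES[5], FEATURE_NAMES[2]
        results = [self._result([f1, f2]), self._result([f1, f2])]
        kept = consensus_features(results, 0.5)
        assert kept == [f2, f1]   # equal frequency -> registry order

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            consensus_features([], 0.5)
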