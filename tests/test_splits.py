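from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from mlfra.splits import (_pig_table, _score_partition, assert_no_leakage,
                          make_cv_folds, make_splits, plans_to_frame)


def toy_labels(pig_specs):
    """pig_specs: list of (pig_id, injury_model, n_fr, n_nr)."""
    rows = []
    for pid, model, n_fr, n_nr in pig_specs:
        for i in range(n_fr):
            rows.append({"pig_id": pid, "injury_model": model, "label": "FR"})
        for i in range(n_nr):
            rows.append({"pig_id": pid, "injury_model": model, "label": "NR"})
    return pd.DataFrame(rows)


def cohort_58():
    rng = np.random.default_rng(0)
    specs = []
    for i in range(58):
        model = ("HEM", "IRI", "EPACC")[i % 3]
        n = int(rng.integers(4, 10))
        n_fr = int(rng.integers(0, n + 1))
        specs.append((f"p{i:02d}", model, n_fr, n - n_fr))
    return toy_labels(specs)


class TestMakeSplits:
    def test_58_pigs_exact_halves(self):
        plans = make_splits(cohort_58(), n_splits=29, seed=3)
        assert len(plans) == 29
        for p in plans:
            assert len(p.train_pigs) == 29 and len(p.test_pigs) == 29
            assert not set(p.train_pigs) & set(p.test_pigs)

    def test_identical_pigs_give_exact_prevalence(self):
        labels = toy_labels([(f"p{i}", "HEM", 2, 2) for i in range(6)])
        plans = make_splits(labels, n_splits=3, seed=0)
        for p in plans:
            assert p.fr_prevalence_train == pytest.approx(0.5)
            assert p.fr_prevalence_test == pytest.approx(0.5)

    def test_adversarial_cohort_near_target(self):
        # pigs are all-FR or all-NR; with an even test half a perfectly
        # balanced partition exists and the splitter must find it
        labels = toy_labels([("a", "HEM", 4, 0), ("b", "HEM", 4, 0),
                             ("c", "HEM", 4, 0), ("d", "IRI", 0, 4),
                             ("e", "IRI", 0, 4), ("f", "IRI", 0, 4),
                             ("g", "HEM", 4, 0), ("h", "IRI", 0, 4)])
        for p in make_splits(labels, n_splits=2, seed=1):
            assert abs(p.fr_prevalence_test - 0.5) <= 0.05
            assert abs(p.fr_prevalence_train - 0.5) <= 0.05

    def test_matches_exhaustive_optimum_on_toys(self):
        """On enumerable cohorts the chosen partition's score is within 10%
        of the brute-force best."""
        rng = np.random.default_rng(7)
        for trial in range(5):
            specs = []
            for i in range(8):
                model = ("HEM", "IRI", "EPACC")[int(rng.integers(3))]
                n = int(rng.integers(2, 7))
                n_fr = int(rng.integers(0, n + 1))
                specs.append((f"p{i}", model, n_fr, n - n_fr))
            labels = toy_labels(specs)
            pigs = _pig_table(labels)
            best = min(_score_partition(pigs, c, 0.5, 0.25)[0]
                       for c in combinations(pigs.index, 4))
            plan = make_splits(labels, n_splits=1, seed=trial)[0]
            assert plan.score <= best * 1.1 + 1e-9

    def test_odd_pig_count_extra_goes_to_training(self):
        labels = toy_labels([(f"p{i}", "HEM", 1, 1) for i in range(7)])
        plan = make_splits(labels, n_splits=1, seed=0)[0]
        assert len(plan.train_pigs) == 4 and len(plan.test_pigs) == 3

    def test_determinism(self):
        a = make_splits(cohort_58(), n_splits=4, seed=9)
        b = make_splits(cohort_58(), n_splits=4, seed=9)
        for x, y in zip(a, b):
            assert x.train_pigs == y.train_pigs and x.test_pigs == y.test_pigs

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            make_splits(cohort_58(), n_splits=0)
        with pytest.raises(ValueError):
            make_splits(toy_labels([("a", "HEM", 1, 1)]), n_splits=1)


class TestCVFolds:
    def test_29_training_pigs_balanced_fold_sizes(self):
        labels = cohort_58()
        plan = make_splits(labels, n_splits=1, seed=2)[0]
        folds = make_cv_folds(plan, labels, k=5, seed=2)
        sizes = pd.Series(list(folds.assignments.values())).value_counts()
        assert sorted(sizes) == [5, 6, 6, 6, 6]

    def test_no_pig_spans_folds(self):
        labels = cohort_58()
        plan = make_splits(labels, n_splits=1, seed=2)[0]
        folds = make_cv_folds(plan, labels, k=5, seed=2)
        assert set(folds.assignments) == set(plan.train_pigs)
        # one fold per pig by construction of the mapping
        assert all(isinstance(v, int) or v in range(1, 6)
                   for v in folds.assignments.values())

    def test_fold_prevalences_balanced_on_toy(self):
        labels = toy_labels([(f"p{i}", "HEM", 2 + i % 2, 2) for i in range(10)])
        plan = make_splits(labels, n_splits=1, seed=0)[0]
        plan = plan.__class__(**{**plan.__dict__,
                                 "train_pigs": tuple(sorted(labels.pig_id.unique())),
                                 "test_pigs": ()})
        folds = make_cv_folds(plan, labels, k=5, seed=0)
        prevs = []
        for f in range(1, 6):
            pigs = [p for p, ff in folds.assignments.items() if ff == f]
            sub = labels[labels.pig_id.isin(pigs)]
            prevs.append((sub.label == "FR").mean())
        assert max(prevs) - min(prevs) <= 0.15

    def test_fewer_pigs_than_folds_rejected(self):
        labels = toy_labels([(f"p{i}", "HEM", 1, 1) for i in range(4)])
        plan = make_splits(labels, n_splits=1, seed=0)[0]
        with pytest.raises(ValueError):
            make_cv_folds(plan, labels, k=5, seed=0)


class TestLeakageGuard:
    def test_serialization_and_guard(self):
        labels = cohort_58()
        plans = make_splits(labels, n_splits=3, seed=5)
        folds = {p.split_id: make_cv_folds(p, labels, 5, p.seed) for p in plans}
        assert_no_leakage(plans, folds)
        frame = plans_to_frame(plans, folds)
        assert set(frame["role"]) == {"train", "test"}
        per_split = frame.groupby("split_id")["pig_id"].nunique()
        assert (per_split == 58).all()
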