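"""Pig-level stratified train/test splits and cross-validation folds.

All partitioning is done at the animal level so no pig contributes boluses to
both sides of any split or to two CV folds (leakage guard).  Splits are chosen
by scoring candidate half-partitions on how close both sides' FR prevalence
comes to the target (default 50%) plus a penalty for injury-model imbalance.
When the number of distinct partitions is small enough they are enumerated
exhaustively, so on toy cohorts the chosen plan is the exact optimum;
otherwise the configured number of random candidates is scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .config import SplitConfig


@dataclass
class SplitPlan:
    split_id: int
    train_pigs: tuple
    test_pigs: tuple
    seed: int
    fr_prevalence_train: float
    fr_prevalence_test: float
    injury_mix_train: dict
    injury_mix_test: dict
    score: float

    def __post_init__(self):
        overlap = set(self.train_pigs) & set(self.test_pigs)
        if overlap:
            raise ValueError(f"leakage: pigs on both sides: {sorted(overlap)}")


@dataclass
class FoldPlan:
    split_id: int
    assignments: dict = field(default_factory=dict)  # pig_id -> fold (1..k)
    k: int = 5


def _pig_table(labels: pd.DataFrame) -> pd.DataFrame:
    """Per-pig bolus counts: total, FR, and injury model."""
    g = labels.groupby("pig_id")
    out = pd.DataFrame({
        "n_boluses": g.size(),
        "n_fr": g["label"].apply(lambda s: int((s == "FR").sum())),
        "injury_model": g["injury_model"].first(),
    })
    return out.sort_index()


def _score_partition(pigs: pd.DataFrame, test_ids, target: float,
                     mix_weight: float):
    test_mask = pigs.index.isin(test_ids)
    tr, te = pigs[~test_mask], pigs[test_mask]
    prev_tr = tr["n_fr"].sum() / tr["n_boluses"].sum()
    prev_te = te["n_fr"].sum() / te["n_boluses"].sum()
    models = pigs["injury_model"].unique()
    mix_tr = {m: tr.loc[tr.injury_model == m, "n_boluses"].sum() / tr["n_boluses"].sum()
              for m in models}
    mix_te = {m: te.loc[te.injury_model == m, "n_boluses"].sum() / te["n_boluses"].sum()
              for m in models}
    imbalance = sum(abs(mix_tr[m] - mix_te[m]) for m in models)
    score = abs(prev_tr - target) + abs(prev_te - target) + mix_weight * imbalance
    return score, prev_tr, prev_te, mix_tr, mix_te


def make_splits(labels: pd.DataFrame, n_splits: int = 29,
                target_prevalence: float = 0.5, seed: int = 0,
                cfg: SplitConfig | None = None) -> list:
    """Generate ``n_splits`` stratified pig-level train/test plans.

    ``labels`` needs columns pig_id, injury_model, label.  Each plan places
    half the pigs in test (the extra pig goes to training when the count is
    odd).  Deterministic given ``seed``; split ``i`` uses substream
    ``seed + i`` so individual splits are independently reproducible.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    cfg = cfg or SplitConfig()
    pigs = _pig_table(labels)
    n = len(pigs)
    if n < 4:
        raise ValueError("need at least 4 pigs to split")
    if (pigs["n_boluses"] == 0).any():
        raise ValueError("every pig must have at least one labeled bolus")
    n_test = n // 2
    ids = np.array(pigs.index)

    exhaustive = comb(n, n_test) <= cfg.n_candidates
    plans = []
    for split_id in range(1, n_splits + 1):
        rng = np.random.default_rng(seed + split_id)
        if exhaustive:
            candidates = [tuple(c) for c in combinations(ids, n_test)]
        else:
            candidates = []
            for _ in range(cfg.n_candidates):
                perm = rng.permutation(ids)
                candidates.append(tuple(sorted(perm[:n_test])))
        best = None
        for idx, test_ids in enumerate(candidates):
            score, p_tr, p_te, m_tr, m_te = _score_partition(
                pigs, test_ids, target_prevalence, cfg.injury_mix_weight)
            if best is None or score < best[0] - 1e-12:
                best = (score, idx, test_ids, p_tr, p_te, m_tr, m_te)
        score, _, test_ids, p_tr, p_te, m_tr, m_te = best
        train_ids = tuple(sorted(set(ids) - set(test_ids)))
        plans.append(SplitPlan(
            split_id=split_id, train_pigs=train_ids,
            test_pigs=tuple(sorted(test_ids)), seed=seed + split_id,
            fr_prevalence_train=p_tr, fr_prevalence_test=p_te,
            injury_mix_train=m_tr, injury_mix_test=m_te, score=score,
        ))
    return plans


def make_cv_folds(plan: SplitPlan, labels: pd.DataFrame, k: int = 5,
                  seed: int = 0) -> FoldPlan:
    """Greedy stratified assignment of training pigs to ``k`` folds.

    Pigs are taken in descending bolus-count order (seeded shuffle breaks
    count ties) and each goes to the fold that minimises, in order: the
    fold's |FR - NR| bolus imbalance after assignment, fold size, fold index.
    """
    train = labels[labels["pig_id"].isin(plan.train_pigs)]
    pigs = _pig_table(train)
    if len(pigs) < k:
        raise ValueError(f"fewer training pigs ({len(pigs)}) than folds ({k})")
    rng = np.random.default_rng(seed)
    order = list(pigs.index)
    rng.shuffle(order)
    order.sort(key=lambda p: -pigs.loc[p, "n_boluses"])

    fr = np.zeros(k)
    nr = np.zeros(k)
    size = np.zeros(k)
    count = np.zeros(k, dtype=int)
    cap = -(-len(pigs) // k)        # ceil: pig counts stay within one of equal
    assignments = {}
    for pig in order:
        p_fr = pigs.loc[pig, "n_fr"]
        p_nr = pigs.loc[pig, "n_boluses"] - p_fr
        best_f, best_key = None, None
        for f in range(k):
            if count[f] >= cap:
                continue
            key = (abs((fr[f] + p_fr) - (nr[f] + p_nr)), size[f], f)
            if best_key is None or key < best_key:
                best_f, best_key = f, key
        assignments[pig] = best_f + 1
        fr[best_f] += p_fr
        nr[best_f] += p_nr
        size[best_f] += p_fr + p_nr
        count[best_f] += 1
    return FoldPlan(split_id=plan.split_id, assignments=assignments, k=k)


def plans_to_frame(plans: list, fold_plans: dict | None = None) -> pd.DataFrame:
    """Serialize plans as tidy rows (split_id, pig_id, role, fold)."""
    rows = []
    for plan in plans:
        folds = fold_plans.get(plan.split_id) if fold_plans else None
        for pig in plan.train_pigs:
            rows.append({"split_id": plan.split_id, "pig_id": pig,
                         "role": "train",
                         "fold": folds.assignments.get(pig) if folds else None})
        for pig in plan.test_pigs:
            rows.append({"split_id": plan.split_id, "pig_id": pig,
                         "role": "test", "fold": None})
    return pd.DataFrame(rows)


def assert_no_leakage(plans: list, fold_plans: dict | None = None) -> None:
    """Programmatic leakage guard, run on every pipeline pass."""
    for plan in plans:
        if set(plan.train_pigs) & set(plan.test_pigs):
            raise AssertionError(f"split {plan.split_id}: train/test overlap")
        if fold_plans and plan.split_id in fold_plans:
            fp = fold_plans[plan.split_id]
            assigned = set(fp.assignments)
            if not assigned <= set(plan.train_pigs):
                raise AssertionError(
                    f"split {plan.split_id}: fold pig outside training set")
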