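"""End-to-end orchestration: simulate -> preprocess -> detect -> featurize ->
label -> split -> select -> train -> evaluate.

Stages exchange delimited-text artifacts in a run directory; a cohort can also
be processed fully in memory (``write_waveforms=False``), in which case the
simulator is streamed bolus-by-bolus so peak memory stays at one bolus.
Structured logs record the seed, config hash and row counts per stage, and
reruns with an identical config are bit-identical for deterministic stages.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import beats as beats_mod
from . import features as feat_mod
from . import labels as label_mod
from . import selection as sel_mod
from . import simulate as sim_mod
from .beats import InsufficientBeatsError
from .config import RunConfig
from .evaluation import aggregate_splits, error_analysis, evaluate_holdout, ks_shift_fraction
from .models import predict_proba, save_bundle, tune_and_fit
from .preprocess import preprocess_abp, qc_segment
from .splits import assert_no_leakage, make_cv_folds, make_splits, plans_to_frame
from .waveform import load_segment

log = logging.getLogger("mlfra")

ALL_STAGES = ("simulate", "featurize", "label", "split", "select", "train", "evaluate")


class MissingArtifactError(FileNotFoundError):
    """An upstream interchange file required by a stage is absent."""


def featurize_bolus(abp_pre, cfg: RunConfig, bolus_id: str = "", pig_id: str = ""):
    """Preprocess one pre-bolus ABP segment and extract its feature vector.

    Returns (FeatureVector, qc_verdict); the vector is None when QC fails or
    too few beats survive filtering.
    """
    seg = preprocess_abp(abp_pre, cfg.preprocess)
    verdict = qc_segment(seg, cfg.preprocess)
    if not verdict:
        return None, verdict
    try:
        detected = beats_mod.detect_beats(seg, cfg.detector)
        kept = beats_mod.beat_quality_filter(detected, seg, cfg.detector)
        vec = feat_mod.aggregate_features(kept, seg, bolus_id=bolus_id, pig_id=pig_id)
    except InsufficientBeatsError:
        return None, verdict
    return vec, verdict


def extract_cohort(boluses, cfg: RunConfig):
    """Features + labels for an iterable of simulated boluses (one pass).

    Returns a merged table with the 50 features, ppv_pct, n_beats_used,
    delta_sv_pct, label, sv_zone and injury_model; QC-failing or beat-poor
    boluses are dropped and counted.
    """
    vectors, labels, dropped = [], [], 0
    for b in boluses:
        vec, verdict = featurize_bolus(b.abp_pre, cfg, b.bolus_id, b.pig_id)
        if vec is None:
            dropped += 1
            log.info("dropped bolus %s (qc=%s)", b.bolus_id, verdict.reasons)
            continue
        vectors.append(vec)
        labels.append(label_mod.label_simulated_bolus(
            b, cfg.thresholds.fr_delta_sv_pct, cfg.thresholds.grey_zone_pct))
    features = feat_mod.feature_frame(vectors)
    lab = pd.DataFrame([vars(r) for r in labels])
    merged = features.merge(
        lab[["bolus_id", "injury_model", "sv_pre_ml", "sv_post_ml",
             "delta_sv_pct", "label", "sv_zone"]], on="bolus_id")
    log.info("extracted %d boluses (%d dropped)", len(merged), dropped)
    return merged


def featurize_from_dir(cohort_dir, cfg: RunConfig) -> pd.DataFrame:
    """File-based featurize + label: read the manifest and waveform files."""
    cohort_dir = Path(cohort_dir)
    manifest_path = cohort_dir / "manifest.csv"
    if not manifest_path.exists():
        raise MissingArtifactError(f"missing interchange file: {manifest_path}")
    manifest = pd.read_csv(manifest_path)

    class _FileBolus:
        pass

    def gen():
        for _, row in manifest.iterrows():
            b = _FileBolus()
            b.bolus_id, b.pig_id = row["bolus_id"], row["pig_id"]
            b.injury_model = row["injury_model"]
            for key in sim_mod._SEGMENT_KEYS:
                channel = key.split("_")[0].upper()
                b.__dict__[key] = load_segment(
                    cohort_dir / row[f"{key}_file"], channel=channel,
                    expected_rate_hz=row[f"{key}_rate_hz"])
            yield b

    return extract_cohort(gen(), cfg)


def select_per_split(table: pd.DataFrame, plans, fold_plans, cfg: RunConfig,
                     methods=("statistical", "rfe", "permutation", "mutual_info")):
    """Run every selection method on every split's training data.

    Returns (results, consensus): ``len(results) == len(methods) * len(plans)``
    selection trials, and the consensus feature list (selected in >= 50% of
    trials).
    """
    results = []
    feature_cols = list(feat_mod.FEATURE_NAMES)
    for plan in plans:
        train = table[table["pig_id"].isin(plan.train_pigs)].reset_index(drop=True)
        train = feat_mod.impute_with_train_medians(train, train)
        X, y = train[feature_cols], train["label"].to_numpy()
        from .models import folds_from_plan
        folds = folds_from_plan(fold_plans[plan.split_id], train)
        for method in methods:
            selector = _make_selector(method, cfg, plan.seed)
            if method == "permutation":
                selector.fit(X, y, folds=folds)
            else:
                selector.fit(X, y)
            results.append(selector.to_result(split_id=plan.split_id))
    consensus = sel_mod.consensus_features(results, cfg.selection.consensus_min_frequency)
    return results, consensus


def _make_selector(method: str, cfg: RunConfig, seed: int):
    s = cfg.selection
    if method == "statistical":
        return sel_mod.KSStatisticalSelector(
            alpha=s.alpha, corr_threshold=s.corr_threshold,
            retain_if_discriminative=s.retain_if_discriminative)
    if method == "rfe":
        return sel_mod.RFESelector(n_keep=s.n_keep, random_state=seed)
    if method == "permutation":
        return sel_mod.PermutationImportanceSelector(
            n_keep=s.n_keep, n_permutations=s.n_permutations, random_state=seed)
    if method == "mutual_info":
        return sel_mod.MutualInfoSelector(n_keep=s.n_keep, random_state=seed)
    raise ValueError(f"unknown selection method {method!r}")


def train_and_evaluate(table: pd.DataFrame, plans, fold_plans, cfg: RunConfig,
                       features_per_split: dict, grid=None, models_dir=None):
    """Train one model per split on its selected features, evaluate MLFRA and
    PPV on the holdouts, and assemble aggregates and error analyses."""
    feature_cols = list(feat_mod.FEATURE_NAMES)
    ml_reports, ppv_reports, bundles, split_rows = [], [], [], []
    for plan in plans:
        train = table[table["pig_id"].isin(plan.train_pigs)].reset_index(drop=True)
        test = table[table["pig_id"].isin(plan.test_pigs)].reset_index(drop=True)
        train_i = feat_mod.impute_with_train_medians(train, train)
        test_i = feat_mod.impute_with_train_medians(train, test)
        selected = features_per_split[plan.split_id]
        bundle = tune_and_fit(train_i, train_i["label"].to_numpy(),
                              fold_plans[plan.split_id], selected,
                              algorithm=cfg.model.algorithm, grid=grid,
                              seed=plan.seed, split_id=plan.split_id)
        bundles.append(bundle)
        if models_dir is not None:
            save_bundle(bundle, Path(models_dir) / f"split{plan.split_id:02d}.joblib")
        probs = predict_proba(bundle, test_i)
        y = test_i["label"].to_numpy()
        ml = evaluate_holdout(probs, y, decision_threshold=cfg.thresholds.decision_threshold,
                              split_id=plan.split_id, method=f"MLFRA-{cfg.model.algorithm}")
        ppv_thresholds = tuple(np.linspace(0, 30, 11))
        ppv = evaluate_holdout(test_i["ppv_pct"].to_numpy(), y,
                               thresholds=ppv_thresholds,
                               decision_threshold=cfg.thresholds.ppv_threshold_pct,
                               split_id=plan.split_id, method="PPV",
                               with_calibration=False)
        ml_reports.append(ml)
        ppv_reports.append(ppv)
        split_rows.append({
            "split_id": plan.split_id,
            "auroc": ml.auroc,
            "ppv_auroc": ppv.auroc,
            "grey_fraction": float((test["sv_zone"] == "grey").mean()),
            "frac_hem": float((test["injury_model"] == "HEM").mean()),
            "frac_iri": float((test["injury_model"] == "IRI").mean()),
            "frac_epacc": float((test["injury_model"] == "EPACC").mean()),
            "shift_fraction": ks_shift_fraction(train, test, cfg.selection.alpha),
        })
    summary = pd.DataFrame(split_rows)
    err = error_analysis(summary[["split_id", "auroc", "grey_fraction",
                                  "frac_hem", "frac_iri", "frac_epacc",
                                  "shift_fraction"]]) if len(plans) >= 3 else None
    out = {
        "ml_reports": ml_reports,
        "ppv_reports": ppv_reports,
        "bundles": bundles,
        "split_summary": summary,
        "error_analysis": err,
    }
    if len(ml_reports) >= 2:
        out["ml_aggregate"] = aggregate_splits(ml_reports)
        out["ppv_aggregate"] = aggregate_splits(ppv_reports)
    return out


def run_pipeline(cfg: RunConfig, outdir, stages=None) -> dict:
    """Execute the requested pipeline stages into ``outdir``.

    In file mode (``cfg.write_waveforms``) the simulate stage materialises the
    cohort to disk and featurize/label read it back; otherwise the cohort is
    streamed in memory.  Returns a dict of artifact paths and key tables.
    """
    stages = list(stages or ALL_STAGES)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    log.info("run start: seed=%d config_hash=%s stages=%s", cfg.seed, chash, stages)
    cfg.to_yaml(outdir / "config.yaml")
    artifacts = {"config": outdir / "config.yaml", "config_hash": chash}
    sim = cfg.simulator
    table = None

    if "simulate" in stages and cfg.write_waveforms:
        boluses, profiles = sim_mod.simulate_cohort(
            sim.n_pigs, sim.boluses_per_pig, sim.fr_prevalence_target,
            cfg.seed, sim)
        manifest = sim_mod.write_cohort(boluses, outdir / "cohort")
        artifacts["manifest"] = manifest
        log.info("simulate: %d boluses from %d pigs", len(boluses), len(profiles))
        del boluses

    if "featurize" in stages or "label" in stages:
        if cfg.write_waveforms:
            table = featurize_from_dir(outdir / "cohort", cfg)
        else:
            stream = sim_mod.iter_cohort(sim.n_pigs, sim.boluses_per_pig,
                                         sim.fr_prevalence_target, cfg.seed, sim)
            table = extract_cohort(stream, cfg)
        table.insert(0, "config_hash", chash)
        table.to_csv(outdir / "features.csv", index=False)
        artifacts["features"] = outdir / "features.csv"

    if table is None and any(s in stages for s in ("split", "select", "train", "evaluate")):
        fpath = outdir / "features.csv"
        if not fpath.exists():
            raise MissingArtifactError(f"missing interchange file: {fpath}")
        table = pd.read_csv(fpath)

    plans = fold_plans = None
    if any(s in stages for s in ("split", "select", "train", "evaluate")):
        plans = make_splits(table, cfg.split.n_splits, cfg.split.target_prevalence,
                            cfg.seed, cfg.split)
        fold_plans = {p.split_id: make_cv_folds(p, table, cfg.split.k_folds, p.seed)
                      for p in plans}
        assert_no_leakage(plans, fold_plans)
        pf = plans_to_frame(plans, fold_plans)
        pf.insert(0, "config_hash", chash)
        pf.to_csv(outdir / "splits.csv", index=False)
        artifacts["splits"] = outdir / "splits.csv"
        artifacts["plans"] = plans
        artifacts["fold_plans"] = fold_plans

    if "select" in stages:
        results, consensus = select_per_split(table, plans, fold_plans, cfg)
        sf = sel_mod.results_to_frame(results)
        sf.insert(0, "config_hash", chash)
        sf.to_csv(outdir / "selection.csv", index=False)
        artifacts["selection"] = outdir / "selection.csv"
        artifacts["selection_results"] = results
        artifacts["consensus_features"] = consensus
        log.info("select: %d trials, %d consensus features",
                 len(results), len(consensus))

    if "train" in stages or "evaluate" in stages:
        if "selection_results" in artifacts:
            rfe = {r.split_id: r.retained for r in artifacts["selection_results"]
                   if r.method == "rfe"}
            per_split = {p.split_id: rfe[p.split_id] for p in plans}
        else:
            per_split = {p.split_id: list(feat_mod.FEATURE_NAMES) for p in plans}
        models_dir = outdir / "models"
        models_dir.mkdir(exist_ok=True)
        out = train_and_evaluate(table, plans, fold_plans, cfg, per_split,
                                 grid=cfg.model.grids.get(cfg.model.algorithm),
                                 models_dir=models_dir)
        artifacts.update(out)
        out["split_summary"].insert(0, "config_hash", chash)
        out["split_summary"].to_csv(outdir / "split_summary.csv", index=False)
        if out.get("error_analysis") is not None:
            out["error_analysis"].to_csv(outdir / "error_analysis.csv", index=False)
        if "ml_aggregate" in out:
            out["ml_aggregate"]["metrics"].to_csv(outdir / "metrics_mlfra.csv", index=False)
            out["ppv_aggregate"]["metrics"].to_csv(outdir / "metrics_ppv.csv", index=False)
            out["ml_aggregate"]["threshold_sweep"].to_csv(
                outdir / "threshold_sweep.csv", index=False)
        log.info("evaluate: mean MLFRA AUROC=%.3f, PPV AUROC=%.3f",
                 out["split_summary"]["auroc"].mean(),
                 out["split_summary"]["ppv_auroc"].mean())
    return artifacts
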