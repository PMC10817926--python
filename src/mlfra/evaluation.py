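"""Holdout evaluation: discrimination, threshold sweep, calibration,
cross-split aggregation, and error analysis.

AUROC is the trapezoidal area under the ROC curve (equal to the Mann-Whitney
probability of correct ranking); AUPRC is step-wise average precision.
Confusion metrics are computed per threshold with the positive rule
``score >= t``; cells that are undefined (e.g. precision with zero positive
calls) are reported as NaN, never as 0.  Cross-split summaries are
mean +/- 1.96 * SD / sqrt(n) over the holdout reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .features import FEATURE_NAMES

DEFAULT_THRESHOLDS = tuple(np.round(np.linspace(0.0, 1.0, 11), 1))


def _binary(labels):
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = (y == "FR").astype(int)
    return y.astype(int)


@dataclass
class EvaluationReport:
    split_id: int
    method: str                     # e.g. "MLFRA-rfe" or "PPV"
    auroc: float
    auprc: float
    thresholds: pd.DataFrame        # threshold, accuracy, precision, recall, specificity, npv
    calibration: pd.DataFrame | None
    n_test: int
    prevalence: float
    at_decision: dict = field(default_factory=dict)


def confusion_metrics(scores, labels, threshold: float) -> dict:
    """Confusion-matrix metrics with positive rule score >= threshold."""
    y = _binary(labels)
    s = np.asarray(scores, dtype=float)
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    n = y.size
    return {
        "threshold": threshold,
        "accuracy": (tp + tn) / n,
        "precision": tp / (tp + fp) if (tp + fp) > 0 else np.nan,
        "recall": tp / (tp + fn) if (tp + fn) > 0 else np.nan,
        "specificity": tn / (tn + fp) if (tn + fp) > 0 else np.nan,
        "npv": tn / (tn + fn) if (tn + fn) > 0 else np.nan,
    }


def evaluate_holdout(scores, labels, thresholds=DEFAULT_THRESHOLDS,
                     decision_threshold: float = 0.5, split_id: int = 0,
                     method: str = "MLFRA",
                     with_calibration: bool = True) -> EvaluationReport:
    """Evaluate one holdout set given per-bolus scores (probabilities, or PPV
    values with thresholds on the PPV scale)."""
    y = _binary(labels)
    s = np.asarray(scores, dtype=float)
    if y.size < 2 or len(np.unique(y)) < 2:
        raise ValueError("holdout evaluation requires both classes present")
    auroc = float(roc_auc_score(y, s))
    auprc = float(average_precision_score(y, s))
    rows = [confusion_metrics(s, y, t) for t in thresholds]
    calib = calibration_curve(s, y) if with_calibration and s.max() <= 1.0 else None
    return EvaluationReport(
        split_id=split_id, method=method, auroc=auroc, auprc=auprc,
        thresholds=pd.DataFrame(rows), calibration=calib,
        n_test=int(y.size), prevalence=float(y.mean()),
        at_decision=confusion_metrics(s, y, decision_threshold),
    )


def calibration_curve(probabilities, labels, n_bins: int = 10) -> pd.DataFrame:
    """Fixed-width probability bins [0,0.1), ..., [0.9,1.0]; per bin the
    count, mean predicted probability and observed FR fraction.  Empty bins
    are reported with count 0."""
    p = np.asarray(probabilities, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    y = _binary(labels)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        rows.append({
            "bin_lo": edges[b], "bin_hi": edges[b + 1],
            "count": int(m.sum()),
            "mean_predicted": float(p[m].mean()) if m.any() else np.nan,
            "observed_fr_fraction": float(y[m].mean()) if m.any() else np.nan,
        })
    return pd.DataFrame(rows)


def aggregate_splits(reports: list) -> dict:
    """Cross-split summary: per metric mean and 95% CI half-width
    (1.96 * SD / sqrt(n)), computed over defined values only.

    Returns a dict with a ``metrics`` table (AUROC, AUPRC and the
    decision-threshold confusion metrics) and a ``threshold_sweep`` table
    averaged across splits.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to aggregate")

    def mci(values):
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            return np.nan, np.nan
        half = 1.96 * np.std(v, ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
        return float(v.mean()), float(half)

    metric_rows = []
    scalar = {"auroc": [r.auroc for r in reports],
              "auprc": [r.auprc for r in reports]}
    for key in ("accuracy", "precision", "recall", "specificity", "npv"):
        scalar[key] = [r.at_decision[key] for r in reports]
    for name, vals in scalar.items():
        mean, half = mci(vals)
        metric_rows.append({"metric": name, "mean": mean, "ci95_half_width": half})

    sweep = pd.concat([r.thresholds for r in reports])
    sweep = sweep.groupby("threshold", as_index=False).mean()
    return {"metrics": pd.DataFrame(metric_rows), "threshold_sweep": sweep,
            "n_splits": len(reports)}


def ks_shift_fraction(train_df: pd.DataFrame, test_df: pd.DataFrame,
                      alpha: float = 0.1) -> float:
    """Fraction of the 50 features whose train-vs-test distributions differ
    by a two-sample KS test at p < alpha (distribution-shift measure)."""
    n_shift = 0
    cols = [c for c in FEATURE_NAMES if c in train_df.columns]
    for c in cols:
        a = train_df[c].dropna().to_numpy()
        b = test_df[c].dropna().to_numpy()
        if a.size < 2 or b.size < 2 or (np.ptp(a) == 0 and np.ptp(b) == 0):
            continue
        if stats.ks_2samp(a, b).pvalue < alpha:
            n_shift += 1
    return n_shift / len(cols)


def error_analysis(split_summary: pd.DataFrame) -> pd.DataFrame:
    """Regress per-split AUROC on candidate error drivers.

    ``split_summary`` needs an ``auroc`` column plus one column per driver
    (e.g. grey-zone fraction, injury-model proportions, KS shift fraction).
    Returns slope, intercept and Pearson r per driver; a zero-variance driver
    yields NaN r, reported as such.
    """
    if len(split_summary) < 3:
        raise ValueError("need at least 3 splits for error analysis")
    y = split_summary["auroc"].to_numpy(dtype=float)
    rows = []
    for col in split_summary.columns:
        if col in ("auroc", "split_id"):
            continue
        x = split_summary[col].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"driver": col, "slope": np.nan, "intercept": np.nan,
                         "pearson_r": np.nan})
            continue
        res = stats.linregress(x, y)
        rows.append({"driver": col, "slope": float(res.slope),
                     "intercept": float(res.intercept),
                     "pearson_r": float(res.rvalue)})
    return pd.DataFrame(rows)
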