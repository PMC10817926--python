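"""Candidate classifiers (RF / LR / SVM / GBM), pig-level CV tuning, bundles.

:class:`FluidResponsivenessClassifier` is a scikit-learn-style estimator: grid
search maximises mean fold AUROC over caller-supplied (pig-level) folds, ties
going to the smallest-capacity configuration, and the winning configuration is
refitted on the full training split.  The random forest is the production
model; its predicted probability is the raw tree-vote fraction (no
recalibration), classified FR when >= the decision threshold (inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import default_grids

ALGORITHMS = ("RF", "LR", "SVM", "GBM")


def _build_estimator(algorithm: str, params: dict, random_state: int):
    if algorithm == "RF":
        return RandomForestClassifier(random_state=random_state, **params)
    if algorithm == "LR":
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=2000, **params))
    if algorithm == "SVM":
        return make_pipeline(StandardScaler(),
                             SVC(kernel="rbf", probability=True,
                                 random_state=random_state, **params))
    if algorithm == "GBM":
        return GradientBoostingClassifier(random_state=random_state, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def _encode_labels(y):
    y = np.asarray(y)
    if y.dtype.kind in "OUS":
        return (y == "FR").astype(int)
    return y.astype(int)


class SchemaError(ValueError):
    """Prediction-time feature columns do not match the fitted schema."""


class FluidResponsivenessClassifier(BaseEstimator, ClassifierMixin):
    """Binary FR/NR classifier with fold-based hyperparameter tuning.

    Parameters
    ----------
    algorithm : {"RF", "LR", "SVM", "GBM"}
    grid : list of dict, optional
        Hyperparameter configurations, ordered smallest capacity first (the
        tie-break keeps the first best).  Defaults to the built-in grid.
    decision_threshold : float
        FR is predicted when P(FR) >= threshold (boundary inclusive).
    random_state : int
    """

    def __init__(self, algorithm: str = "RF", grid: list | None = None,
                 decision_threshold: float = 0.5, random_state: int = 0):
        self.algorithm = algorithm
        self.grid = grid
        self.decision_threshold = decision_threshold
        self.random_state = random_state

    def fit(self, X, y, folds=None):
        """Tune on ``folds`` (list of (train_idx, val_idx) arrays, typically
        pig-level) and refit the best configuration on all rows."""
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = list(X.columns)
            mat = X.to_numpy(dtype=float)
        else:
            mat = np.asarray(X, dtype=float)
            self.feature_names_in_ = None
        yb = _encode_labels(y)
        if folds is None:
            cv = StratifiedKFold(5, shuffle=True, random_state=self.random_state)
            folds = list(cv.split(mat, yb))
        grid = self.grid if self.grid is not None else default_grids()[self.algorithm]

        best_score, best_params = -np.inf, None
        cv_scores = []
        for params in grid:
            fold_aucs = []
            for tr, va in folds:
                if len(np.unique(yb[tr])) < 2 or len(np.unique(yb[va])) < 2:
                    warnings.warn("single-class fold scored as 0.5")
                    fold_aucs.append(0.5)
                    continue
                est = _build_estimator(self.algorithm, params, self.random_state)
                est.fit(mat[tr], yb[tr])
                p = est.predict_proba(mat[va])[:, 1]
                fold_aucs.append(roc_auc_score(yb[va], p))
            score = float(np.mean(fold_aucs))
            cv_scores.append({"params": params, "mean_auroc": score,
                              "sd_auroc": float(np.std(fold_aucs, ddof=1))
                              if len(fold_aucs) > 1 else 0.0})
            if score > best_score + 1e-12:   # strict: ties keep smaller capacity
                best_score, best_params = score, params
        self.best_params_ = best_params
        self.cv_results_ = cv_scores
        self.cv_auroc_mean_ = best_score
        self.cv_auroc_sd_ = next(r["sd_auroc"] for r in cv_scores
                                 if r["params"] is best_params)
        self.estimator_ = _build_estimator(self.algorithm, best_params,
                                           self.random_state)
        self.estimator_.fit(mat, yb)
        self.classes_ = np.array([0, 1])
        return self

    def _check_schema(self, X):
        if isinstance(X, pd.DataFrame) and self.feature_names_in_ is not None:
            got, want = list(X.columns), self.feature_names_in_
            if got != want:
                missing = [c for c in want if c not in got]
                extra = [c for c in got if c not in want]
                if missing or extra:
                    raise SchemaError(
                        f"feature columns mismatch: missing={missing}, extra={extra}")
                X = X[want]
            return X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def predict_proba(self, X):
        mat = self._check_schema(X)
        return self.estimator_.predict_proba(mat)

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return (p >= self.decision_threshold).astype(int)


@dataclass
class ModelBundle:
    """A fitted model with full provenance for one train/test split."""

    split_id: int
    algorithm: str
    selected_features: list
    hyperparameters: dict
    model: FluidResponsivenessClassifier
    metadata: dict = field(default_factory=dict)


def folds_from_plan(fold_plan, df: pd.DataFrame) -> list:
    """(train_idx, val_idx) index pairs over ``df`` rows from a pig-level
    FoldPlan; every pig's boluses stay within one validation fold."""
    pig_fold = df["pig_id"].map(fold_plan.assignments)
    folds = []
    for f in range(1, fold_plan.k + 1):
        va = np.flatnonzero(pig_fold == f)
        tr = np.flatnonzero((pig_fold != f) & pig_fold.notna())
        if va.size and tr.size:
            folds.append((tr, va))
    return folds


def tune_and_fit(train_df: pd.DataFrame, y, fold_plan, selected_features: list,
                 algorithm: str = "RF", grid: list | None = None,
                 seed: int = 0, split_id: int = 0,
                 selection_method: str = "") -> ModelBundle:
    """Grid-tune and refit one model for a split; returns a provenance bundle."""
    folds = folds_from_plan(fold_plan, train_df)
    clf = FluidResponsivenessClassifier(algorithm=algorithm, grid=grid,
                                        random_state=seed)
    clf.fit(train_df[selected_features], y, folds=folds)
    return ModelBundle(
        split_id=split_id, algorithm=algorithm,
        selected_features=list(selected_features),
        hyperparameters=dict(clf.best_params_ or {}),
        model=clf,
        metadata={
            "seed": seed,
            "cv_auroc_mean": clf.cv_auroc_mean_,
            "cv_auroc_sd": clf.cv_auroc_sd_,
            "selection_method": selection_method,
            "n_train": len(train_df),
        },
    )


def predict_proba(bundle: ModelBundle, features: pd.DataFrame) -> np.ndarray:
    """P(FR) per bolus from a bundle; validates the feature schema."""
    if isinstance(features, pd.DataFrame):
        missing = [c for c in bundle.selected_features
                   if c not in features.columns]
        if missing:
            raise SchemaError(
                f"feature columns mismatch: missing={missing}, extra=[]")
        features = features[bundle.selected_features]
    return bundle.model.predict_proba(features)[:, 1]


def save_bundle(bundle: ModelBundle, path) -> Path:
    """Serialize a bundle (joblib) plus a plain-text provenance sidecar."""
    path = Path(path)
    joblib.dump(bundle, path)
    side = path.with_suffix(path.suffix + ".meta.txt")
    lines = [f"split_id: {bundle.split_id}",
             f"algorithm: {bundle.algorithm}",
             f"selected_features: {','.join(bundle.selected_features)}",
             f"hyperparameters: {bundle.hyperparameters}"]
    lines += [f"{k}: {v}" for k, v in bundle.metadata.items()]
    side.write_text("\n".join(lines) + "\n")
    return path


def load_bundle(path) -> ModelBundle:
    return joblib.load(path)
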