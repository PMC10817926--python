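"""Feature selection: KS screening, RFE, permutation importance, mutual
information, and the cross-trial consensus rule.

The four selectors are scikit-learn-style transformers (``fit`` /
``transform`` / ``get_support``) over the 50-column feature table.  The
statistical selector keeps features whose FR and NR distributions differ
(two-sample Kolmogorov-Smirnov p < alpha) and then prunes correlated pairs;
the three model-based selectors each retain exactly ``n_keep`` features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, mutual_info_classif
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold

from .features import FEATURE_NAMES


@dataclass
class SelectionResult:
    method: str                      # statistical | rfe | permutation | mutual_info
    split_id: int
    retained: list
    diagnostics: dict = field(default_factory=dict)  # feature -> score


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def _binary_labels(y):
    y = np.asarray(y)
    if y.dtype.kind in "OUS":
        y = (y == "FR").astype(int)
    else:
        y = y.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("selection requires both FR and NR examples")
    return y


class _SelectorBase(BaseEstimator):
    """Shared transform/support plumbing for the four selectors."""

    def get_support(self):
        return self.support_

    @property
    def retained_features_(self):
        return [n for n, keep in zip(self.feature_names_in_, self.support_) if keep]

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X[self.retained_features_]
        return np.asarray(X, dtype=float)[:, self.support_]

    def fit_transform(self, X, y=None, **kw):
        return self.fit(X, y, **kw).transform(X)

    def to_result(self, split_id: int = 0) -> SelectionResult:
        return SelectionResult(method=self.method, split_id=split_id,
                               retained=list(self.retained_features_),
                               diagnostics=dict(self.scores_))


class KSStatisticalSelector(_SelectorBase):
    """Two-sample KS screen followed by correlation pruning.

    Features are retained when the KS test between their FR and NR
    distributions gives p < ``alpha`` (set ``retain_if_discriminative=False``
    for the opposite, literal-threshold direction).  Among retained features,
    any pair with |Pearson r| >= ``corr_threshold`` loses its less
    discriminative member (larger KS p; ties drop the later registry entry)
    until no such pair remains.  If nothing passes the screen, the single
    most discriminative feature is kept so the result is never empty.
    """

    method = "statistical"

    def __init__(self, alpha: float = 0.1, corr_threshold: float = 0.9,
                 retain_if_discriminative: bool = True):
        self.alpha = alpha
        self.corr_threshold = corr_threshold
        self.retain_if_discriminative = retain_if_discriminative

    def fit(self, X, y, **kw):
        mat, names = _as_matrix(X)
        yb = _binary_labels(y)
        pvals = np.ones(mat.shape[1])
        for j in range(mat.shape[1]):
            a, b = mat[yb == 1, j], mat[yb == 0, j]
            if np.ptp(mat[:, j]) == 0:
                pvals[j] = 1.0
            else:
                pvals[j] = stats.ks_2samp(a, b).pvalue
        if self.retain_if_discriminative:
            keep = pvals < self.alpha
        else:
            keep = pvals > self.alpha
        if not keep.any():
            keep[np.argmin(pvals)] = True
        kept_idx = [j for j in range(mat.shape[1]) if keep[j]]
        kept_idx = self._prune_correlated(mat, pvals, kept_idx)
        self.feature_names_in_ = names
        self.pvalues_ = pvals
        self.scores_ = dict(zip(names, pvals))
        self.support_ = np.zeros(mat.shape[1], dtype=bool)
        self.support_[kept_idx] = True
        return self

    def _prune_correlated(self, mat, pvals, kept):
        kept = list(kept)
        while len(kept) > 1:
            sub = mat[:, kept]
            with np.errstate(invalid="ignore"):
                corr = np.abs(np.corrcoef(sub, rowvar=False))
            np.fill_diagonal(corr, 0.0)
            corr = np.nan_to_num(corr)
            i, j = np.unravel_index(np.argmax(corr), corr.shape)
            if corr[i, j] < self.corr_threshold:
                break
            a, b = kept[i], kept[j]
            # drop the member with larger KS p; tie -> later registry position
            victim = a if (pvals[a], a) >= (pvals[b], b) else b
            kept.remove(victim)
        return kept


class RFESelector(_SelectorBase):
    """Recursive feature elimination with a random-forest scorer, one feature
    eliminated per round, down to exactly ``n_keep``."""

    method = "rfe"

    def __init__(self, n_keep: int = 10, n_estimators: int = 50,
                 random_state: int = 0):
        self.n_keep = n_keep
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y, **kw):
        mat, names = _as_matrix(X)
        yb = _binary_labels(y)
        if self.n_keep > mat.shape[1]:
            raise ValueError(f"n_keep={self.n_keep} exceeds {mat.shape[1]} features")
        rf = RandomForestClassifier(n_estimators=self.n_estimators,
                                    random_state=self.random_state)
        rfe = RFE(rf, n_features_to_select=self.n_keep, step=1)
        rfe.fit(mat, yb)
        self.feature_names_in_ = names
        self.support_ = rfe.support_.copy()
        self.ranking_ = rfe.ranking_.copy()
        self.scores_ = dict(zip(names, (1.0 / rfe.ranking_).tolist()))
        return self


class PermutationImportanceSelector(_SelectorBase):
    """Permutation importance on held-out folds (not in-bag).

    A random forest is fitted on each training fold and the mean decrease in
    AUROC under feature permutation is measured on the corresponding held-out
    fold; importances are averaged across folds and the top ``n_keep``
    features are retained (ties resolve in registry order).
    """

    method = "permutation"

    def __init__(self, n_keep: int = 10, n_permutations: int = 10,
                 n_estimators: int = 50, random_state: int = 0):
        self.n_keep = n_keep
        self.n_permutations = n_permutations
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y, folds=None, **kw):
        mat, names = _as_matrix(X)
        yb = _binary_labels(y)
        if self.n_keep > mat.shape[1]:
            raise ValueError(f"n_keep={self.n_keep} exceeds {mat.shape[1]} features")
        if folds is None:
            cv = StratifiedKFold(5, shuffle=True, random_state=self.random_state)
            folds = list(cv.split(mat, yb))
        imps = []
        for f, (tr, te) in enumerate(folds):
            if len(np.unique(yb[te])) < 2 or len(np.unique(yb[tr])) < 2:
                continue
            rf = RandomForestClassifier(n_estimators=self.n_estimators,
                                        random_state=self.random_state)
            rf.fit(mat[tr], yb[tr])
            res = permutation_importance(
                rf, mat[te], yb[te], scoring="roc_auc",
                n_repeats=self.n_permutations,
                random_state=self.random_state + f)
            imps.append(res.importances_mean)
        imp = np.mean(imps, axis=0)
        order = np.argsort(-imp, kind="stable")     # ties -> registry order
        keep = np.zeros(mat.shape[1], dtype=bool)
        keep[order[:self.n_keep]] = True
        self.feature_names_in_ = names
        self.importances_ = imp
        self.scores_ = dict(zip(names, imp.tolist()))
        self.support_ = keep
        return self


class MutualInfoSelector(_SelectorBase):
    """Top ``n_keep`` features by nearest-neighbour mutual information with
    the binary label (ties resolve in registry order)."""

    method = "mutual_info"

    def __init__(self, n_keep: int = 10, random_state: int = 0):
        self.n_keep = n_keep
        self.random_state = random_state

    def fit(self, X, y, **kw):
        mat, names = _as_matrix(X)
        yb = _binary_labels(y)
        if self.n_keep > mat.shape[1]:
            raise ValueError(f"n_keep={self.n_keep} exceeds {mat.shape[1]} features")
        mi = mutual_info_classif(mat, yb, random_state=self.random_state)
        order = np.argsort(-mi, kind="stable")
        keep = np.zeros(mat.shape[1], dtype=bool)
        keep[order[:self.n_keep]] = True
        self.feature_names_in_ = names
        self.mi_ = mi
        self.scores_ = dict(zip(names, mi.tolist()))
        self.support_ = keep
        return self


SELECTORS = {
    "statistical": KSStatisticalSelector,
    "rfe": RFESelector,
    "permutation": PermutationImportanceSelector,
    "mutual_info": MutualInfoSelector,
}


def consensus_features(results: list, min_frequency: float = 0.5) -> list:
    """Features selected in at least ``min_frequency`` of all trials
    (boundary inclusive), ordered by descending frequency then registry order."""
    if not results:
        raise ValueError("need at least one selection result")
    counts = {}
    for r in results:
        for name in r.retained:
            counts[name] = counts.get(name, 0) + 1
    n = len(results)
    reg_pos = {name: i for i, name in enumerate(FEATURE_NAMES)}
    kept = [name for name, c in counts.items() if c / n >= min_frequency]
    kept.sort(key=lambda name: (-counts[name], reg_pos.get(name, len(reg_pos))))
    return kept


def results_to_frame(results: list) -> pd.DataFrame:
    """Serialize selection results (method, split_id, feature, score, retained)."""
    rows = []
    for r in results:
        retained = set(r.retained)
        for name, score in r.diagnostics.items():
            rows.append({"method": r.method, "split_id": r.split_id,
                         "feature": name, "score": score,
                         "retained": name in retained})
    return pd.DataFrame(rows)
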