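"""Leave-one-subject-out evaluation with in-fold feature selection.

The sweep engine trains, for every (modality, classifier, feature count k,
fold), on all subjects but one and tests on the held-out subject.  Within
each training fold features are z-scored (population SD; zero-SD features
mapped to 0), ranked once by mutual information with the class label
(k-NN estimator, 3 neighbours, seeded), and the top-k prefix is used for
every k in the grid — mathematically identical to per-k selection.
Classifiers (SVM, KNN, Random Forest, gradient-boosted trees) are called
with library defaults; only random seeds are pinned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin, mutual_info_classif
from sklearn.metrics import confusion_matrix
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .cohort import LABELS, ConfigError

__all__ = [
    "CLASSIFIERS",
    "FoldSpec",
    "SelectionResult",
    "FoldResult",
    "SweepResult",
    "loso_folds",
    "FoldStandardiser",
    "standardise_fold",
    "MutualInfoTopK",
    "mi_rank",
    "select_top_k",
    "make_classifier",
    "fit_predict",
    "run_sweep",
]

#: Valid classifier specs, in canonical (tie-breaking) order.
CLASSIFIERS = ("svm", "knn", "rf", "xgboost")

#: Ordinal class encoding (pain intensity order).
LABEL_TO_INT = {"NP": 0, "LP": 1, "HP": 2}
INT_TO_LABEL = {v: k for k, v in LABEL_TO_INT.items()}


@dataclass(frozen=True)
class FoldSpec:
    held_out: str
    training: tuple[str, ...]


@dataclass
class SelectionResult:
    """A full MI ranking (descending) for one training fold."""

    ranked_names: tuple[str, ...]
    ranked_idx: np.ndarray
    scores: np.ndarray            # aligned with the *original* feature order
    seed: int


@dataclass
class FoldResult:
    held_out: str
    modality: str
    classifier: str
    k: int
    y_true: tuple[str, ...]
    y_pred: tuple[str, ...]
    confusion: np.ndarray         # 3x3, rows = true NP/LP/HP
    selected_features: tuple[str, ...]


@dataclass
class SweepResult:
    grid: tuple[int, ...]
    classifiers: tuple[str, ...]
    modalities: tuple[str, ...]
    results: Mapping[tuple[str, str, int], list[FoldResult]]
    rankings: Mapping[tuple[str, str], tuple[str, ...]]  # (modality, fold) -> ranking
    seed: int

    def cell(self, modality: str, classifier: str, k: int) -> list[FoldResult]:
        try:
            return self.results[(modality, classifier, k)]
        except KeyError:
            raise KeyError(f"no sweep cell ({modality}, {classifier}, {k})")


def loso_folds(subject_ids: Sequence[str]) -> list[FoldSpec]:
    """One fold per subject, sorted by subject id; duplicates are an error."""
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ConfigError(f"duplicate subject ids: {dupes}")
    if len(ids) < 2:
        raise ConfigError("LOSO needs at least 2 subjects")
    ids = sorted(ids)
    return [FoldSpec(held_out=s, training=tuple(t for t in ids if t != s))
            for s in ids]


class FoldStandardiser(BaseEstimator, TransformerMixin):
    """Feature z-scoring by training-fold mean and population SD.

    Zero-SD (constant) training features are mapped to exactly 0 in both
    training and test data, so no degenerate feature can leak information.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)        # population SD (divisor n)
        self.zero_mask_ = self.scale_ == 0
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        scale = np.where(self.zero_mask_, 1.0, self.scale_)
        Z = (X - self.mean_) / scale
        Z[:, self.zero_mask_] = 0.0
        return Z


def standardise_fold(train: np.ndarray,
                     test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = FoldStandardiser().fit(train)
    return s.transform(train), s.transform(test)


def mi_rank(X: np.ndarray, y: Sequence[str], seed: int,
            feature_names: Sequence[str],
            n_neighbors: int = 3) -> SelectionResult:
    """Rank features by estimated mutual information with the class label.

    Uses the k-nearest-neighbour MI estimator for continuous features vs a
    discrete target.  Ties are broken by canonical feature order (stable
    sort), and the ranking is deterministic given the seed.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ConfigError("mutual information needs at least 2 classes")
    scores = mutual_info_classif(np.asarray(X, dtype=float), y,
                                 n_neighbors=n_neighbors, random_state=seed)
    order = np.argsort(-scores, kind="stable")
    names = tuple(feature_names[i] for i in order)
    return SelectionResult(ranked_names=names, ranked_idx=order,
                           scores=scores, seed=seed)


def select_top_k(selection: SelectionResult, k: int) -> tuple[str, ...]:
    n = len(selection.ranked_names)
    if not (1 <= k <= n):
        raise ConfigError(f"k must be in [1, {n}], got {k}")
    return selection.ranked_names[:k]


class MutualInfoTopK(BaseEstimator, SelectorMixin):
    """sklearn selector retaining the top-k MI-ranked features."""

    def __init__(self, k: int = 10, n_neighbors: int = 3,
                 random_state: int = 0):
        self.k = k
        self.n_neighbors = n_neighbors
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.scores_ = mutual_info_classif(X, y, n_neighbors=self.n_neighbors,
                                           random_state=self.random_state)
        self.ranking_ = np.argsort(-self.scores_, kind="stable")
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_[:self.k]] = True
        return mask


def make_classifier(spec: str, seed: int):
    """Library classifiers with default hyperparameters, seed pinned."""
    if spec == "svm":
        return SVC(random_state=seed)
    if spec == "knn":
        return KNeighborsClassifier()
    if spec == "rf":
        return RandomForestClassifier(random_state=seed)
    if spec == "xgboost":
        return XGBClassifier(random_state=seed)
    raise ConfigError(f"unknown classifier {spec!r}; valid: {list(CLASSIFIERS)}")


def fit_predict(spec: str, X_train: np.ndarray, y_train: Sequence[str],
                X_test: np.ndarray, seed: int = 0) -> np.ndarray:
    """Train on the fold and predict string labels for the held-out rows."""
    y_enc = np.asarray([LABEL_TO_INT[l] for l in y_train])
    if np.unique(y_enc).size == 1:
        return np.full(np.asarray(X_test).shape[0],
                       INT_TO_LABEL[int(y_enc[0])], dtype=object)
    clf = make_classifier(spec, seed)
    clf.fit(np.asarray(X_train, dtype=float), y_enc)
    pred = clf.predict(np.asarray(X_test, dtype=float))
    return np.asarray([INT_TO_LABEL[int(p)] for p in pred], dtype=object)


def _sub_seed(master: int, *path: int) -> int:
    """Deterministic substream seed below 2**31."""
    ss = np.random.SeedSequence([int(master), *map(int, path)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _split_table(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    feats = [c for c in df.columns if c not in ("subject", "label")]
    return df[feats].to_numpy(dtype=float), df["label"].to_numpy(), feats


def run_sweep(tables: Mapping[str, pd.DataFrame],
              grid: Sequence[int],
              classifiers: Sequence[str] = CLASSIFIERS,
              seed: int = 0,
              mi_neighbors: int = 3) -> SweepResult:
    """Full factorial LOSO sweep over (modality, classifier, k, fold).

    ``tables``: per-modality feature tables with columns ``subject``,
    ``label`` and the named features.  Standardisation and MI ranking use
    training rows only; the MI ranking is computed once per (modality,
    fold) and prefixed for every k in the grid.
    """
    grid = tuple(sorted(int(k) for k in grid))
    classifiers = tuple(classifiers)
    for c in classifiers:
        if c not in CLASSIFIERS:
            raise ConfigError(f"unknown classifier {c!r}; valid: {list(CLASSIFIERS)}")
    modalities = tuple(sorted(tables))
    if not modalities:
        raise ConfigError("no modality feature tables given")

    results: dict[tuple[str, str, int], list[FoldResult]] = {
        (m, c, k): [] for m in modalities for c in classifiers for k in grid}
    rankings: dict[tuple[str, str], tuple[str, ...]] = {}

    for mi_idx, modality in enumerate(modalities):
        df = tables[modality]
        X_all, y_all, feats = _split_table(df)
        if grid[-1] > len(feats):
            raise ConfigError(f"grid value {grid[-1]} exceeds feature count "
                              f"{len(feats)} for modality {modality}")
        subjects = df["subject"].to_numpy()
        folds = loso_folds(sorted(set(subjects)))
        for f_idx, fold in enumerate(folds):
            te_mask = subjects == fold.held_out
            X_tr, X_te = standardise_fold(X_all[~te_mask], X_all[te_mask])
            y_tr, y_te = y_all[~te_mask], y_all[te_mask]
            sel = mi_rank(X_tr, y_tr, seed=_sub_seed(seed, mi_idx, f_idx),
                          feature_names=feats, n_neighbors=mi_neighbors)
            rankings[(modality, fold.held_out)] = sel.ranked_names
            for k in grid:
                idx = sel.ranked_idx[:k]
                chosen = sel.ranked_names[:k]
                for c_idx, clf in enumerate(classifiers):
                    y_pred = fit_predict(
                        clf, X_tr[:, idx], y_tr, X_te[:, idx],
                        seed=_sub_seed(seed, mi_idx, f_idx, 1 + c_idx))
                    cm = confusion_matrix(y_te, y_pred, labels=list(LABELS))
                    results[(modality, clf, k)].append(FoldResult(
                        held_out=fold.held_out, modality=modality,
                        classifier=clf, k=k,
                        y_true=tuple(y_te), y_pred=tuple(y_pred),
                        confusion=cm, selected_features=chosen))
    return SweepResult(grid=grid, classifiers=classifiers,
                       modalities=modalities, results=results,
                       rankings=rankings, seed=seed)
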