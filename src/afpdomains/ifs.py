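"""Incremental feature selection with a random-forest classifier.

Given an mRMR feature list F = [f1, f2, ...], nested subsets
F1 = {f1}, F2 = {f1, f2}, ... are each evaluated by k-fold
cross-validation of a random forest trained on the subset's columns;
confusion counts are pooled over folds and summarised as SN/SP/ACC/MCC.
The subset size with the highest MCC (smallest size on ties) defines
the optimum features and the optimum classifier.

The forest mirrors the common default configuration: B = 100 trees,
bootstrap samples of size n drawn with replacement, and
floor(log2(m)) + 1 candidate features per split for m features.

Determinism: fold assignment and per-fold training order are
canonicalised on (label, row_id), and every random-forest seed is
derived from the user seeds and the (subset size, fold) pair alone, so
the IFS curve does not depend on the row order of the input matrix.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .domain_encoding import NEGATIVE, POSITIVE, DomainMatrix
from .metrics import ConfusionCounts, MetricSet, compute_metrics, confusion_counts
from .mrmr import FeatureRanking, MRMRRanker

MODEL_FORMAT_VERSION = 1


@dataclasses.dataclass
class ClassifierSpec:
    """Random-forest configuration (all fields overridable)."""

    algorithm: str = "random_forest"
    n_trees: int = 100
    max_features: int | None = None  # None -> floor(log2 m) + 1
    seed: int = 0
    class_weight: str | None = None  # optional "balanced"; off by default

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def resolve_max_features(self, m: int) -> int:
        if self.max_features is not None:
            if not 1 <= self.max_features <= m:
                raise ValueError(f"max_features must be in [1, {m}]")
            return self.max_features
        return min(m, int(math.floor(math.log2(m))) + 1)


@dataclasses.dataclass
class CVSpec:
    """Cross-validation configuration."""

    k: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("number of folds must be >= 2")


@dataclasses.dataclass
class IFSResult:
    """Per-subset-size metric curve and the MCC-optimal prefix."""

    records: pd.DataFrame  # columns: k, SN, SP, ACC, MCC
    optimum_k: int
    optimum_features: list[str]
    optimum_metrics: MetricSet

    def write_curve_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def write_optimum_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tdomain_id\n")
            for r, acc in enumerate(self.optimum_features, start=1):
                fh.write(f"{r}\t{acc}\n")


def make_folds(
    labels: Sequence[int] | np.ndarray,
    spec: CVSpec,
    row_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Assign each sample to one of k folds, stratified by class.

    Works for any class count below the fold count (a class with c < k
    members simply occupies c distinct folds).  Fold sizes are balanced
    within one sample overall and per class.  Assignment is a function
    of (row_id, label, seed) only: permuting the rows permutes the
    returned vector identically.
    """
    y = np.asarray(labels)
    n = y.shape[0]
    if n < spec.k:
        raise ValueError(f"need at least k={spec.k} samples, got {n}")
    if row_ids is None:
        keys = [str(i) for i in range(n)]
    else:
        if len(row_ids) != n:
            raise ValueError("row_ids length must match labels")
        keys = [str(r) for r in row_ids]

    classes = np.unique(y)
    if spec.stratified:
        if classes.size < 2:
            raise ValueError("stratification requires both classes present")
        groups = [np.flatnonzero(y == c) for c in classes]
    else:
        groups = [np.arange(n)]

    rng = np.random.default_rng(spec.seed)
    folds = np.empty(n, dtype=np.int64)
    total_load = np.zeros(spec.k, dtype=np.int64)
    for members in groups:
        # canonical order by row_id, then a seeded shuffle
        members = members[np.argsort([keys[i] for i in members], kind="stable")]
        members = rng.permutation(members)
        pref = rng.permutation(spec.k)  # tie-break order among equal loads
        class_load = np.zeros(spec.k, dtype=np.int64)
        pref_rank = np.empty(spec.k, dtype=np.int64)
        pref_rank[pref] = np.arange(spec.k)
        for idx in members:
            # lexicographic (class_load, total_load, pref_rank)
            key = (class_load * (n + 1) + total_load) * (spec.k + 1) + pref_rank
            f = int(np.argmin(key))
            folds[idx] = f
            class_load[f] += 1
            total_load[f] += 1
    return folds


def _rf_seed(cspec_seed: int, subset_size: int, fold: int) -> int:
    # fold -1 (the final full-data fit) maps to stream 0; CV folds to 1..k
    ss = np.random.SeedSequence([int(cspec_seed), int(subset_size), int(fold) + 1])
    return int(ss.generate_state(1)[0] % (2**31))


def _fit_rf(Xtr, ytr, m: int, cspec: ClassifierSpec, seed: int) -> RandomForestClassifier:
    rf = RandomForestClassifier(
        n_estimators=cspec.n_trees,
        max_features=cspec.resolve_max_features(m),
        bootstrap=True,
        class_weight=cspec.class_weight,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(Xtr, ytr)
    return rf


def _predict_negative_ties(rf: RandomForestClassifier, X) -> np.ndarray:
    """Majority vote with 50/50 ties broken toward the negative class."""
    classes = list(rf.classes_)
    proba = rf.predict_proba(X)
    if POSITIVE in classes:
        p_pos = proba[:, classes.index(POSITIVE)]
    else:  # degenerate single-class training fold
        return np.full(X.shape[0], classes[0])
    return np.where(p_pos > 0.5, POSITIVE, NEGATIVE)


def _cv_counts(
    Xd: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    order_keys: np.ndarray,
    k_cols: int,
    cspec: ClassifierSpec,
) -> list[ConfusionCounts]:
    """Per-fold confusion counts for the first k_cols columns of Xd."""
    out = []
    for f in range(folds.max() + 1):
        train = np.flatnonzero(folds != f)
        test = np.flatnonzero(folds == f)
        train = train[np.argsort(order_keys[train], kind="stable")]
        rf = _fit_rf(
            Xd[np.ix_(train, np.arange(k_cols))],
            y[train],
            k_cols,
            cspec,
            _rf_seed(cspec.seed, k_cols, f),
        )
        pred = _predict_negative_ties(rf, Xd[np.ix_(test, np.arange(k_cols))])
        out.append(confusion_counts(y[test], pred))
    return out


def _summarise(per_fold: list[ConfusionCounts], pooling: str) -> MetricSet:
    if pooling == "pooled":
        total = per_fold[0]
        for c in per_fold[1:]:
            total = total + c
        return compute_metrics(total)
    if pooling == "per_fold":
        sets = [compute_metrics(c) for c in per_fold]
        return MetricSet(
            SN=float(np.mean([s.SN for s in sets])),
            SP=float(np.mean([s.SP for s in sets])),
            ACC=float(np.mean([s.ACC for s in sets])),
            MCC=float(np.mean([s.MCC for s in sets])),
            degenerate=any(s.degenerate for s in sets),
        )
    raise ValueError(f"unknown pooling mode {pooling!r}")


def _prepare(matrix: DomainMatrix, ranking: FeatureRanking, k_max: int, vspec: CVSpec):
    cols = ranking.top(k_max)
    Xd = np.asarray(matrix.X[:, cols].todense(), dtype=np.int8)
    y = matrix.labels
    folds = make_folds(y, vspec, matrix.row_ids)
    order_keys = np.array([str(r) for r in matrix.row_ids])
    return Xd, y, folds, order_keys


def evaluate_subset(
    matrix: DomainMatrix,
    ranking: FeatureRanking,
    k: int,
    cspec: ClassifierSpec | None = None,
    vspec: CVSpec | None = None,
    pooling: str = "pooled",
) -> MetricSet:
    """Cross-validated metrics for the top-k ranked feature subset."""
    if k < 1:
        raise ValueError("subset size k must be >= 1")
    cspec = cspec or ClassifierSpec()
    vspec = vspec or CVSpec()
    Xd, y, folds, order_keys = _prepare(matrix, ranking, k, vspec)
    return _summarise(_cv_counts(Xd, y, folds, order_keys, k, cspec), pooling)


def ifs_search(
    matrix: DomainMatrix,
    ranking: FeatureRanking,
    k_max: int = 500,
    cspec: ClassifierSpec | None = None,
    vspec: CVSpec | None = None,
    pooling: str = "pooled",
    progress: bool = False,
) -> IFSResult:
    """Evaluate nested subsets of sizes 1..k_max and locate the MCC peak."""
    cspec = cspec or ClassifierSpec()
    vspec = vspec or CVSpec()
    k_max = int(k_max)
    if not 1 <= k_max <= len(ranking):
        raise ValueError(f"k_max must be in [1, {len(ranking)}]")
    Xd, y, folds, order_keys = _prepare(matrix, ranking, k_max, vspec)
    rows = []
    for k in range(1, k_max + 1):
        ms = _summarise(_cv_counts(Xd, y, folds, order_keys, k, cspec), pooling)
        rows.append((k, ms.SN, ms.SP, ms.ACC, ms.MCC))
        if progress and (k % 10 == 0 or k == k_max):
            print(f"[ifs] k={k}/{k_max} MCC={ms.MCC:.4f}", flush=True)
    records = pd.DataFrame(rows, columns=["k", "SN", "SP", "ACC", "MCC"])
    best = int(records["k"][records["MCC"].idxmax()])  # idxmax -> smallest k on ties
    opt_row = records.loc[records["k"] == best].iloc[0]
    optimum = MetricSet(
        SN=float(opt_row.SN), SP=float(opt_row.SP), ACC=float(opt_row.ACC), MCC=float(opt_row.MCC)
    )
    features = [ranking.accessions[i] for i in range(best)]
    return IFSResult(records, best, features, optimum)


# ---------------------------------------------------------------------------
# Final model: train on all rows with the optimum features, persist, predict.

@dataclasses.dataclass
class FittedModel:
    """A trained forest plus the domain accessions it expects, in order."""

    forest: RandomForestClassifier
    features: list[str]
    format_version: int = MODEL_FORMAT_VERSION


def train_final(
    matrix: DomainMatrix,
    features: Sequence[str],
    cspec: ClassifierSpec | None = None,
) -> FittedModel:
    """Fit the forest on the full matrix restricted to the given domains."""
    cspec = cspec or ClassifierSpec()
    Xd = _align_columns(matrix, features, allow_missing=False)
    rf = _fit_rf(Xd, matrix.labels, len(features), cspec, _rf_seed(cspec.seed, len(features), -1))
    return FittedModel(rf, list(features))


def predict(model: FittedModel, matrix: DomainMatrix, allow_missing: bool = False) -> np.ndarray:
    """Predict class codes (1/2) for each row of a new domain matrix.

    Columns are aligned by domain accession.  Accessions absent from the
    matrix raise an error listing them unless ``allow_missing`` is set,
    in which case they are treated as absent from every protein (0).
    """
    Xd = _align_columns(matrix, model.features, allow_missing=allow_missing)
    return _predict_negative_ties(model.forest, Xd)


def save_model(model: FittedModel, path: str | Path) -> None:
    joblib.dump(
        {"format_version": model.format_version, "features": model.features, "forest": model.forest},
        path,
    )


def load_model(path: str | Path) -> FittedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format {payload.get('format_version')!r}")
    return FittedModel(payload["forest"], payload["features"], payload["format_version"])


def _align_columns(
    matrix: DomainMatrix, features: Sequence[str], allow_missing: bool
) -> np.ndarray:
    col_index = {c: j for j, c in enumerate(matrix.col_ids)}
    missing = [f for f in features if f not in col_index]
    if missing and not allow_missing:
        raise ValueError(f"matrix lacks columns for domains: {', '.join(missing)}")
    n = matrix.n_proteins
    Xd = np.zeros((n, len(features)), dtype=np.int8)
    for j, f in enumerate(features):
        if f in col_index:
            Xd[:, j] = np.asarray(matrix.X[:, col_index[f]].todense()).ravel()
    return Xd


# ---------------------------------------------------------------------------
# scikit-learn estimator facade.

class IFSRandomForest(BaseEstimator, ClassifierMixin):
    """mRMR ranking + incremental feature selection + random forest.

    ``fit(X, y)`` ranks the binary columns of X by mRMR, sweeps nested
    top-k subsets with cross-validated forests, picks the subset size
    with peak Matthews correlation, and refits a final forest on the
    optimum subset.  ``predict(X)`` applies that forest.

    Parameters
    ----------
    top_n : int, default 500
        Ranking depth (upper bound for the subset sweep).
    k_max : int or None, default None
        Largest subset size to evaluate; None means ``top_n``.
    n_estimators : int, default 100
        Trees per forest.
    cv : int, default 10
        Cross-validation folds, stratified.
    pooling : {"pooled", "per_fold"}, default "pooled"
        Whether fold confusion counts are pooled before computing the
        metrics or metrics are averaged across folds.
    positive_label : default 1
        The label code treated as the positive class.
    random_state : int, default 0
        Master seed; fold assignment and every forest derive from it.
    class_weight : None or "balanced", default None

    Attributes
    ----------
    ranking_ : ndarray — column indices in mRMR order.
    ifs_curve_ : DataFrame with columns k, SN, SP, ACC, MCC.
    optimum_k_ : int — subset size at the MCC peak (smallest on ties).
    optimum_indices_ : ndarray — the optimum columns, in rank order.
    best_metrics_ : MetricSet at the peak.
    estimator_ : the final fitted RandomForestClassifier.
    classes_ : ndarray of the two class codes.
    """

    def __init__(
        self,
        top_n: int = 500,
        k_max: int | None = None,
        n_estimators: int = 100,
        cv: int = 10,
        pooling: str = "pooled",
        positive_label=POSITIVE,
        random_state: int = 0,
        class_weight: str | None = None,
    ):
        self.top_n = top_n
        self.k_max = k_max
        self.n_estimators = n_estimators
        self.cv = cv
        self.pooling = pooling
        self.positive_label = positive_label
        self.random_state = random_state
        self.class_weight = class_weight

    def fit(self, X, y):
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("binary classification only (got %d classes)" % classes.size)
        if self.positive_label not in classes:
            raise ValueError(f"positive_label {self.positive_label!r} not present in y")
        negative = classes[classes != self.positive_label][0]
        # internal convention: 1 = positive, 2 = negative
        y12 = np.where(y == self.positive_label, POSITIVE, NEGATIVE)

        matrix = DomainMatrix(
            X,
            row_ids=[f"s{i}" for i in range(np.shape(X)[0])],
            col_ids=[f"c{j}" for j in range(np.shape(X)[1])],
            labels=y12,
        )
        top_n = min(self.top_n, matrix.n_domains)
        r = MRMRRanker(top_n=top_n).fit(matrix.X, y12)
        ranking = FeatureRanking(
            indices=r.ranking_,
            accessions=[matrix.col_ids[i] for i in r.ranking_],
            scores=r.scores_,
            relevance=r.relevance_,
            redundancy=r.redundancy_,
        )
        cspec = ClassifierSpec(
            n_trees=self.n_estimators,
            seed=int(self.random_state),
            class_weight=self.class_weight,
        )
        vspec = CVSpec(k=self.cv, stratified=True, seed=int(self.random_state))
        k_max = min(self.k_max or top_n, top_n)
        result = ifs_search(matrix, ranking, k_max, cspec, vspec, pooling=self.pooling)

        self.n_features_in_ = matrix.n_domains
        self.ranking_ = ranking.indices
        self.ifs_curve_ = result.records
        self.optimum_k_ = result.optimum_k
        self.optimum_indices_ = ranking.indices[: result.optimum_k]
        self.best_metrics_ = result.optimum_metrics
        self.classes_ = np.array([self.positive_label, negative])
        self._negative_label = negative
        self.estimator_ = _fit_rf(
            np.asarray(matrix.X[:, self.optimum_indices_].todense()),
            y12,
            result.optimum_k,
            cspec,
            _rf_seed(cspec.seed, result.optimum_k, -1),
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        Xs = np.asarray(X.todense() if hasattr(X, "todense") else X)
        pred12 = _predict_negative_ties(self.estimator_, Xs[:, self.optimum_indices_])
        return np.where(pred12 == POSITIVE, self.positive_label, self._negative_label)

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        Xs = np.asarray(X.todense() if hasattr(X, "todense") else X)
        proba = self.estimator_.predict_proba(Xs[:, self.optimum_indices_])
        # reorder to self.classes_ (positive first)
        order = [list(self.estimator_.classes_).index(c) for c in (POSITIVE, NEGATIVE)]
        return proba[:, order]
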