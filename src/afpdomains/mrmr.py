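"""Minimum-redundancy-maximum-relevance feature ranking.

Features (binary domain indicators) are ranked greedily.  At each step
the non-selected feature maximising

    score(f) = I(f, labels) - (1/|S|) * sum_{s in S} I(f, s)

is appended, where ``S`` is the already-selected set, the redundancy
term is 0 while ``S`` is empty (so step 1 picks the most label-relevant
feature), and ``I`` is the plug-in discrete mutual information in bits:

    I(x, y) = sum_{a,b} p(a,b) * log2( p(a,b) / (p(a) p(b)) )

with empirical probabilities count/n and the convention 0*log(.) = 0.
This is the MID (difference) variant with arithmetic-mean redundancy.

Ties are broken toward the lowest original column index; scores within
``TIE_TOL`` of the step maximum count as tied, so the ranking does not
depend on floating-point summation order.

For binary columns the pairwise MI values needed for redundancy are
computed lazily from sparse column co-occurrence counts (one sparse
mat-vec per selected feature), so ranking ``top_n`` of ``N`` features
costs O(N * top_n) MI evaluations rather than O(N^2).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .domain_encoding import DomainMatrix

#: Scores closer than this are treated as exactly tied (broken by index).
TIE_TOL = 1e-9


def mutual_information(x, y) -> float:
    """Plug-in mutual information between two discrete vectors, in bits.

    Values are treated as categorical levels.  Symmetric, nonnegative
    (up to rounding), and bounded by min(H(x), H(y)).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("inputs must be 1-D vectors")
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] == 0:
        raise ValueError("inputs must be nonempty")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    counts = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(counts, (xi, yi), 1.0)
    return mi_from_counts(counts)


def mi_from_counts(counts: np.ndarray) -> float:
    """MI in bits from a joint contingency table of counts."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty contingency table")
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    terms = np.zeros_like(p)
    terms[mask] = p[mask] * np.log2(p[mask] / (px @ py)[mask])
    return float(terms.sum())


def _binary_mi(n11: np.ndarray, nx: np.ndarray, ny: float | np.ndarray, n: int) -> np.ndarray:
    """Vectorised MI in bits for pairs of binary vectors given counts.

    Parameters are the co-occurrence count ``n11 = sum(x*y)``, the
    one-counts ``nx = sum(x)`` and ``ny = sum(y)``, and the length ``n``.
    Broadcasts over arrays of pairs.
    """
    n11 = np.asarray(n11, dtype=float)
    nx = np.asarray(nx, dtype=float)
    ny = np.asarray(ny, dtype=float)
    n10 = nx - n11
    n01 = ny - n11
    n00 = n - nx - ny + n11

    def term(nab, na, nb):
        out = np.zeros(np.broadcast_shapes(np.shape(nab), np.shape(na), np.shape(nb)))
        nab, na, nb = np.broadcast_arrays(nab, na, nb)
        pos = nab > 0
        out[pos] = (nab[pos] / n) * np.log2(n * nab[pos] / (na[pos] * nb[pos]))
        return out

    return (
        term(n11, nx, ny)
        + term(n10, nx, n - ny)
        + term(n01, n - nx, ny)
        + term(n00, n - nx, n - ny)
    )


@dataclasses.dataclass
class FeatureRanking:
    """Ordered mRMR feature list F = [f1, f2, ..., fN].

    Per selected feature: original column index, domain accession, the
    greedy selection score, its relevance I(f, labels) and its mean
    redundancy to the features selected before it (0 for f1), in bits.
    """

    indices: np.ndarray
    accessions: list[str]
    scores: np.ndarray
    relevance: np.ndarray
    redundancy: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)

    def top(self, k: int) -> np.ndarray:
        if not 1 <= k <= len(self):
            raise ValueError(f"k must be in [1, {len(self)}], got {k}")
        return self.indices[:k]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tcolumn_index\tdomain_id\tscore\trelevance\tredundancy\n")
            for r in range(len(self)):
                fh.write(
                    f"{r + 1}\t{self.indices[r]}\t{self.accessions[r]}\t"
                    f"{self.scores[r]:.10g}\t{self.relevance[r]:.10g}\t"
                    f"{self.redundancy[r]:.10g}\n"
                )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureRanking":
        idx, acc, sco, rel, red = [], [], [], [], []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("rank\t"):
                raise ValueError("not a ranking TSV (missing header)")
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                idx.append(int(fields[1]))
                acc.append(fields[2])
                sco.append(float(fields[3]))
                rel.append(float(fields[4]))
                red.append(float(fields[5]))
        return cls(
            np.array(idx, dtype=np.int64), acc, np.array(sco), np.array(rel), np.array(red)
        )


class MRMRRanker(BaseEstimator, TransformerMixin):
    """Greedy mRMR (MID variant) feature ranker / selector.

    scikit-learn transformer: ``fit(X, y)`` ranks the columns of a
    binary matrix against a binary label vector; ``transform(X)``
    keeps the ``top_n`` ranked columns in rank order.

    Parameters
    ----------
    top_n : int or None, default 500
        Number of features to rank (the greedy list is cut here, which
        bounds the incremental-selection search depth downstream).
        None ranks every column.

    Attributes
    ----------
    ranking_ : ndarray of int
        Column indices in mRMR order.
    scores_, relevance_, redundancy_ : ndarray of float
        Per-rank selection score, relevance and mean redundancy (bits).
    n_features_in_ : int
    """

    def __init__(self, top_n: int | None = 500):
        self.top_n = top_n

    def fit(self, X, y):
        X = _as_binary_csc(X)
        y = np.asarray(y)
        n, m = X.shape
        if n < 1 or m < 1:
            raise ValueError("matrix must have at least one row and one column")
        if y.shape != (n,):
            raise ValueError("y length must equal the number of rows")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError(
                "labels contain a single class; relevance to the label is "
                "identically 0 and an mRMR order would be arbitrary"
            )
        top_n = m if self.top_n is None else int(self.top_n)
        if not 1 <= top_n <= m:
            raise ValueError(f"top_n must be in [1, {m}], got {top_n}")

        ypos = (y == classes[0]).astype(np.int8)  # which class is "1" is immaterial
        col_ones = np.asarray(X.sum(axis=0)).ravel().astype(float)
        n11 = np.asarray(X.T @ ypos, dtype=float).ravel()
        relevance = _binary_mi(n11, col_ones, float(ypos.sum()), n)

        selected = np.empty(top_n, dtype=np.int64)
        sel_score = np.empty(top_n)
        sel_rel = np.empty(top_n)
        sel_red = np.empty(top_n)
        redundancy_sum = np.zeros(m)
        available = np.ones(m, dtype=bool)
        for t in range(top_n):
            mean_red = redundancy_sum / t if t else redundancy_sum
            score = relevance - mean_red
            score[~available] = -np.inf
            best = score.max()
            # lowest index among scores within TIE_TOL of the maximum
            pick = int(np.flatnonzero(score >= best - TIE_TOL)[0])
            selected[t] = pick
            sel_score[t] = score[pick]
            sel_rel[t] = relevance[pick]
            sel_red[t] = mean_red[pick] if t else 0.0
            available[pick] = False
            if t + 1 < top_n:
                co = np.asarray((X.T @ X[:, [pick]]).todense(), dtype=float).ravel()
                redundancy_sum += _binary_mi(co, col_ones, col_ones[pick], n)

        self.n_features_in_ = m
        self.ranking_ = selected
        self.scores_ = sel_score
        self.relevance_ = sel_rel
        self.redundancy_ = sel_red
        return self

    def transform(self, X):
        check_is_fitted(self, "ranking_")
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, expected {self.n_features_in_}"
            )
        return X[:, self.ranking_]

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "ranking_")
        if indices:
            return self.ranking_.copy()
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_] = True
        return mask


def mrmr_rank(matrix: DomainMatrix, top_n: int | None = 500) -> FeatureRanking:
    """Rank a domain matrix's columns by mRMR against its class labels."""
    if matrix.is_empty:
        raise ValueError("cannot rank an empty (0-row) matrix")
    ranker = MRMRRanker(top_n=top_n).fit(matrix.X, matrix.labels)
    return FeatureRanking(
        indices=ranker.ranking_,
        accessions=[matrix.col_ids[i] for i in ranker.ranking_],
        scores=ranker.scores_,
        relevance=ranker.relevance_,
        redundancy=ranker.redundancy_,
    )


def _as_binary_csc(X) -> sp.csc_matrix:
    X = sp.csc_matrix(X)
    if X.nnz and not np.isin(X.data, [0, 1]).all():
        raise ValueError("feature matrix must be binary")
    return X
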