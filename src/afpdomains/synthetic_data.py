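"""Synthetic domain matrices with planted ground truth.

Emulates the shape of a real protein x InterPro incidence matrix —
large, very sparse, heavily imbalanced toward the negative class —
with three kinds of columns:

* informative: present with probability ``p_pos`` in positives and
  ``p_neg`` in negatives (class-conditional independent Bernoulli);
* redundant: a noisy copy of a designated informative column, each
  entry flipped with probability ``flip_prob``;
* noise: Bernoulli(q) regardless of class.

The defaults (200 positives vs 4000 negatives, 10 informative + 20
redundant + 1000 noise columns) mirror the sparsity and ~4.5%% positive
fraction of real domain-annotation data at about half scale.  Rows that
come out all-zero are resampled, not dropped, so the requested class
counts are exact and the no-all-zero-row matrix invariant holds.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp

from .domain_encoding import NEGATIVE, POSITIVE, DomainMatrix

_MAX_RESAMPLE = 50


@dataclasses.dataclass
class SyntheticSpec:
    n_pos: int = 200
    n_neg: int = 4000
    d_inf: int = 10
    p_pos: float = 0.6
    p_neg: float = 0.02
    d_red: int = 20
    flip_prob: float = 0.05
    d_noise: int = 1000
    q: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_pos", "p_neg", "flip_prob", "q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.d_inf and self.p_pos == self.p_neg:
            raise ValueError("informative domains need p_pos != p_neg")
        if min(self.n_pos, self.n_neg) < 1 or min(self.d_inf, self.d_red, self.d_noise) < 0:
            raise ValueError("counts must be positive (classes) / nonnegative (columns)")

    @property
    def n_cols(self) -> int:
        return self.d_inf + self.d_red + self.d_noise


@dataclasses.dataclass
class SyntheticTruth:
    """Which columns are informative, redundant (with source), or noise."""

    informative: list[int]
    redundant: dict[int, int]  # redundant column -> source informative column
    noise: list[int]


def generate(spec: SyntheticSpec) -> tuple[DomainMatrix, SyntheticTruth]:
    """Draw a matrix and its planted truth; bit-identical under one seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    m = spec.n_cols
    if m < 1:
        raise ValueError("need at least one column")
    is_pos = np.zeros(n, dtype=bool)
    is_pos[: spec.n_pos] = True

    inf_cols = list(range(spec.d_inf))
    red_cols = list(range(spec.d_inf, spec.d_inf + spec.d_red))
    noise_cols = list(range(spec.d_inf + spec.d_red, m))
    if spec.d_red and not spec.d_inf:
        raise ValueError("redundant columns require at least one informative column")
    sources = {c: inf_cols[i % spec.d_inf] for i, c in enumerate(red_cols)}

    X = np.zeros((n, m), dtype=np.int8)
    for j in inf_cols:
        p = np.where(is_pos, spec.p_pos, spec.p_neg)
        X[:, j] = rng.random(n) < p
    for j in red_cols:
        flips = rng.random(n) < spec.flip_prob
        X[:, j] = X[:, sources[j]] ^ flips
    for j in noise_cols:
        X[:, j] = rng.random(n) < spec.q

    # resample all-zero rows so class counts stay exact
    for _ in range(_MAX_RESAMPLE):
        zero = np.flatnonzero(X.sum(axis=1) == 0)
        if zero.size == 0:
            break
        for i in zero:
            row = np.empty(m, dtype=np.int8)
            p = spec.p_pos if is_pos[i] else spec.p_neg
            row[inf_cols] = rng.random(spec.d_inf) < p
            for j in red_cols:
                row[j] = row[sources[j]] ^ (rng.random() < spec.flip_prob)
            row[noise_cols] = rng.random(len(noise_cols)) < spec.q
            X[i] = row
    else:
        raise ValueError(
            "could not produce nonzero rows; the spec's presence "
            "probabilities are degenerate"
        )

    labels = np.where(is_pos, POSITIVE, NEGATIVE)
    matrix = DomainMatrix(
        sp.csr_matrix(X),
        row_ids=[f"P{i:05d}" for i in range(n)],
        col_ids=[f"SYN{j:05d}" for j in range(m)],
        labels=labels,
    )
    return matrix, SyntheticTruth(inf_cols, sources, noise_cols)


def write_truth_tsv(truth: SyntheticTruth, path) -> None:
    """TSV listing each column's role (and source for redundant columns)."""
    with open(path, "w") as fh:
        fh.write("column_index\trole\tsource_index\n")
        for j in truth.informative:
            fh.write(f"{j}\tinformative\t-\n")
        for j, src in truth.redundant.items():
            fh.write(f"{j}\tredundant\t{src}\n")
        for j in truth.noise:
            fh.write(f"{j}\tnoise\t-\n")
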