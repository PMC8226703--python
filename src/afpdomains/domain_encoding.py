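"""Binary protein x domain incidence matrices.

Proteins are encoded as binary vectors over InterPro accessions: entry
(i, j) is 1 iff protein i carries domain j.  Proteins without any
annotated domain carry no information under this encoding and are
removed at matrix-construction time.  Class labels use the convention
1 = antifreeze protein (positive), 2 = non-AFP (negative).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import scipy.io
import scipy.sparse as sp

POSITIVE = 1
NEGATIVE = 2
VALID_LABELS = (POSITIVE, NEGATIVE)

#: Supported annotation dialects.  "interproscan" is the standard
#: InterProScan TSV (protein accession in column 1, InterPro accession in
#: column 12 when present); "pairs" is a minimal 2-column
#: "protein_id<TAB>domain_id" file.  The dialect is always declared by the
#: caller, never sniffed.
DIALECTS = ("interproscan", "pairs")

_IPS_MIN_COLS = 11  # InterProScan TSV has >= 11 columns; col 12 is optional


class AnnotationError(ValueError):
    """Malformed annotation or label input."""


class MatrixFormatError(ValueError):
    """Matrix file violates the binary-incidence / label format."""


@dataclasses.dataclass
class AnnotationSet:
    """Domain accessions annotated on one protein."""

    protein_id: str
    domains: set[str]

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise AnnotationError("protein_id must be non-empty")


@dataclasses.dataclass
class DomainMatrix:
    """Sparse binary protein x domain incidence with per-row class labels.

    Attributes
    ----------
    X : scipy.sparse.csr_matrix of int8
        Incidence values, strictly {0, 1}.
    row_ids, col_ids : list of str
        Protein and domain identifiers, in first-appearance order.
    labels : ndarray of int
        Per-row class code, 1 = positive (AFP), 2 = negative.
    """

    X: sp.csr_matrix
    row_ids: list[str]
    col_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n, m = self.X.shape
        if len(self.row_ids) != n or len(self.col_ids) != m:
            raise MatrixFormatError("row/col id lengths do not match matrix shape")
        if self.labels.shape != (n,):
            raise MatrixFormatError("labels length does not match row count")
        if n and not np.isin(self.labels, VALID_LABELS).all():
            raise MatrixFormatError("labels must be 1 (AFP) or 2 (non-AFP)")
        if self.X.nnz and not np.isin(self.X.data, [0, 1]).all():
            raise MatrixFormatError("incidence values must be 0 or 1")
        if len(set(self.row_ids)) != n:
            raise MatrixFormatError("duplicate row_ids")
        if len(set(self.col_ids)) != m:
            raise MatrixFormatError("duplicate col_ids")

    @property
    def n_proteins(self) -> int:
        return self.X.shape[0]

    @property
    def n_domains(self) -> int:
        return self.X.shape[1]

    @property
    def is_empty(self) -> bool:
        """Degenerate matrix (no rows); downstream operations refuse it."""
        return self.X.shape[0] == 0

    def y01(self) -> np.ndarray:
        """Labels as 1 = positive, 0 = negative (for numeric work)."""
        return (self.labels == POSITIVE).astype(np.int8)

    def equals(self, other: "DomainMatrix") -> bool:
        return (
            self.row_ids == other.row_ids
            and self.col_ids == other.col_ids
            and np.array_equal(self.labels, other.labels)
            and (self.X != other.X).nnz == 0
        )


def _iter_lines(stream: Iterable[str] | TextIO) -> Iterable[tuple[int, str]]:
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def parse_annotations(
    stream: Iterable[str] | TextIO, dialect: str = "pairs"
) -> list[AnnotationSet]:
    """Parse tab-separated annotation lines into per-protein domain sets.

    One :class:`AnnotationSet` is produced per distinct protein, in order
    of first appearance; domains are the union (set semantics) of the
    accessions on that protein's lines.  Lines without an accession
    contribute the protein but no domain.  An empty stream yields an
    empty list.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    order: dict[str, set[str]] = {}
    for lineno, line in _iter_lines(stream):
        fields = line.split("\t")
        if dialect == "pairs":
            if len(fields) > 2 or not fields[0]:
                raise AnnotationError(
                    f"line {lineno}: expected 'protein_id<TAB>domain_id', got "
                    f"{len(fields)} fields"
                )
            pid = fields[0]
            acc = fields[1] if len(fields) == 2 else ""
        else:  # interproscan
            if len(fields) < _IPS_MIN_COLS or not fields[0]:
                raise AnnotationError(
                    f"line {lineno}: InterProScan TSV needs >= {_IPS_MIN_COLS} "
                    f"columns, got {len(fields)}"
                )
            pid = fields[0]
            acc = fields[11] if len(fields) > 11 else ""
        domains = order.setdefault(pid, set())
        if acc and acc != "-":
            domains.add(acc)
    return [AnnotationSet(pid, doms) for pid, doms in order.items()]


def read_labels(stream: Iterable[str] | TextIO) -> dict[str, int]:
    """Read a "protein_id<TAB>class" label file with class in {1, 2}."""
    labels: dict[str, int] = {}
    for lineno, line in _iter_lines(stream):
        fields = line.split("\t")
        if len(fields) != 2:
            raise AnnotationError(f"line {lineno}: expected 'protein_id<TAB>class'")
        pid, cls = fields
        try:
            code = int(cls)
        except ValueError:
            code = -1
        if code not in VALID_LABELS:
            raise AnnotationError(f"line {lineno}: class must be 1 or 2, got {cls!r}")
        if pid in labels and labels[pid] != code:
            raise AnnotationError(f"line {lineno}: conflicting labels for {pid!r}")
        labels[pid] = code
    return labels


def build_domain_matrix(
    annotations: Sequence[AnnotationSet], labels: Mapping[str, int]
) -> tuple[DomainMatrix, dict[int, int]]:
    """Assemble the binary incidence matrix, dropping domainless proteins.

    Rows are proteins with at least one domain in first-appearance order;
    columns are the union of their domains in first-appearance order.
    Proteins present in `labels` but absent from `annotations` count as
    removed, the same as annotated-but-empty proteins.

    Returns
    -------
    (matrix, removed) where removed maps class code -> number of proteins
    dropped for lack of domain annotation.
    """
    seen: set[str] = set()
    for ann in annotations:
        if ann.protein_id in seen:
            raise AnnotationError(f"duplicate protein_id {ann.protein_id!r}")
        seen.add(ann.protein_id)
        if ann.protein_id not in labels:
            raise AnnotationError(f"protein {ann.protein_id!r} has no label")

    removed = {POSITIVE: 0, NEGATIVE: 0}
    for pid, code in labels.items():
        if pid not in seen:
            removed[code] += 1

    row_ids: list[str] = []
    row_labels: list[int] = []
    col_index: dict[str, int] = {}
    rows: list[int] = []
    cols: list[int] = []
    for ann in annotations:
        if not ann.domains:
            removed[labels[ann.protein_id]] += 1
            continue
        i = len(row_ids)
        row_ids.append(ann.protein_id)
        row_labels.append(labels[ann.protein_id])
        # first-appearance column order requires iterating the set in a
        # deterministic order; sort within one protein's set for stability
        for acc in sorted(ann.domains):
            j = col_index.setdefault(acc, len(col_index))
            rows.append(i)
            cols.append(j)
    X = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(row_ids), len(col_index)),
    )
    matrix = DomainMatrix(X, row_ids, list(col_index), np.array(row_labels, dtype=np.int64))
    return matrix, removed


# ---------------------------------------------------------------------------
# Matrix storage: sparse triplet TSV and MatrixMarket with sidecars.

def write_matrix(matrix: DomainMatrix, path: str | Path) -> None:
    """Write in the sparse triplet TSV dialect (or .mtx with sidecars).

    The triplet dialect carries "#rows", "#cols" and "#labels" header
    lines listing row order, column order, and per-row labels, followed
    by one "row_id<TAB>col_id<TAB>1" line per nonzero.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        _write_mtx(matrix, path)
        return
    coo = matrix.X.tocoo()
    with open(path, "w") as fh:
        fh.write("#rows\t" + "\t".join(matrix.row_ids) + "\n")
        fh.write("#cols\t" + "\t".join(matrix.col_ids) + "\n")
        fh.write("#labels\t" + "\t".join(str(c) for c in matrix.labels) + "\n")
        order = np.lexsort((coo.col, coo.row))
        for i, j in zip(coo.row[order], coo.col[order]):
            fh.write(f"{matrix.row_ids[i]}\t{matrix.col_ids[j]}\t1\n")


def read_matrix(path: str | Path) -> DomainMatrix:
    """Read a matrix written by :func:`write_matrix`; inverse of it."""
    path = Path(path)
    if path.suffix == ".mtx":
        return _read_mtx(path)
    row_ids: list[str] | None = None
    col_ids: list[str] | None = None
    labels: list[int] | None = None
    triplets: list[tuple[int, str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if fields[0] == "#rows":
                row_ids = _header_values(fields)
            elif fields[0] == "#cols":
                col_ids = _header_values(fields)
            elif fields[0] == "#labels":
                labels = [_parse_label(v, lineno) for v in _header_values(fields)]
            elif line.startswith("#"):
                continue
            else:
                if len(fields) != 3:
                    raise MatrixFormatError(f"line {lineno}: expected 3 fields")
                if fields[2] != "1":
                    raise MatrixFormatError(
                        f"line {lineno}: incidence value must be 1, got {fields[2]!r}"
                    )
                triplets.append((lineno, fields[0], fields[1]))
    if row_ids is None or col_ids is None or labels is None:
        raise MatrixFormatError("missing #rows, #cols or #labels header")
    row_index = {v: i for i, v in enumerate(row_ids)}
    col_index = {v: i for i, v in enumerate(col_ids)}
    rows, cols = [], []
    for lineno, rid, cid in triplets:
        if rid not in row_index:
            raise MatrixFormatError(f"line {lineno}: unknown row id {rid!r}")
        if cid not in col_index:
            raise MatrixFormatError(f"line {lineno}: unknown col id {cid!r}")
        rows.append(row_index[rid])
        cols.append(col_index[cid])
    X = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(row_ids), len(col_ids)),
    )
    X.sum_duplicates()
    X.data = np.minimum(X.data, 1).astype(np.int8)
    return DomainMatrix(X, row_ids, col_ids, np.array(labels, dtype=np.int64))


def _header_values(fields: list[str]) -> list[str]:
    values = fields[1:]
    return [] if values == [""] else values


def _parse_label(value: str, lineno: int) -> int:
    try:
        code = int(value)
    except ValueError:
        code = -1
    if code not in VALID_LABELS:
        raise MatrixFormatError(f"line {lineno}: label must be 1 or 2, got {value!r}")
    return code


def _write_mtx(matrix: DomainMatrix, path: Path) -> None:
    scipy.io.mmwrite(str(path), matrix.X.tocoo(), field="integer")
    path.with_suffix(".rows").write_text("".join(r + "\n" for r in matrix.row_ids))
    path.with_suffix(".cols").write_text("".join(c + "\n" for c in matrix.col_ids))
    path.with_suffix(".labels").write_text(
        "".join(f"{c}\n" for c in matrix.labels)
    )


def _read_mtx(path: Path) -> DomainMatrix:
    X = sp.csr_matrix(scipy.io.mmread(str(path)))
    row_ids = path.with_suffix(".rows").read_text().splitlines()
    col_ids = path.with_suffix(".cols").read_text().splitlines()
    labels = [
        _parse_label(v, i + 1)
        for i, v in enumerate(path.with_suffix(".labels").read_text().splitlines())
    ]
    if X.nnz and not np.isin(X.data, [0, 1]).all():
        raise MatrixFormatError("incidence values must be 0 or 1")
    return DomainMatrix(X, row_ids, col_ids, np.array(labels, dtype=np.int64))
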