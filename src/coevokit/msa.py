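"""Reading, validating, trimming and reweighting multiple sequence alignments.

An :class:`MSA` is an integer-encoded ``N x L`` matrix plus sequence ids and
the row index of the query (target) sequence. Trimming follows the usual
two-pass protocol for coupling analysis: drop columns that are gapped in the
query or have a gap fraction above a threshold, then drop sequences whose
coverage of the surviving columns is too low. Sequence weights down-weight
redundant sequences so that densely sampled sub-families do not dominate the
frequency estimates; ``Neff`` is the resulting effective sequence count.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import AlignIO, SeqIO

from .alphabet import DEFAULT, Alphabet


class AlignmentShapeError(ValueError):
    """Rows of an alignment do not all have the same length."""


class EmptyInputError(ValueError):
    """An alignment file contained no sequences."""


class DegenerateAlignmentError(ValueError):
    """Trimming removed every column of the alignment."""


class InsufficientInputError(ValueError):
    """The operation needs more sequences than the alignment has."""


@dataclass
class MSA:
    """Integer-encoded multiple sequence alignment.

    Attributes
    ----------
    matrix:
        ``(N, L)`` int8 array of alphabet indices.
    ids:
        Sequence identifiers, one per row.
    query_index:
        Row of the target sequence (positions downstream index this row).
    column_map:
        For each retained column, its index in the original alignment.
    alphabet:
        The encoding alphabet.
    """

    matrix: np.ndarray
    ids: list[str]
    query_index: int = 0
    column_map: np.ndarray | None = None
    alphabet: Alphabet = field(default_factory=lambda: DEFAULT)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise AlignmentShapeError("alignment matrix must be 2-D")
        n, length = self.matrix.shape
        if len(self.ids) != n:
            raise AlignmentShapeError("ids and matrix row count differ")
        if not 0 <= self.query_index < n:
            raise IndexError("query_index out of range")
        if self.matrix.size and (
            self.matrix.min() < 0 or self.matrix.max() >= self.alphabet.q
        ):
            raise ValueError("matrix contains out-of-alphabet codes")
        if self.column_map is None:
            self.column_map = np.arange(length)
        self.column_map = np.asarray(self.column_map, dtype=np.int64)

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def query(self) -> np.ndarray:
        return self.matrix[self.query_index]

    def sequence(self, k: int) -> str:
        return self.alphabet.decode(self.matrix[k])


def _encode_records(
    records: Iterable[tuple[str, str]],
    alphabet: Alphabet,
    query_index: int,
) -> MSA:
    ids, rows = [], []
    for name, seq in records:
        ids.append(name)
        rows.append(alphabet.encode(seq))
    if not rows:
        raise EmptyInputError("no sequences found")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise AlignmentShapeError(
            f"unequal aligned lengths: {sorted(lengths)}"
        )
    return MSA(np.vstack(rows), ids, query_index=query_index, alphabet=alphabet)


def _strip_inserts(records: list[tuple[str, str]]) -> list[tuple[str, str]]:
    # A2M marks insert states as lowercase letters or '.'; they are not
    # aligned columns and are removed before encoding.
    return [
        (name, "".join(c for c in seq if not (c.islower() or c == ".")))
        for name, seq in records
    ]


def read_msa(
    path: str | Path | io.TextIOBase,
    format: str = "fasta",
    alphabet: Alphabet | None = None,
    query_index: int = 0,
) -> MSA:
    """Read an alignment in ``fasta``, ``a2m`` or ``stockholm`` format.

    The first sequence is taken as the query unless ``query_index`` says
    otherwise. A2M insert states (lowercase, ``.``) are dropped as columns.
    """
    alphabet = alphabet or DEFAULT
    fmt = format.lower()
    if fmt not in {"fasta", "a2m", "stockholm"}:
        raise ValueError(f"unsupported alignment format {format!r}")
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        if fmt == "stockholm":
            try:
                aln = AlignIO.read(handle, "stockholm")
            except ValueError as exc:  # Biopython: empty or malformed file
                raise EmptyInputError(str(exc)) from exc
            records = [(rec.id, str(rec.seq)) for rec in aln]
        else:
            records = [
                (rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")
            ]
        if fmt == "a2m":
            records = _strip_inserts(records)
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    return _encode_records(records, alphabet, query_index)


def write_fasta(msa: MSA, path: str | Path | io.TextIOBase) -> None:
    """Write the alignment as FASTA (round-trips exactly with read_msa)."""
    handle = open(path, "w") if isinstance(path, (str, Path)) else path
    try:
        for k in range(msa.n_sequences):
            handle.write(f">{msa.ids[k]}\n{msa.sequence(k)}\n")
    finally:
        if isinstance(path, (str, Path)):
            handle.close()


def trim_msa(
    msa: MSA, max_col_gap: float = 0.30, min_query_cov: float = 0.50
) -> MSA:
    """Trim columns then rows.

    Pass 1 removes columns where the query is gapped or whose gap fraction
    exceeds ``max_col_gap``; pass 2 removes sequences whose non-gap fraction
    over the retained columns is below ``min_query_cov``. The query row is
    always kept, and ``column_map`` tracks surviving original columns.
    """
    for name, v in (("max_col_gap", max_col_gap), ("min_query_cov", min_query_cov)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    gap = msa.alphabet.gap_index
    is_gap = msa.matrix == gap
    col_gap_frac = is_gap.mean(axis=0)
    keep_cols = (~is_gap[msa.query_index]) & (col_gap_frac <= max_col_gap)
    if not keep_cols.any():
        raise DegenerateAlignmentError("trimming removed every column")
    sub = msa.matrix[:, keep_cols]
    coverage = (sub != gap).mean(axis=1)
    keep_rows = coverage >= min_query_cov
    keep_rows[msa.query_index] = True
    row_idx = np.flatnonzero(keep_rows)
    return MSA(
        sub[row_idx],
        [msa.ids[i] for i in row_idx],
        query_index=int(np.searchsorted(row_idx, msa.query_index)),
        column_map=msa.column_map[keep_cols],
        alphabet=msa.alphabet,
    )


@dataclass
class SequenceWeights:
    """Per-sequence redundancy weights.

    ``w[k] = 1 / #{k' : identity(k, k') >= identity_threshold}`` (the cluster
    containing ``k`` includes ``k`` itself, so every weight is in (0, 1]).
    ``Neff = sum(w)`` is the effective number of sequences.
    """

    w: np.ndarray
    identity_threshold: float

    @property
    def neff(self) -> float:
        return float(self.w.sum())


def pairwise_similarity(msa: MSA, chunk: int = 512) -> np.ndarray:
    """Symmetric ``N x N`` matrix of fractional sequence identities.

    Identity is the fraction of columns with equal symbols; gap-gap counts
    as a match. Computed in row chunks to bound memory at large N.
    """
    if msa.n_sequences < 2:
        raise InsufficientInputError("pairwise similarity needs N >= 2")
    m = msa.matrix
    n = m.shape[0]
    sim = np.empty((n, n), dtype=np.float64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = (m[start:stop, None, :] == m[None, :, :]).mean(axis=2)
        sim[start:stop] = block
    return sim


def compute_weights(
    msa: MSA, identity_threshold: float = 0.80
) -> SequenceWeights:
    """Standard identity-based reweighting for coupling inference."""
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    m = msa.matrix
    n, length = m.shape
    counts = np.zeros(n, dtype=np.int64)
    chunk = max(1, int(2**24 // max(1, n * length)))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        ident = (m[start:stop, None, :] == m[None, :, :]).mean(axis=2)
        counts[start:stop] = (ident >= identity_threshold).sum(axis=1)
    return SequenceWeights(1.0 / counts, identity_threshold)
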