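"""Multiple-sequence-alignment assembly for multidomain protein families.

This module covers the composite-MSA workflow used for large multidomain
enzymes whose homologs occur both as a single chain and as separately encoded
subunits: per-class length filtering, redundancy filtering, construction of a
synthetic tandem-duplicated subunit ("dimer") row, organism-keyed
concatenation of subunit alignments, a structure-anchored merge of the
single-chain and concatenated alignments, and truncation to a reference
sequence or to a positional-occupancy level.

Alignments are immutable value objects over the 20 standard amino acids plus
the gap character ``-``.  Nonstandard residue codes (B, Z, X, J, U, O) are
normalized to gap on construction so that every downstream statistic sees a
clean 21-letter alphabet.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import AA_ALPHABET, AA_INDEX, GAP_CHAR, GAP_CODE, NONSTANDARD_AA

__all__ = [
    "Alignment",
    "ReferenceMap",
    "AnchorPairing",
    "ColumnComposition",
    "read_alignment",
    "write_alignment",
    "read_sequences",
    "filter_by_length",
    "redundancy_filter",
    "pairwise_identity",
    "build_tandem_dimer",
    "concatenate_components",
    "merge_via_anchor",
    "truncate_to_reference",
    "truncate_by_occupancy",
    "column_composition",
    "organism_key",
]

_VALID = set(AA_ALPHABET) | {GAP_CHAR}


def _normalize_row(seq: str) -> str:
    """Uppercase, map '.' to '-', and nonstandard residue codes to gap."""
    out = []
    for ch in seq.upper():
        if ch == ".":
            ch = GAP_CHAR
        if ch in NONSTANDARD_AA:
            ch = GAP_CHAR
        if ch not in _VALID:
            raise ValueError(f"invalid alignment symbol {ch!r}")
        out.append(ch)
    return "".join(out)


@dataclass(frozen=True)
class Alignment:
    """An aligned set of protein sequences.

    Parameters
    ----------
    ids
        Unique sequence identifiers; an organism tag may be embedded in the
        identifier (``NAME_ECOLI`` style) for concatenation keying.
    rows
        Aligned sequences, all of identical length, over the 20 standard
        residues plus ``-``.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __init__(self, ids: Iterable[str], rows: Iterable[str]):
        ids = tuple(ids)
        rows = tuple(_normalize_row(r) for r in rows)
        if len(ids) != len(rows):
            raise ValueError("ids and rows length mismatch")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids")
        if rows:
            n = len(rows[0])
            for rid, r in zip(ids, rows):
                if len(r) != n:
                    raise ValueError(
                        f"ragged alignment: row {rid!r} has length {len(r)}, expected {n}"
                    )
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "rows", rows)

    @property
    def n_seq(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None

    def to_indices(self) -> np.ndarray:
        """Integer encoding, shape (n_seq, n_cols); residues 0..19, gap 20."""
        arr = np.full((self.n_seq, self.n_cols), GAP_CODE, dtype=np.int8)
        for i, r in enumerate(self.rows):
            for j, ch in enumerate(r):
                if ch != GAP_CHAR:
                    arr[i, j] = AA_INDEX[ch]
        return arr

    def select_columns(self, cols: Sequence[int]) -> "Alignment":
        cols = list(cols)
        return Alignment(self.ids, ["".join(r[c] for c in cols) for r in self.rows])

    def select_rows(self, indices: Sequence[int]) -> "Alignment":
        return Alignment(
            [self.ids[i] for i in indices], [self.rows[i] for i in indices]
        )


@dataclass(frozen=True)
class ReferenceMap:
    """Map from retained column index (0-based) to reference residue number
    (1-based, sequential over the ungapped reference sequence)."""

    ref_id: str
    col_to_resnum: dict[int, int]

    def __post_init__(self):
        cols = sorted(self.col_to_resnum)
        nums = [self.col_to_resnum[c] for c in cols]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError("reference map must be strictly increasing")

    @property
    def resnum_to_col(self) -> dict[int, int]:
        return {v: k for k, v in self.col_to_resnum.items()}


@dataclass(frozen=True)
class AnchorPairing:
    """Column pairs (col_in_A, col_in_B) from a structural alignment of one
    representative of each component alignment."""

    pairs: tuple[tuple[int, int], ...]

    def __init__(self, pairs: Iterable[tuple[int, int]]):
        pairs = tuple((int(a), int(b)) for a, b in pairs)
        for (a1, b1), (a2, b2) in zip(pairs, pairs[1:]):
            if a2 <= a1 or b2 <= b1:
                raise ValueError("anchor pairs must be strictly monotonic in both coordinates")
        object.__setattr__(self, "pairs", pairs)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnchorPairing":
        pairs = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")[:2]
            pairs.append((int(a), int(b)))
        return cls(pairs)


# ---------------------------------------------------------------------------
# I/O


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Stockholm file.

    Raises ``ValueError`` on an empty file or on rows of unequal length.
    """
    path = Path(path)
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        # Biopython raises on ragged rows and empty files alike; re-raise with
        # the file name for context.
        raise ValueError(f"cannot parse {path} as {format} alignment: {exc}") from exc
    if len(msa) == 0:
        raise ValueError(f"empty alignment: {path}")
    return Alignment([rec.id for rec in msa], [str(rec.seq) for rec in msa])


def write_alignment(alignment: Alignment, path: str | Path, format: str = "fasta") -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(alignment.ids, alignment.rows)
    ]
    AlignIO.write(MultipleSeqAlignment(records), str(path), format)


def read_sequences(path: str | Path, format: str = "fasta") -> dict[str, str]:
    """Read unaligned sequences (id -> sequence), e.g. for length filtering."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), format)}


# ---------------------------------------------------------------------------
# Filtering


def filter_by_length(
    sequences: dict[str, str],
    min_len: int | None = None,
    max_len: int | None = None,
    inclusive_min: bool = False,
) -> dict[str, str]:
    """Keep sequences by ungapped length.

    By default the lower bound is strict and the upper inclusive
    (``min_len < L <= max_len``), matching a "longer than N" class
    definition.  A length-window class such as 500-800 residues is inclusive
    at both ends; pass ``inclusive_min=True`` for that reading.  Either bound
    may be ``None`` (open).
    """
    if min_len is not None and max_len is not None and min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    out = {}
    for sid, seq in sequences.items():
        L = len(seq.replace(GAP_CHAR, "").replace(".", ""))
        if min_len is not None:
            if L < min_len or (not inclusive_min and L == min_len):
                continue
        if max_len is not None and L > max_len:
            continue
        out[sid] = seq
    return out


def pairwise_identity(row_a: str, row_b: str) -> float:
    """Fraction of identical residues over columns where both rows are non-gap.

    Returns 0.0 when the rows share no mutually occupied column.
    """
    both = ident = 0
    for x, y in zip(row_a, row_b):
        if x != GAP_CHAR and y != GAP_CHAR:
            both += 1
            if x == y:
                ident += 1
    return ident / both if both else 0.0


def _identity_matrix(idx: np.ndarray) -> np.ndarray:
    """All-pairs identity (vectorized), same definition as pairwise_identity."""
    nongap = idx != GAP_CODE
    onehot = np.zeros((*idx.shape, 20), dtype=np.float32)
    rows, cols = np.nonzero(nongap)
    onehot[rows, cols, idx[rows, cols]] = 1.0
    flat = onehot.reshape(idx.shape[0], -1)
    matches = flat @ flat.T
    shared = nongap.astype(np.float32) @ nongap.astype(np.float32).T
    with np.errstate(invalid="ignore", divide="ignore"):
        ident = np.where(shared > 0, matches / np.maximum(shared, 1), 0.0)
    return ident


def redundancy_filter(alignment: Alignment, identity_cutoff: float) -> Alignment:
    """Greedy redundancy removal at the given identity cutoff.

    Rows are scanned in input order; a row is dropped if its identity to any
    already-retained row exceeds ``identity_cutoff``.  Identity is counted
    over columns where both rows are non-gap.
    """
    if not 0 < identity_cutoff <= 1:
        raise ValueError("identity_cutoff must be in (0, 1]")
    if alignment.n_seq == 0:
        raise ValueError("cannot redundancy-filter an empty alignment")
    ident = _identity_matrix(alignment.to_indices())
    kept: list[int] = []
    for i in range(alignment.n_seq):
        if all(ident[i, j] <= identity_cutoff for j in kept):
            kept.append(i)
    return alignment.select_rows(kept)


# ---------------------------------------------------------------------------
# Assembly


def build_tandem_dimer(alignment: Alignment) -> Alignment:
    """Concatenate each row with itself (synthetic tandem dimer of a subunit
    that occurs twice per holoenzyme, e.g. a PurS-PurS unit standing in for
    the duplicated N-terminal region of the single-chain protein)."""
    if alignment.n_seq == 0:
        raise ValueError("empty alignment")
    return Alignment(alignment.ids, [r + r for r in alignment.rows])


_ORG_BRACKET = re.compile(r"\[([^\]]+)\]")


def organism_key(seq_id: str) -> str | None:
    """Extract an organism token from a sequence identifier.

    A ``[Species name]`` bracket wins; otherwise the token after the last
    underscore (UniProt ``NAME_ECOLI`` convention).  Returns ``None`` when no
    token can be extracted.
    """
    m = _ORG_BRACKET.search(seq_id)
    if m:
        return m.group(1).strip()
    if "_" in seq_id:
        tok = seq_id.rsplit("_", 1)[1]
        if tok:
            return tok
    return None


def concatenate_components(
    alignments: Sequence[Alignment],
    pairing_key=organism_key,
) -> Alignment:
    """Column-wise concatenation of component alignments matched by key.

    Only keys present in *all* components are retained (rows without a full
    set of subunits are dropped).  The output id is ``key`` and the output row
    is the concatenation of each component's row in the given order.
    """
    if not alignments:
        raise ValueError("no components given")
    keyed: list[dict[str, str]] = []
    for aln in alignments:
        d: dict[str, str] = {}
        for sid, row in zip(aln.ids, aln.rows):
            k = pairing_key(sid)
            if k is None:
                continue
            if k in d:
                raise ValueError(f"duplicate pairing key {k!r} within a component")
            d[k] = row
        keyed.append(d)
    shared = set(keyed[0])
    for d in keyed[1:]:
        shared &= set(d)
    if not shared:
        raise ValueError(
            f"no pairing keys shared by all {len(alignments)} components"
        )
    # deterministic order: first component's input order
    order = [pairing_key(sid) for sid in alignments[0].ids]
    keys = [k for k in order if k in shared]
    return Alignment(keys, ["".join(d[k] for d in keyed) for k in keys])


def merge_via_anchor(
    msa_a: Alignment, msa_b: Alignment, anchors: AnchorPairing
) -> Alignment:
    """Merge two alignments into one, aligning them only at anchored columns.

    At each anchor pair the corresponding columns of A and B share one output
    column.  Between consecutive anchors the unanchored A columns are emitted
    first, then the unanchored B columns, each gap-padded for the other
    input's rows.  Every input row's ungapped sequence is preserved exactly.
    """
    if set(msa_a.ids) & set(msa_b.ids):
        raise ValueError("row ids of the two alignments must be disjoint")
    for a, b in anchors.pairs:
        if not (0 <= a < msa_a.n_cols) or not (0 <= b < msa_b.n_cols):
            raise ValueError(f"anchor ({a}, {b}) out of column range")

    na, nb = msa_a.n_seq, msa_b.n_seq
    out_a: list[list[str]] = [[] for _ in range(na)]
    out_b: list[list[str]] = [[] for _ in range(nb)]

    def emit_a(cols: range) -> None:
        for c in cols:
            for i in range(na):
                out_a[i].append(msa_a.rows[i][c])
            for i in range(nb):
                out_b[i].append(GAP_CHAR)

    def emit_b(cols: range) -> None:
        for c in cols:
            for i in range(na):
                out_a[i].append(GAP_CHAR)
            for i in range(nb):
                out_b[i].append(msa_b.rows[i][c])

    prev_a = prev_b = 0
    for ca, cb in anchors.pairs:
        emit_a(range(prev_a, ca))
        emit_b(range(prev_b, cb))
        # the anchored column itself: A and B symbols share one column
        for i in range(na):
            out_a[i].append(msa_a.rows[i][ca])
        for i in range(nb):
            out_b[i].append(msa_b.rows[i][cb])
        prev_a, prev_b = ca + 1, cb + 1
    emit_a(range(prev_a, msa_a.n_cols))
    emit_b(range(prev_b, msa_b.n_cols))

    return Alignment(
        list(msa_a.ids) + list(msa_b.ids),
        ["".join(r) for r in out_a] + ["".join(r) for r in out_b],
    )


# ---------------------------------------------------------------------------
# Truncation


def truncate_to_reference(
    alignment: Alignment, ref_id: str
) -> tuple[Alignment, ReferenceMap]:
    """Keep exactly the columns occupied (non-gap) in the reference row and
    return the column -> reference-residue-number map."""
    ref = alignment.row(ref_id)
    cols = [c for c, ch in enumerate(ref) if ch != GAP_CHAR]
    truncated = alignment.select_columns(cols)
    refmap = ReferenceMap(ref_id, {i: i + 1 for i in range(len(cols))})
    return truncated, refmap


def truncate_by_occupancy(alignment: Alignment, min_occupancy: float) -> Alignment:
    """Keep columns whose non-gap fraction is >= ``min_occupancy`` (inclusive)."""
    if not 0 < min_occupancy <= 1:
        raise ValueError("min_occupancy must be in (0, 1]")
    if alignment.n_seq == 0:
        return alignment
    idx = alignment.to_indices()
    occ = (idx != GAP_CODE).mean(axis=0)
    cols = [c for c in range(alignment.n_cols) if occ[c] >= min_occupancy - 1e-12]
    return alignment.select_columns(cols)


# ---------------------------------------------------------------------------
# Composition


@dataclass(frozen=True)
class ColumnComposition:
    """Residue composition of a single alignment column.

    ``frequencies`` sums to 1 over the non-gap rows; ``gap_fraction`` is
    reported separately.  For an all-gap column ``frequencies`` is ``None``
    and ``all_gap`` is True.
    """

    column: int
    frequencies: dict[str, float] | None
    gap_fraction: float
    all_gap: bool = False

    def to_series(self):
        import pandas as pd

        data = self.frequencies or {}
        return pd.Series({a: data.get(a, 0.0) for a in AA_ALPHABET}, name=self.column)


def column_composition(
    alignment: Alignment,
    column: int,
    weights: np.ndarray | None = None,
) -> ColumnComposition:
    """Weighted residue frequency table for one column (gap mass separate)."""
    if not 0 <= column < alignment.n_cols:
        raise IndexError(f"column {column} out of range")
    if weights is None:
        weights = np.ones(alignment.n_seq)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (alignment.n_seq,):
        raise ValueError("weights length must equal number of sequences")
    total = weights.sum()
    counts: dict[str, float] = {}
    gap_w = 0.0
    for w, row in zip(weights, alignment.rows):
        ch = row[column]
        if ch == GAP_CHAR:
            gap_w += w
        else:
            counts[ch] = counts.get(ch, 0.0) + w
    nongap = total - gap_w
    if nongap <= 0:
        return ColumnComposition(column, None, 1.0, all_gap=True)
    freqs = {a: c / nongap for a, c in sorted(counts.items())}
    return ColumnComposition(column, freqs, gap_w / total)
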