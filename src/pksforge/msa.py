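"""Multiple-sequence-alignment ingestion, filtering and column statistics.

This module prepares protein alignments for coupling analysis: it reads
aligned FASTA / Stockholm files, removes gap-ridden sequences and columns,
down-weights redundant sequences, and computes weighted per-column residue
frequencies and the positional conservation profile

.. math::

    D_i = \\sum_a f_{ia} \\, \\ln \\frac{f_{ia}}{q_a},

the relative entropy of column *i*'s residue usage against the background
distribution :math:`q`.  Filtered alignments carry a ``column_map`` back to
the original column coordinates so that downstream sector and boundary
reports can be expressed in the input numbering.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO

from .background import (
    AA_ALPHABET,
    GAP_CHAR,
    GAP_CODE,
    background_frequencies,
    decode_codes,
    encode_sequence,
)

__all__ = [
    "MSA",
    "SequenceWeights",
    "ColumnProfile",
    "ConservationProfile",
    "read_alignment",
    "filter_alignment",
    "sequence_weights",
    "column_frequencies",
    "positional_conservation",
    "consensus",
    "write_alignment",
    "write_column_map",
    "write_conservation",
]


@dataclass
class MSA:
    """An alignment over the 20 canonical residues plus gap.

    Attributes
    ----------
    ids:
        Sequence identifiers, one per row.
    seqs:
        Aligned sequences (uppercase, identical length; non-canonical
        characters already mapped to gap).
    column_map:
        For each retained column, its index in the originally read
        alignment.  Strictly increasing; identity on freshly read files.
    """

    ids: list[str]
    seqs: list[str]
    column_map: np.ndarray

    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            for name, s in zip(self.ids, self.seqs):
                if len(s) != len(self.seqs[0]):
                    raise ValueError(
                        f"ragged alignment: record {name!r} has length "
                        f"{len(s)}, expected {len(self.seqs[0])}"
                    )
        self.column_map = np.asarray(self.column_map, dtype=int)
        if len(self.column_map) != self.L:
            raise ValueError("column_map length must equal alignment length")
        if self.L > 1 and not np.all(np.diff(self.column_map) > 0):
            raise ValueError("column_map must be strictly increasing")

    @property
    def N(self) -> int:
        return len(self.ids)

    @property
    def L(self) -> int:
        return len(self.seqs[0])

    def codes(self) -> np.ndarray:
        """(N, L) int8 matrix; residues 0..19, gap = 20. Cached."""
        if self._codes is None:
            self._codes = np.vstack([encode_sequence(s) for s in self.seqs])
        return self._codes

    @classmethod
    def from_codes(cls, ids: list[str], codes: np.ndarray, column_map=None) -> "MSA":
        codes = np.asarray(codes, dtype=np.int8)
        if column_map is None:
            column_map = np.arange(codes.shape[1])
        msa = cls(ids=list(ids), seqs=[decode_codes(r) for r in codes], column_map=column_map)
        msa._codes = codes
        return msa


@dataclass
class SequenceWeights:
    """Redundancy-correction weights: w_s = 1 / (# neighbours at >= cutoff identity)."""

    w: np.ndarray
    identity_cutoff: float

    @property
    def m_eff(self) -> float:
        return float(self.w.sum())


@dataclass
class ColumnProfile:
    """Weighted, pseudocount-regularized residue frequencies per column.

    ``freqs[i, a] = (1 - lam) * (weighted count of a at i) / M_eff + lam * q[a]``

    Gap usage is not part of the 20-residue simplex; it is reported in
    ``gap_frac`` (weighted gap fraction per column) so that
    ``freqs[i].sum() + (1 - lam) * gap_frac[i] == 1``.
    """

    freqs: np.ndarray  # (L, 20)
    gap_frac: np.ndarray  # (L,)
    pseudocount: float
    q: np.ndarray  # (20,)

    def residue_simplex(self) -> np.ndarray:
        """Frequencies renormalized over the 20 residues (gap share removed)."""
        totals = self.freqs.sum(axis=1, keepdims=True)
        return self.freqs / np.clip(totals, 1e-300, None)


@dataclass
class ConservationProfile:
    """Per-column relative entropy D_i (nats) against the background q."""

    D: np.ndarray
    q: np.ndarray


def _clean_seq(seq: str) -> str:
    """Uppercase and map every non-canonical character to the gap symbol."""
    out = []
    for c in seq.upper():
        out.append(c if c in AA_ALPHABET else GAP_CHAR)
    return "".join(out)


def read_alignment(path: str | Path, fmt: str = "aligned-fasta") -> MSA:
    """Read an alignment from aligned FASTA or Stockholm.

    Non-canonical residues (X, B, Z, ., lowercase insert states, ...) are
    mapped to gap.  A ragged FASTA raises an error naming the first
    offending record.
    """
    path = Path(path)
    if fmt in ("aligned-fasta", "fasta"):
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"empty alignment file: {path}")
        ids = [r.id for r in records]
        seqs = [_clean_seq(str(r.seq)) for r in records]
        ref_len = len(seqs[0])
        for rid, s in zip(ids, seqs):
            if len(s) != ref_len:
                raise ValueError(
                    f"ragged alignment: record {rid!r} has length {len(s)}, "
                    f"expected {ref_len}"
                )
    elif fmt == "stockholm":
        try:
            aln = AlignIO.read(str(path), "stockholm")
        except ValueError as exc:
            raise ValueError(f"could not parse Stockholm file {path}: {exc}") from exc
        ids = [r.id for r in aln]
        seqs = [_clean_seq(str(r.seq)) for r in aln]
        if not ids:
            raise ValueError(f"empty alignment file: {path}")
    else:
        raise ValueError(f"unknown alignment format: {fmt!r}")
    return MSA(ids=ids, seqs=seqs, column_map=np.arange(len(seqs[0])))


def filter_alignment(msa: MSA, max_col_gap: float = 0.2, max_seq_gap: float = 0.2) -> MSA:
    """Drop gap-ridden sequences, then gap-ridden columns.

    Sequences with a gap fraction above ``max_seq_gap`` are removed first;
    columns whose gap fraction (over the surviving sequences) exceeds
    ``max_col_gap`` are removed second.  ``column_map`` tracks surviving
    original column indices, composing across repeated filtering.
    """
    for name, v in (("max_col_gap", max_col_gap), ("max_seq_gap", max_seq_gap)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    codes = msa.codes()
    is_gap = codes == GAP_CODE
    keep_seq = is_gap.mean(axis=1) <= max_seq_gap
    if not keep_seq.any():
        raise ValueError("alignment fully filtered: no sequence passes max_seq_gap")
    codes = codes[keep_seq]
    keep_col = (codes == GAP_CODE).mean(axis=0) <= max_col_gap
    if not keep_col.any():
        raise ValueError("alignment fully filtered: no column passes max_col_gap")
    ids = [i for i, k in zip(msa.ids, keep_seq) if k]
    return MSA.from_codes(ids, codes[:, keep_col], column_map=msa.column_map[keep_col])


def pairwise_identity_matrix(msa: MSA, chunk: int = 256) -> np.ndarray:
    """(N, N) fraction of identical alignment positions (gap counts as a symbol)."""
    codes = msa.codes()
    n = msa.N
    out = np.empty((n, n))
    for start in range(0, n, chunk):
        block = codes[start : start + chunk]
        out[start : start + chunk] = (
            (block[:, None, :] == codes[None, :, :]).mean(axis=2)
        )
    return out


def sequence_weights(msa: MSA, identity_cutoff: float = 0.8) -> SequenceWeights:
    """Down-weight redundant sequences.

    Each sequence receives weight ``1 / n_s`` where ``n_s`` counts sequences
    (itself included) at pairwise identity >= ``identity_cutoff``.
    """
    if not 0.0 < identity_cutoff < 1.0:
        raise ValueError(f"identity_cutoff must be in (0, 1), got {identity_cutoff}")
    ident = pairwise_identity_matrix(msa)
    counts = (ident >= identity_cutoff).sum(axis=1)
    return SequenceWeights(w=1.0 / counts, identity_cutoff=identity_cutoff)


def _weighted_counts(msa: MSA, weights: SequenceWeights) -> tuple[np.ndarray, np.ndarray]:
    """Return (L, 20) weighted residue counts and (L,) weighted gap counts."""
    codes = msa.codes()
    w = weights.w
    counts = np.zeros((msa.L, 21))
    for a in range(21):
        counts[:, a] = ((codes == a) * w[:, None]).sum(axis=0)
    return counts[:, :20], counts[:, 20]


def column_frequencies(
    msa: MSA,
    weights: SequenceWeights,
    pseudocount: float = 0.03,
    q: np.ndarray | None = None,
) -> ColumnProfile:
    """Pseudocount-regularized weighted residue frequencies per column."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if q is None:
        q = background_frequencies()
    lam = pseudocount
    res_counts, gap_counts = _weighted_counts(msa, weights)
    m_eff = weights.m_eff
    freqs = (1.0 - lam) * res_counts / m_eff + lam * q[None, :]
    gap_frac = gap_counts / m_eff
    return ColumnProfile(freqs=freqs, gap_frac=gap_frac, pseudocount=lam, q=np.asarray(q))


def positional_conservation(profile: ColumnProfile, q: np.ndarray | None = None) -> ConservationProfile:
    """Relative entropy D_i of each column against the background.

    Computed on the gap-renormalized residue simplex so that D_i >= 0 holds
    for gappy columns as well; 0*ln(0) is taken as 0.
    """
    if q is None:
        q = profile.q
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("background distribution must be strictly positive")
    f = profile.residue_simplex()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(f / q[None, :]), 0.0)
    return ConservationProfile(D=terms.sum(axis=1), q=q)


def consensus(msa: MSA, weights: SequenceWeights) -> str:
    """Weighted majority residue per column; gap if gap has the plurality.

    Exact ties between residues break alphabetically; a residue/gap tie is
    resolved in favour of the residue.
    """
    res_counts, gap_counts = _weighted_counts(msa, weights)
    # argmax over the alphabet is already the alphabetical tie-break because
    # AA_ALPHABET is sorted.
    best = res_counts.argmax(axis=1)
    best_count = res_counts[np.arange(msa.L), best]
    out = [
        GAP_CHAR if gap_counts[i] > best_count[i] + 1e-12 else AA_ALPHABET[best[i]]
        for i in range(msa.L)
    ]
    return "".join(out)


def write_alignment(msa: MSA, path: str | Path) -> None:
    """Write the alignment as aligned FASTA."""
    with open(path, "w") as fh:
        for rid, seq in zip(msa.ids, msa.seqs):
            fh.write(f">{rid}\n{seq}\n")


def write_column_map(msa: MSA, path: str | Path) -> None:
    """TSV sidecar: retained_index, original_index (both 1-based for humans)."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh, delimiter="\t")
        wr.writerow(["retained_index", "original_index"])
        for i, orig in enumerate(msa.column_map):
            wr.writerow([i + 1, int(orig) + 1])


def write_conservation(msa: MSA, cons: ConservationProfile, profile: ColumnProfile, path: str | Path) -> None:
    """TSV: 1-based original column, D_i (nats), gap fraction."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh, delimiter="\t")
        wr.writerow(["column", "D", "gap_frac"])
        for i in range(msa.L):
            wr.writerow([int(msa.column_map[i]) + 1, f"{cons.D[i]:.6f}", f"{profile.gap_frac[i]:.6f}"])
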