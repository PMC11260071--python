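"""PKS protein architecture: domains, motifs, exchange units, recombination scans.

Trans-AT PKS proteins are modelled as an amino-acid sequence plus an
ordered, non-overlapping list of domain spans (KS, FSD, KR, ACP, ...).
Two conserved motifs matter for engineering: NAHVILEE near the KS
C-terminus and LPTYPFxxxxxW (five arbitrary residues) at the C-terminus of
the flanking subdomain (FSD).  Exchange units — the evolutionarily
autonomous segments swapped between assembly lines — are delimited by the
residue immediately after the motif's terminal W, in contrast to the
biochemical KS-to-ACP module boundaries.

The module also provides a sliding-window pairwise-identity scan that
localizes where sequence similarity between two natural hybrid PKSs drops
off, the signature of a recombination breakpoint.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "DOMAIN_KINDS",
    "DomainSpan",
    "PKSProtein",
    "MotifPattern",
    "MotifHit",
    "ExchangeUnit",
    "NAHVILEE",
    "LPTYPF_X5_W",
    "read_domain_table",
    "write_domain_table",
    "extract_tridomains",
    "find_motifs",
    "delimit_exchange_units",
    "similarity_dropoff",
    "write_unit_report",
]

DOMAIN_KINDS = ("KS", "FSD", "AT", "KR", "DH", "ACP", "TE", "C", "DUF", "other")

WILDCARD = "x"


@dataclass(frozen=True)
class DomainSpan:
    """A domain occupying [start, end) in protein coordinates (0-based)."""

    kind: str
    start: int
    end: int
    module_index: int | None = None

    def __post_init__(self):
        if self.kind not in DOMAIN_KINDS:
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if not self.start < self.end:
            raise ValueError(f"empty/inverted span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PKSProtein:
    """Sequence plus sorted, non-overlapping domain spans."""

    id: str
    sequence: str
    domains: list[DomainSpan] = field(default_factory=list)
    source_bgc: str = ""

    def __post_init__(self):
        self.domains = sorted(self.domains, key=lambda d: d.start)
        prev = None
        for d in self.domains:
            if self.sequence and d.end > len(self.sequence):
                raise ValueError(
                    f"{self.id}: domain {d.kind} [{d.start},{d.end}) exceeds "
                    f"sequence length {len(self.sequence)}"
                )
            if prev is not None and d.start < prev.end:
                raise ValueError(
                    f"{self.id}: overlapping domains {prev.kind} "
                    f"[{prev.start},{prev.end}) and {d.kind} [{d.start},{d.end})"
                )
            prev = d

    def architecture(self) -> str:
        return "-".join(d.kind for d in self.domains)


@dataclass(frozen=True)
class MotifPattern:
    """Degenerate motif: literal residues plus wildcards (``x``).

    ``max_mismatch`` bounds substitutions at literal positions only;
    wildcards match any residue.
    """

    elements: tuple[str, ...]
    max_mismatch: int = 0

    @classmethod
    def from_string(cls, s: str, max_mismatch: int = 0) -> "MotifPattern":
        return cls(tuple(c if c.isupper() else WILDCARD for c in s), max_mismatch)

    def __len__(self) -> int:
        return len(self.elements)

    def __str__(self) -> str:
        return "".join(self.elements)


#: Conserved motif near the KS C-terminus (unproductive fusion site).
NAHVILEE = MotifPattern.from_string("NAHVILEE")

#: FSD C-terminal boundary motif, L P T Y P F x x x x x W (length 12).
LPTYPF_X5_W = MotifPattern.from_string("LPTYPFxxxxxW")


@dataclass(frozen=True)
class MotifHit:
    start: int
    mismatches: int
    matched_string: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched_string)


@dataclass
class ExchangeUnit:
    """A segment [start, end) delimited by FSD boundary motifs or termini."""

    start: int
    end: int
    contained_domains: list[DomainSpan] = field(default_factory=list)
    substrate_in: "object | None" = None
    substrate_out: "object | None" = None

    def __len__(self) -> int:
        return self.end - self.start

    def domain_string(self) -> str:
        return "-".join(d.kind for d in self.contained_domains)


def read_domain_table(
    path: str | Path, sequences: dict[str, str] | None = None
) -> list[PKSProtein]:
    """Read a domain-architecture TSV into PKSProtein records.

    Required columns: ``protein_id, kind, start, end, module_index``
    (coordinates 1-based inclusive on input; converted to 0-based
    half-open).  ``module_index`` may be empty.  Unknown kinds map to
    ``other`` with a warning; overlapping spans are an error naming the
    offending pair.  ``sequences`` optionally supplies protein sequences
    keyed by id (empty string otherwise).
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "kind": str})
    required = {"protein_id", "kind", "start", "end", "module_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"domain table missing columns: {sorted(missing)}")
    proteins: list[PKSProtein] = []
    for pid, grp in df.groupby("protein_id", sort=False):
        spans = []
        for _, row in grp.iterrows():
            kind = row["kind"]
            if kind not in DOMAIN_KINDS:
                warnings.warn(f"{pid}: unknown domain kind {kind!r}, mapped to 'other'")
                kind = "other"
            mi = row["module_index"]
            module_index = None if pd.isna(mi) else int(mi)
            spans.append(
                DomainSpan(
                    kind=kind,
                    start=int(row["start"]) - 1,
                    end=int(row["end"]),
                    module_index=module_index,
                )
            )
        seq = (sequences or {}).get(pid, "")
        proteins.append(PKSProtein(id=str(pid), sequence=seq, domains=spans))
    return proteins


def write_domain_table(proteins: list[PKSProtein], path: str | Path) -> None:
    """Inverse of :func:`read_domain_table` (1-based inclusive coordinates)."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh, delimiter="\t")
        wr.writerow(["protein_id", "kind", "start", "end", "module_index"])
        for p in proteins:
            for d in p.domains:
                mi = "" if d.module_index is None else d.module_index
                wr.writerow([p.id, d.kind, d.start + 1, d.end, mi])


def extract_tridomains(
    proteins: list[PKSProtein],
    upstream_flank: int = 50,
    downstream_flank: int = 50,
) -> list[tuple[str, str]]:
    """Cut out each KS with flanking context for alignment building.

    For every annotated KS the emitted subsequence spans from
    ``KS.start - upstream_flank`` to the end of the following KR (or FSD,
    whichever comes last before the next KS; the KS itself if neither
    follows) plus ``downstream_flank``, clamped to the protein bounds.
    Returns (fasta_id, subsequence) pairs; ids encode protein id and
    module index.
    """
    out: list[tuple[str, str]] = []
    for prot in proteins:
        ks_list = [d for d in prot.domains if d.kind == "KS"]
        if not ks_list:
            raise ValueError(f"{prot.id}: no KS domain annotated")
        for n, ks in enumerate(ks_list):
            next_ks_start = min(
                (d.start for d in prot.domains if d.kind == "KS" and d.start > ks.start),
                default=len(prot.sequence),
            )
            region_end = ks.end
            for d in prot.domains:
                if d.kind in ("KR", "FSD") and ks.end <= d.start < next_ks_start:
                    region_end = max(region_end, d.end)
            lo = max(0, ks.start - upstream_flank)
            hi = min(len(prot.sequence), region_end + downstream_flank)
            module = ks.module_index if ks.module_index is not None else n + 1
            out.append((f"{prot.id}_KS{module}", prot.sequence[lo:hi]))
    return out


def find_motifs(sequence: str, pattern: MotifPattern) -> list[MotifHit]:
    """All matches of a degenerate motif with bounded literal mismatches.

    Hits are sorted by start position, then by mismatch count.
    """
    if len(pattern) == 0:
        raise ValueError("empty motif pattern")
    m = len(pattern)
    hits: list[MotifHit] = []
    literals = [(i, c) for i, c in enumerate(pattern.elements) if c != WILDCARD]
    for s in range(len(sequence) - m + 1):
        mm = 0
        for i, c in literals:
            if sequence[s + i] != c:
                mm += 1
                if mm > pattern.max_mismatch:
                    break
        else:
            hits.append(MotifHit(start=s, mismatches=mm, matched_string=sequence[s : s + m]))
    hits.sort(key=lambda h: (h.start, h.mismatches))
    return hits


def _greedy_nonoverlapping(hits: list[MotifHit], length: int) -> list[MotifHit]:
    """Resolve overlaps greedily left-to-right, fewest mismatches first."""
    chosen: list[MotifHit] = []
    for h in sorted(hits, key=lambda h: (h.start, h.mismatches)):
        if not chosen or h.start >= chosen[-1].start + length:
            chosen.append(h)
    return chosen


def delimit_exchange_units(
    protein: PKSProtein, max_mismatch: int = 0
) -> list[ExchangeUnit]:
    """Partition a protein into exchange units at FSD boundary motifs.

    Boundaries sit immediately after the terminal W of each
    non-overlapping LPTYPFxxxxxW hit; both protein termini are implicit
    boundaries, so the units tile [0, len) without overlap.  A domain
    belongs to the unit containing its start.  With zero motif hits a
    single whole-protein unit is returned with a warning.
    """
    if not protein.sequence:
        raise ValueError(f"{protein.id}: protein sequence required")
    pattern = MotifPattern(LPTYPF_X5_W.elements, max_mismatch)
    hits = _greedy_nonoverlapping(find_motifs(protein.sequence, pattern), len(pattern))
    bounds = [0] + [h.end for h in hits if 0 < h.end < len(protein.sequence)] + [
        len(protein.sequence)
    ]
    if len(bounds) == 2:
        warnings.warn(f"{protein.id}: no boundary motif found; single unit emitted")
    units = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        contained = [d for d in protein.domains if lo <= d.start < hi]
        units.append(ExchangeUnit(start=lo, end=hi, contained_domains=contained))
    return units


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _global_align(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Affine-gap global alignment (BLOSUM62, open -11, extend -1)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    return a, b


def similarity_dropoff(
    seq_a: str,
    seq_b: str,
    window: int = 30,
    min_drop: float = 0.2,
    prealigned: bool = False,
):
    """Locate where pairwise similarity between two sequences collapses.

    Equal-length inputs (or ``prealigned=True``) are compared position by
    position; otherwise a global alignment is computed first.  The profile
    is the ``window``-wide rolling identity fraction.  The changepoint is
    the position maximizing the drop in mean identity between the left and
    right windows, reported only when the drop exceeds ``min_drop`` (the
    significance floor); otherwise the changepoint is None.

    Returns a dict with ``profile`` (rolling identity), ``changepoint``
    (aligned-column index or None) and ``drop`` (drop magnitude).
    """
    if prealigned or len(seq_a) == len(seq_b):
        a, b = seq_a, seq_b
    else:
        a, b = _global_align(seq_a, seq_b)
    n = len(a)
    if window > n:
        raise ValueError(f"window {window} larger than aligned length {n}")
    match = np.array([1.0 if x == y and x != "-" else 0.0 for x, y in zip(a, b)])
    kernel = np.ones(window) / window
    profile = np.convolve(match, kernel, mode="same")
    csum = np.concatenate([[0.0], np.cumsum(match)])
    drops = np.full(n, -np.inf)
    for p in range(window, n - window + 1):
        left = (csum[p] - csum[p - window]) / window
        right = (csum[p + window] - csum[p]) / window
        drops[p] = left - right
    if np.all(np.isinf(drops)):
        return {"profile": profile, "changepoint": None, "drop": 0.0}
    p_best = int(np.argmax(drops))
    drop = float(drops[p_best])
    if drop < min_drop:
        return {"profile": profile, "changepoint": None, "drop": max(drop, 0.0)}
    return {"profile": profile, "changepoint": p_best, "drop": drop}


def write_unit_report(
    proteins_units: list[tuple[PKSProtein, list[ExchangeUnit]]], path: str | Path
) -> None:
    """TSV: protein, unit index (1-based), start, end (1-based incl.), domains."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh, delimiter="\t")
        wr.writerow(["protein_id", "unit", "start", "end", "domains"])
        for prot, units in proteins_units:
            for i, u in enumerate(units, start=1):
                wr.writerow([prot.id, i, u.start + 1, u.end, u.domain_string()])
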