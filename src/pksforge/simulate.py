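"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its arguments plus a seed, and emits a
:class:`TruthSidecar` holding the planted ground truth (sector membership,
boundary positions, motif placements, exchange-unit spans, compound tables)
so that recovery can be scored without re-generation.

The alignment generator uses a latent-spin sector model: each sequence
draws a Bernoulli(0.5) hidden state per sector, and sector positions emit
one of two position-specific residues according to that state with
probability ρ (the coupling strength), falling back to the background
distribution otherwise.  Non-sector positions emit a position-specific
consensus residue with probability c (the conservation backbone) and a
background draw otherwise.  This plants exactly the covariance structure
coupling analysis looks for, without phylogenetic correlations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .architecture import DomainSpan, PKSProtein
from .background import AA_ALPHABET, GAP_CODE, background_frequencies
from .masscalc import ADDUCTS, adduct_mz, isotope_pattern
from .msa import MSA
from .msdata import MSRun

__all__ = [
    "SectorSpec",
    "TruthSidecar",
    "simulate_alignment",
    "simulate_pks_protein",
    "simulate_hybrid_pair",
    "simulate_lcms",
]


@dataclass(frozen=True)
class SectorSpec:
    """A planted sector: member columns, coupling strength, residue states."""

    positions: tuple[int, ...]
    rho: float = 0.9
    residue_pairs: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")


@dataclass
class TruthSidecar:
    """Ground truth of a simulated dataset; JSON round-trippable."""

    kind: str
    seed: int
    sectors: list[list[int]] = field(default_factory=list)
    boundary: int | None = None
    gap_columns: list[int] = field(default_factory=list)
    motifs: dict[str, list[int]] = field(default_factory=dict)
    unit_spans: list[list[int]] = field(default_factory=list)
    domains: list[dict] = field(default_factory=list)
    changepoint: int | None = None
    compounds: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "TruthSidecar":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        return cls(**data)


def _draw_background(rng: np.random.Generator, size, q: np.ndarray) -> np.ndarray:
    return rng.choice(20, size=size, p=q)


def simulate_alignment(
    N: int,
    L: int,
    sectors: list[SectorSpec] | None = None,
    conservation: float = 0.3,
    gap_rate: float = 0.0,
    seed: int = 0,
    gap_columns: list[int] | None = None,
    gap_column_rate: float = 0.8,
    q: np.ndarray | None = None,
) -> tuple[MSA, TruthSidecar]:
    """Simulate an alignment with planted coevolving sectors.

    Parameters
    ----------
    N, L:
        Number of sequences and columns (N >= 2).
    sectors:
        Planted sectors with disjoint positions < L.
    conservation:
        Probability c that a non-sector position emits its consensus residue.
    gap_rate:
        I.i.d. gap probability applied everywhere.
    gap_columns / gap_column_rate:
        Optional planted gap-heavy columns (gap probability
        ``gap_column_rate``), recorded in the truth sidecar — the target of
        gap-filtering tests.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    sectors = list(sectors or [])
    seen: set[int] = set()
    for spec in sectors:
        if any(p >= L or p < 0 for p in spec.positions):
            raise ValueError("sector position out of range")
        if seen & set(spec.positions):
            raise ValueError("overlapping sector positions")
        seen |= set(spec.positions)
    if q is None:
        q = background_frequencies()
    rng = np.random.default_rng(seed)

    codes = _draw_background(rng, (N, L), q).astype(np.int8)

    # Conservation backbone at non-sector positions.
    consensus_res = rng.integers(0, 20, size=L)
    keep = rng.random((N, L)) < conservation
    for j in range(L):
        if j in seen:
            continue
        codes[keep[:, j], j] = consensus_res[j]

    # Latent-spin sectors.
    truth_sectors: list[list[int]] = []
    for spec in sectors:
        pairs = spec.residue_pairs
        if pairs is None:
            pairs = tuple(
                tuple(AA_ALPHABET[i] for i in rng.choice(20, size=2, replace=False))
                for _ in spec.positions
            )
        if len(pairs) != len(spec.positions):
            raise ValueError("one residue pair per sector position required")
        z = rng.integers(0, 2, size=N)
        for pos, (a0, a1) in zip(spec.positions, pairs):
            emit = rng.random(N) < spec.rho
            states = np.where(z == 0, AA_ALPHABET.index(a0), AA_ALPHABET.index(a1))
            codes[emit, pos] = states[emit].astype(np.int8)
        truth_sectors.append(sorted(spec.positions))

    if gap_rate > 0:
        codes[rng.random((N, L)) < gap_rate] = GAP_CODE
    gap_cols = sorted(gap_columns or [])
    for j in gap_cols:
        codes[rng.random(N) < gap_column_rate, j] = GAP_CODE

    ids = [f"seq{i:05d}" for i in range(N)]
    msa = MSA.from_codes(ids, codes)
    truth = TruthSidecar(
        kind="alignment", seed=seed, sectors=truth_sectors, gap_columns=gap_cols
    )
    return msa, truth


#: Default stub lengths per domain kind (residues), loosely realistic.
DOMAIN_LENGTHS = {
    "KS": 420,
    "FSD": 120,
    "AT": 300,
    "KR": 180,
    "DH": 280,
    "ACP": 80,
    "TE": 250,
    "C": 450,
    "DUF": 150,
    "other": 100,
}

_NAHVILEE_STR = "NAHVILEE"
_BOUNDARY_LITERALS = "LPTYPF"  # + 5 random residues + W


def simulate_pks_protein(
    architecture: str,
    seed: int = 0,
    domain_lengths: dict[str, int] | None = None,
    q: np.ndarray | None = None,
) -> tuple[PKSProtein, TruthSidecar]:
    """Simulate a PKS protein with planted motifs for a domain architecture.

    ``architecture`` is a dash-separated token string over the domain
    vocabulary, e.g. ``"KS-FSD-KR-ACP-KS-FSD-ACP"``.  Domain stubs are
    random sequences of configurable length; NAHVILEE is embedded 30
    residues before each KS C-terminus and LPTYPF + 5 random residues + W
    occupies the last 12 residues of each FSD, so each FSD C-terminus is an
    exchange-unit boundary.  The truth sidecar records motif positions and
    the implied unit spans.
    """
    lengths = dict(DOMAIN_LENGTHS)
    if domain_lengths:
        lengths.update(domain_lengths)
    if q is None:
        q = background_frequencies()
    rng = np.random.default_rng(seed)
    tokens = architecture.split("-")
    for t in tokens:
        if t not in lengths:
            raise ValueError(f"unknown domain token {t!r}")

    seq_parts: list[str] = []
    domains: list[DomainSpan] = []
    nahvilee_pos: list[int] = []
    boundary_pos: list[int] = []
    pos = 0
    module = 0
    for t in tokens:
        n = lengths[t]
        stub = "".join(AA_ALPHABET[i] for i in _draw_background(rng, n, q))
        if t == "KS":
            module += 1
            insert_at = n - 30 - len(_NAHVILEE_STR)
            stub = (
                stub[:insert_at]
                + _NAHVILEE_STR
                + stub[insert_at + len(_NAHVILEE_STR) :]
            )
            nahvilee_pos.append(pos + insert_at)
        elif t == "FSD":
            wild = "".join(AA_ALPHABET[i] for i in _draw_background(rng, 5, q))
            motif = _BOUNDARY_LITERALS + wild + "W"
            stub = stub[: n - len(motif)] + motif
            boundary_pos.append(pos + n - len(motif))
        domains.append(
            DomainSpan(kind=t, start=pos, end=pos + n, module_index=module or None)
        )
        seq_parts.append(stub)
        pos += n

    sequence = "".join(seq_parts)
    protein = PKSProtein(id=f"sim_{architecture}_{seed}", sequence=sequence, domains=domains)
    bounds = [0] + [p + 12 for p in boundary_pos if 0 < p + 12 < len(sequence)] + [
        len(sequence)
    ]
    unit_spans = [[lo, hi] for lo, hi in zip(bounds[:-1], bounds[1:])]
    truth = TruthSidecar(
        kind="pks_protein",
        seed=seed,
        motifs={"NAHVILEE": nahvilee_pos, "LPTYPFx5W": boundary_pos},
        unit_spans=unit_spans,
        domains=[
            {"kind": d.kind, "start": d.start, "end": d.end, "module_index": d.module_index}
            for d in domains
        ],
    )
    return protein, truth


def simulate_hybrid_pair(
    shared_len: int,
    total_len: int,
    identity_after: float = 0.05,
    seed: int = 0,
    q: np.ndarray | None = None,
) -> tuple[str, str, TruthSidecar]:
    """Two sequences sharing a prefix, diverging to a target identity after it.

    Emulates a natural hybrid pair whose similarity collapses downstream of
    the last shared module.  Truth changepoint = ``shared_len``.
    """
    if not shared_len < total_len:
        raise ValueError("shared_len must be < total_len")
    if q is None:
        q = background_frequencies()
    rng = np.random.default_rng(seed)
    prefix = "".join(AA_ALPHABET[i] for i in _draw_background(rng, shared_len, q))
    tail = total_len - shared_len
    a_tail = _draw_background(rng, tail, q)
    b_tail = a_tail.copy()
    for i in range(tail):
        if rng.random() >= identity_after:
            choices = [c for c in range(20) if c != a_tail[i]]
            b_tail[i] = choices[rng.integers(0, 19)]
    seq_a = prefix + "".join(AA_ALPHABET[i] for i in a_tail)
    seq_b = prefix + "".join(AA_ALPHABET[i] for i in b_tail)
    truth = TruthSidecar(kind="hybrid_pair", seed=seed, changepoint=shared_len)
    return seq_a, seq_b, truth


def simulate_lcms(
    compounds: list[dict],
    noise_sd: float = 0.05,
    seed: int = 0,
    run_length: float = 20.0,
    scan_spacing: float = 0.02,
    elution_sigma: float = 0.05,
    envelope_threshold: float = 1e-3,
    noise_peaks_per_scan: int = 5,
    noise_intensity: float = 50.0,
    mz_range: tuple[float, float] = (150.0, 900.0),
) -> tuple[MSRun, TruthSidecar]:
    """Simulate a centroided LC-MS run of known compounds.

    ``compounds`` entries are dicts with keys ``name, formula, adducts
    (list of adduct names), rt (minutes), intensity``.  Each compound x
    adduct elutes as a Gaussian of width ``elution_sigma``; every scan
    carries the compound's isotope envelope scaled by the elution profile
    with multiplicative log-normal noise, plus flat low-level noise peaks.
    """
    for c in compounds:
        if not 0.0 <= c["rt"] <= run_length:
            raise ValueError(f"compound {c.get('name')}: rt outside run")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, run_length + scan_spacing / 2, scan_spacing)

    features = []  # (mz array, abundance array, rt, intensity)
    truth_compounds = []
    for c in compounds:
        pattern = isotope_pattern(c["formula"], threshold=envelope_threshold)
        for add in c["adducts"]:
            adduct = ADDUCTS[add]
            mz0 = adduct_mz(c["formula"], adduct)
            shift = mz0 - pattern.peaks[0][0]
            mzs = np.array([m + shift for m, _ in pattern.peaks])
            abund = np.array([a for _, a in pattern.peaks])
            features.append((mzs, abund / abund.max(), c["rt"], c["intensity"]))
            truth_compounds.append(
                {
                    "name": c["name"],
                    "formula": c["formula"] if isinstance(c["formula"], str) else dict(c["formula"]),
                    "adduct": add,
                    "mz": float(mz0),
                    "rt": float(c["rt"]),
                    "intensity": float(c["intensity"]),
                }
            )

    peaks: list[np.ndarray] = []
    for t in times:
        scan_mz: list[float] = []
        scan_int: list[float] = []
        for mzs, abund, rt, inten in features:
            scale = inten * np.exp(-((t - rt) ** 2) / (2.0 * elution_sigma**2))
            if scale < 1e-3 * inten:
                continue
            noise = (
                rng.lognormal(mean=0.0, sigma=noise_sd, size=len(mzs))
                if noise_sd > 0
                else np.ones(len(mzs))
            )
            scan_mz.extend(mzs)
            scan_int.extend(scale * abund * noise)
        n_noise = rng.poisson(noise_peaks_per_scan)
        if n_noise:
            scan_mz.extend(rng.uniform(*mz_range, size=n_noise))
            scan_int.extend(rng.exponential(noise_intensity, size=n_noise))
        if scan_mz:
            order = np.argsort(scan_mz)
            arr = np.column_stack([np.array(scan_mz)[order], np.array(scan_int)[order]])
        else:
            arr = np.empty((0, 2))
        peaks.append(arr)

    run = MSRun(times=times, peaks=peaks)
    truth = TruthSidecar(kind="lcms", seed=seed, compounds=truth_compounds)
    return run, truth
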