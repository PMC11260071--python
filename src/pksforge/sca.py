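"""Statistical coupling analysis: coupling matrix, significance, sectors.

The coupling matrix measures how strongly residue usage covaries between
alignment columns.  For columns *i*, *j* and residues *a*, *b* the raw
weighted covariance is

.. math::

    c_{ij}^{ab} = f_{ij}^{ab} - f_{ia} f_{jb},

with frequencies taken over sequences that are non-gapped at the relevant
columns.  Each term is weighted by the conservation gradient

.. math::

    \\phi_{ia} = \\ln \\frac{\\tilde f_{ia} (1 - q_a)}{(1 - \\tilde f_{ia}) q_a},

the derivative of the binary relative entropy of column *i* at residue *a*,
evaluated on pseudocount-regularized (and clipped) frequencies
:math:`\\tilde f`.  The scalar coupling is the Frobenius norm

.. math::

    C_{ij} = \\Big( \\sum_{ab} (\\phi_{ia} \\phi_{jb} c_{ij}^{ab})^2 \\Big)^{1/2},

which is symmetric and entrywise nonnegative.  Networks of coevolving
positions ("sectors") live in the leading eigenmodes of :math:`C`;
significance is calibrated against a null in which every column is
independently permuted across sequences — this destroys inter-column
covariance while preserving each column's conservation exactly, so a
conservation-driven leading mode appears in the null as well and cancels
out of the comparison.  The retained eigenmodes are unmixed by fixed-point
independent component analysis, and positions are assigned to the component
on which they load most strongly, subject to a heavy-tail quantile cutoff.

A sector *boundary* is an inter-column position that separates sectors: the
boundary score within a window of ``w`` columns on each side is 1 when every
sector's windowed members fall entirely on one side and approaches 0 when
the sectors straddle the position evenly.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from scipy import stats

from .background import GAP_CODE, background_frequencies
from .msa import MSA, SequenceWeights, column_frequencies, sequence_weights

__all__ = [
    "CouplingMatrix",
    "EigenSpectrum",
    "SectorAssignment",
    "BoundaryProfile",
    "NullSpectrum",
    "coupling_matrix",
    "eigendecompose",
    "null_spectrum",
    "significant_modes",
    "extract_sectors",
    "boundary_profile",
    "sca_pipeline",
    "write_coupling_matrix",
    "write_sector_report",
    "write_boundary_profile",
]

_CLIP = 1e-12


@dataclass
class CouplingMatrix:
    """L x L symmetric, entrywise-nonnegative coupling matrix with metadata."""

    C: np.ndarray
    pseudocount: float
    identity_cutoff: float | None
    background: str

    @property
    def L(self) -> int:
        return self.C.shape[0]


@dataclass
class EigenSpectrum:
    """Eigenvalues (descending) and orthonormal eigenvectors of a coupling matrix."""

    values: np.ndarray  # (L,), descending
    vectors: np.ndarray  # (L, L), columns match values
    k_significant: int | None = None


@dataclass
class SectorAssignment:
    """Position -> sector mapping with per-position component loadings.

    Sectors are numbered 1..K by descending summed loading, so "sector 1"
    is the most significant network.  Unassigned positions are absent from
    ``sector_of``.
    """

    sector_of: dict[int, int]
    loading: dict[int, float]
    K: int
    n_positions: int
    ica_loadings: np.ndarray = field(repr=False)  # (L, K) sign-fixed sources

    def members(self, k: int) -> list[int]:
        return sorted(p for p, s in self.sector_of.items() if s == k)


@dataclass
class BoundaryProfile:
    """Boundary score per inter-column cut position.

    ``scores[p]`` scores the cut between columns ``p-1`` and ``p`` for
    ``p = 1..L-1`` (``scores[0]`` is unused and set to 0).
    """

    scores: np.ndarray
    window: int
    maxima: list[int]

    @property
    def argmax(self) -> int:
        return int(np.argmax(self.scores))


@dataclass
class NullSpectrum:
    """Leading null eigenvalues from within-column permutation trials."""

    values: np.ndarray
    statistic: str
    n_trials: int

    def percentile(self, p: float = 95.0) -> float:
        return float(np.percentile(self.values, p))


def _phi_weights(freqs_reg: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Conservation-gradient weights on clipped regularized frequencies."""
    f = np.clip(freqs_reg, _CLIP, 1.0 - _CLIP)
    return np.log(f * (1.0 - q[None, :]) / ((1.0 - f) * q[None, :]))


def coupling_matrix(
    msa: MSA,
    weights: SequenceWeights,
    pseudocount: float = 0.03,
    q: np.ndarray | None = None,
    phi_weighting: bool = True,
    background_id: str = "database",
) -> CouplingMatrix:
    """Compute the SCA coupling matrix of a (filtered) alignment.

    The covariance term uses raw weighted frequencies restricted to
    non-gapped sequences, so constant columns carry exactly zero coupling;
    the pseudocount enters only through the conservation weights phi.
    Set ``phi_weighting=False`` for the unweighted covariance norm.
    """
    if not 0.0 <= pseudocount < 1.0:
        raise ValueError("pseudocount must be in [0, 1)")
    if q is None:
        q = background_frequencies(background_id)
    codes = np.asarray(msa.codes(), dtype=np.int64)
    N, L = codes.shape
    w = weights.w
    nongap = codes != GAP_CODE
    if not nongap.any(axis=0).all():
        raise ValueError("alignment contains an all-gap column; filter first")

    # One-hot (N, L*20) with zeros at gaps.
    X = np.zeros((N, L * 20))
    rows, cols = np.nonzero(nongap)
    X[rows, cols * 20 + codes[rows, cols]] = 1.0

    Xw = X * w[:, None]
    pair_counts = Xw.T @ X  # (L*20, L*20) weighted joint counts
    Gw = nongap * w[:, None]
    denom = Gw.T @ nongap.astype(float)  # weighted both-non-gap counts
    denom = np.clip(denom, 1e-300, None)

    col_counts = Xw.sum(axis=0).reshape(L, 20)
    col_totals = np.clip(Gw.sum(axis=0), 1e-300, None)  # weighted non-gap per column
    f_raw = col_counts / col_totals[:, None]  # gap-excluded marginals

    f_pair = pair_counts.reshape(L, 20, L, 20) / denom[:, None, :, None]
    c = f_pair - f_raw[:, :, None, None] * f_raw[None, None, :, :]

    if phi_weighting:
        f_reg = (1.0 - pseudocount) * f_raw + pseudocount * q[None, :]
        phi = _phi_weights(f_reg, np.asarray(q, dtype=float))
        c *= phi[:, :, None, None] * phi[None, None, :, :]

    C = np.sqrt(np.einsum("iajb,iajb->ij", c, c))
    C = 0.5 * (C + C.T)  # exact symmetry against floating-point jitter
    return CouplingMatrix(
        C=C,
        pseudocount=pseudocount,
        identity_cutoff=weights.identity_cutoff,
        background=background_id,
    )


def eigendecompose(cm: CouplingMatrix) -> EigenSpectrum:
    """Eigendecomposition with eigenvalues sorted in descending order."""
    vals, vecs = np.linalg.eigh(cm.C)
    order = np.argsort(vals)[::-1]
    return EigenSpectrum(values=vals[order], vectors=vecs[:, order])


def null_spectrum(
    msa: MSA,
    weights: SequenceWeights | None = None,
    n_trials: int = 100,
    seed: int = 0,
    pseudocount: float = 0.03,
    q: np.ndarray | None = None,
    statistic: str = "lambda_max",
) -> NullSpectrum:
    """Null eigenvalue distribution from within-column permutations.

    Each trial independently permutes every column's entries across
    sequences, recomputes the coupling matrix (reusing the input sequence
    weights) and records its leading eigenvalue (``statistic="lambda_max"``,
    default) or its second-largest (``"lambda2"``).  The permutation
    preserves every column's residue composition — and therefore the
    conservation profile — exactly.
    """
    if n_trials < 10:
        raise ValueError("n_trials must be >= 10")
    if statistic not in ("lambda_max", "lambda2"):
        raise ValueError("statistic must be 'lambda_max' or 'lambda2'")
    if weights is None:
        weights = sequence_weights(msa)
    rng = np.random.default_rng(seed)
    codes = msa.codes()
    N, L = codes.shape
    vals = np.empty(n_trials)
    idx = 1 if statistic == "lambda2" else 0
    for t in range(n_trials):
        perm = np.empty_like(codes)
        for j in range(L):
            perm[:, j] = codes[rng.permutation(N), j]
        shuffled = MSA.from_codes(msa.ids, perm, column_map=msa.column_map)
        cm = coupling_matrix(shuffled, weights, pseudocount=pseudocount, q=q)
        ev = np.linalg.eigvalsh(cm.C)
        vals[t] = np.sort(ev)[::-1][idx]
    return NullSpectrum(values=vals, statistic=statistic, n_trials=n_trials)


def significant_modes(
    spec: EigenSpectrum, null_cutoff: float, skip_first: bool = False
) -> int:
    """Count eigenvalues above the null cutoff.

    With ``skip_first=True`` the leading eigenvalue is excluded from the
    count (the classical convention when the conservation mode is not
    represented in the null statistic; unnecessary with the default
    ``lambda_max`` null, which calibrates the conservation mode away).
    The count is stored on ``spec.k_significant``.
    """
    values = spec.values[1:] if skip_first else spec.values
    k = int((values > null_cutoff).sum())
    spec.k_significant = k
    return k


_LOGCOSH_GAUSS = 0.3745232061467120  # E[log cosh X], X ~ N(0, 1)


def _negentropy(sources: np.ndarray) -> float:
    """Summed logcosh negentropy approximation over unit-variance sources."""
    s = sources / sources.std(axis=0, keepdims=True)
    g = np.log(np.cosh(s)).mean(axis=0)
    return float(((g - _LOGCOSH_GAUSS) ** 2).sum())


def extract_sectors(
    spec: EigenSpectrum,
    k: int,
    seed: int = 0,
    loading_quantile: float = 0.95,
    skip_first: bool = False,
    n_restarts: int = 5,
) -> SectorAssignment:
    """Rotate the top-k eigenmodes by ICA and assign positions to sectors.

    The top-k eigenvectors (optionally skipping the first) are unmixed by
    fixed-point ICA (tanh contrast, seeded, tol 1e-6, max 500 iterations).
    Fixed-point iteration can stall in partially mixed solutions, so the
    rotation is restarted ``n_restarts`` times from seeded initializations
    and the solution with the largest total negentropy is kept
    (deterministic for a given seed).  Each component's sign is fixed so
    its largest-magnitude loading is positive.  A Student-t distribution is
    fitted to each component's loadings and positions are assigned to the
    component on which their loading is maximal, retained only when that
    loading exceeds the fitted ``loading_quantile`` quantile.  Sectors are
    renumbered 1..K by descending summed loading.
    """
    L = spec.vectors.shape[0]
    offset = 1 if skip_first else 0
    if not 1 <= k <= L - 1:
        raise ValueError(f"k must be in [1, {L - 1}], got {k}")
    if offset + k > L:
        raise ValueError("k exceeds available eigenmodes")
    V = spec.vectors[:, offset : offset + k]

    if k == 1:
        sources = V / np.linalg.norm(V, axis=0, keepdims=True)
    else:
        best: tuple[float, np.ndarray] | None = None
        for r in range(max(1, n_restarts)):
            ica = FastICA(
                n_components=k,
                fun="logcosh",
                max_iter=500,
                tol=1e-6,
                random_state=(seed * 1000 + r) % (2**31),
                whiten="unit-variance",
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                cand = ica.fit_transform(V)
            obj = _negentropy(cand)
            if best is None or obj > best[0]:
                best = (obj, cand)
        sources = best[1]
        sources = sources / np.linalg.norm(sources, axis=0, keepdims=True)

    # Sign convention: dominant loading of every component is positive.
    for j in range(sources.shape[1]):
        if sources[np.argmax(np.abs(sources[:, j])), j] < 0:
            sources[:, j] *= -1.0

    cutoffs = np.empty(sources.shape[1])
    for j in range(sources.shape[1]):
        df, loc, scale = stats.t.fit(sources[:, j])
        cutoffs[j] = stats.t.ppf(loading_quantile, df, loc=loc, scale=scale)

    best = np.argmax(sources, axis=1)
    best_loading = sources[np.arange(L), best]
    assigned = best_loading > cutoffs[best]

    sector_of: dict[int, int] = {}
    loading: dict[int, float] = {}
    comp_total = np.zeros(sources.shape[1])
    for p in range(L):
        if assigned[p]:
            comp_total[best[p]] += best_loading[p]
    order = np.argsort(comp_total)[::-1]
    rank = {int(c): r + 1 for r, c in enumerate(order) if comp_total[c] > 0}
    for p in range(L):
        if assigned[p] and int(best[p]) in rank:
            sector_of[p] = rank[int(best[p])]
            loading[p] = float(best_loading[p])
    K = len(rank)
    return SectorAssignment(
        sector_of=sector_of,
        loading=loading,
        K=K,
        n_positions=L,
        ica_loadings=sources,
    )


def boundary_profile(assign: SectorAssignment, w: int = 30) -> BoundaryProfile:
    """Score every inter-column cut for how cleanly it separates sectors.

    For cut position p and sector k, let ``n_k_left``/``n_k_right`` count
    sector-k members within w columns left/right of the cut.  The
    separation term

    ``sep_p = 1 - sum_k min(n_k_left, n_k_right) / (sum_k (n_k_left + n_k_right) / 2)``

    is 1 when each sector's windowed members lie entirely on one side and
    tends to 0 when every sector straddles the cut evenly.  It is
    multiplied by a balance term ``min(left_total, right_total) /
    (total / 2)`` so that cuts whose window sees sector members on only
    one side (which separate nothing) score 0 rather than 1; a genuine
    boundary — one sector ending, another beginning — scores 1.  Cuts with
    no sector members in the window score 0.  Local maxima of the profile
    are reported.
    """
    if w < 1:
        raise ValueError("window must be >= 1")
    L = assign.n_positions
    member = np.zeros((assign.K + 1, L))
    for p, k in assign.sector_of.items():
        member[k, p] = 1.0
    scores = np.zeros(L)
    for p in range(1, L):
        lo, hi = max(0, p - w), min(L, p + w)
        n_left = member[1:, lo:p].sum(axis=1)
        n_right = member[1:, p:hi].sum(axis=1)
        total = (n_left + n_right).sum()
        if total == 0:
            continue
        straddle = np.minimum(n_left, n_right).sum()
        separation = 1.0 - straddle / (total / 2.0)
        balance = min(n_left.sum(), n_right.sum()) / (total / 2.0)
        scores[p] = separation * balance
    maxima = [
        p
        for p in range(1, L)
        if scores[p] > 0
        and scores[p] >= scores[p - 1]
        and (p == L - 1 or scores[p] > scores[p + 1])
    ]
    return BoundaryProfile(scores=scores, window=w, maxima=maxima)


def sca_pipeline(
    msa: MSA,
    identity_cutoff: float = 0.8,
    pseudocount: float = 0.03,
    n_trials: int = 100,
    seed: int = 0,
    loading_quantile: float = 0.95,
    boundary_window: int = 30,
    q: np.ndarray | None = None,
):
    """Run weights -> coupling -> null -> sectors -> boundary in one call.

    Returns a dict with keys ``weights, coupling, spectrum, null, k,
    sectors, boundary`` (``sectors``/``boundary`` are None when no mode is
    significant).  Deterministic for fixed inputs and seed.
    """
    weights = sequence_weights(msa, identity_cutoff=identity_cutoff)
    cm = coupling_matrix(msa, weights, pseudocount=pseudocount, q=q)
    spec = eigendecompose(cm)
    null = null_spectrum(
        msa, weights, n_trials=n_trials, seed=seed, pseudocount=pseudocount, q=q
    )
    k = significant_modes(spec, null.percentile(95.0))
    sectors = None
    boundary = None
    if k >= 1:
        sectors = extract_sectors(
            spec, min(k, msa.L - 1), seed=seed, loading_quantile=loading_quantile
        )
        boundary = boundary_profile(sectors, w=boundary_window)
    return {
        "weights": weights,
        "coupling": cm,
        "spectrum": spec,
        "null": null,
        "k": k,
        "sectors": sectors,
        "boundary": boundary,
    }


def write_coupling_matrix(cm: CouplingMatrix, tsv_path: str | Path, meta_path: str | Path) -> None:
    np.savetxt(tsv_path, cm.C, delimiter="\t", fmt="%.10g")
    meta = {
        "pseudocount": cm.pseudocount,
        "identity_cutoff": cm.identity_cutoff,
        "background": cm.background,
        "L": cm.L,
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2) + "\n")


def write_sector_report(
    assign: SectorAssignment,
    msa: MSA,
    consensus_seq: str,
    path: str | Path,
) -> None:
    """TSV: 1-based original column, consensus residue, sector id, loading."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh, delimiter="\t")
        wr.writerow(["column", "consensus", "sector", "loading"])
        for p in range(assign.n_positions):
            sec = assign.sector_of.get(p, "")
            load = f"{assign.loading[p]:.6f}" if p in assign.loading else ""
            wr.writerow([int(msa.column_map[p]) + 1, consensus_seq[p], sec, load])


def write_boundary_profile(profile: BoundaryProfile, msa: MSA, path: str | Path) -> None:
    """TSV: 1-based cut position (before this original column), score."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh, delimiter="\t")
        wr.writerow(["cut_before_column", "score"])
        for p in range(1, len(profile.scores)):
            wr.writerow([int(msa.column_map[p]) + 1, f"{profile.scores[p]:.6f}"])
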