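# Methods

This note documents the models and procedures implemented in `pksforge`,
the parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical choices made where the
design was genuinely open.

## Alignment preprocessing

Alignments (aligned FASTA or Stockholm) are restricted to the 20 canonical
residues plus gap; every non-canonical character maps to gap. Filtering
drops sequences with a gap fraction above `max_seq_gap` (default 0.2),
then columns above `max_col_gap` (default 0.2); a `column_map` carries
surviving columns back to the original numbering and composes across
repeated filtering. Sequence weights follow the standard redundancy
correction `w_s = 1 / |{t : identity(s, t) ≥ h}|` with identity cutoff
`h = 0.8` (identity counts identical alignment symbols, gap included).
These defaults are conventional coupling-analysis values and are
configurable everywhere; nothing downstream assumes them.

Column frequencies are weighted and pseudocount-regularized,
`f_ia = (1−λ)·c_ia/M_eff + λ·q_a` with `λ = 0.03`. Gaps are not part of
the 20-residue simplex: the gap share is carried separately, and the
conservation profile `D_i = Σ_a f_ia ln(f_ia/q_a)` (nats) is evaluated on
gap-renormalized frequencies so `D_i ≥ 0` holds for gappy columns too.
The default background `q` is the amino-acid composition of a large
nonredundant protein database (bundled, pinned); a uniform 1/20 option
exists for sensitivity analysis.

## Coupling matrix

For columns *i, j* the raw covariance `c_ij^ab = f_ij^ab − f_ia f_jb` is
computed from **unregularized** weighted frequencies restricted to
sequences non-gapped at the relevant columns; the pseudocount enters only
through the conservation weight
`φ_ia = ln[f̃_ia(1−q_a)/((1−f̃_ia)q_a)]` (the binary relative-entropy
gradient), with `f̃` regularized and clipped to `[1e-12, 1−1e-12]`. The
scalar coupling is the Frobenius norm `C_ij = ||φ_ia φ_jb c_ij^ab||_F`,
symmetric and entrywise nonnegative. Keeping the covariance term
unregularized makes two exact identities hold that a regularized pair
term would break: constant columns carry exactly zero coupling, and
independent columns converge to zero coupling as N grows. An unweighted
(`φ ≡ 1`) variant is available via `phi_weighting=False`.

## Significance and the permutation null

The null permutes each column's entries independently across sequences:
inter-column covariance is destroyed while every column's composition —
and hence the conservation profile and the matrix diagonal — is preserved
exactly. Each of `n_trials` (default 100) permutations yields a coupling
matrix whose **largest** eigenvalue is recorded; the significance cutoff
is the 95th percentile and `significant_modes` counts real eigenvalues
above it. Because a conservation-driven leading mode survives the
permutation, it appears in the null statistic as well and calibrates
itself out of the comparison; no mode needs to be discarded a priori.
The classical convention — compare against the second null eigenvalue and
always exclude the leading "conservation" mode from the count — is
retained behind `statistic="lambda2"` / `skip_first=True`, but it is not
the default: on data whose leading modes are the coevolving networks
themselves (as in the planted-sector simulations below) it silently
discards one real sector dimension.

Sequence weights are computed once on the real alignment and reused for
the permuted replicas.

## Sector extraction

The top-k eigenvectors are unmixed by fixed-point ICA (tanh contrast,
tolerance 1e-6, max 500 iterations, seeded). Fixed-point iteration can
stall at partially mixed fixed points (e.g. a component equal to the sum
of two sectors), so the rotation restarts from `n_restarts = 5` seeded
initializations and the solution with the largest summed logcosh
negentropy is kept; the procedure is deterministic for a given seed.
Each component's sign is fixed so its largest-magnitude loading is
positive. A Student-t distribution is fitted to each component's
loadings, and a position joins the component on which it loads most
strongly when that loading exceeds the fitted `loading_quantile`
(default 0.95) quantile — a heavy-tail cutoff that adapts to each
component's null width. Sectors are renumbered by descending summed
loading, so sector 1 is the most significant network.

Identifiability caveat: ICA separates sparse, independent loading
patterns. When planted sectors jointly cover about half of all columns,
the balanced "sum of sectors" direction becomes an extremum of the
contrast function and the rotation is no longer reliable; real sectors
(and the simulation studies here) occupy a minority of positions, where
separation is clean.

## Boundary profile

For every inter-column cut p, with `n_k^left/right` counting sector-k
members within `w` columns (default 30) of the cut,

```
b_p = [1 − Σ_k min(n_k^left, n_k^right) / (Σ_k (n_k^left+n_k^right)/2)]
      × [min(Σ_k n_k^left, Σ_k n_k^right) / (Σ_k (n_k^left+n_k^right)/2)]
```

The first factor (separation) is 1 when no sector straddles the cut; the
second (balance) discounts cuts whose window sees members on one side
only, which separate nothing. A clean boundary — one sector ending where
another begins — scores 1; a cut through the middle of a sector scores 0.
The window default reflects that natural recombination sites could only
be localized to within roughly a hundred residues by raw similarity, so
the profile should integrate evidence over a few dozen columns. The
boundary score is this package's own operationalization of "boundary
between sectors"; no standard quantitative definition exists.

## PKS architecture and design

Proteins are sequences plus sorted, non-overlapping domain spans
(0-based half-open internally; 1-based inclusive in all files and
reports). Degenerate motif search matches literal positions with a
bounded substitution count (wildcards free); overlapping hits are
resolved greedily left-to-right, fewest mismatches first. The exchange
unit boundary is the residue immediately after the boundary motif's
terminal W — the convention used for all designs, adjustable by an
offset. Unit delimitation uses `max_mismatch = 0` (precision over recall
at fusion sites); genome-scale motif scanning defaults to 1.

Chimera plans cut an acceptor at a motif-anchored fusion site, splice in
donor exchange units (motif-anchored in their sources unless forced) and
append a terminal segment; deletion plans remove a contiguous run of
units. Deleting units and reinserting them at the same junction
reconstructs the wild type byte-exactly. Substrate tags (β-keto,
β-hydroxy, enoyl, reduced) are user-supplied chemistry labels; a
mismatch annotates the design report but never blocks it, since
substrate-mismatched chimeras remain productive at reduced titers.
Product formulas follow collinearity with integer element deltas
(extension +C2H2O, KR +H2, DH −H2O, halogenation +Cl−H; offload as free
acid +H2O or lactone ±0). β-branching, methylation and other trans-AT
chemistries are representable through the configurable delta table but
ship without defaults. KS substrate specificity is not predicted from
sequence, and no DNA-level construct design is attempted.

Pairwise similarity drop-off scans (for localizing natural recombination)
use a global affine-gap alignment (BLOSUM62, open −11, extend −1) when
inputs differ in length, a rolling identity window (default 30), and
report a changepoint only when the left-minus-right mean identity drop
exceeds 0.2 — below that floor, unrelated-sequence noise produces
spurious maxima.

## Mass spectrometry

Atomic masses and isotope abundances are pinned in the package so every
number is bit-stable. Monoisotopic masses sum lightest-isotope masses;
adduct m/z is `(M + Δ_adduct − z·m_e)/|z|` with singly charged positive
adducts (H+, NH4+, Na+) shipped by default. Isotope envelopes convolve
per-element isotopologue distributions and aggregate peaks by total
neutron excess with abundance-weighted centroid masses — the picture a
unit-resolution centroided spectrum gives. Abundances are exact fractions
of the full distribution; threshold truncation does not renormalize, so
peak ratios are unaffected.

The chlorine tag is scored on the summed M and M+2 (=m/z + 1.99705)
intensities within ±0.5 min of the feature's EIC apex (m/z tolerance
0.005 Da). For a candidate of known formula, the predicted M+2
contribution of the non-chlorine atoms (¹³C pairs, ¹⁸O, ³⁴S) is
subtracted first — for a C24 polyketide this baseline is ≈ 0.047 and
would otherwise bias the ratio. The residual excess is compared to the
n-Cl expectations (n × 0.3200 for n = 0..3): `n_cl_best` is the nearest
hypothesis and the score is a Gaussian kernel
`exp(−(excess − 0.3200)²/2σ²)` against the single-Cl tag with σ = 0.1,
wide enough to absorb envelope bias for unknown formulas yet leaving a
Cl-free organic (excess ≈ 0) at a score below 0.01.

## Synthetic data

The alignment generator plants a latent-spin sector model: per sequence
and sector a hidden Bernoulli(0.5) state selects one of two
position-specific residues, emitted with probability ρ (coupling
strength, default 0.9); non-sector positions emit a position-specific
consensus residue with probability c (conservation backbone, default
0.3, a moderate conservation level) and a background draw otherwise.
Gaps are i.i.d. (default rate 0), with optional planted gap-heavy
columns for filter testing. The model reproduces exactly the covariance
structure coupling analysis assumes — independent coevolving networks on
a conserved backbone — but **not** phylogenetic correlation between
sequences, compositional biases along the sequence, or indel structure;
recovery results on it bound what the pipeline can do when its model
assumptions hold, not performance on arbitrary real alignments.

PKS protein stubs use realistic domain lengths (KS 420, FSD 120, KR 180,
ACP 80, ...) with NAHVILEE embedded 30 residues before each KS C-terminus
and LPTYPF+x₅+W as the last 12 residues of each FSD. LC-MS runs place
Gaussian elution profiles (σ 0.05 min, scan spacing 0.02 min) of
isotope envelopes with multiplicative log-normal noise (default 5%) and
sparse flat noise peaks; chromatographic tailing and isotope fine
structure are not modelled.

## Study sizes

The validation studies run at sizes chosen to exercise the estimators
well inside their operating regime while keeping a full run at minutes
on a single CPU: sector recovery at N=400, L=120 with three 15-position
sectors over 5 seeds (null with 20 permutation trials); boundary
localization at N=300 with two abutting 15-column blocks; null
calibration over 20 sector-free alignments at N=80, L=40 with 100 trials
each; oracle comparisons on 25 alignments (≤12 columns × 30 sequences)
and 20 random formulas up to C30H50N2O10Cl2; 50 simulated proteins for
motif/unit recovery and 20 random deletion round-trips.

## Known limitations

- Sector extraction assumes sectors are sparse relative to alignment
  length (see the ICA identifiability caveat above).
- The permutation null preserves conservation but not phylogenetic
  relatedness; on strongly clade-structured alignments the significance
  cutoff will be liberal. The per-run false-positive rate of the 95th-
  percentile rule is ~5% by construction.
- Product prediction is validated on relative formula deltas (e.g. the
  KR-vs-DH pair differing by exactly H2O), not on absolute masses of any
  particular pathway's starter unit.
- The FSD span is treated operationally as whatever lies between the
  annotated KS end and the boundary motif; no structural definition is
  attempted.
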