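import numpy as np
import pytest

from pksforge.background import background_frequencies
from pksforge.msa import MSA, sequence_weights
from pksforge.sca import (
    SectorAssignment,
    boundary_profile,
    coupling_matrix,
    eigendecompose,
    extract_sectors,
    null_spectrum,
    sca_pipeline,
    significant_modes,
)
from pksforge.simulate import SectorSpec, simulate_alignment

from .conftest import random_msa
from .oracles import coupling_oracle


class TestCouplingMatrix:
    def test_conserved_columns_carry_no_coupling(self):
        msa = MSA(ids=list("abcd"), seqs=["AC"] * 4, column_map=np.arange(2))
        w = sequence_weights(msa, 0.8)
        cm = coupling_matrix(msa, w)
        assert cm.C[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        q = background_frequencies()
        for _ in range(5):
            msa = random_msa(rng, n=20, length=6, gap_rate=0.1)
            w = sequence_weights(msa, 0.7)
            cm = coupling_matrix(msa, w, pseudocount=0.03, q=q)
            expected = coupling_oracle(msa.codes(), w.w, q, 0.03)
            assert np.max(np.abs(cm.C - expected)) < 1e-10

    def test_symmetric_nonnegative(self, rng):
        for _ in range(5):
            msa = random_msa(rng, n=25, length=10, gap_rate=0.15)
            w = sequence_weights(msa, 0.8)
            cm = coupling_matrix(msa, w)
            assert np.all(cm.C >= 0)
            assert np.max(np.abs(cm.C - cm.C.T)) < 1e-12
            assert np.all(np.isfinite(np.diag(cm.C)))

    def test_independent_columns_below_null(self):
        msa, _ = simulate_alignment(2000, 12, [], seed=11)
        w = sequence_weights(msa)
        cm = coupling_matrix(msa, w)
        null = null_spectrum(msa, w, n_trials=20, seed=12)
        off = cm.C[~np.eye(cm.L, dtype=bool)]
        # off-diagonal couplings of independent columns sit inside the null
        assert off.max() <= np.percentile(null.values, 99)

    def test_all_gap_column_errors(self):
        msa = MSA(ids=["a", "b"], seqs=["A-", "C-"], column_map=np.arange(2))
        w = sequence_weights(msa, 0.8)
        with pytest.raises(ValueError, match="all-gap"):
            coupling_matrix(msa, w)


class TestEigenSpectrum:
    def test_descending_orthonormal(self, rng):
        msa = random_msa(rng, n=30, length=15, gap_rate=0.05)
        w = sequence_weights(msa, 0.8)
        spec = eigendecompose(coupling_matrix(msa, w))
        assert np.all(np.diff(spec.values) <= 1e-12)
        gram = spec.vectors.T @ spec.vectors
        assert np.max(np.abs(gram - np.eye(msa.L))) < 1e-8


class TestNullSpectrum:
    def test_deterministic_under_seed(self, rng):
        msa = random_msa(rng, n=25, length=10, gap_rate=0.0)
        w = sequence_weights(msa, 0.8)
        a = null_spectrum(msa, w, n_trials=10, seed=4)
        b = null_spectrum(msa, w, n_trials=10, seed=4)
        assert np.array_equal(a.values, b.values)
        assert len(a.values) == 10

    def test_null_values_positive(self, rng):
        msa = random_msa(rng, n=25, length=10, gap_rate=0.0)
        w = sequence_weights(msa, 0.8)
        null = null_spectrum(msa, w, n_trials=10, seed=4)
        assert np.all(null.values > 0)

    def test_planted_coupling_detected_shuffled_not(self):
        sectors = [SectorSpec(positions=tuple(range(20, 35)))]
        msa, _ = simulate_alignment(300, 60, sectors, seed=21)
        w = sequence_weights(msa)
        spec = eigendecompose(coupling_matrix(msa, w))
        null = null_spectrum(msa, w, n_trials=20, seed=22)
        assert spec.values[0] > null.percentile(95)
        # destroy the coupling by an independent within-column shuffle
        rng = np.random.default_rng(23)
        codes = msa.codes().copy()
        for j in range(msa.L):
            codes[:, j] = codes[rng.permutation(msa.N), j]
        shuffled = MSA.from_codes(msa.ids, codes)
        w2 = sequence_weights(shuffled)
        spec2 = eigendecompose(coupling_matrix(shuffled, w2))
        null2 = null_spectrum(shuffled, w2, n_trials=20, seed=24)
        assert significant_modes(spec2, null2.percentile(95)) == 0


class TestSignificantModes:
    def test_counts_against_cutoff(self):
        spec = eigendecompose(
            coupling_matrix(
                MSA(ids=list("abcd"), seqs=["ACDE", "ACDF", "GCDE", "GCDF"], column_map=np.arange(4)),
                sequence_weights(
                    MSA(ids=list("abcd"), seqs=["ACDE", "ACDF", "GCDE", "GCDF"], column_map=np.arange(4)),
                    0.8,
                ),
            )
        )
        assert significant_modes(spec, np.inf) == 0
        L = len(spec.values)
        assert significant_modes(spec, -1.0) == L
        assert significant_modes(spec, -1.0, skip_first=True) == L - 1
        assert spec.k_significant == L - 1

    def test_planted_sectors_reach_three_modes(self):
        rng = np.random.default_rng(9)
        pos = rng.permutation(120)
        sectors = [
            SectorSpec(positions=tuple(int(p) for p in sorted(pos[i * 15 : (i + 1) * 15])))
            for i in range(3)
        ]
        msa, _ = simulate_alignment(400, 120, sectors, seed=9)
        w = sequence_weights(msa)
        spec = eigendecompose(coupling_matrix(msa, w))
        null = null_spectrum(msa, w, n_trials=20, seed=10)
        assert significant_modes(spec, null.percentile(95)) >= 3


class TestExtractSectors:
    def _planted(self, n_sectors, seed, L=120, N=400, size=15, rho=0.9):
        rng = np.random.default_rng(seed)
        pos = rng.permutation(L)
        sectors = [
            SectorSpec(
                positions=tuple(int(p) for p in sorted(pos[i * size : (i + 1) * size])),
                rho=rho,
            )
            for i in range(n_sectors)
        ]
        msa, truth = simulate_alignment(N, L, sectors, seed=seed)
        return msa, truth

    def test_single_sector_recovery(self):
        sectors = [SectorSpec(positions=tuple(range(30, 42)))]  # 12 positions
        msa, truth = simulate_alignment(300, 80, sectors, seed=31)
        w = sequence_weights(msa)
        spec = eigendecompose(coupling_matrix(msa, w))
        assign = extract_sectors(spec, 1, seed=31)
        recovered = set(assign.members(1))
        assert len(recovered & set(truth.sectors[0])) >= 10

    def test_no_position_in_two_sectors(self):
        msa, _ = self._planted(3, seed=33)
        w = sequence_weights(msa)
        spec = eigendecompose(coupling_matrix(msa, w))
        assign = extract_sectors(spec, 3, seed=33)
        all_members = [p for k in range(1, assign.K + 1) for p in assign.members(k)]
        assert len(all_members) == len(set(all_members))

    def test_three_sector_jaccard(self):
        from scipy.optimize import linear_sum_assignment

        msa, truth = self._planted(3, seed=35)
        w = sequence_weights(msa)
        spec = eigendecompose(coupling_matrix(msa, w))
        assign = extract_sectors(spec, 3, seed=35)
        truth_sets = [set(s) for s in truth.sectors]
        ext = [set(assign.members(k + 1)) for k in range(assign.K)]
        J = np.array(
            [[len(t & e) / len(t | e) for e in ext] for t in truth_sets]
        )
        ri, ci = linear_sum_assignment(-J)
        assert all(J[i, j] >= 0.8 for i, j in zip(ri, ci))

    def test_k_exceeding_modes_errors(self):
        msa, _ = simulate_alignment(50, 10, [], seed=1)
        w = sequence_weights(msa)
        spec = eigendecompose(coupling_matrix(msa, w))
        with pytest.raises(ValueError, match="k must be"):
            extract_sectors(spec, 10, seed=0)


class TestBoundaryProfile:
    def _assign(self, sectors, L):
        sector_of = {}
        loading = {}
        for k, members in enumerate(sectors, start=1):
            for p in members:
                sector_of[p] = k
                loading[p] = 1.0
        return SectorAssignment(
            sector_of=sector_of,
            loading=loading,
            K=len(sectors),
            n_positions=L,
            ica_loadings=np.zeros((L, len(sectors))),
        )

    def test_clean_split_scores_one(self):
        assign = self._assign([range(10, 20), range(20, 30)], 40)
        bp = boundary_profile(assign, w=20)
        assert bp.scores[20] == pytest.approx(1.0)
        assert bp.argmax == 20

    def test_interleaved_sector_scores_zero_at_center(self):
        assign = self._assign([range(0, 40)], 40)
        bp = boundary_profile(assign, w=20)
        assert bp.scores[20] == pytest.approx(0.0)

    def test_scores_within_unit_interval(self, rng):
        members = rng.choice(60, size=20, replace=False)
        assign = self._assign([members[:10], members[10:]], 60)
        bp = boundary_profile(assign, w=15)
        assert np.all(bp.scores >= 0) and np.all(bp.scores <= 1)

    def test_planted_boundary_localized(self):
        sectors = [
            SectorSpec(positions=tuple(range(45, 60))),
            SectorSpec(positions=tuple(range(60, 75))),
        ]
        msa, _ = simulate_alignment(300, 120, sectors, seed=41)
        res = sca_pipeline(msa, n_trials=10, seed=41)
        assert res["boundary"] is not None
        assert abs(res["boundary"].argmax - 60) <= 5


def test_pipeline_deterministic():
    """Identical inputs and seeds give byte-identical sector reports."""
    sectors = [SectorSpec(positions=tuple(range(10, 25)))]
    msa, _ = simulate_alignment(150, 60, sectors, seed=51)
    outs = []
    for _ in range(2):
        res = sca_pipeline(msa, n_trials=10, seed=51)
        assign = res["sectors"]
        outs.append(
            (
                res["k"],
                tuple(sorted(assign.sector_of.items())),
                tuple(sorted((p, round(v, 12)) for p, v in assign.loading.items())),
            )
        )
    assert outs[0] == outs[1]
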