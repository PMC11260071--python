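import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pksforge.background import background_frequencies
from pksforge.msa import (
    MSA,
    column_frequencies,
    consensus,
    filter_alignment,
    positional_conservation,
    read_alignment,
    sequence_weights,
    write_alignment,
)
from pksforge.simulate import simulate_alignment

from .conftest import random_msa
from .oracles import sequence_weight_oracle


class TestReadAlignment:
    def test_identity_read(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACDEFGHIKL\n>b\nACDEFGHIKM\n>c\nACDEFGH-KL\n")
        msa = read_alignment(p)
        assert msa.L == 10 and msa.N == 3
        assert list(msa.column_map) == list(range(10))

    def test_noncanonical_maps_to_gap(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACXEF\n>b\nacdef\n")
        msa = read_alignment(p)
        assert msa.seqs[0] == "AC-EF"
        assert msa.seqs[1] == "ACDEF"  # lowercase canonical uppercased

    def test_ragged_names_offender(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">ok\nACDEFGHIKL\n>short\nACDEFGHIK\n")
        with pytest.raises(ValueError, match="short"):
            read_alignment(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_alignment(p)

    def test_stockholm_roundtrip(self, tmp_path):
        p = tmp_path / "a.sto"
        p.write_text(
            "# STOCKHOLM 1.0\nseqA  ACDEF\nseqB  AC-EF\n//\n"
        )
        msa = read_alignment(p, "stockholm")
        assert msa.ids == ["seqA", "seqB"]
        assert msa.seqs[1] == "AC-EF"


class TestFilterAlignment:
    def test_gappy_column_removed(self):
        seqs = ["A-CD", "A-CD", "A-CD", "AACD"]
        msa = MSA(ids=list("abcd"), seqs=seqs, column_map=np.arange(4))
        out = filter_alignment(msa, max_col_gap=0.5, max_seq_gap=1.0)
        assert out.L == 3
        assert list(out.column_map) == [0, 2, 3]

    def test_gap_free_identity(self, toy_msa):
        clean = MSA(ids=["a", "b"], seqs=["ACDE", "ACDF"], column_map=np.arange(4))
        out = filter_alignment(clean, 0.0, 0.0)
        assert out.seqs == clean.seqs

    def test_planted_gap_columns_removed(self):
        gap_cols = [3, 17, 40, 77, 95]
        msa, truth = simulate_alignment(
            60, 100, [], seed=5, gap_columns=gap_cols, gap_column_rate=0.9
        )
        out = filter_alignment(msa, max_col_gap=0.2, max_seq_gap=1.0)
        removed = sorted(set(range(100)) - set(out.column_map))
        assert removed == truth.gap_columns

    def test_idempotent(self, rng):
        msa = random_msa(rng, n=30, length=40, gap_rate=0.2)
        once = filter_alignment(msa, 0.3, 0.5)
        twice = filter_alignment(once, 0.3, 0.5)
        assert once.seqs == twice.seqs
        assert list(once.column_map) == list(twice.column_map)

    def test_column_map_composes(self, rng):
        msa = random_msa(rng, n=30, length=50, gap_rate=0.25)
        loose = filter_alignment(msa, 0.5, 1.0)
        tight = filter_alignment(loose, 0.15, 1.0)
        direct = filter_alignment(msa, 0.15, 1.0)
        # tight-after-loose column_map points at original coordinates
        assert set(tight.column_map) <= set(loose.column_map)
        assert list(tight.column_map) == list(direct.column_map)

    def test_fully_filtered_errors(self):
        msa = MSA(ids=["a", "b"], seqs=["--", "A-"], column_map=np.arange(2))
        with pytest.raises(ValueError, match="fully filtered"):
            filter_alignment(msa, max_col_gap=0.0, max_seq_gap=1.0)


class TestSequenceWeights:
    def test_identical_sequences_share_weight(self):
        msa = MSA(ids=list("abcd"), seqs=["ACDE"] * 4, column_map=np.arange(4))
        w = sequence_weights(msa, 0.8)
        assert np.allclose(w.w, 0.25)
        assert w.m_eff == pytest.approx(1.0)

    def test_dissimilar_sequences_unit_weight(self):
        msa = MSA(
            ids=list("abcd"),
            seqs=["AAAA", "CCCC", "DDDD", "EEEE"],
            column_map=np.arange(4),
        )
        w = sequence_weights(msa, 0.8)
        assert np.allclose(w.w, 1.0)
        assert w.m_eff == pytest.approx(4.0)

    def test_matches_brute_force_oracle(self, rng):
        msa = random_msa(rng, n=10, length=12, gap_rate=0.1)
        w = sequence_weights(msa, 0.6)
        expected = sequence_weight_oracle(msa.seqs, 0.6)
        assert np.allclose(w.w, expected)


class TestColumnFrequencies:
    def test_single_residue_column(self):
        msa = MSA(ids=["a"], seqs=["AAAA"], column_map=np.arange(4))
        w = sequence_weights(msa, 0.8)
        prof = column_frequencies(msa, w, pseudocount=0.0)
        assert np.allclose(prof.freqs[:, 0], 1.0)

    def test_pure_prior_limit(self, toy_msa):
        w = sequence_weights(toy_msa, 0.8)
        q = background_frequencies()
        prof = column_frequencies(toy_msa, w, pseudocount=1.0, q=q)
        assert np.allclose(prof.freqs, np.tile(q, (toy_msa.L, 1)))

    def test_hand_counted(self):
        # 3 sequences, unequal weights arise from identity clustering
        msa = MSA(ids=list("abc"), seqs=["AC", "AC", "AD"], column_map=np.arange(2))
        w = sequence_weights(msa, 0.9)  # a,b identical -> 0.5 each; c -> 1
        prof = column_frequencies(msa, w, pseudocount=0.0)
        # column 0: all A with total weight 2 -> f_A = 1
        assert prof.freqs[0, 0] == pytest.approx(1.0)
        # column 1: C weight 1, D weight 1 over M_eff 2
        assert prof.freqs[1, 1] == pytest.approx(0.5)
        assert prof.freqs[1, 2] == pytest.approx(0.5)

    @given(lam=st.floats(min_value=0.0, max_value=1.0))
    def test_normalization_invariant(self, lam):
        rng = np.random.default_rng(7)
        msa = random_msa(rng, n=15, length=10, gap_rate=0.15)
        w = sequence_weights(msa, 0.8)
        prof = column_frequencies(msa, w, pseudocount=lam)
        total = prof.freqs.sum(axis=1) + (1 - lam) * prof.gap_frac
        assert np.allclose(total, 1.0, atol=1e-9)


class TestConservation:
    def test_background_column_is_zero(self):
        q = background_frequencies()
        from pksforge.msa import ColumnProfile

        prof = ColumnProfile(
            freqs=np.tile(q, (3, 1)), gap_frac=np.zeros(3), pseudocount=0.0, q=q
        )
        cons = positional_conservation(prof)
        assert np.allclose(cons.D, 0.0, atol=1e-12)

    def test_conserved_column_uniform_background(self):
        msa = MSA(ids=["a", "b"], seqs=["AA", "AA"], column_map=np.arange(2))
        w = sequence_weights(msa, 0.8)
        q = background_frequencies("uniform")
        prof = column_frequencies(msa, w, pseudocount=0.0, q=q)
        cons = positional_conservation(prof)
        assert np.allclose(cons.D, np.log(20.0), atol=1e-9)

    def test_matches_direct_summation(self, rng):
        msa = random_msa(rng, n=20, length=8, gap_rate=0.1)
        w = sequence_weights(msa, 0.8)
        prof = column_frequencies(msa, w, pseudocount=0.03)
        cons = positional_conservation(prof)
        f = prof.residue_simplex()
        q = prof.q
        direct = np.array(
            [
                sum(f[i, a] * np.log(f[i, a] / q[a]) for a in range(20) if f[i, a] > 0)
                for i in range(msa.L)
            ]
        )
        assert np.allclose(cons.D, direct, atol=1e-12)

    def test_row_duplication_invariance(self, rng):
        """Duplicating every sequence leaves D unchanged once reweighted."""
        msa = random_msa(rng, n=10, length=12, gap_rate=0.0)
        dup = MSA.from_codes(
            msa.ids + [i + "_dup" for i in msa.ids],
            np.vstack([msa.codes(), msa.codes()]),
        )
        w1 = sequence_weights(msa, 0.9)
        w2 = sequence_weights(dup, 0.9)
        d1 = positional_conservation(column_frequencies(msa, w1)).D
        d2 = positional_conservation(column_frequencies(dup, w2)).D
        assert np.allclose(d1, d2, atol=1e-12)

    def test_zero_background_errors(self, toy_msa):
        w = sequence_weights(toy_msa, 0.8)
        prof = column_frequencies(toy_msa, w)
        bad = np.zeros(20)
        bad[0] = 1.0
        with pytest.raises(ValueError, match="strictly positive"):
            positional_conservation(prof, q=bad)


class TestConsensus:
    def test_dominant_residues(self):
        msa = MSA(
            ids=list("abc"), seqs=["ACD", "ACD", "ACE"], column_map=np.arange(3)
        )
        w = sequence_weights(msa, 0.99)
        assert consensus(msa, w) == "ACD"

    def test_alphabetical_tie_break(self):
        msa = MSA(ids=["a", "b"], seqs=["CA", "AC"], column_map=np.arange(2))
        w = sequence_weights(msa, 0.99)
        assert consensus(msa, w) == "AA"

    def test_planted_motif_in_consensus(self):
        from pksforge.simulate import simulate_pks_protein

        # Build an alignment of noisy copies of a motif-bearing segment.
        prot, truth = simulate_pks_protein("KS-ACP", seed=3)
        start = truth.motifs["NAHVILEE"][0]
        segment = prot.sequence[start - 6 : start + 14]
        rng = np.random.default_rng(0)
        seqs = []
        for _ in range(40):
            s = list(segment)
            for pos in range(len(s)):
                if rng.random() < 0.3:
                    s[pos] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)]
            seqs.append("".join(s))
        msa = MSA(
            ids=[f"v{i}" for i in range(40)],
            seqs=seqs,
            column_map=np.arange(len(segment)),
        )
        w = sequence_weights(msa, 0.9)
        assert "NAHVILEE" in consensus(msa, w)


def test_alignment_write_read_roundtrip(tmp_path, rng):
    msa = random_msa(rng, n=8, length=20, gap_rate=0.1)
    p = tmp_path / "out.fasta"
    write_alignment(msa, p)
    back = read_alignment(p)
    assert back.seqs == msa.seqs and back.ids == msa.ids
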