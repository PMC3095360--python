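"""Alignment kernels against brute-force enumeration and EMBOSS semantics."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from homoeolog.pairwise_align import (AlignmentParams, global_align, local_align,
                                      identity_and_similarity,
                                      sliding_identity_profile, evalue,
                                      karlin_altschul_params)
from oracles import brute_force_global_score, brute_force_local_score

DNA = st.text(alphabet="ACGT", min_size=1, max_size=7)


class TestGlobalAlign:
    def test_identical_sequences_full_identity(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.identity_pct == 100.0
        assert aln.score == 20.0

    def test_single_mismatch_identity(self):
        assert global_align("ACGT", "ACGA").identity_pct == 75.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_gap_cost_is_emboss_convention(self):
        # aligning ACGTACGT vs ACGT forces a 4-gap: 4*5 - (10 + 3*0.5)
        aln = global_align("ACGTACGT", "ACGT")
        assert aln.score == pytest.approx(20.0 - 11.5)

    @given(a=DNA, b=DNA)
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_score_matches_enumeration(self, a, b):
        assert global_align(a, b).score == pytest.approx(
            brute_force_global_score(a, b))

    @given(a=DNA, b=DNA)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_identity_symmetric_under_swap(self, a, b):
        assert global_align(a, b).identity_pct == pytest.approx(
            global_align(b, a).identity_pct)

    def test_no_gap_gap_columns(self):
        rnd = random.Random(5)
        for _ in range(20):
            a = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(3, 30)))
            b = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(3, 30)))
            aln = global_align(a, b)
            assert all(not (x == "-" and y == "-")
                       for x, y in zip(aln.aligned_a, aln.aligned_b))
            assert aln.aligned_a.replace("-", "") == a
            assert aln.aligned_b.replace("-", "") == b

    def test_agrees_with_biopython_aligner(self):
        # independent implementation cross-check (same scoring convention)
        from Bio import Align
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 5.0
        aligner.mismatch_score = -4.0
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        rnd = random.Random(11)
        for _ in range(25):
            a = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(5, 40)))
            b = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(5, 40)))
            assert global_align(a, b).score == pytest.approx(aligner.score(a, b))


class TestLocalAlign:
    def test_identical_sequences_span_full_length(self):
        aln = local_align("ACGTACGT", "ACGTACGT")
        assert aln.identity_pct == 100.0
        assert len(aln) == 8

    def test_no_positive_pair_gives_empty_alignment(self):
        aln = local_align("AAAA", "TTTT")
        assert aln.score == 0.0
        assert len(aln.aligned_a) == 0

    @given(a=st.text(alphabet="ACGT", min_size=1, max_size=6),
           b=st.text(alphabet="ACGT", min_size=1, max_size=6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_score_matches_substring_enumeration(self, a, b):
        assert local_align(a, b).score == pytest.approx(
            brute_force_local_score(a, b))


class TestIdentitySimilarity:
    def test_protein_self_alignment(self, params):
        aln = global_align("MKTAYIAKQR", "MKTAYIAKQR", params, molecule="protein")
        assert identity_and_similarity(aln, params) == (100.0, 100.0)

    def test_conservative_substitution_counts_as_similar(self, params):
        # 10 columns, 9 identical, one D->E (BLOSUM62 score +2)
        aln = global_align("MKTAYIAKQD", "MKTAYIAKQE", params, molecule="protein")
        ident, simil = identity_and_similarity(aln, params)
        assert (ident, simil) == (90.0, 100.0)

    def test_manual_column_count_12_residues(self, params):
        # hand-constructed: MKTAYIAKQRQI vs MKTAYIGKQWQI
        # identical columns: all but positions 7 (A/G) and 10 (R/W) -> 10/12
        # BLOSUM62: A-G = 0 (not similar), R-W = -3 -> similar = 10/12
        aln = global_align("MKTAYIAKQRQI", "MKTAYIGKQWQI", params,
                           molecule="protein")
        ident, simil = identity_and_similarity(aln, params)
        assert ident == pytest.approx(100 * 10 / 12)
        assert simil == pytest.approx(100 * 10 / 12)

    def test_gap_columns_count_in_denominator(self):
        aln = global_align("ACGTACGT", "ACGT")
        # 4 identical columns of 8
        assert aln.identity_pct == pytest.approx(50.0)

    def test_n_is_never_identical(self):
        aln = global_align("ACGN", "ACGN")
        assert aln.identity_pct == pytest.approx(75.0)


class TestIdentityProfile:
    def test_identical_sequences_all_windows_100(self):
        aln = global_align("ACGT" * 100, "ACGT" * 100)
        prof = sliding_identity_profile(aln, window_size=100, step=25)
        assert prof.windows
        assert all(w[2] == 100.0 for w in prof.windows)

    def test_half_identical_half_mismatched(self):
        # an alignment whose first 100 columns match and next 100 do not
        from homoeolog.pairwise_align import PairwiseAlignment
        rnd = random.Random(3)
        a = "".join(rnd.choice("ACGT") for _ in range(100))
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        aln = PairwiseAlignment(a + a, a + "".join(flip[c] for c in a),
                                score=0.0, mode="global", molecule="dna",
                                identity_pct=50.0, similarity_pct=50.0)
        prof = sliding_identity_profile(aln, window_size=100, step=100)
        assert [w[2] for w in prof.windows] == [100.0, 0.0]

    def test_profile_mean_equals_overall_identity_without_gaps(self):
        rnd = random.Random(9)
        a = "".join(rnd.choice("ACGT") for _ in range(400))
        b = "".join(c if rnd.random() < 0.9 else rnd.choice("ACGT") for c in a)
        aln = global_align(a, b)
        if "-" in aln.aligned_a or "-" in aln.aligned_b:
            pytest.skip("alignment introduced gaps")
        prof = sliding_identity_profile(aln, window_size=100, step=100)
        assert np.mean([w[2] for w in prof.windows]) == pytest.approx(
            aln.identity_pct)

    def test_window_smaller_than_step_rejected(self):
        aln = global_align("ACGT", "ACGT")
        with pytest.raises(ValueError):
            sliding_identity_profile(aln, window_size=10, step=20)


class TestEvalue:
    def test_score_zero_limit(self, params):
        lam, K = params.karlin_altschul()
        assert evalue(0.0, 100, 200, params) == pytest.approx(K * 100 * 200)

    def test_doubling_target_doubles_evalue(self, params):
        assert evalue(30, 100, 400, params) == pytest.approx(
            2 * evalue(30, 100, 200, params))

    def test_strictly_decreasing_in_score(self, params):
        es = [evalue(s, 500, 500, params) for s in range(0, 200, 10)]
        assert all(x > y for x, y in zip(es, es[1:]))

    def test_lambda_solves_ungapped_system(self):
        lam, K, H = karlin_altschul_params(5, -4)
        # independent check of the defining equation at equal base frequencies
        assert 0.25 * math.exp(5 * lam) + 0.75 * math.exp(-4 * lam) == \
            pytest.approx(1.0, abs=1e-10)
        assert K > 0 and H > 0
        # published ungapped blastn constants for +5/-4
        assert lam == pytest.approx(0.192, abs=0.001)
        assert K == pytest.approx(0.176, rel=0.05)

    def test_bad_lengths_rejected(self, params):
        with pytest.raises(ValueError):
            evalue(10, 0, 100, params)


class TestParams:
    def test_gap_order_invariant_enforced(self):
        with pytest.raises(ValueError):
            AlignmentParams(gap_open=0.2, gap_extend=0.5)

    def test_self_identity_is_100_for_any_params(self):
        p = AlignmentParams(gap_open=2.0, gap_extend=1.0, dna_match=1.0,
                            dna_mismatch=-3.0)
        rnd = random.Random(17)
        for _ in range(10):
            s = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(5, 50)))
            assert global_align(s, s, p).identity_pct == 100.0
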