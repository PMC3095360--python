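"""Codon alignment construction, GY94 machinery and NG86 counting."""

import math

import numpy as np
import pytest

from homoeolog.codon_evolution import (
    SENSE_CODONS, CODON_INDEX, CodonAlignment, SaturationError,
    build_codon_alignment, f3x4_frequencies, gy94_rate_matrix,
    estimate_gy94, estimate_ng86, simulate_codon_pair,
    _transition_matrix, _ng86_site_counts)


def _random_cds(rng, n_codons):
    idx = rng.integers(0, 61, size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


class TestBuildCodonAlignment:
    def test_identical_cds_keeps_all_codons(self, rng):
        cds = _random_cds(rng, 20)
        aln = build_codon_alignment(cds, cds)
        assert aln.n_codons == 20
        assert all(a == b for a, b in aln.codon_pairs)

    def test_inframe_deletion_drops_one_column(self, rng):
        cds = _random_cds(rng, 30)
        deleted = cds[:30] + cds[33:]  # remove codon 11
        aln = build_codon_alignment(cds, deleted)
        assert aln.n_codons == 29

    def test_frame_preserving_insertion(self, rng):
        # 6-nt insertion mid-gene: aligned codons = shorter protein length
        cds = _random_cds(rng, 25)
        ins = cds[:36] + "GCTGCA" + cds[36:]
        aln = build_codon_alignment(cds, ins)
        assert aln.n_codons == 25

    def test_too_few_codons_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            build_codon_alignment("ATGAAA", "ATGAAA")

    def test_stop_and_n_columns_dropped(self, rng):
        cds = _random_cds(rng, 15)
        with_stop = cds[:15] + "TAA" + cds[18:]
        aln = build_codon_alignment(cds, with_stop)
        assert aln.n_codons == 14
        assert all("N" not in a + b and a not in ("TAA", "TAG", "TGA")
                   for a, b in aln.codon_pairs)


class TestRateMatrix:
    def test_rows_sum_to_zero_and_scaled(self):
        pi = f3x4_frequencies([SENSE_CODONS[i] for i in range(0, 61, 3)])
        Q = gy94_rate_matrix(2.0, 0.3, pi)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert -np.sum(pi * np.diag(Q)) == pytest.approx(1.0)

    def test_detailed_balance(self):
        pi = f3x4_frequencies([SENSE_CODONS[i] for i in range(61)] * 2)
        Q = gy94_rate_matrix(3.0, 0.2, pi)
        flow = pi[:, None] * Q
        assert np.allclose(flow, flow.T, atol=1e-12)

    def test_neutral_uniform_rates_all_equal(self):
        pi = np.full(61, 1.0 / 61)
        Q = gy94_rate_matrix(1.0, 1.0, pi)
        off = Q[(Q != 0) & ~np.eye(61, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_multi_step_changes_have_zero_rate(self):
        Q = gy94_rate_matrix(2.0, 0.5, np.full(61, 1 / 61))
        i, j = CODON_INDEX["TTT"], CODON_INDEX["CCT"]  # two differences
        assert Q[i, j] == 0.0

    def test_transition_probabilities(self):
        pi = np.full(61, 1.0 / 61)
        Q = gy94_rate_matrix(2.0, 0.5, pi)
        P0 = _transition_matrix(Q, pi, 0.0)
        assert np.allclose(P0, np.eye(61), atol=1e-10)
        for t in (0.1, 1.0, 5.0):
            P = _transition_matrix(Q, pi, t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert (P >= 0).all()


class TestEstimateGY94:
    def test_identical_sequences_zero_rates(self, rng):
        cds = _random_cds(rng, 50)
        est = estimate_gy94(build_codon_alignment(cds, cds))
        assert est.Ks == 0.0 and est.Ka == 0.0 and est.t == 0.0

    def test_site_counts_partition_codons(self, rng):
        aln, _ = simulate_codon_pair(200, 0.2, 2.0, 0.3, rng=rng)
        est = estimate_gy94(aln)
        assert est.S_sites + est.N_sites == pytest.approx(3 * aln.n_codons)
        assert est.codon_freqs.sum() == pytest.approx(1.0)

    def test_optimum_beats_perturbations(self, rng):
        aln, _ = simulate_codon_pair(300, 0.3, 2.0, 0.2, rng=rng)
        est = estimate_gy94(aln)
        from homoeolog.codon_evolution import f3x4_frequencies as f3x4
        pi = f3x4([c for p in aln.codon_pairs for c in p])
        ia, ib = aln.index_pairs()

        def lnl(t, kappa, omega):
            Q = gy94_rate_matrix(kappa, omega, pi)
            P = _transition_matrix(Q, pi, t)
            return float(np.sum(np.log(pi[ia]) + np.log(P[ia, ib])))

        base = lnl(est.t, est.kappa, est.omega)
        assert base == pytest.approx(est.lnL, abs=1e-6)
        for dt in (-0.01, 0.01):
            assert lnl(est.t * (1 + dt), est.kappa, est.omega) <= base + 1e-9

    def test_estimates_invariant_under_sequence_swap(self, rng):
        aln, _ = simulate_codon_pair(300, 0.25, 2.0, 0.3, rng=rng)
        swapped = CodonAlignment([(b, a) for a, b in aln.codon_pairs])
        e1, e2 = estimate_gy94(aln), estimate_gy94(swapped)
        assert e1.Ks == pytest.approx(e2.Ks, abs=1e-5)
        assert e1.Ka == pytest.approx(e2.Ka, abs=1e-5)

    def test_saturated_alignment_rejected(self, rng):
        aln, _ = simulate_codon_pair(300, 20.0, 2.0, 1.0, rng=rng)
        if aln.p_distance() <= 0.75:
            pytest.skip("draw not saturated")
        with pytest.raises(SaturationError):
            estimate_gy94(aln)

    def test_ks_monotone_in_generating_distance(self):
        rng = np.random.default_rng(77)
        grid = [0.02, 0.05, 0.1, 0.2, 0.4, 0.8]
        ks = []
        for t in grid:
            aln, _ = simulate_codon_pair(1500, t, 2.0, 0.2, rng=rng)
            ks.append(estimate_gy94(aln).Ks)
        assert all(x < y for x, y in zip(ks, ks[1:]))

    def test_neutral_omega_split_matches_site_ratio(self):
        # with omega = 1 the non-synonymous share of substitutions matches
        # the non-synonymous site fraction
        rng = np.random.default_rng(5)
        aln, truth = simulate_codon_pair(8000, 0.4, 2.0, 1.0, rng=rng)
        frac_non = truth["non_subs"] / (truth["non_subs"] + truth["syn_subs"])
        expected = truth["N_sites"] / (truth["S_sites"] + truth["N_sites"])
        assert frac_non == pytest.approx(expected, rel=0.05)


class TestNG86:
    def test_identical_sequences(self, rng):
        cds = _random_cds(rng, 40)
        est = estimate_ng86(build_codon_alignment(cds, cds))
        assert est.Ks == 0.0 and est.Ka == 0.0

    def test_single_synonymous_transition(self):
        # 100 identical codons except one third-position synonymous change
        pairs = [("GGT", "GGT")] * 99 + [("GGT", "GGC")]
        aln = CodonAlignment(pairs)
        est = estimate_ng86(aln)
        assert est.Ka == 0.0
        p = 1.0 / est.S_sites
        assert est.Ks == pytest.approx(-0.75 * math.log(1 - 4 * p / 3))

    def test_site_counts_fourfold_codon(self):
        # GGG (glycine): third position fully synonymous, others not
        s, n = _ng86_site_counts("GGG")
        assert s == pytest.approx(1.0)
        assert n == pytest.approx(2.0)

    def test_agreement_with_gy94_at_low_divergence(self):
        rng = np.random.default_rng(101)
        for _ in range(5):
            aln, truth = simulate_codon_pair(1500, 0.08, 1.0, 0.3, rng=rng)
            if truth["expected_ks"] > 0.1:
                continue
            gy = estimate_gy94(aln)
            ng = estimate_ng86(aln)
            assert abs(gy.Ks - ng.Ks) < 0.02
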