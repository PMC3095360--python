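"""Homoeologue pairing, per-element identities and region statistics."""

import numpy as np
import pytest

from homoeolog.seqio import AnnotatedRegion, GeneModel
from homoeolog.datasets import load_homoeolog_gene_stats
from homoeolog.homoeolog_compare import (pair_homoeologues,
                                         compare_gene_structure,
                                         region_summary, aggregate_pair_stats,
                                         HomoeologPair)
from conftest import make_region, random_cds
from oracles import brute_force_chain, base_by_base_coverage


class TestPairing:
    def test_identical_annotation_pairs_everything(self, rng):
        spec = [(f"protein {i}", random_cds(rng, 40), 2, "+") for i in range(3)]
        ro = make_region("O", spec, seed=1)
        rp = make_region("P", spec, seed=2)
        cmp = pair_homoeologues(ro, rp, fill=False)
        assert len(cmp.pairs) == 3
        assert cmp.unique_o == [] and cmp.unique_p == []

    def test_unique_genes_listed(self, rng):
        shared = [(f"shared {i}", random_cds(rng, 30), 1, "+") for i in range(4)]
        o_only = [(f"o-only {i}", random_cds(rng, 30), 1, "+") for i in range(3)]
        p_only = [(f"p-only {i}", random_cds(rng, 30), 1, "-") for i in range(2)]
        ro = make_region("O", shared[:2] + o_only + shared[2:], seed=3)
        rp = make_region("P", shared[:2] + p_only + shared[2:], seed=4)
        cmp = pair_homoeologues(ro, rp, fill=False)
        assert len(cmp.pairs) == 4
        assert len(cmp.unique_o) == 3 and len(cmp.unique_p) == 2

    def test_order_preservation(self, rng):
        spec = [(f"fn {i}", random_cds(rng, 25), 1, "+") for i in range(5)]
        ro = make_region("O", spec, seed=5)
        rp = make_region("P", spec, seed=6)
        cmp = pair_homoeologues(ro, rp, fill=False)
        idx_o = [ro.genes.index(p.gene_o) for p in cmp.pairs]
        idx_p = [rp.genes.index(p.gene_p) for p in cmp.pairs]
        assert idx_o == sorted(idx_o) and idx_p == sorted(idx_p)

    def test_partition_property(self, rng):
        spec_o = [(f"fn {i % 4}", random_cds(rng, 25), 1, "+") for i in range(6)]
        spec_p = [(f"fn {(i + 1) % 5}", random_cds(rng, 25), 1, "+")
                  for i in range(5)]
        ro = make_region("O", spec_o, seed=8)
        rp = make_region("P", spec_p, seed=9)
        cmp = pair_homoeologues(ro, rp, fill=False)
        assert len(cmp.pairs) + len(cmp.unique_o) == len(ro.genes)
        assert len(cmp.pairs) + len(cmp.unique_p) == len(rp.genes)

    @pytest.mark.parametrize("labels_o,labels_p", [
        (["a", "b", "a", "c"], ["a", "a", "c", "b"]),
        (["x", "x", "y"], ["y", "x", "x"]),
        (["a", "b", "c", "a", "b"], ["b", "a", "c", "b", "a"]),
    ])
    def test_chain_length_matches_enumeration(self, rng, labels_o, labels_p):
        spec_o = [(lab, random_cds(rng, 25), 1, "+") for lab in labels_o]
        spec_p = [(lab, random_cds(rng, 25), 1, "+") for lab in labels_p]
        ro = make_region("O", spec_o, seed=10)
        rp = make_region("P", spec_p, seed=11)
        cmp = pair_homoeologues(ro, rp, fill=False)
        assert len(cmp.pairs) == brute_force_chain(labels_o, labels_p)

    def test_duplicate_labels_resolved_by_identity(self, rng):
        # two "kinase" genes each side; the true partner carries the
        # identical CDS, the decoy a diverged one
        cds1, cds2 = random_cds(rng, 40), random_cds(rng, 40)
        ro = make_region("O", [("kinase", cds1, 1, "+"),
                               ("kinase", cds2, 1, "+")], seed=12)
        rp = make_region("P", [("kinase", cds1, 1, "+"),
                               ("kinase", cds2, 1, "+")], seed=13)
        cmp = pair_homoeologues(ro, rp, fill=False)
        assert [(p.gene_o.id, p.gene_p.id) for p in cmp.pairs] == \
            [("O_g1", "P_g1"), ("O_g2", "P_g2")]


class TestGeneStructure:
    def test_identical_genes_all_100(self, rng):
        cds = random_cds(rng, 60)
        ro = make_region("O", [("fn", cds, 3, "+")], seed=20)
        rp = make_region("P", [("fn", cds, 3, "+")], seed=21)
        pair = pair_homoeologues(ro, rp).pairs[0]
        assert pair.structure_match
        assert pair.exon_identities == [100.0] * 3
        assert pair.intron_identities  # introns differ between fixtures
        assert pair.protein_identity == 100.0
        assert pair.kaks.Ks == 0.0

    def test_extra_exon_flags_structure_mismatch(self, rng):
        cds = random_cds(rng, 60)
        ro = make_region("O", [("fn", cds, 3, "+")], seed=22)
        rp = make_region("P", [("fn", cds, 2, "+")], seed=23)
        pair = pair_homoeologues(ro, rp, kaks=False).pairs[0]
        assert not pair.structure_match
        assert pair.surplus_exons_o == 1
        assert len(pair.exon_identities) == 2

    def test_minus_strand_pairing(self, rng):
        cds = random_cds(rng, 45)
        ro = make_region("O", [("fn", cds, 2, "-")], seed=24)
        rp = make_region("P", [("fn", cds, 2, "-")], seed=25)
        pair = pair_homoeologues(ro, rp).pairs[0]
        assert pair.exon_identities == [100.0, 100.0]
        assert pair.protein_identity == 100.0

    def test_hand_built_two_exon_identities(self):
        # exon1: 12 bp with 1 mismatch -> 11/12; exon2: 9 bp identical
        e1o, e1p = "ATGGCTGCAGAT", "ATGGCTGCTGAT"
        e2 = "AAAGGGTGA"
        # keep the mismatch run short (5) so gapping it out is dearer than
        # aligning it: the optimal alignment is then the column-wise one
        intron_o = "GT" + "A" * 20 + "AG"
        intron_p = "GT" + "A" * 5 + "C" * 5 + "A" * 10 + "AG"
        seq_o = "C" * 10 + e1o + intron_o + e2 + "C" * 10
        seq_p = "C" * 10 + e1p + intron_p + e2 + "C" * 10
        go = GeneModel(id="o", strand="+", exons=[(11, 22), (47, 55)],
                       function="fn")
        gp = GeneModel(id="p", strand="+", exons=[(11, 22), (47, 55)],
                       function="fn")
        ro = AnnotatedRegion(name="o", sequence=seq_o, genes=[go])
        rp = AnnotatedRegion(name="p", sequence=seq_p, genes=[gp])
        pair = compare_gene_structure(
            HomoeologPair(gene_o=go, gene_p=gp, region_o=ro, region_p=rp),
            kaks=False)
        assert pair.exon_identities[0] == pytest.approx(100 * 11 / 12)
        assert pair.exon_identities[1] == 100.0
        # intron: 24 aligned columns, 5 mismatching (A vs C)
        assert pair.intron_identities[0] == pytest.approx(100 * 19 / 24)


class TestRegionSummary:
    def test_gene_incidence_61kb_10_genes(self):
        genes = [GeneModel(id=f"g{i}", strand="+",
                           exons=[(i * 6000 + 1, i * 6000 + 300)])
                 for i in range(10)]
        region = AnnotatedRegion(name="r", sequence="A" * 61000, genes=genes)
        s = region_summary(region)
        assert s.gene_incidence_bp == 6100

    def test_small_worked_example(self):
        genes = [GeneModel(id="g1", strand="+", exons=[(101, 350)]),
                 GeneModel(id="g2", strand="+", exons=[(1001, 1250)])]
        region = AnnotatedRegion(name="r", sequence="A" * 2000, genes=genes)
        s = region_summary(region)
        assert s.gene_incidence_bp == 1000
        assert s.gene_space_pct == pytest.approx(25.0)

    def test_coverage_matches_base_by_base_oracle(self, rng):
        spans = []
        genes = []
        pos = 1
        for i in range(8):
            start = pos + int(rng.integers(0, 50))
            end = start + int(rng.integers(10, 400))
            genes.append(GeneModel(id=f"g{i}", strand="+", exons=[(start, end)]))
            spans.append((start, end))
            pos = start + int(rng.integers(5, 300))  # may overlap previous
        length = max(e for _, e in spans) + 100
        region = AnnotatedRegion(name="r", sequence="A" * length, genes=genes)
        s = region_summary(region)
        expected = base_by_base_coverage(spans, 1, length)
        assert s.gene_space_pct == pytest.approx(100 * expected / length)

    def test_interval_outside_region_rejected(self):
        region = AnnotatedRegion(name="r", sequence="A" * 100, genes=[])
        with pytest.raises(ValueError):
            region_summary(region, restrict_to=(50, 200))


class TestAggregates:
    def test_published_table_means(self):
        df = load_homoeolog_gene_stats()
        agg = aggregate_pair_stats(df)
        assert round(agg["mean_exon_identity_pct"], 2) == 97.15
        assert round(agg["mean_intron_identity_pct"], 2) == 88.66
        assert round(agg["mean_protein_identity_pct"], 2) == 97.19
        assert round(agg["mean_protein_similarity_pct"], 2) == 97.84
        assert round(agg["mean_ks"], 4) == 0.0518
        assert round(agg["mean_ka"], 4) == 0.0071

    def test_single_pair_mean_is_value(self):
        import pandas as pd
        df = pd.DataFrame([{"exon_identity_pct": 97.0, "ks": 0.05,
                            "complete": True}])
        agg = aggregate_pair_stats(df)
        assert agg["mean_exon_identity_pct"] == 97.0
        assert agg["mean_ks"] == 0.05

    def test_permutation_invariance(self):
        df = load_homoeolog_gene_stats()
        shuffled = df.sample(frac=1.0, random_state=3)
        assert aggregate_pair_stats(df) == pytest.approx(
            aggregate_pair_stats(shuffled))
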