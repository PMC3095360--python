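"""Pairing and comparison of homoeologous genes between two sub-genome regions.

Genes are candidate homoeologues when their normalised putative-function
strings match; the reported pairing is the best order-preserving matching
(longest chain respecting genomic order in both regions, ties broken by
higher summed protein identity).  Paired genes are compared element-wise
(per-exon and per-intron identities, protein identity/similarity, Ka/Ks),
and region-level summaries (gene incidence, gene-space fraction, mean
element lengths) mirror the per-BAC characteristics table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .seqio import AnnotatedRegion, GeneModel
from .pairwise_align import (AlignmentParams, PairwiseAlignment, IdentityProfile,
                             global_align, identity_and_similarity,
                             sliding_identity_profile)
from .codon_evolution import (KaKsEstimate, SaturationError,
                              build_codon_alignment, estimate_gy94)

__all__ = [
    "HomoeologPair",
    "RegionComparison",
    "RegionSummary",
    "normalise_function",
    "pair_homoeologues",
    "compare_gene_structure",
    "region_summary",
    "aggregate_pair_stats",
    "region_identity_profile",
]


def normalise_function(s: str) -> str:
    """Lower-case, whitespace-collapsed function string for exact matching."""
    return " ".join(s.lower().split())


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class HomoeologPair:
    """A paired homoeologous gene with element-wise comparison statistics."""

    gene_o: GeneModel
    gene_p: GeneModel
    region_o: AnnotatedRegion = field(repr=False, default=None)
    region_p: AnnotatedRegion = field(repr=False, default=None)
    exon_identities: list[float] = field(default_factory=list)
    intron_identities: list[float] = field(default_factory=list)
    protein_identity: float = float("nan")
    protein_similarity: float = float("nan")
    kaks: KaKsEstimate | None = None
    structure_match: bool = True
    surplus_exons_o: int = 0
    surplus_exons_p: int = 0
    complete: bool = True

    @property
    def mean_exon_identity(self) -> float:
        return float(np.mean(self.exon_identities)) if self.exon_identities else float("nan")

    @property
    def mean_intron_identity(self) -> float:
        return (float(np.mean(self.intron_identities))
                if self.intron_identities else float("nan"))

    def as_record(self) -> dict:
        return {
            "gene_o": self.gene_o.id,
            "gene_p": self.gene_p.id,
            "putative_function": self.gene_o.function,
            "exon_identity_pct": self.mean_exon_identity,
            "intron_identity_pct": self.mean_intron_identity,
            "protein_identity_pct": self.protein_identity,
            "protein_similarity_pct": self.protein_similarity,
            "ks": self.kaks.Ks if self.kaks else float("nan"),
            "ka": self.kaks.Ka if self.kaks else float("nan"),
            "structure_match": self.structure_match,
            "complete": self.complete,
        }


@dataclass
class RegionComparison:
    """Paired genes plus uniques and an identity profile for two regions."""

    region_o: AnnotatedRegion
    region_p: AnnotatedRegion
    overlap_o: tuple[int, int]
    overlap_p: tuple[int, int]
    pairs: list[HomoeologPair]
    unique_o: list[str]
    unique_p: list[str]
    profile: IdentityProfile | None = None

    def pairs_table(self) -> pd.DataFrame:
        return pd.DataFrame([p.as_record() for p in self.pairs])


@dataclass
class RegionSummary:
    """Region-level gene geometry statistics."""

    name: str
    length_bp: int
    n_genes: int
    gene_incidence_bp: int
    gene_space_pct: float
    mean_exon_len: float
    mean_intron_len: float

    def as_record(self) -> dict:
        return {
            "region": self.name, "length_bp": self.length_bp,
            "n_genes": self.n_genes, "gene_incidence_bp": self.gene_incidence_bp,
            "gene_space_pct": self.gene_space_pct,
            "mean_exon_len": self.mean_exon_len,
            "mean_intron_len": self.mean_intron_len,
        }


# --------------------------------------------------------------------------
# Pairing
# --------------------------------------------------------------------------

def _protein_identity(region_a: AnnotatedRegion, ga: GeneModel,
                      region_b: AnnotatedRegion, gb: GeneModel,
                      params: AlignmentParams) -> float:
    pa, pb = region_a.protein(ga), region_b.protein(gb)
    if not pa or not pb:
        return 0.0
    return global_align(pa, pb, params, molecule="protein").identity_pct


def _span_in(gene: GeneModel, interval: tuple[int, int]) -> bool:
    return gene.end >= interval[0] and gene.start <= interval[1]


def pair_homoeologues(region_o: AnnotatedRegion, region_p: AnnotatedRegion,
                      params: AlignmentParams | None = None,
                      overlap_o: tuple[int, int] | None = None,
                      overlap_p: tuple[int, int] | None = None,
                      fill: bool = True, kaks: bool = True,
                      profile: bool = False,
                      window_size: int = 100, step: int = 25,
                      ) -> RegionComparison:
    """Order-preserving homoeologue pairing between two annotated regions.

    Candidate pairs share a normalised putative-function string; among
    all order-preserving matchings the longest chain is chosen, ties
    broken by higher summed protein identity (computed by global protein
    alignment, which also disambiguates duplicated function labels
    reciprocally).  Genes inside the compared overlap that stay unpaired
    are listed as unique to their region.  With ``fill`` the per-pair
    statistics are computed (see :func:`compare_gene_structure`); with
    ``profile`` a region-scale identity profile over the overlap is
    attached.
    """
    params = params or AlignmentParams()
    overlap_o = overlap_o or (1, len(region_o))
    overlap_p = overlap_p or (1, len(region_p))
    genes_o = [g for g in region_o.genes if _span_in(g, overlap_o)]
    genes_p = [g for g in region_p.genes if _span_in(g, overlap_p)]
    n, m = len(genes_o), len(genes_p)
    # candidate weights: protein identity where functions match, else None
    weight: dict[tuple[int, int], float] = {}
    for i, go in enumerate(genes_o):
        for j, gp in enumerate(genes_p):
            if normalise_function(go.function) == normalise_function(gp.function):
                weight[(i, j)] = _protein_identity(region_o, go, region_p, gp, params)
    # DP for the heaviest order-preserving chain: primary = chain length,
    # secondary = summed identity
    dp = [[(0, 0.0)] * (m + 1) for _ in range(n + 1)]
    choice = [[0] * (m + 1) for _ in range(n + 1)]  # 0 skip-o, 1 skip-p, 2 match
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = dp[i - 1][j]
            c = 0
            if dp[i][j - 1] > best:
                best = dp[i][j - 1]
                c = 1
            w = weight.get((i - 1, j - 1))
            if w is not None:
                cand = (dp[i - 1][j - 1][0] + 1, dp[i - 1][j - 1][1] + w)
                if cand > best:
                    best = cand
                    c = 2
            dp[i][j] = best
            choice[i][j] = c
    matched: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 and j > 0:
        c = choice[i][j]
        if c == 2:
            matched.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif c == 0:
            i -= 1
        else:
            j -= 1
    matched.reverse()
    pairs = [HomoeologPair(gene_o=genes_o[i], gene_p=genes_p[j],
                           region_o=region_o, region_p=region_p)
             for i, j in matched]
    used_o = {i for i, _ in matched}
    used_p = {j for _, j in matched}
    unique_o = [g.id for i, g in enumerate(genes_o) if i not in used_o]
    unique_p = [g.id for j, g in enumerate(genes_p) if j not in used_p]
    if fill:
        for pair in pairs:
            compare_gene_structure(pair, params, kaks=kaks)
    prof = None
    if profile:
        prof = region_identity_profile(region_o, region_p, overlap_o, overlap_p,
                                       window_size=window_size, step=step)
    return RegionComparison(region_o=region_o, region_p=region_p,
                            overlap_o=overlap_o, overlap_p=overlap_p,
                            pairs=pairs, unique_o=unique_o, unique_p=unique_p,
                            profile=prof)


# --------------------------------------------------------------------------
# Per-pair structure comparison
# --------------------------------------------------------------------------

def _element_seqs(region: AnnotatedRegion, gene: GeneModel, which: str) -> list[str]:
    """Exon or intron sequences in transcription order, reading strand."""
    ivals = gene.exons_tx_order() if which == "exon" else gene.introns_tx_order()
    seqs = []
    for s, e in ivals:
        sub = region.subseq(s, e)
        if gene.strand == "-":
            sub = str(Seq(sub).reverse_complement())
        seqs.append(sub)
    return seqs


def compare_gene_structure(pair: HomoeologPair,
                           params: AlignmentParams | None = None,
                           kaks: bool = True) -> HomoeologPair:
    """Fill a pair with element-wise identities, protein statistics and Ka/Ks.

    Exons and introns are matched positionally from the 5' end of the
    transcript; surplus elements of the longer gene are reported
    unmatched and excluded from the identity lists.  Single-exon pairs
    have no intron identity (missing, not zero).  Ka/Ks uses the GY94
    maximum-likelihood estimator; pairs whose CDSs cannot be aligned or
    estimated are flagged incomplete.
    """
    params = params or AlignmentParams()
    ro, rp = pair.region_o, pair.region_p
    go, gp = pair.gene_o, pair.gene_p
    exons_o = _element_seqs(ro, go, "exon")
    exons_p = _element_seqs(rp, gp, "exon")
    pair.structure_match = len(exons_o) == len(exons_p)
    pair.surplus_exons_o = max(0, len(exons_o) - len(exons_p))
    pair.surplus_exons_p = max(0, len(exons_p) - len(exons_o))
    pair.exon_identities = [
        global_align(a, b, params).identity_pct
        for a, b in zip(exons_o, exons_p)
    ]
    introns_o = _element_seqs(ro, go, "intron")
    introns_p = _element_seqs(rp, gp, "intron")
    pair.intron_identities = [
        global_align(a, b, params).identity_pct
        for a, b in zip(introns_o, introns_p)
    ]
    prot_o, prot_p = ro.protein(go), rp.protein(gp)
    pair.complete = pair.structure_match
    if prot_o and prot_p:
        aln = global_align(prot_o, prot_p, params, molecule="protein")
        pair.protein_identity = aln.identity_pct
        pair.protein_similarity = aln.similarity_pct
    else:
        pair.complete = False
    if kaks:
        try:
            codon_aln = build_codon_alignment(
                ro.spliced_cds(go), rp.spliced_cds(gp),
                gene_ids=(go.id, gp.id), params=params)
            pair.kaks = estimate_gy94(codon_aln)
        except (ValueError, SaturationError):
            pair.kaks = None
            pair.complete = False
    return pair


# --------------------------------------------------------------------------
# Region summaries and aggregates
# --------------------------------------------------------------------------

def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def region_summary(region: AnnotatedRegion,
                   restrict_to: tuple[int, int] | None = None) -> RegionSummary:
    """Gene geometry statistics over a region (or a sub-interval of it).

    ``gene_space_pct`` is the fraction of bases covered by gene spans
    (first exon start to last exon end, introns included), merged across
    overlapping genes; gene incidence is bp of region per gene, rounded.
    """
    lo, hi = restrict_to or (1, len(region))
    if not (1 <= lo <= hi <= len(region)):
        raise ValueError(f"interval {lo}..{hi} outside region {region.name}")
    genes = [g for g in region.genes if _span_in(g, (lo, hi))]
    length = hi - lo + 1
    spans = [(max(g.start, lo), min(g.end, hi)) for g in genes]
    covered = sum(e - s + 1 for s, e in _merge_intervals(spans))
    exon_lens = [e - s + 1 for g in genes for s, e in g.exons]
    intron_lens = [e - s + 1 for g in genes for s, e in g.introns]
    return RegionSummary(
        name=region.name, length_bp=length, n_genes=len(genes),
        gene_incidence_bp=round(length / len(genes)) if genes else 0,
        gene_space_pct=100.0 * covered / length,
        mean_exon_len=float(np.mean(exon_lens)) if exon_lens else float("nan"),
        mean_intron_len=float(np.mean(intron_lens)) if intron_lens else float("nan"),
    )


_AGG_COLUMNS = ["exon_identity_pct", "intron_identity_pct",
                "protein_identity_pct", "protein_similarity_pct", "ks", "ka"]


def aggregate_pair_stats(pairs) -> dict[str, float]:
    """Means of the per-pair statistics over pairs with complete statistics.

    ``pairs`` is a list of :class:`HomoeologPair` or a DataFrame with the
    per-pair columns.  Pairs flagged incomplete (e.g. exon-structure
    mismatches whose exon identity covers matched exons only) are
    excluded from every mean; among complete pairs a missing value (such
    as the intron identity of a single-exon gene) is excluded from that
    statistic's mean only.
    """
    if isinstance(pairs, pd.DataFrame):
        df = pairs.copy()
    else:
        df = pd.DataFrame([p.as_record() for p in pairs])
    if df.empty:
        raise ValueError("no pairs to aggregate")
    if "complete" in df.columns:
        df = df[df["complete"].astype(bool)]
    out: dict[str, float] = {"n_pairs": int(len(df))}
    for col in _AGG_COLUMNS:
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce").dropna()
            out[f"mean_{col}"] = float(vals.mean()) if len(vals) else float("nan")
    return out


# --------------------------------------------------------------------------
# Region-scale identity profile
# --------------------------------------------------------------------------

def region_identity_profile(region_o: AnnotatedRegion, region_p: AnnotatedRegion,
                            overlap_o: tuple[int, int] | None = None,
                            overlap_p: tuple[int, int] | None = None,
                            window_size: int = 100, step: int = 25,
                            ) -> IdentityProfile:
    """Windowed identity over the overlap of two regions.

    Region-scale sequences are globally aligned with an edit-distance
    aligner (linear gap costs; fast enough for BAC-sized input) and the
    aligned path is profiled with the same sliding-window machinery used
    for element-level alignments.  Coordinates are relative to the start
    of the first region's overlap interval.
    """
    overlap_o = overlap_o or (1, len(region_o))
    overlap_p = overlap_p or (1, len(region_p))
    a = region_o.subseq(*overlap_o)
    b = region_p.subseq(*overlap_p)
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    aln = PairwiseAlignment(
        aligned_a=nice["query_aligned"], aligned_b=nice["target_aligned"],
        score=-float(res["editDistance"]), mode="global", molecule="dna",
        identity_pct=0.0, similarity_pct=0.0)
    aln.identity_pct, aln.similarity_pct = identity_and_similarity(aln)
    return sliding_identity_profile(aln, window_size=window_size, step=step)
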