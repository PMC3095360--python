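"""Sub-genome assignment of candidate haplotypes in an allopolyploid.

Two complementary strategies, mirroring how BAC clones are attributed to
the O and P' sub-genomes of white clover against the diploid progenitor
surrogate *T. occidentale*:

* identity ranking — among the candidate haplotypes for one locus, the
  one with the highest global-alignment nucleotide identity to the
  progenitor reference is called O and its counterparts P' (a tie makes
  all calls ambiguous);
* diagnostic variants — homoeologous sequence variants (HSVs) read off
  the candidate-to-reference alignment; a majority vote with a margin of
  at least two calls the sub-genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .pairwise_align import AlignmentParams, global_align

__all__ = [
    "DiagnosticVariantSet",
    "SubgenomeCall",
    "assign_by_identity",
    "genotype_hsvs",
]

VOTE_MARGIN = 2  # minimum vote difference for an unambiguous HSV call
MIN_COVERAGE = 0.5  # fraction of variant positions that must be aligned


@dataclass
class DiagnosticVariantSet:
    """Diagnostic O/P' variants at known positions of a progenitor reference.

    Positions are 1-based in the reference; the two alleles must differ
    at every position.
    """

    locus: str
    variants: list[tuple[int, str, str]]  # (position, allele_O, allele_Pprime)
    reference: str

    def __post_init__(self) -> None:
        self.reference = self.reference.upper()
        prev = 0
        for pos, o, p in self.variants:
            if pos <= prev:
                raise ValueError("variant positions must be strictly increasing")
            if pos > len(self.reference):
                raise ValueError(f"variant position {pos} outside reference")
            if o.upper() == p.upper():
                raise ValueError(f"alleles equal at position {pos}")
            prev = pos

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"locus": self.locus, "pos": p, "allele_O": o, "allele_P": q}
             for p, o, q in self.variants])


@dataclass
class SubgenomeCall:
    """The sub-genome call for one candidate sequence."""

    candidate: str
    call: str  # "O" | "P'" | "ambiguous"
    identity_to_reference: float = float("nan")
    hsv_matches_O: int = 0
    hsv_matches_P: int = 0

    def as_record(self) -> dict:
        return {"candidate": self.candidate, "call": self.call,
                "identity_to_reference": self.identity_to_reference,
                "hsv_matches_O": self.hsv_matches_O,
                "hsv_matches_P": self.hsv_matches_P}


def assign_by_identity(candidates: list[tuple[str, str]], reference: str,
                       params: AlignmentParams | None = None,
                       ) -> list[SubgenomeCall]:
    """Designate the candidate with the highest identity to the progenitor
    reference as O and the others as P'; an exact tie for the maximum
    makes every call ambiguous.  Requires >= 2 candidates."""
    if len(candidates) < 2:
        raise ValueError("need at least two candidate sequences for one locus")
    params = params or AlignmentParams()
    idents = [
        (name, global_align(seq, reference, params).identity_pct)
        for name, seq in candidates
    ]
    best = max(v for _, v in idents)
    tie = sum(1 for _, v in idents if v == best) > 1
    calls = []
    for name, v in idents:
        if tie:
            call = "ambiguous"
        else:
            call = "O" if v == best else "P'"
        calls.append(SubgenomeCall(candidate=name, call=call,
                                   identity_to_reference=v))
    return calls


def genotype_hsvs(candidate: tuple[str, str], variant_set: DiagnosticVariantSet,
                  params: AlignmentParams | None = None,
                  margin: int = VOTE_MARGIN,
                  min_coverage: float = MIN_COVERAGE) -> SubgenomeCall:
    """Call the sub-genome of one candidate from diagnostic variants.

    The candidate is globally aligned to the reference; the candidate
    base at each variant position is compared to the two diagnostic
    alleles (positions falling in an alignment gap are excluded from both
    counts).  A majority with margin >= ``margin`` calls the sub-genome,
    otherwise the call is ambiguous.  Alignment coverage of the variant
    positions below ``min_coverage`` raises ``ValueError``.
    """
    name, seq = candidate
    params = params or AlignmentParams()
    aln = global_align(seq, variant_set.reference, params)
    # map reference position (1-based) -> candidate base at that column
    ref_pos = 0
    at_ref: dict[int, str] = {}
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if y != "-":
            ref_pos += 1
            if x != "-":
                at_ref[ref_pos] = x
    n_cov = sum(1 for pos, _, _ in variant_set.variants if pos in at_ref)
    if n_cov < min_coverage * len(variant_set.variants):
        raise ValueError(
            f"candidate {name} covers only {n_cov}/{len(variant_set.variants)} "
            "variant positions")
    o_votes = p_votes = 0
    for pos, allele_o, allele_p in variant_set.variants:
        base = at_ref.get(pos)
        if base is None:
            continue
        if base == allele_o.upper():
            o_votes += 1
        elif base == allele_p.upper():
            p_votes += 1
    if o_votes - p_votes >= margin:
        call = "O"
    elif p_votes - o_votes >= margin:
        call = "P'"
    else:
        call = "ambiguous"
    return SubgenomeCall(candidate=name, call=call,
                         identity_to_reference=aln.identity_pct,
                         hsv_matches_O=o_votes, hsv_matches_P=p_votes)
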