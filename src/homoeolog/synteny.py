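"""Microsynteny detection against reference gene sets and synteny quality.

Each query CDS is searched against a reference region's CDS set by local
alignment; the best hit per query is kept with a Karlin-Altschul E-value.
A region pair is called syntenic when at least ``min_genes`` (default 3)
query genes hit it at E <= ``max_evalue`` (default 0.01).  Synteny
quality defaults to the symmetric 100 * 2S / (Nq + Nt) with S the shared
gene count; alternative formulas are selectable and the formula used is
always recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .pairwise_align import AlignmentParams, local_align, evalue

__all__ = [
    "SyntenyMatch",
    "SyntenyBlock",
    "match_genes",
    "detect_syntenic_region",
    "synteny_quality",
    "orientation_report",
    "QUALITY_FORMULAS",
    "search_params",
]


def search_params() -> AlignmentParams:
    """Default scoring for similarity *search* (as opposed to identity
    measurement): BLAST-like stiff gap costs keep local scores of
    unrelated sequences in the logarithmic regime where the ungapped
    Karlin-Altschul E-value is a usable approximation.  The permissive
    EMBOSS extension penalty (0.5) used for identity statistics would let
    chance alignments chain matches through long cheap gaps and deflate
    E-values."""
    return AlignmentParams(gap_open=30.0, gap_extend=15.0)


@dataclass
class SyntenyMatch:
    """Best local-alignment hit of one query gene in the target set."""

    query_gene: str
    target_gene: str
    score: float
    evalue: float
    target_position: int  # ordinal index of the target gene in its region


@dataclass
class SyntenyBlock:
    """An ordered set of cross-region gene matches with a quality score."""

    query_region: str
    target_region: str
    shared_genes: list[SyntenyMatch]
    n_query_genes: int
    n_target_genes: int
    quality_pct: float = float("nan")
    quality_formula: str = "2S/(Nq+Nt)"
    orientation_conserved: dict[str, bool] = field(default_factory=dict)

    @property
    def n_shared(self) -> int:
        return len(self.shared_genes)

    def as_record(self) -> dict:
        return {
            "query_region": self.query_region,
            "target_region": self.target_region,
            "n_query_genes": self.n_query_genes,
            "n_target_genes": self.n_target_genes,
            "shared_genes": self.n_shared,
            "quality_pct": self.quality_pct,
            "formula": self.quality_formula,
        }


def match_genes(query_genes: list[tuple[str, str]],
                target_genes: list[tuple[str, str]],
                params: AlignmentParams | None = None,
                max_evalue: float = 0.01) -> list[SyntenyMatch]:
    """Best local-alignment hit per query CDS against a target CDS set.

    ``query_genes``/``target_genes`` are (id, CDS) lists in region order.
    Ties between equally scoring targets are broken by the smaller target
    ordinal; hits with E-value above ``max_evalue`` are discarded.
    """
    if not query_genes or not target_genes:
        raise ValueError("empty CDS set")
    params = params or search_params()
    out: list[SyntenyMatch] = []
    for qid, qseq in query_genes:
        best: SyntenyMatch | None = None
        for pos, (tid, tseq) in enumerate(target_genes):
            aln = local_align(qseq, tseq, params)
            if best is None or aln.score > best.score:
                e = evalue(aln.score, len(qseq), len(tseq), params)
                best = SyntenyMatch(query_gene=qid, target_gene=tid,
                                    score=aln.score, evalue=e,
                                    target_position=pos)
        if best is not None and best.evalue <= max_evalue:
            out.append(best)
    return out


def detect_syntenic_region(matches: list[SyntenyMatch],
                           query_region: str = "query",
                           target_region: str = "target",
                           n_query_genes: int = 0, n_target_genes: int = 0,
                           min_genes: int = 3, max_evalue: float = 0.01,
                           ) -> SyntenyBlock | None:
    """Report a syntenic block iff >= ``min_genes`` matches qualify at
    E <= ``max_evalue``; shared genes keep query order."""
    qualifying = [m for m in matches if m.evalue <= max_evalue]
    if len(qualifying) < min_genes:
        return None
    return SyntenyBlock(query_region=query_region, target_region=target_region,
                        shared_genes=qualifying,
                        n_query_genes=n_query_genes or len(matches),
                        n_target_genes=n_target_genes)


QUALITY_FORMULAS = {
    "2S/(Nq+Nt)": lambda s, nq, nt: 200.0 * s / (nq + nt),
    "S/Nq": lambda s, nq, nt: 100.0 * s / nq,
    "S/union": lambda s, nq, nt: 100.0 * s / (nq + nt - s),
}


def synteny_quality(block: SyntenyBlock, formula: str = "2S/(Nq+Nt)") -> float:
    """Percentage synteny quality of a detected block.

    The default symmetric formula is 100 * 2S / (Nq + Nt); the formula
    tag is stored on the block alongside the value.
    """
    if formula not in QUALITY_FORMULAS:
        raise ValueError(f"unknown quality formula {formula!r}")
    if block.n_query_genes <= 0 or block.n_target_genes <= 0:
        raise ValueError("block needs positive gene counts on both sides")
    q = QUALITY_FORMULAS[formula](block.n_shared, block.n_query_genes,
                                  block.n_target_genes)
    block.quality_pct = q
    block.quality_formula = formula
    return q


def _lis_length(seq: list[int]) -> int:
    """Longest strictly increasing subsequence length (patience, O(n log n))."""
    import bisect
    tails: list[int] = []
    for x in seq:
        i = bisect.bisect_left(tails, x)
        if i == len(tails):
            tails.append(x)
        else:
            tails[i] = x
    return len(tails)


def orientation_report(block: SyntenyBlock,
                       query_strands: dict[str, str],
                       target_strands: dict[str, str],
                       ) -> tuple[pd.DataFrame, float]:
    """Per-gene order/orientation conservation for a block.

    A gene's orientation is conserved when its strand matches between
    query and target.  Order conservation is the longest-common-
    subsequence fraction of the target positions taken in query order
    (equivalently the longest increasing subsequence over target
    ordinals, divided by the number of shared genes).  Results are also
    stored on ``block.orientation_conserved``.
    """
    records = []
    positions = []
    for m in block.shared_genes:
        conserved = query_strands[m.query_gene] == target_strands[m.target_gene]
        block.orientation_conserved[m.query_gene] = conserved
        records.append({"query_gene": m.query_gene, "target_gene": m.target_gene,
                        "orientation_conserved": conserved})
        positions.append(m.target_position)
    lcs_fraction = _lis_length(positions) / len(positions) if positions else 0.0
    return pd.DataFrame(records), lcs_fraction
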