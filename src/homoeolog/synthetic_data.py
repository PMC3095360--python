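"""Ground-truthed simulation of paired homoeologous regions.

The generator emulates the statistical structure the comparison pipeline
assumes for an allopolyploid region pair: an ancestral region with gene
models (exon/intron geometry drawn to match the observed clover averages
of 348 bp exons, 314 bp introns and one gene per ~9 kb), duplicated onto
two sub-genome lineages that then diverge independently — coding
sequence under the GY94 codon model (defaults tuned to a realised median
Ks of about 0.05), introns and intergenic sequence under a
transition-biased nucleotide process with geometric indels, plus
optional segmental deletions (with a planted breakpoint repeat) and
sub-genome-specific TE insertions.  Every stochastic choice flows from a
single seeded RNG stream, so identical parameters give byte-identical
output, and a :class:`SimTruth` record carries the ground truth needed
by recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import AnnotatedRegion, GeneModel, FeatureInterval, write_fasta, write_gff3
from .codon_evolution import (SENSE_CODONS, CODON_INDEX, gy94_rate_matrix,
                              simulate_codon_path, _flow_fractions)

__all__ = [
    "SimParams",
    "DeletionSpec",
    "TESpec",
    "SimTruth",
    "simulate_ancestor",
    "diverge_pair",
    "simulate_pair",
    "make_reference_set",
    "write_simulation",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_INDEX = {b"A"[0]: 0, b"C"[0]: 1, b"G"[0]: 2, b"T"[0]: 3}

MIN_EXON = 20
MIN_INTRON = 50
MIN_INTERGENIC = 100


@dataclass
class DeletionSpec:
    """A segmental deletion applied to one sub-genome after divergence.

    Either an explicit interval (ancestor coordinates, 1-based closed via
    ``start``/``length``) or a list of ancestor gene ids to delete.  A
    short repeat of ``breakpoint_repeat_len`` bp (a copy of the sequence
    immediately 5' of the junction) is planted at the deletion site,
    mimicking an illegitimate-recombination footprint.
    """

    genes: list[str] | None = None
    start: int | None = None
    length: int | None = None
    target: str = "P'"
    breakpoint_repeat_len: int = 32


@dataclass
class TESpec:
    """A sub-genome-specific TE insertion (labelled random sequence)."""

    label: str = "Copia"
    length: int = 3000
    target: str = "P'"


@dataclass
class SimParams:
    """Parameters of the paired-region simulation.

    Structural defaults follow the observed clover region geometry (mean
    exon 348 bp, mean intron 314 bp, 1-5 exons per gene, one gene per
    9148 bp).  ``genic_t`` (expected substitutions per codon on the whole
    O+P path) is derived from ``target_median_ks`` (default 0.05) when
    left unset.  ``intergenic_sub_rate`` is the expected substitutions
    per site across both lineages for intron/intergenic sequence; indels
    arrive per-site at ``indel_rate`` with geometric lengths and never
    hit coding exons.
    """

    n_genes: int = 10
    mean_exon_len: int = 348
    mean_intron_len: int = 314
    min_exons_per_gene: int = 1
    max_exons_per_gene: int = 5
    target_gene_incidence: int = 9148
    target_median_ks: float = 0.05
    genic_t: float | None = None
    genic_kappa: float = 2.0
    genic_omega: float = 0.14
    intergenic_sub_rate: float = 0.15
    indel_rate: float = 0.002
    indel_mean_len: float = 8.0
    deletion_spec: DeletionSpec | None = None
    te_spec: list[TESpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("mean_exon_len", "mean_intron_len", "target_gene_incidence"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("target_median_ks", "genic_kappa", "genic_omega",
                     "intergenic_sub_rate", "indel_rate", "indel_mean_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def resolved_genic_t(self) -> float:
        """Branch-pair codon distance giving the target median Ks under
        the generating (kappa, omega) at uniform codon frequencies."""
        if self.genic_t is not None:
            return self.genic_t
        pi = np.full(61, 1.0 / 61)
        sf, _ = _flow_fractions(self.genic_kappa, self.genic_omega, pi)
        sf1, _ = _flow_fractions(self.genic_kappa, 1.0, pi)
        return self.target_median_ks * 3.0 * sf1 / sf


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated region pair."""

    homoeolog_map: list[tuple[str, str]]
    true_ks: dict[str, float]
    true_ka: dict[str, float]
    realised_syn: dict[str, int]
    realised_non: dict[str, int]
    generating_t: float
    generating_kappa: float
    generating_omega: float
    expected_ks: float
    deletion_intervals: dict[str, list[tuple[int, int]]]
    deleted_genes: dict[str, list[str]]
    te_intervals: dict[str, list[FeatureInterval]]
    ancestral_region: AnnotatedRegion


# --------------------------------------------------------------------------
# Ancestor construction
# --------------------------------------------------------------------------

def _draw_len(rng: np.random.Generator, mean: int, floor: int) -> int:
    return max(floor, int(rng.geometric(1.0 / mean)))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + stop."""
    body = rng.integers(0, 61, size=n_codons - 2)
    stop = ["TAA", "TGA", "TAG"][int(rng.integers(0, 3))]
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + stop


def simulate_ancestor(params: SimParams,
                      rng: np.random.Generator | None = None) -> AnnotatedRegion:
    """Build an ancestral annotated region with ``n_genes`` gene models.

    Exon/intron lengths are geometric draws (clipped at 20 / 50 bp) with
    the configured means; each CDS is in frame with a start and stop
    codon and no internal stops; intergenic filler is sized so the region
    length is ``n_genes * target_gene_incidence``.  Same seed, same
    bytes.
    """
    rng = rng or np.random.default_rng(params.seed)
    region_length = params.n_genes * params.target_gene_incidence
    gene_blocks: list[tuple[str, list[tuple[int, int]], str, int]] = []
    total_gene_len = 0
    for gi in range(params.n_genes):
        n_ex = int(rng.integers(params.min_exons_per_gene,
                                params.max_exons_per_gene + 1))
        exon_lens = [_draw_len(rng, params.mean_exon_len, MIN_EXON)
                     for _ in range(n_ex)]
        total = sum(exon_lens)
        pad = (3 - total % 3) % 3
        exon_lens[-1] += pad
        total += pad
        if total < 36:  # at least 12 codons incl. start/stop
            exon_lens[-1] += 36 - total
            total = 36
        intron_lens = [_draw_len(rng, params.mean_intron_len, MIN_INTRON)
                       for _ in range(n_ex - 1)]
        cds = _random_cds(rng, total // 3)
        strand = "+" if rng.random() < 0.5 else "-"
        # transcript-layout block: exons interleaved with introns
        parts = []
        layout = []  # (start, end) of exons within the block, 0-based
        off = 0
        cpos = 0
        for k, el in enumerate(exon_lens):
            parts.append(cds[cpos:cpos + el])
            layout.append((off, off + el - 1))
            cpos += el
            off += el
            if k < len(intron_lens):
                iv = "GT" + _random_dna(rng, intron_lens[k] - 4) + "AG"
                parts.append(iv)
                off += intron_lens[k]
        block = "".join(parts)
        if strand == "-":
            comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
            block = "".join(comp[c] for c in reversed(block))
            L = len(block)
            layout = [(L - 1 - e, L - 1 - s) for s, e in reversed(layout)]
        gene_blocks.append((block, layout, strand, gi))
        total_gene_len += len(block)
    n_gaps = params.n_genes + 1
    intergenic_total = region_length - total_gene_len
    if intergenic_total < n_gaps * MIN_INTERGENIC:
        raise ValueError(
            f"infeasible gene incidence: genes occupy {total_gene_len} bp of a "
            f"{region_length} bp region")
    # split the filler into gaps with random proportions (Dirichlet-ish)
    w = rng.random(n_gaps) + 0.2
    gap_lens = np.floor(w / w.sum() * (intergenic_total - n_gaps * MIN_INTERGENIC)
                        ).astype(int) + MIN_INTERGENIC
    gap_lens[-1] += intergenic_total - int(gap_lens.sum())
    seq_parts = []
    genes: list[GeneModel] = []
    pos = 0  # 0-based cursor
    for k, (block, layout, strand, gi) in enumerate(gene_blocks):
        filler = _random_dna(rng, int(gap_lens[k]))
        seq_parts.append(filler)
        pos += len(filler)
        exons = [(pos + s + 1, pos + e + 1) for s, e in layout]
        genes.append(GeneModel(
            id=f"g{gi + 1:03d}", strand=strand, exons=exons,
            function=f"simulated protein {gi + 1}"))
        seq_parts.append(block)
        pos += len(block)
    seq_parts.append(_random_dna(rng, int(gap_lens[-1])))
    sequence = "".join(seq_parts)
    return AnnotatedRegion(name="ancestor", sequence=sequence, genes=genes,
                           sub_genome="unknown")


# --------------------------------------------------------------------------
# Divergence machinery
# --------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _k2p_matrix(d: float, kappa: float) -> np.ndarray:
    """Nucleotide transition-probability matrix at distance ``d`` with
    transition/transversion rate ratio ``kappa`` (order ACGT)."""
    rate = np.ones((4, 4))
    for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):  # A<->G, C<->T
        rate[i, j] = kappa
    np.fill_diagonal(rate, 0.0)
    np.fill_diagonal(rate, -rate.sum(axis=1))
    scale = -np.mean(np.diag(rate))
    rate /= scale
    w, U = np.linalg.eig(rate)
    P = (U * np.exp(w * d)) @ np.linalg.inv(U)
    return np.clip(P.real, 0.0, None)


class _EvolvingRegion:
    """Mutable sequence + annotation with coordinate lift-over."""

    def __init__(self, region: AnnotatedRegion):
        self.seq = list(region.sequence)
        self.genes = [GeneModel(id=g.id, strand=g.strand, exons=list(g.exons),
                                function=g.function, cds_phase=g.cds_phase)
                      for g in region.genes]
        self.tes: list[FeatureInterval] = [
            FeatureInterval(t.label, t.start, t.end, t.strand) for t in region.tes]

    def exon_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.seq), dtype=bool)
        for g in self.genes:
            for s, e in g.exons:
                mask[s - 1:e] = True
        return mask

    def splice(self, pos0: int, del_len: int, ins: str) -> None:
        """Delete ``del_len`` bases starting at 0-based ``pos0``, then
        insert ``ins`` there, shifting annotations."""
        self.seq[pos0:pos0 + del_len] = list(ins)
        shift = len(ins) - del_len

        def move(x: int) -> int:  # x is 1-based
            if x <= pos0:
                return x
            if x > pos0 + del_len:
                return x + shift
            return max(1, pos0)  # inside deleted chunk: collapse to junction

        for g in self.genes:
            g.exons = [(move(s), move(e)) for s, e in g.exons]
        kept = []
        for t in self.tes:
            s, e = move(t.start), move(t.end)
            if 1 <= s < e:
                kept.append(FeatureInterval(t.label, s, e, t.strand))
        self.tes = kept

    def to_region(self, name: str, sub_genome: str) -> AnnotatedRegion:
        return AnnotatedRegion(name=name, sequence="".join(self.seq),
                               genes=self.genes, tes=self.tes,
                               sub_genome=sub_genome)


def _evolve_cds(ev: _EvolvingRegion, gene: GeneModel, Q: np.ndarray,
                branch_t: float, rng: np.random.Generator) -> tuple[int, int]:
    """Evolve a gene's coding sequence in place along one branch; the
    terminal stop codon is held fixed.  Returns realised (syn, non)."""
    seq = "".join(ev.seq)
    region = AnnotatedRegion(name="tmp", sequence=seq, genes=[gene])
    cds = region.spliced_cds(gene)
    n_cod = len(cds) // 3
    codons = [cds[i * 3:(i + 1) * 3] for i in range(n_cod)]
    stop = codons[-1] if codons[-1] not in CODON_INDEX else None
    states = np.array([CODON_INDEX[c] for c in codons if c in CODON_INDEX])
    new_states, syn, non = simulate_codon_path(states, Q, branch_t, rng)
    out = [SENSE_CODONS[i] for i in new_states]
    if stop is not None:
        out.append(stop)
    new_cds = "".join(out)
    # write back through the exon structure
    if gene.strand == "-":
        new_genomic = _revcomp(new_cds)
        order = gene.exons
    else:
        new_genomic = new_cds
        order = gene.exons
    off = 0
    for s, e in order:
        ln = e - s + 1
        ev.seq[s - 1:e] = list(new_genomic[off:off + ln])
        off += ln
    return syn, non


def _substitute_noncoding(ev: _EvolvingRegion, d: float, kappa: float,
                          rng: np.random.Generator) -> None:
    """Apply a K2P substitution process at distance ``d`` to every
    non-exonic site (vectorised)."""
    if d <= 0:
        return
    P = _k2p_matrix(d, kappa)
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    arr = np.frombuffer("".join(ev.seq).encode(), dtype="S1").copy()
    codes = np.full(arr.size, -1, dtype=np.int8)
    for b, i in zip(b"ACGT", range(4)):
        codes[arr == bytes([b])] = i
    mask = (~ev.exon_mask()) & (codes >= 0)
    idx = np.where(mask)[0]
    u = rng.random(idx.size)
    old = codes[idx]
    new = (u[:, None] > cum[old]).sum(axis=1)
    arr[idx] = _BASES[new]
    ev.seq = [chr(c[0]) for c in arr]


def _touches_exon(genes: list[GeneModel], lo: int, hi: int) -> bool:
    """Does the 1-based closed interval [lo, hi] overlap any exon?"""
    for g in genes:
        if g.end < lo or g.start > hi:
            continue
        for s, e in g.exons:
            if s <= hi and e >= lo:
                return True
    return False


def _apply_indels(ev: _EvolvingRegion, rate: float, mean_len: float,
                  rng: np.random.Generator) -> None:
    """Geometric-length insertions/deletions in non-coding sequence.

    Events that would touch a coding exon (with a 2 bp buffer) are
    re-drawn; annotations are lifted over through each edit.
    """
    n_events = rng.poisson(rate * len(ev.seq))
    for _ in range(n_events):
        for _attempt in range(50):
            L = len(ev.seq)
            pos0 = int(rng.integers(0, L))
            length = max(1, int(rng.geometric(1.0 / mean_len)))
            is_del = rng.random() < 0.5
            if is_del and pos0 + length > L:
                continue
            hi = pos0 + (length if is_del else 0)
            if _touches_exon(ev.genes, max(1, pos0 - 1), hi + 2):
                continue
            if is_del:
                ev.splice(pos0, length, "")
            else:
                ev.splice(pos0, 0, _random_dna(rng, length))
            break


def _apply_segmental_deletion(ev: _EvolvingRegion, spec: DeletionSpec,
                              ) -> tuple[tuple[int, int], list[str]]:
    """Delete an interval (covering whole genes when specified by ids) and
    plant the breakpoint repeat; returns the deleted interval in the
    pre-deletion coordinates and the removed gene ids."""
    if spec.genes:
        chosen = [g for g in ev.genes if g.id in spec.genes]
        if len(chosen) != len(spec.genes):
            missing = set(spec.genes) - {g.id for g in chosen}
            raise ValueError(f"deletion names unknown genes: {sorted(missing)}")
        start = min(g.start for g in chosen) - 20
        end = max(g.end for g in chosen) + 20
    elif spec.start is not None and spec.length is not None:
        start, end = spec.start, spec.start + spec.length - 1
    else:
        raise ValueError("deletion spec needs genes or start+length")
    start = max(1, start)
    end = min(len(ev.seq), end)
    if end <= start:
        raise ValueError("empty deletion interval")
    removed = [g.id for g in ev.genes if g.start >= start and g.end <= end]
    straddling = [g.id for g in ev.genes
                  if g.id not in removed and g.end >= start and g.start <= end]
    if straddling:
        raise ValueError(f"deletion would truncate genes {straddling}")
    rep_len = spec.breakpoint_repeat_len
    rep_src = max(0, start - 1 - rep_len)
    repeat = "".join(ev.seq[rep_src:start - 1])[-rep_len:]
    ev.genes = [g for g in ev.genes if g.id not in removed]
    ev.splice(start - 1, end - start + 1, repeat)
    return (start, end), removed


def _insert_te(ev: _EvolvingRegion, spec: TESpec, rng: np.random.Generator,
               ) -> FeatureInterval:
    """Insert a labelled random-sequence TE at an intergenic position."""
    for _attempt in range(200):
        pos0 = int(rng.integers(0, len(ev.seq)))
        if _touches_exon(ev.genes, max(1, pos0 - 1), pos0 + 2):
            continue
        if any(g.start <= pos0 + 1 <= g.end for g in ev.genes):
            continue
        ev.splice(pos0, 0, _random_dna(rng, spec.length))
        te = FeatureInterval(spec.label, pos0 + 1, pos0 + spec.length,
                             "+" if rng.random() < 0.5 else "-")
        ev.tes.append(te)
        return te
    raise RuntimeError("could not place TE outside gene space")


def diverge_pair(ancestor: AnnotatedRegion, params: SimParams,
                 rng: np.random.Generator | None = None,
                 ) -> tuple[AnnotatedRegion, AnnotatedRegion, SimTruth]:
    """Evolve two sub-genome copies of an ancestral region.

    Coding sequence follows GY94 jump-chain sampling on two branches of
    ``genic_t / 2``; introns and intergenic sequence follow a K2P process
    at ``intergenic_sub_rate / 2`` per branch with geometric indels that
    never hit exons; the optional segmental deletion and TE insertions
    are applied post-divergence to their target sub-genome.
    """
    rng = rng or np.random.default_rng(params.seed)
    t_total = params.resolved_genic_t()
    pi = np.full(61, 1.0 / 61)
    Q = gy94_rate_matrix(params.genic_kappa, params.genic_omega, pi)
    sf1, _ = _flow_fractions(params.genic_kappa, 1.0, pi)
    sf, _ = _flow_fractions(params.genic_kappa, params.genic_omega, pi)
    regions: dict[str, _EvolvingRegion] = {}
    syn_counts: dict[str, int] = {g.id: 0 for g in ancestor.genes}
    non_counts: dict[str, int] = {g.id: 0 for g in ancestor.genes}
    sites: dict[str, tuple[float, float]] = {}
    for g in ancestor.genes:
        n_cod = g.spliced_length // 3 - 1  # terminal stop held fixed
        S = 3 * n_cod * sf1
        sites[g.id] = (S, 3 * n_cod - S)
    for label in ("O", "P'"):
        ev = _EvolvingRegion(ancestor)
        for g in ev.genes:
            syn, non = _evolve_cds(ev, g, Q, t_total / 2.0, rng)
            syn_counts[g.id] += syn
            non_counts[g.id] += non
        _substitute_noncoding(ev, params.intergenic_sub_rate / 2.0,
                              params.genic_kappa, rng)
        _apply_indels(ev, params.indel_rate, params.indel_mean_len, rng)
        regions[label] = ev
    deletion_intervals: dict[str, list[tuple[int, int]]] = {"O": [], "P'": []}
    deleted_genes: dict[str, list[str]] = {"O": [], "P'": []}
    if params.deletion_spec is not None:
        spec = params.deletion_spec
        interval, removed = _apply_segmental_deletion(regions[spec.target], spec)
        deletion_intervals[spec.target].append(interval)
        deleted_genes[spec.target].extend(removed)
    te_intervals: dict[str, list[FeatureInterval]] = {"O": [], "P'": []}
    for spec in params.te_spec:
        te = _insert_te(regions[spec.target], spec, rng)
        te_intervals[spec.target].append(te)
    all_deleted = set(deleted_genes["O"]) | set(deleted_genes["P'"])
    homoeolog_map = [(g.id, g.id) for g in ancestor.genes
                     if g.id not in all_deleted]
    true_ks = {gid: syn_counts[gid] / sites[gid][0] for gid in syn_counts}
    true_ka = {gid: non_counts[gid] / sites[gid][1] for gid in non_counts}
    region_O = regions["O"].to_region("region_O", "O")
    region_P = regions["P'"].to_region("region_P", "P'")
    truth = SimTruth(
        homoeolog_map=homoeolog_map, true_ks=true_ks, true_ka=true_ka,
        realised_syn=syn_counts, realised_non=non_counts,
        generating_t=t_total, generating_kappa=params.genic_kappa,
        generating_omega=params.genic_omega,
        expected_ks=t_total * sf / (3.0 * sf1),
        deletion_intervals=deletion_intervals, deleted_genes=deleted_genes,
        te_intervals=te_intervals, ancestral_region=ancestor)
    return region_O, region_P, truth


def simulate_pair(params: SimParams,
                  ) -> tuple[AnnotatedRegion, AnnotatedRegion, SimTruth]:
    """Ancestor construction plus divergence from one seeded stream."""
    rng = np.random.default_rng(params.seed)
    ancestor = simulate_ancestor(params, rng)
    return diverge_pair(ancestor, params, rng)


# --------------------------------------------------------------------------
# Reference gene sets for synteny tests
# --------------------------------------------------------------------------

def make_reference_set(ancestor: AnnotatedRegion, ortholog_t: float,
                       retention_prob: float = 1.0, seed: int = 0,
                       shuffle: bool = False, kappa: float = 2.0,
                       omega: float = 0.14,
                       ) -> tuple[list[tuple[str, str]], dict]:
    """Evolve the ancestor's CDSs into an orthologous reference gene set.

    Each CDS evolves at codon distance ``ortholog_t``; genes are retained
    with probability ``retention_prob`` (emulating gaps in a draft
    genome) and optionally shuffled into a different order (gene
    islands).  Returns the (id, CDS) list plus a truth dict with the
    retained gene ids.
    """
    rng = np.random.default_rng(seed)
    pi = np.full(61, 1.0 / 61)
    Q = gy94_rate_matrix(kappa, omega, pi)
    out: list[tuple[str, str]] = []
    retained: list[str] = []
    for g in ancestor.genes:
        cds = ancestor.spliced_cds(g)
        codons = [cds[i:i + 3] for i in range(0, len(cds) - 2, 3)]
        states = np.array([CODON_INDEX[c] for c in codons if c in CODON_INDEX])
        stop = codons[-1] if codons and codons[-1] not in CODON_INDEX else ""
        new_states, _, _ = simulate_codon_path(states, Q, ortholog_t, rng)
        keep = rng.random() < retention_prob
        if keep:
            new_cds = "".join(SENSE_CODONS[i] for i in new_states) + stop
            out.append((f"ref_{g.id}", new_cds))
            retained.append(g.id)
    if shuffle and out:
        order = rng.permutation(len(out))
        out = [out[i] for i in order]
    return out, {"retained": retained, "ortholog_t": ortholog_t}


def write_simulation(region_O: AnnotatedRegion, region_P: AnnotatedRegion,
                     truth: SimTruth, outdir: str | Path) -> None:
    """Emit FASTA + GFF3 per sub-genome and truth tables (TSV/JSON)."""
    import json
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for region in (region_O, region_P):
        write_fasta([(region.name, region.sequence)],
                    outdir / f"{region.name}.fasta")
        write_gff3(region, outdir / f"{region.name}.gff3")
    rows = []
    for gid_o, gid_p in truth.homoeolog_map:
        rows.append({"gene_O": gid_o, "gene_P": gid_p,
                     "true_ks": round(truth.true_ks[gid_o], 6),
                     "true_ka": round(truth.true_ka[gid_o], 6)})
    with open(outdir / "truth_pairs.tsv", "w") as fh:
        fh.write("gene_O\tgene_P\ttrue_ks\ttrue_ka\n")
        for r in rows:
            fh.write(f"{r['gene_O']}\t{r['gene_P']}\t{r['true_ks']}\t{r['true_ka']}\n")
    meta = {
        "generating_t": truth.generating_t,
        "generating_kappa": truth.generating_kappa,
        "generating_omega": truth.generating_omega,
        "expected_ks": truth.expected_ks,
        "deleted_genes": truth.deleted_genes,
        "deletion_intervals": truth.deletion_intervals,
        "te_intervals": {k: [(t.label, t.start, t.end) for t in v]
                         for k, v in truth.te_intervals.items()},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")
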