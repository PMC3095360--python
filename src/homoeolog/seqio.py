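"""Reading and writing of the formats the pipeline touches.

FASTA and GFF3 (1-based closed coordinates throughout) come in; annotated
regions, gene models and tabular/JSON result files go out.  All other
modules consume the in-memory types defined here and never read files
directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "FeatureInterval",
    "AnnotatedRegion",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "write_results",
]

_IUPAC_DNA = set("ACGTN")  # the pipeline's working alphabet


class FormatError(ValueError):
    """Malformed input file."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class FeatureInterval:
    """A labelled interval (1-based closed), e.g. a transposable element."""

    label: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError(f"bad interval {self.start}..{self.end}")
        if self.strand not in "+-.":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneModel:
    """A gene model: ordered exons (genomic 1-based closed) on a strand.

    ``exons`` are kept sorted 5'->3' in genomic coordinates (ascending
    start) regardless of strand; ``function`` is a free-text putative
    function used for homoeologue/orthologue candidate matching.
    """

    id: str
    strand: str
    exons: list[tuple[int, int]]
    function: str = ""
    cds_phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = 0
        for s, e in self.exons:
            if s > e or s < 1:
                raise ValueError(f"bad exon {s}..{e}")
            if s <= prev_end:
                raise ValueError(f"overlapping exons in gene {self.id}")
            prev_end = e
        if self.spliced_length < 3:
            raise ValueError(f"spliced CDS of gene {self.id} shorter than one codon")
        if self.cds_phase not in (0, 1, 2):
            raise ValueError("cds_phase must be 0, 1 or 2")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span from first exon start to last exon end."""
        return self.start, self.end

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Intervals between consecutive exons, genomic order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def exons_tx_order(self) -> list[tuple[int, int]]:
        """Exons in transcription (5'->3' of the mRNA) order."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def introns_tx_order(self) -> list[tuple[int, int]]:
        return self.introns if self.strand == "+" else list(reversed(self.introns))


@dataclass
class AnnotatedRegion:
    """A contiguous sequence with gene models and optional TE features."""

    name: str
    sequence: str
    genes: list[GeneModel] = field(default_factory=list)
    tes: list[FeatureInterval] = field(default_factory=list)
    sub_genome: str = "unknown"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _IUPAC_DNA
        if bad:
            raise FormatError(f"non-ACGTN characters in {self.name}: {sorted(bad)}")
        if self.sub_genome not in ("O", "P'", "unknown"):
            raise ValueError(f"bad sub-genome label {self.sub_genome!r}")
        self.genes = sorted(self.genes, key=lambda g: g.start)
        ids = [g.id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate gene ids in region {self.name}")
        n = len(self.sequence)
        for g in self.genes:
            if g.end > n:
                raise FormatError(f"gene {g.id} extends beyond sequence end ({n})")
        for t in self.tes:
            if t.end > n:
                raise FormatError(f"TE {t.label} extends beyond sequence end ({n})")

    def __len__(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """1-based closed slice of the sequence."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise ValueError(f"interval {start}..{end} outside region {self.name}")
        return self.sequence[start - 1:end]

    def spliced_cds(self, gene: GeneModel) -> str:
        """Spliced CDS in reading direction (reverse-complemented for -)."""
        s = "".join(self.subseq(a, b) for a, b in gene.exons)
        if gene.strand == "-":
            s = str(Seq(s).reverse_complement())
        if gene.cds_phase:
            s = s[gene.cds_phase:]
        return s

    def protein(self, gene: GeneModel) -> str:
        """Translation of the spliced CDS (trailing partial codon and
        trailing stop dropped)."""
        cds = self.spliced_cds(gene)
        cds = cds[: len(cds) - len(cds) % 3]
        aa = str(Seq(cds).translate())
        return aa[:-1] if aa.endswith("*") else aa


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (name, upper-cased sequence) tuples.

    Names are truncated at the first whitespace; duplicate names, empty
    files and non-ACGTN characters raise :class:`FormatError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        name = rec.id
        if name in seen:
            raise FormatError(f"duplicate FASTA record name {name!r}")
        seen.add(name)
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC_DNA
        if bad:
            raise FormatError(f"non-ACGTN characters in record {name!r}: {sorted(bad)}")
        out.append((name, seq))
    return out


def write_fasta(records: list[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    seq_records = [SeqRecord(Seq(s), id=n, description="") for n, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# --------------------------------------------------------------------------
# GFF3
# --------------------------------------------------------------------------

def read_gff3(path: str | Path, region: tuple[str, str] | AnnotatedRegion,
              sub_genome: str | None = None) -> AnnotatedRegion:
    """Assemble an :class:`AnnotatedRegion` from a GFF3 file.

    ``region`` is the (name, sequence) pair the features annotate.
    gene/mRNA/exon/CDS rows become :class:`GeneModel` (exon intervals are
    taken from CDS rows when present, else exon rows); ``repeat_region``
    rows become TE features.  Coordinates outside the sequence or exons
    without a resolvable gene parent raise :class:`FormatError`.
    """
    if isinstance(region, AnnotatedRegion):
        name, seq = region.name, region.sequence
        if sub_genome is None:
            sub_genome = region.sub_genome
    else:
        name, seq = region
    text = Path(path).read_text()
    if not text.lstrip().startswith("##gff-version"):
        raise FormatError(f"{path}: missing ##gff-version header")
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        parts = [f for f in db.children(gene, featuretype="CDS")]
        if not parts:
            parts = [f for f in db.children(gene, featuretype="exon")]
        if not parts:
            raise FormatError(f"gene {gene.id} has no exon or CDS children")
        exons = [(f.start, f.end) for f in parts]
        phases = [f.frame for f in sorted(parts, key=lambda f: f.start)]
        first = phases[-1] if gene.strand == "-" else phases[0]
        phase = int(first) if first not in (None, ".", "") else 0
        func = gene.attributes.get("function", gene.attributes.get("Note", [""]))[0]
        genes.append(GeneModel(id=gene.id, strand=gene.strand, exons=exons,
                               function=func, cds_phase=phase))
    tes = []
    for rep in db.features_of_type("repeat_region"):
        label = rep.attributes.get("class", rep.attributes.get("Name", ["repeat"]))[0]
        tes.append(FeatureInterval(label=label, start=rep.start, end=rep.end,
                                   strand=rep.strand if rep.strand in "+-" else "."))
    # orphan exon/CDS rows (missing parents) are a format error
    for f in db.features_of_type(("exon", "CDS")):
        parents = list(db.parents(f))
        if not parents:
            raise FormatError(f"{f.featuretype} row without a parent gene/mRNA")
    return AnnotatedRegion(name=name, sequence=seq, genes=genes, tes=tes,
                           sub_genome=sub_genome or "unknown")


def write_gff3(region: AnnotatedRegion, path: str | Path) -> None:
    """Write the region's annotation as GFF3 (gene/mRNA/CDS + repeat_region)."""
    src = "homoeolog"
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {region.name} 1 {len(region.sequence)}\n")
        for g in region.genes:
            attrs = f"ID={g.id}"
            if g.function:
                attrs += f";function={g.function}"
            fh.write(f"{region.name}\t{src}\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            fh.write(f"{region.name}\t{src}\tmRNA\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.id}.t1;Parent={g.id}\n")
            exons_tx = g.exons_tx_order()
            phase = g.cds_phase
            phases = {}
            for s, e in exons_tx:
                phases[(s, e)] = phase
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{region.name}\t{src}\tCDS\t{s}\t{e}\t.\t{g.strand}\t"
                         f"{phases[(s, e)]}\tID={g.id}.cds{i};Parent={g.id}.t1\n")
        for t in region.tes:
            fh.write(f"{region.name}\t{src}\trepeat_region\t{t.start}\t{t.end}\t.\t"
                     f"{t.strand}\t.\tName={t.label};class={t.label}\n")


# --------------------------------------------------------------------------
# Result tables
# --------------------------------------------------------------------------

# columns rounded to fixed precision on output
_PRECISION = {
    "identity": 2, "similarity": 2, "identity_pct": 2, "similarity_pct": 2,
    "exon_identity_pct": 2, "intron_identity_pct": 2,
    "protein_identity_pct": 2, "protein_similarity_pct": 2,
    "quality_pct": 2, "gene_space_pct": 2,
    "ks": 4, "ka": 4, "omega": 4, "kappa": 4, "t": 4, "lnL": 4,
    "median_ks": 4, "mean_ks": 4, "sd_ks": 4,
}


def _round_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col, ndp in _PRECISION.items():
        if col in df.columns:
            df[col] = df[col].map(
                lambda v: round(float(v), ndp) if pd.notna(v) else v)
    return df


def write_results(table, path: str | Path, format: str = "tsv") -> None:
    """Write a result table as TSV or JSON with fixed float precision
    (identities at 2 dp, Ks/Ka and friends at 4 dp); deterministic column
    order (input order).  An empty table produces a header-only file."""
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table)
    table = _round_table(table)
    if format == "tsv":
        fmt = {}
        for col in table.columns:
            if col in _PRECISION:
                nd = _PRECISION[col]
                fmt[col] = nd
        out = table.copy()
        for col, nd in fmt.items():
            out[col] = out[col].map(
                lambda v, nd=nd: (f"{v:.{nd}f}" if pd.notna(v) else ""))
        out.to_csv(path, sep="\t", index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(table.to_dict(orient="records"), fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")
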