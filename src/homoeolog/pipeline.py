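"""End-to-end orchestration: config, logging, reports and the CLI.

Everything that affects numbers lives in a YAML config (paths, alignment
penalties, codon-model settings, clock rate, synteny thresholds, seed);
command-line flags only select the config, the output directory and
verbosity.  Every run writes a machine-readable manifest (config hash,
seed, package version) next to its outputs so results can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import click
import pandas as pd
import yaml

from . import __version__
from .seqio import read_fasta, read_gff3, write_results
from .pairwise_align import AlignmentParams
from .codon_evolution import build_codon_alignment, estimate_gy94, estimate_ng86
from .divergence_clock import DEFAULT_RATE, clock_report
from .homoeolog_compare import (pair_homoeologues, region_summary,
                                aggregate_pair_stats)
from .synteny import match_genes, detect_syntenic_region, synteny_quality
from .subgenome_assign import (DiagnosticVariantSet, assign_by_identity,
                               genotype_hsvs)
from . import synthetic_data as sim

log = logging.getLogger("homoeolog")

__all__ = ["PipelineConfig", "run_compare", "run_synteny", "main"]


@dataclass
class PipelineConfig:
    """Run configuration (parsed from YAML)."""

    region_o_fasta: str = ""
    region_o_gff3: str = ""
    region_p_fasta: str = ""
    region_p_gff3: str = ""
    references: list[dict] = field(default_factory=list)  # [{name, cds_fasta}]
    overlap_o: tuple[int, int] | None = None
    overlap_p: tuple[int, int] | None = None
    gap_open: float = 10.0
    gap_extend: float = 0.5
    dna_match: float = 5.0
    dna_mismatch: float = -4.0
    clock_rate: float = DEFAULT_RATE
    search_gap_open: float = 30.0
    search_gap_extend: float = 15.0
    min_genes: int = 3
    max_evalue: float = 0.01
    quality_formula: str = "2S/(Nq+Nt)"
    window_size: int = 100
    step: int = 25
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_genes < 1 or self.max_evalue <= 0:
            raise ValueError("synteny thresholds must be positive")
        if self.clock_rate <= 0:
            raise ValueError("clock rate must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg._source = Path(path)
        return cfg

    def alignment_params(self) -> AlignmentParams:
        return AlignmentParams(gap_open=self.gap_open, gap_extend=self.gap_extend,
                               dna_match=self.dna_match,
                               dna_mismatch=self.dna_mismatch)

    def manifest(self) -> dict:
        cfg = {k: v for k, v in asdict(self).items() if not k.startswith("_")}
        blob = json.dumps(cfg, sort_keys=True, default=str).encode()
        return {"config": cfg, "config_sha256": hashlib.sha256(blob).hexdigest(),
                "seed": self.seed, "version": __version__}


def _load_region(fasta: str, gff3: str, sub_genome: str):
    records = read_fasta(fasta)
    name, seq = records[0]
    return read_gff3(gff3, (name, seq), sub_genome=sub_genome)


def _write_manifest(cfg: PipelineConfig, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(cfg.manifest(), fh, indent=1, default=str)
        fh.write("\n")


def run_compare(cfg: PipelineConfig) -> dict:
    """Full homoeologous-region comparison: pairing, per-pair statistics,
    region summaries, identity profile and clock estimate; writes TSV/JSON
    outputs under ``cfg.outdir`` and returns the headline numbers."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = cfg.alignment_params()
    log.info("alignment penalties: gap_open=%s gap_extend=%s match=%s mismatch=%s",
             cfg.gap_open, cfg.gap_extend, cfg.dna_match, cfg.dna_mismatch)
    region_o = _load_region(cfg.region_o_fasta, cfg.region_o_gff3, "O")
    region_p = _load_region(cfg.region_p_fasta, cfg.region_p_gff3, "P'")
    comparison = pair_homoeologues(
        region_o, region_p, params, overlap_o=cfg.overlap_o,
        overlap_p=cfg.overlap_p, profile=True,
        window_size=cfg.window_size, step=cfg.step)
    pairs_df = comparison.pairs_table()
    write_results(pairs_df, outdir / "homoeolog_pairs.tsv")
    summaries = pd.DataFrame([region_summary(region_o).as_record(),
                              region_summary(region_p).as_record()])
    write_results(summaries, outdir / "region_summaries.tsv")
    prof = comparison.profile
    prof_df = pd.DataFrame(prof.windows, columns=["start", "end", "identity"])
    write_results(prof_df, outdir / "identity_profile.tsv")
    with open(outdir / "unique_genes.json", "w") as fh:
        json.dump({"unique_o": comparison.unique_o,
                   "unique_p": comparison.unique_p}, fh, indent=1)
        fh.write("\n")
    result: dict = {"n_pairs": len(comparison.pairs),
                    "unique_o": comparison.unique_o,
                    "unique_p": comparison.unique_p}
    estimates = [p.kaks for p in comparison.pairs if p.kaks is not None]
    if estimates:
        log.info("clock rate: %g substitutions/synonymous site/year", cfg.clock_rate)
        clock, per_pair = clock_report(estimates, cfg.clock_rate)
        write_results(per_pair, outdir / "divergence_times.tsv")
        with open(outdir / "clock_summary.json", "w") as fh:
            json.dump(clock.summary(), fh, indent=1)
            fh.write("\n")
        result["clock"] = clock.summary()
        result["aggregates"] = aggregate_pair_stats(comparison.pairs)
    else:
        log.warning("no homoeologue pairs with Ka/Ks estimates; clock skipped")
    _write_manifest(cfg, outdir)
    return result


def run_synteny(cfg: PipelineConfig) -> pd.DataFrame:
    """Synteny of the O (and P' if given) region against each reference CDS
    set; one row per (region, reference) with shared-gene count and
    quality, written as TSV."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = AlignmentParams(gap_open=cfg.search_gap_open,
                             gap_extend=cfg.search_gap_extend,
                             dna_match=cfg.dna_match,
                             dna_mismatch=cfg.dna_mismatch)
    rows = []
    queries = []
    for label, fa, gff in (("O", cfg.region_o_fasta, cfg.region_o_gff3),
                           ("P'", cfg.region_p_fasta, cfg.region_p_gff3)):
        if fa and gff:
            region = _load_region(fa, gff, label)
            queries.append((label, [(g.id, region.spliced_cds(g))
                                    for g in region.genes]))
    if not queries:
        raise ValueError("no query region configured")
    for ref in cfg.references:
        target = read_fasta(ref["cds_fasta"])
        for label, query_cds in queries:
            matches = match_genes(query_cds, target, params,
                                  max_evalue=cfg.max_evalue)
            block = detect_syntenic_region(
                matches, query_region=label, target_region=ref["name"],
                n_query_genes=len(query_cds), n_target_genes=len(target),
                min_genes=cfg.min_genes, max_evalue=cfg.max_evalue)
            if block is None:
                rows.append({"query_region": label, "target_region": ref["name"],
                             "n_query_genes": len(query_cds),
                             "n_target_genes": len(target), "shared_genes": 0,
                             "quality_pct": float("nan"),
                             "formula": "no synteny"})
                log.info("%s vs %s: no synteny (<%d qualifying genes)",
                         label, ref["name"], cfg.min_genes)
                continue
            synteny_quality(block, cfg.quality_formula)
            rows.append(block.as_record())
    df = pd.DataFrame(rows)
    write_results(df, outdir / "synteny_quality.tsv")
    _write_manifest(cfg, outdir)
    return df


# --------------------------------------------------------------------------
# CLI
# --------------------------------------------------------------------------

def _setup_logging(verbose: bool, outdir: str | None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if outdir:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(Path(outdir) / "run.log"))
    logging.basicConfig(level=logging.DEBUG if verbose else logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s",
                        handlers=handlers, force=True)


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Debug logging.")
@click.pass_context
def main(ctx: click.Context, verbose: bool) -> None:
    """Homoeologous-region comparison toolkit."""
    ctx.ensure_object(dict)
    ctx.obj["verbose"] = verbose


@main.command()
@click.argument("config", type=click.Path(exists=True))
@click.pass_context
def compare(ctx: click.Context, config: str) -> None:
    """Pair homoeologues between two regions and report statistics."""
    cfg = PipelineConfig.from_yaml(config)
    _setup_logging(ctx.obj["verbose"], cfg.outdir)
    result = run_compare(cfg)
    click.echo(json.dumps(result, indent=1, default=str))


@main.command()
@click.argument("config", type=click.Path(exists=True))
@click.pass_context
def synteny(ctx: click.Context, config: str) -> None:
    """Detect syntenic reference regions and compute synteny quality."""
    cfg = PipelineConfig.from_yaml(config)
    _setup_logging(ctx.obj["verbose"], cfg.outdir)
    df = run_synteny(cfg)
    click.echo(df.to_string(index=False))


@main.command()
@click.argument("cds_a", type=click.Path(exists=True))
@click.argument("cds_b", type=click.Path(exists=True))
@click.option("--method", type=click.Choice(["GY94", "NG86"]), default="GY94")
@click.option("--out", type=click.Path(), default=None)
@click.pass_context
def kaks(ctx: click.Context, cds_a: str, cds_b: str, method: str,
         out: str | None) -> None:
    """Ka/Ks for CDS pairs (records matched by file order)."""
    _setup_logging(ctx.obj["verbose"], None)
    a_recs, b_recs = read_fasta(cds_a), read_fasta(cds_b)
    rows = []
    for (na, sa), (nb, sb) in zip(a_recs, b_recs):
        aln = build_codon_alignment(sa, sb, gene_ids=(na, nb))
        est = estimate_gy94(aln) if method == "GY94" else estimate_ng86(aln)
        rows.append(est.as_record())
    df = pd.DataFrame(rows)
    if out:
        write_results(df, out)
    click.echo(df.to_string(index=False))


@main.command()
@click.argument("ks_file", type=click.Path(exists=True))
@click.option("--rate", type=float, default=DEFAULT_RATE, show_default=True,
              help="Substitutions per synonymous site per year (per lineage).")
@click.pass_context
def clock(ctx: click.Context, ks_file: str, rate: float) -> None:
    """Clock dating from a file with one Ks value per line."""
    _setup_logging(ctx.obj["verbose"], None)
    ks = [float(line) for line in Path(ks_file).read_text().split()]
    est, _ = clock_report(ks, rate)
    click.echo(json.dumps(est.summary(), indent=1))


@main.command()
@click.argument("candidates", type=click.Path(exists=True))
@click.argument("reference", type=click.Path(exists=True))
@click.option("--variants", type=click.Path(exists=True), default=None,
              help="TSV with columns locus, pos, allele_O, allele_P.")
@click.pass_context
def assign(ctx: click.Context, candidates: str, reference: str,
           variants: str | None) -> None:
    """Assign candidate haplotypes to sub-genomes."""
    _setup_logging(ctx.obj["verbose"], None)
    cands = read_fasta(candidates)
    ref_name, ref_seq = read_fasta(reference)[0]
    calls = assign_by_identity(cands, ref_seq)
    if variants:
        vt = pd.read_csv(variants, sep="\t")
        vset = DiagnosticVariantSet(
            locus=str(vt["locus"].iloc[0]),
            variants=[(int(r.pos), str(r.allele_O), str(r.allele_P))
                      for r in vt.itertuples()],
            reference=ref_seq)
        calls = [genotype_hsvs(c, vset) for c in cands]
    df = pd.DataFrame([c.as_record() for c in calls])
    click.echo(df.to_string(index=False))


@main.command()
@click.option("--n-genes", type=int, default=10, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--incidence", type=int, default=9148, show_default=True,
              help="Target gene incidence (bp per gene).")
@click.option("--delete-genes", type=str, default=None,
              help="Comma-separated ancestor gene ids to delete from P'.")
@click.option("--outdir", type=click.Path(), default="simulated")
@click.pass_context
def simulate(ctx: click.Context, n_genes: int, seed: int, incidence: int,
             delete_genes: str | None, outdir: str) -> None:
    """Simulate a homoeologous region pair with ground truth."""
    _setup_logging(ctx.obj["verbose"], outdir)
    spec = (sim.DeletionSpec(genes=delete_genes.split(","))
            if delete_genes else None)
    params = sim.SimParams(n_genes=n_genes, seed=seed,
                           target_gene_incidence=incidence,
                           deletion_spec=spec)
    region_o, region_p, truth = sim.simulate_pair(params)
    sim.write_simulation(region_o, region_p, truth, outdir)
    click.echo(f"wrote {outdir}/: region_O/region_P FASTA+GFF3, truth tables")


if __name__ == "__main__":
    main()
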