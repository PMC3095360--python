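# homoeolog

Comparison of paired homoeologous genomic regions in allopolyploid
genomes.

Allopolyploids carry two (or more) diverged sub-genomes in one nucleus.
In white clover (*Trifolium repens*, 2n = 4x = 32) these are called
**O** — the complement closest to the diploid progenitor
*T. occidentale* — and **P'**.  Given two annotated regions, one per
sub-genome (FASTA + GFF3), this package answers the questions a
sequencing or comparative-genomics project asks of such a pair:

* which genes are **homoeologues** (same putative function, conserved
  order), and which are unique to one sub-genome;
* how similar are they — per-exon and per-intron nucleotide identity,
  protein identity and similarity (EMBOSS-style, affine-gap
  Smith–Waterman/Needleman–Wunsch with gap open 10 / extend 0.5), and a
  VISTA-style sliding-window identity profile of the whole region;
* how fast are they evolving — **Ka/Ks** under the Goldman–Yang (GY94)
  maximum-likelihood codon model (Nei–Gojobori counting as an
  independent cross-check), with the substitution flow through the rate
  matrix partitioned into synonymous/non-synonymous components the way
  CODEML does;
* when did the sub-genomes split — a molecular clock
  **T = Ks / (2r)** applied to the median Ks, default
  r = 6.1×10⁻⁹ synonymous substitutions per site per year;
* is the region **microsyntenic** with a reference genome segment —
  ≥ 3 genes matching at E ≤ 0.01 (Karlin–Altschul statistics), with a
  synteny-quality percentage (default 100·2S/(Nq+Nt));
* which sub-genome is a candidate haplotype from — highest identity to
  the progenitor, or a vote over diagnostic variants (HSVs).

A ground-truthed **simulator** generates paired homoeologous regions —
gene structures with the observed clover geometry (mean exon 348 bp,
intron 314 bp, one gene per 9148 bp), coding sequence evolved by GY94
jump-chain sampling (defaults tuned to median Ks ≈ 0.05), diverged
intergenic sequence with indels, segmental deletions with a 32 bp
breakpoint repeat, and sub-genome-specific TE insertions — so every
stage is testable at desk scale.  See `docs/methods.md` for the models
and defaults.

## Worked example

Simulate a region pair with one segmental deletion and one
sub-genome-specific TE, then run the comparison:

```python
from homoeolog import (SimParams, DeletionSpec, TESpec, simulate_pair,
                       pair_homoeologues, clock_report)

params = SimParams(n_genes=8, target_gene_incidence=3000, seed=42,
                   deletion_spec=DeletionSpec(genes=["g004"]),
                   te_spec=[TESpec("Copia", 1000, "P'")])
region_o, region_p, truth = simulate_pair(params)
comparison = pair_homoeologues(region_o, region_p)
print(comparison.pairs_table()[["gene_o", "exon_identity_pct",
      "intron_identity_pct", "protein_identity_pct", "ks", "ka"]]
      .round(4).to_string(index=False))
print("unique to O:", comparison.unique_o, " unique to P':", comparison.unique_p)
clock, _ = clock_report([p.kaks for p in comparison.pairs if p.kaks])
print("median Ks =", round(clock.median_ks, 4), "->",
      round(clock.T_mya, 1), "Mya")
```

prints

```
gene_o  exon_identity_pct  intron_identity_pct  protein_identity_pct     ks     ka
  g001            98.7700                  NaN               98.8889 0.0333 0.0051
  g002            98.7504              86.0566               99.2366 0.0538 0.0036
  g003            98.5490              81.1895               98.2716 0.0600 0.0081
  g005            98.3273              85.8065               98.7805 0.0545 0.0055
  g006            97.7377              80.3922               95.4128 0.0291 0.0235
  g007            97.9097              86.6438               98.3209 0.0428 0.0080
  g008            98.7654                  NaN               99.0654 0.0315 0.0045
unique to O: ['g004']  unique to P': []
median Ks = 0.0428 -> 3.5 Mya
```

Seven of the eight ancestral genes pair up with exon identities near
99 % and introns near 85 % (introns drift faster); `g004`, deleted from
the P' copy by the simulated segmental deletion, correctly surfaces as
unique to O.  Single-exon pairs have *missing* (not zero) intron
identity.  The median Ks of 0.0428 converts to a ~3.5 Mya split under
the default clock — close to the generating target of Ks 0.05 / 4.1 Mya
for this small sample of genes.

The same pipeline runs from the shell on FASTA/GFF3 inputs via a YAML
config:

```sh
homoeolog simulate --n-genes 8 --seed 42 --outdir simdata
homoeolog compare config.yaml      # pairing, identities, Ka/Ks, clock
homoeolog synteny config.yaml      # shared genes + synteny quality
homoeolog kaks a_cds.fasta b_cds.fasta
homoeolog assign candidates.fasta progenitor.fasta --variants hsvs.tsv
```

Every run writes a `manifest.json` (config hash, seed, version) beside
its outputs.

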