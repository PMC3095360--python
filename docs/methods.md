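# Methods

`homoeolog` compares paired homoeologous genomic regions of an
allopolyploid — the model system is white clover (*Trifolium repens*),
whose two co-resident diploid complements are labelled O (the one closest
to the progenitor *T. occidentale*) and P' — and quantifies their
divergence in genic and intergenic space.  This note documents the models,
the defaults, and the choices made where the design was genuinely open.

## Pairwise alignment

Global (Needleman–Wunsch) and local (Smith–Waterman) alignment use Gotoh's
three-state affine-gap recurrences with EMBOSS gap semantics: a gap of
length L costs `gap_open + (L−1)·gap_extend`, defaults 10 and 0.5, so the
dynamic programme runs in floats.  DNA scoring defaults to +5/−4
(EDNAFULL-like); protein alignments use BLOSUM62.  `N` scores as a
mismatch against everything, itself included, and never counts as an
identity.  The traceback tie-break is fixed — diagonal over up (gap in the
second sequence) over left — so alignments are deterministic; identity is
identical columns over all aligned columns (end gaps included in the
denominator), and protein similarity counts columns with a positive
substitution score, matching EMBOSS `water`/`needle` semantics.  The
kernels are exact: tests compare their scores against exhaustive
enumeration of the alignment space for all short sequence pairs, and
against Biopython's independent `PairwiseAligner` implementation.

Windowed identity profiles (default 100 bp windows, 25 bp step — the
classic VISTA-style view; both configurable) are computed over alignment
columns indexed by first-sequence coordinate.  For whole-region profiles,
where an affine DP over 10⁵–10⁶ bp per side is not sensible, the regions
are aligned with an edit-distance aligner (edlib) and its alignment path
feeds the same profiler; element-level (exon/intron/protein) statistics
always use the affine kernels.

### E-values

Local-alignment significance uses the ungapped Karlin–Altschul statistic
E = K·m·n·e^(−λS).  λ solves Σ pᵢpⱼ·e^(λ·sᵢⱼ) = 1 by root-finding; K is
computed by the lattice-score series (iterated convolution of the
per-column score distribution).  For the default +5/−4 scheme this
reproduces the published ungapped blastn constants (λ ≈ 0.192,
K ≈ 0.176).  Applied to gapped scores the statistic is approximate, so
similarity *search* (synteny matching) uses stiff gap costs
(open 30, extend 15) that keep chance alignments in the logarithmic
regime where the approximation is calibrated — checked in simulation: the
chance-hit rate at E ≤ 0.01 matches what the E-value predicts.  The
permissive EMBOSS extension of 0.5 is reserved for identity measurement
between sequences already known to be homologous; using it for search
would let chance alignments chain short matches through long cheap gaps
and grossly deflate E-values.

## Ka/Ks estimation

The Goldman–Yang (GY94) codon model is fit by maximum likelihood to each
aligned homoeologue pair.  States are the 61 sense codons of the standard
code; the rate for a single-nucleotide change i→j is
πⱼ·κ^[transition]·ω^[non-synonymous], zero for multi-step changes, and the
matrix is scaled to one expected substitution per codon per unit branch
length.  Codon frequencies are F3x4 from both sequences pooled, floored
at 10⁻⁶ and renormalised.  The likelihood Π πₐ·P(t)ₐᵦ is maximised over
(log t, log κ, log ω) by L-BFGS-B from a p-distance start (t₀ = 3·p,
κ₀ = 2, ω₀ = 0.4), with three seeded random restarts on failure; P(t) is
computed by symmetrised eigendecomposition (the model is reversible).
Ks and Ka are derived CODEML-style: the substitution flow through Q at
the MLE is partitioned into synonymous and non-synonymous components, and
each is divided by the corresponding mutational-opportunity site fraction
(the flow partition at ω = 1), so S + N = 3·(codons).  Identical
sequences short-circuit to Ks = Ka = 0; codon p-distance above 0.75 is
reported as saturation rather than a number.

Codon alignments are protein-guided: translate, globally align the
proteins, back-map to codons, and drop columns containing gaps, stops or
N (CODEML `cleandata` behaviour).  Fewer than 10 clean codon pairs is an
error, not an estimate.

Nei–Gojobori (1986) counting with Jukes–Cantor correction is implemented
as an independent cross-check: sites per codon from the fraction of
synonymous single-base changes (stop-creating changes counted
non-synonymous), differences averaged over minimal mutational pathways
(stop-crossing pathways excluded).  On simulated data with Ks ≤ 0.1 the
two estimators agree within 0.02; NG86's upward bias under transition
bias (κ > 1) is visible at larger distances, as expected.

## Molecular-clock dating

T = Ks / (2r), with r = 6.1×10⁻⁹ synonymous substitutions per site per
year — a legume-calibrated per-lineage rate; the divisor 2 is there
because Ks accumulates on both lineages since the split.  The headline
estimator is the **median** Ks across pairs (robust to the occasional
saturated or constrained gene); mean and sample standard deviation
(ddof = 1) are reported alongside.  The bundled reference table of 16
homoeologue Ks values reproduces the published median 0.05085 and the
4.2 Mya O/P' divergence estimate exactly.

## Homoeologue pairing and region statistics

Genes are candidate homoeologues when their putative-function strings
match after normalisation (lower-case, collapsed whitespace); nothing
else is parsed out of the free text.  The reported pairing is the
longest order-preserving chain (dynamic programme over the two gene
orders), with ties broken by the higher summed protein identity, which
also resolves duplicated function labels reciprocally.  Genes left
unpaired inside the compared interval are reported as unique to their
sub-genome — this is how simulated segmental deletions surface.

Paired genes are compared element-wise: exons and introns are matched
positionally from the 5' end of the transcript (surplus elements of the
longer structure are reported but excluded from identity means — a
single-exon pair has *missing* intron identity, not zero), each element
globally aligned; protein identity/similarity comes from the global
protein alignment; Ka/Ks from GY94.  Pairs whose structures disagree or
whose CDSs cannot be estimated are flagged incomplete and excluded from
aggregate means entirely, mirroring how such rows are footnoted out of
published averages.

Region summaries: gene incidence = region length / gene count (rounded);
gene space = the fraction of bases under gene *spans* (first exon start
to last exon end, introns included), merged across overlapping genes.
Span semantics, not exon-only coverage, is what reproduces the published
per-BAC gene-space fractions (e.g. 45.20 % for a 61 kb, 10-gene clone).

By default the compared interval is each whole region; when two clones
only partially overlap, the overlap intervals can be supplied explicitly
(`overlap_o`/`overlap_p`).  An alignment-based overlap detector was
considered and rejected: at BAC scale the affine kernels do not apply,
and an edit-distance band is ambiguous when intergenic sequence has
diverged past recognition, so the package prefers an explicit, recorded
choice.

## Microsynteny

Each query CDS is searched against a reference region's CDS set by local
alignment (search scoring above); the best hit per query is kept, ties
broken by the smaller target ordinal, and hits above the E-value cutoff
are discarded.  A region pair is syntenic when ≥ `min_genes` (default 3)
queries hit at E ≤ 0.01 — the classic microsynteny rule.  Quality
defaults to the symmetric 100·2S/(Nq+Nt); S/Nq and S/union are selectable
and the formula used is always recorded in the output, because no single
simple formula reproduces every published quality figure and the choice
must stay visible.  Order conservation is summarised as the longest
increasing subsequence of target ordinals (in query order) over S;
orientation is conserved when strands agree.

## Sub-genome assignment

Identity ranking: among ≥ 2 candidate haplotypes of one locus, the unique
maximum of global-alignment identity to the progenitor reference is
called O, the rest P'; an exact tie makes all calls ambiguous.
Diagnostic variants (HSVs): the candidate base is read at each variant
position through the candidate-to-reference alignment (gap positions are
excluded from both counts); a majority with margin ≥ 2 calls the
sub-genome.  The margin of 2 exists because a one-variant majority is
within sequencing-error range; the coverage floor (≥ 50 % of variant
positions aligned) guards against calling from fragments.

## The simulator

The generator produces the statistical structure the analysis assumes,
with full ground truth, so every stage is testable without external data.

* **Ancestor**: `n_genes` gene models with geometric exon/intron lengths
  (means 348/314 bp, floors 20/50 bp), 1–5 exons per gene, CDS in frame
  with start/stop and no internal stop, random strand; intergenic filler
  sized so the region length is `n_genes × 9148` bp.  These defaults are
  the observed clover region geometry.
* **Divergence**: each CDS evolves on two branches of t/2 by sampling the
  GY94 jump chain (exponential waiting times), so realised synonymous and
  non-synonymous counts per gene are known exactly; the 61-state space
  keeps truth CDSs stop-free by construction (the terminal stop is held
  fixed).  The default total distance is derived from a target median Ks
  of 0.05 at κ = 2, ω = 0.14 (ω from the observed Ka/Ks ratio
  0.0071/0.0518).  Introns and intergenic sequence follow a
  transition-biased (K2P) process at 0.15 substitutions/site across both
  lineages, plus geometric indels (rate 0.002/site, mean 8 bp) that never
  touch exons; annotations are lifted over through every edit.
* **Structural events**: an optional segmental deletion removes whole
  genes from one sub-genome and plants a 32 bp repeat (a copy of the
  immediate 5' flank) at the junction — the footprint illegitimate
  recombination leaves; optional TE insertions place labelled random
  sequence (not realistic TE models) into intergenic space of one
  sub-genome post-divergence.
* **Determinism**: one seeded RNG stream drives all sampling in a fixed
  order; identical parameters give byte-identical FASTA/GFF3/truth
  output.  Reordering draws is a breaking change.

What the simulator does *not* emulate: real TE sequence families,
tandem repeats, recombination, polymorphism within sub-genomes,
sequencing or assembly error, and annotation error (gene models are
correct by construction).  Passing recovery tests therefore demonstrates
the statistical machinery, not robustness to mis-annotation.

## Problem sizes and numerical choices

The recovery experiments run at desk scale, chosen to give tight Monte
Carlo error while staying cheap: 20 replicates of 2000 codons for the
GY94 check (median recovered Ks lands within a few percent of the
generating value), and a single 100-gene pair (~0.9 Mb per sub-genome,
two deleted genes) for the end-to-end round trip, which recovers the
generating median Ks within 10 % and lists every deleted gene as
sub-genome-unique.  Optimiser convergence uses `ftol` 10⁻¹², transition
probabilities are floored at 10⁻³⁰⁰ before logs, codon frequencies at
10⁻⁶.  Ks/Ka are reported at 4 decimals and identities at 2, matching
the precision of the published tables they mirror.

## Known limitations

* Pairwise (two-sequence) GY94 only; no site/branch models, no
  likelihood-ratio tests of ω.
* E-values are an ungapped approximation applied to gapped scores and are
  flagged as such; they support a detection rule, not fine-grained
  significance claims.
* Homoeologue candidacy relies on consistent function annotation between
  the two regions; unannotated or inconsistently named genes fall out as
  unique.
* The clock assumes neutral, clock-like synonymous divergence; the
  reported time inherits the calibration uncertainty of the rate.
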