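# Methods

`sexchrom` reimplements, as a tested library, the analysis stages used to
characterize a young, partially degenerate Y chromosome from a long-read
male assembly: partitioning contigs between the X and the Y, validating
and patching the Y scaffold with BAC inserts, measuring gametolog
divergence and dating evolutionary strata, classifying the origin of Y
genes, profiling the centromeric repeat and its CENP-A ChIP signal,
testing transposable-element (TE) density, and quantifying dosage and
expression bias.  Every stage runs end-to-end on a synthetic genome with
known truth, so the whole pipeline is testable without any external data.

## The synthetic genome

`simulate.SimulationConfig` fixes the study conditions.  The generator
builds a handful of autosomes and an X chromosome carrying intact ORFs
(ATG…stop, no internal stops, introns of jittered length), then derives
the Y from the X:

* The pseudoautosomal region (PAR) is copied byte-identically.
* The non-PAR X is divided into three strata (fractions 0.40/0.35/0.25 of
  the non-PAR length) mutated at per-site rates 0.15, 0.04, and 0.03 with
  a 2:1 transition bias.  These rates and the per-stratum gene-loss
  fractions (0.82/0.24/0.31) mirror the observed median gametolog
  divergences and retention levels of a three-strata fish Y; gene counts
  per stratum (62/24/34) mirror the observed relative stratum sizes at
  desk scale (~1/10 of the real gene census on a ~0.2 Mb chromosome).
* Lost gametologs are deleted from the Y; a subset of retained genes is
  duplicated within the Y (~1% divergence between copies); autosomal
  genes are translocated DNA-wise (introns retained, ~2% divergence),
  some in two copies; a few de novo ORFs of unknown origin are added.
* TEs are mutated copies (5% from a common consensus) overwriting
  intergenic sequence at 3% density on autosomes/X (5% in the PAR) and
  12% on the Y.  Gene and intron lengths are jittered per gene because
  size-quantized indels would otherwise make unrelated regions share
  alignment diagonals and produce artifactual chained blocks.
* A tandem array of a 187 bp monomer (60 copies, 10% per-copy mutation)
  is planted in stratum two as the centromere.
* The Y scaffold masks six hidden intervals (2.5–4 kb) with 300 bp
  N-runs; contigs are the non-N runs, and one gap sits exactly at the
  PAR boundary so the PAR forms its own contig.  BAC-sized inserts
  (~8 kb, scaled from real ~170 kb clones in proportion to the genome)
  are cut from the true Y sequence in four classes: within-contig,
  gap-spanning, gap-extending (overhang > 1 kb so the verdict is
  decidable), and discordant with a planted 2 kb inversion or deletion.
* ChIP IP/input tracks are Poisson coverage with 8-fold IP enrichment
  inside the planted centromere; male/female depth tracks use factors
  1/0.5/0.5 (autosome/X/Y) for males and 1/1/0 for females; tissue
  counts are negative binomial (dispersion 0.3) over 17 samples
  (testis 6, liver 6, brain 3, larvae 2) with an 8-fold testis bias for
  duplicated and translocated Y genes.

Identical seeds give byte-identical outputs.  What the generator does
*not* emulate: sequencing error, indel mutation within homologous
sequence, realistic TE families, Hi-C contacts, or read-level data.
Passing truth-recovery tests therefore demonstrates the correctness of
the decision rules and statistics on substitution-dominated divergence,
not robustness to alignment artifacts of real long-read data — for real
inputs the PAF/coords ingestion path expects alignments from minimap2 or
nucmer.

## Alignment

`align.anchor_align` is an exact-k-mer-seeded, strictly gapless local
aligner: anchored diagonals are scanned for maximal positive-scoring runs
(+1 match, −1 mismatch by default), equivalent to the exhaustive best
gapless segment under the same scoring (verified against an O(n³)
enumeration in tests).  Repetitive anchors can be suppressed MUM-style
(`max_kmer_hits=1`), which the genome-scale stages use.  Chaining
(`chain_colinear`) joins colinear same-strand blocks when the implied
indel is ≤ 1 kb; for a chain step across an annotated N-gap only the
gap itself is of unknown length, so the gap's span is discounted and the
remainder of the target skip is still held to the indel bound.  This
aligner is adequate for the substitution-only synthetic data; it is not a
general-purpose aligner.

## Contig partitioning

Per-contig identity to the reference X is the alignment-length-weighted
mean over blocks; coverage is the union of query intervals.  Contigs with
≥ 25% coverage are X-linked above the identity threshold and Y candidates
at or below it (the boundary value goes to the Y); contigs with less
coverage are `partial`, with none `unaligned`; the Y set is the union of
the last three.  The threshold is not fixed a priori: following the
procedure of sweeping 92–98% and choosing the value whose X-linked total
length best matches the known X length, the truth-recovery stage
classifies at the swept threshold.  At the synthetic divergences
(reference 0.5%, strata ≥ 3%) the sweep lands strictly between them.
Haplotig collapse marks the shorter contig of any pair aligned over
≥ 1 kb at ≥ 98% identity, greedily from the longest contig down so a
redundant contig never absorbs others.

## BAC concordance and merging

Split alignments are chained into one footprint before rule evaluation.
The three rule sets apply in order at ≥ 99% footprint identity:
concordant (both ends within 1 kb of the BAC ends, footprint span within
10 kb of the BAC length, and — to keep the rules mutually exclusive —
no gap inside the footprint), spans-gap (ends within 1 kb, aligned
columns not exceeding the BAC length, ≥ 1 gap wholly contained), and
extends-into-gap (one alignment end exactly on a contig end abutting a
gap, the outer BAC end reached within 1 kb).  Anything else is
discordant, which is how planted inversions (mixed-orientation blocks)
and multi-kb indels (chain break) surface.  Blocks below 95% identity
are dropped before chaining since no verdict can use them.  Merging
applies at most one BAC per gap (highest identity, ties to the longer
insert): spanning BACs replace their whole footprint, extending BACs
replace only the reached-into Ns with their overhang; a liftover table
maps old to new coordinates, and total non-N length can only grow.

## Divergence, strata, and dating

dS/dN uses Nei–Gojobori (1986) counting with Jukes–Cantor correction:
site fractions enumerated per codon (mutations to stops excluded from
the denominators), multi-position differences averaged over equally
weighted mutational pathways (pathways through stops skipped, with a
fallback to all pathways when none avoid one), and proportions ≥ 0.75
flagged saturated.  The estimator matches an independent brute-force
oracle to 1e-9 on random codon pairs.  This replaces pairwise ML
(codeml-style) estimation: at the divergence levels involved the
counting estimate is adequate, is fully verifiable, and needs no
external binary; on real data small numeric differences from ML output
are expected, so published ML medians are not asserted.  Filters follow
the source procedure: ≥ 95% CDS coverage, lowest-dS hit for multi-hit
genes (ties to the leftmost Y position), dS > 2 removed, dN/dS undefined
at dS = 0 (an ML sentinel of 99 maps to the same flag).  Strata are
assigned by half-open breakpoint lookup — Y order PAR/S1/S2/S3 at
0.34/4.67/9.67 Mb, X order PAR/S2/S3/S1 at 2.5/6.89/12.5 Mb.  Ages scale
the stratum median dS against a 0.184 outgroup divergence dated at 26 My
(so 0.155 → 21.9 My), and the loss rate is 100 × fraction lost / age.
Mann-Whitney tests use the exact null for tie-free samples with
min(n) ≤ 8 and a tie-corrected normal approximation otherwise.

## Gene origin

An X hit always wins (X-ancestral); otherwise an autosomal paralog
counts only below dS 0.101 (the oldest stratum's median), guarding
against ancient paralogs; otherwise unknown.  Copy class comes from the
number of distinct Y loci after lowest-dS de-duplication; ChrUn-style
hits are dropped before any rule.  Intron retention classifies
translocations as DNA-based versus retrogene candidates, with
single-intron autosomal paralogs uninformative.

## Centromere and ChIP

Monomers are gapless local hits of the consensus kept within ±10 bp of
the consensus length (mismatch cost 2 so truncated copies trim to their
true extent and fail the window); overlaps resolve to the higher
identity.  The majority consensus votes per column with ties in the
fixed order A<C<G<T.  Pairwise and windowed identities use global
(Needleman–Wunsch) alignment with gap columns as mismatches; windows are
matched against the doubled consensus so junction-straddling windows
(rotations) score as array.  ChIP fold enrichment is the ratio of
library-size-normalized IP to input per position (zero-input positions
masked), averaged in 1 kb windows; the peak is the longest run of
windows above 4× the track median (the factor 4 is a package choice —
the source reports only "a prominent peak" — and is configurable).

## TE permutation test

Null windows are drawn with replacement from the autosomes, chromosome
probability proportional to its number of valid starts.  P uses the
add-one convention (1 + #{null ≥ obs}) / (n_perm + 1), one-sided for
enrichment; under a uniform TE null the P distribution is uniform (KS
checked over 200 seeds).  Assembly gaps are not modelled in the
synthetic autosomes; on gapped real references callers should pass
gap-free interval sets.

## Dosage and expression

TMM factors are computed on autosomal transcripts only and then applied
to Y genes, so male-biased Y expression cannot distort the scaling.  The
implementation follows the standard recipe (reference sample by
upper-quartile closest to the mean, 30% M-trim, 5% A-trim,
inverse-variance weighting, geometric-mean-one normalization) and
matches edgeR's `calcNormFactors` to 1e-8 in a cross-check test; edgeR
itself is never the implementation.  log2 fold changes compare group
means of CPM with a 0.5 pseudocount — a transparent substitute for a
full count-model fit, which is out of scope.  Class contrasts and the
haploinsufficiency contrast (retained-on-Y < lost-from-Y, one-sided per
stratum) use the same Mann-Whitney machinery.  Coverage checks take the
median of 1 kb window medians per chromosome relative to autosomes.

## Not reproducible at desk scale

The following published quantities depend on the deposited sequencing
data and external tools and are deliberately not targets of the test
suite; the property and truth-recovery suites above stand in for them:

* the real Table-of-medians dS/dN values per stratum (codeml on real
  alignments; our NG86 recovers the *configured* synthetic rates),
* the 92 of 101 concordant BAC clones (real Sanger inserts),
* the centromere identity percentages 84.6% (to the genome-wide core
  repeat), 89.5% (among Y monomers), and 86.8% (Y monomers vs the
  female-derived consensus),
* the TE permutation P = 0.135 for the real PAR,
* all edgeR FDR values quoted for individual genes.

## Numerical choices and degenerate inputs

Half-open 0-based coordinates internally; GFF written 1-based inclusive.
Identity ties in monomer resolution go to the leftmost hit; chain ties
to the leftmost target start; threshold-sweep ties to the lower
threshold.  Empty inputs return empty results where meaningful (no
anchors → no blocks; no BACs → zero counts) and raise `ValueError` where
a computation is undefined (zero-length windows, all-zero input track,
zero autosomal median).  dN/dS is `None`, not 0 or inf, when dS = 0.
Problem sizes used throughout (0.15–0.22 Mb chromosomes, ~8 kb BACs,
~120 genes) are the package's chosen desk scale: large enough that every
classifier margin is several standard deviations wide, small enough to
regenerate from a seed in about a second.
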