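# Methods

`xenomix` is a self-contained simulation study of how contaminating mouse
reads in patient-derived xenograft (PDX) DNA sequencing affect read
alignment and SNV calling under three handling strategies. Everything —
the genome pair, the reads, the aligner, the caller, and the scoring — is
generated and executed inside the package, so every accuracy number is
computed against known ground truth.

## The model

### Surrogate genome pair

Real PDX analyses align against hg19 and mm10. At desk scale we forge a
surrogate pair instead:

* An ancestor ("human") genome is drawn i.i.d. with configurable GC
  content (default 0.41, human-like), split over `n_chromosomes`.
  Defaults: 500 kb over 2 chromosomes.
* ~50 protein-coding gene models are placed without overlap (1–3 exons,
  total CDS a multiple of 3, exons ≥ 200 bp so reads fit inside single
  exons). They cover roughly 15% of the genome.
* A related ("mouse") genome is evolved from the ancestor with per-base
  substitution rates of **0.15 inside exons** and **0.35 outside**, plus
  indels (rate 0.02, geometric lengths with mean 2) outside exons only.

The exonic rate is anchored to the observed ~85% human/mouse coding
identity; the non-exonic rate and indel rate are chosen so that 50–100 bp
reads from one genome only occasionally align to the other — the ambiguity
regime that makes strategy choice matter. Keeping indels out of exons
keeps coding regions colinear between the genomes, mirroring the strong
selection against coding frameshifts; it also keeps homologous exons
alignable without large gaps. The forge does **not** model repeats, GC
isochores, or synteny; consequences are discussed under Limitations.

### Sample mutation and read simulation

Each reference genome is mutated at a per-base `mutation_rate` to create
the sampled individual's genome; a mutation is an SNV with probability
0.9, otherwise an indel (insertion/deletion 50:50, geometric lengths,
mean 2). Mutations swallowed by an earlier deletion are dropped, so
replaying the recorded truth list against the reference reproduces the
mutated genome exactly (tested). Truth positions are recorded in
*reference* coordinates via a per-base coordinate map, so alignments are
scoreable even downstream of sample indels.

Reads are single-ended, fixed-length, drawn uniformly (position and
strand) from the sample genome (whole genome or exome intervals), with
each base flipped to a different uniform base with probability
`error_rate`. Base qualities are the flat Phred equivalent of the error
rate, capped at Q40; platform-specific error profiles are out of scope.
Read names encode full truth
(`origin:chrom_start_strand_nerrors_serial`), following the read-simulator
convention of encoding truth in names so external aligners stay scoreable.

Host and graft reads are mixed at an exact ratio (9:1 = 10% contamination,
1:1 = 50%) to a total of `round(depth × host_region_length / read_length)`
reads; the effective host depth is `total_depth × host_fraction`
(e.g. 60× × 0.9 = 54×).

The 8 parameter profiles cross mutation rate {0, 1%}, read length
{50, 100} bp and error rate {0.01%, 1%}, named `m{L,H}.len{050,100}.e{L,H}`;
crossing them with the two ratios and two region modes gives the 32-run
grid.

### The aligner

A deliberately small seed-and-extend aligner stands in for Bowtie2/BWA:

* exact 15-mer seeds sampled every ⌊L/4⌋ bases on both strands;
* candidate loci scored by a banded (±10) global-in-read, affine-gap DP
  (match +1, mismatch −2, gap of length g costs 4 + g); candidates with
  ≤1 mismatch take a gap-free shortcut that is provably optimal under
  this scoring;
* **unique-best-match rule**: a read is aligned only when a single locus
  attains the best score; ties (within or across genomes) leave it
  unmapped with MAPQ 0. MAPQ is otherwise `min(60, 2·(best − second))`;
  only its zero/non-zero distinction is load-bearing.
* a read is "**successfully aligned**" when mapped, unique, and its score
  reaches `floor(0.6 · L)` — an end-to-end identity floor mimicking
  default aligner sensitivity; configurable.

The aligner is verified against an exhaustive full-scan affine DP oracle
on hundreds of randomized ≤1 kb instances; unmapped outcomes are accepted
only for genuine score ties or when the planted edits destroy every
sampled exact seed (the stated sensitivity contract of exact seeding).
External aligners can be substituted through SAM ingestion; the truth
codec in read names keeps their output scoreable.

### Strategies

* **direct**: align everything to the human index only.
* **filtering**: align to mouse first; discard reads that are
  successfully aligned (optionally with a stricter score cutoff, default
  none — mirroring "discard whatever the aligner reports as aligned");
  align the remainder to human. Discarded reads are retained as the
  mouse-aligned set so contamination can still be estimated.
* **combined**: align once against a union index over both genomes
  (namespaced chromosomes, semantically identical to concatenating the
  FASTAs); assign each read to the genome of its unique best locus.

The experiment runner computes one alignment pass per genome and derives
all three strategies from the two record sets; this is exactly equivalent
to running them independently (the union-index outcome is a function of
the per-genome best/second-best scores) and is verified against the
independent code paths in the tests.

Contamination is estimated as
`mouse_aligned / (mouse_aligned + human_aligned)`; for the direct
strategy the mouse count comes from additionally aligning all reads to
the mouse reference, matching the published bookkeeping.

### Variant calling

A minimal pileup caller stands in for samtools (it is a stand-in, not a
replica): per covered column, diploid genotype likelihoods for
{ref/ref, ref/alt, alt/alt} under independent observations with per-base
error from the Phred quality; uniform genotype prior; only the most
frequent non-reference allele is considered; ploidy is fixed at 2 and
indels are not called (evaluation is SNV-level). QUAL is
−10·log₁₀ P(ref/ref | data); a call is emitted when the MAP genotype is
non-reference, requires depth ≥ 3, and passes the inclusive QUAL ≥ 13
filter (error probability 10^−1.3 = 0.05012). Pileup columns store
per-base counts with the per-base mean quality — exact for the
flat-quality reads this simulator produces.

### Scoring

FDR = FP/(FP+TP), FNR = FN/(FN+TP); an empty denominator is reported as
NaN. At the alignment level a human read must hit its true position
(tolerance 5 bp, absorbing indel-induced leftmost shifts) on the correct
strand; a misplaced human read counts **both** as FP and FN, since it is
both incorrectly aligned and not correctly aligned. Variant matching
requires chromosome, position and alternate allele (position-only
matching would inflate TP). Non-synonymous classification rebuilds the
codon strand-aware from the reference and translates with the standard
genetic code.

In exome mode the variant-level truth set is restricted to the simulated
exome intervals: reads cannot reach variants outside the regions they
were drawn from, and scoring them would pin FNR near 1 and carry no
information about strategy differences.

## Problem sizes and study conditions

Defaults were chosen once, before any accuracy targets were evaluated, to
give stable rates in minutes on one CPU:

| quantity | default |
|---|---|
| host genome | 500 kb, 2 chromosomes |
| genes / coding fraction | 50 genes, ~15% of bases |
| divergence | 0.15 exonic / 0.35 non-exonic / 0.02 indel |
| perceived depth | 30× (stand-in for the original 60×) |
| qualitative-suite runs | whole-genome 24×, exome 40×, seeds {1,2,3} |

The exome runs use higher depth because the exome is ~7× smaller (so the
runs stay cheap) and variant-calling rates stabilise with depth. The
depth-variation experiment keeps the published 54×:6× / 30×:30× /
60×:60× labels with a proportional scale knob.

## Design decisions on genuinely open points

* The original filtering step's score threshold beyond "aligned" is not
  documented; the default discards exactly what the aligner reports as
  successfully aligned, with `filter_min_score` exposed.
* Whether planted indels were length-1 only is unknown; geometric lengths
  (mean 2) are used and exposed as a knob.
* The positional tolerance for "correct position" is not documented;
  default 5 bp, configurable.
* The no-contamination baseline uses the same *total* read count drawn
  from human only (a `baseline_host_share_only` switch matches host-share
  depth instead).
* The divergence/mutation model is this package's own; it does not
  replicate the internals of any particular read simulator.
* FDR/FNR follow the standard definitions above (the formulas in the
  source text are typographically lost but consistent with its prose).

## What passing tests do and do not show

The synthetic genomes are i.i.d. sequence without repeats or conserved
non-coding elements, divergence is spatially homogeneous within each
region class, and read errors are uniform. Passing the qualitative suite
shows the *mechanisms* — mouse reads cross-aligning into human exons
inflate direct mapping's FDR; filtering throws away conserved human
reads; the combined reference resolves most ambiguity and tracks the true
mixing fraction within ±0.02 — and reproduces the published orderings
(direct's FDR ≥ the special strategies' at 1:1, a much larger gap in
exome mode, combined's variant FNR ≤ filtering's, combined's variant FDR
the most stable across contamination levels). It does **not** reproduce
the absolute published rates, which depend on genome-scale repeat
structure, real aligner heuristics and 60× depth. One published
stability finding — variant *FNR* being insensitive to the mixing ratio
for the combined strategy — is a saturation effect at 60× and is not
expected at desk-scale depths, where FNR is depth-limited for every
strategy; the stability check is therefore made on FDR, where the
mechanism (mouse-read false positives) is what the strategy controls.

## Numerical notes

* All randomness flows from a single integer seed per run through
  labelled, CRC-derived child seeds; identical configs are byte-identical
  in outputs (tested on FASTQ and report tables).
* DP scores are exact integers computed in float32 with a −10⁹ sentinel;
  band ±10 covers the indel burden of the default rates with margin.
* Genotype likelihoods are computed in log10 with a 3-term log-sum-exp;
  QUAL is clamped at 0 from below and unbounded above.
* Ties for the most frequent alternate allele break deterministically
  (count, then base order).
* Degenerate inputs (empty genomes, regions shorter than the read length,
  reads shorter than k, empty pileups) return empty results or raise
  parameter errors; they are covered in the unit tests.

## Known limitations

* Single-end reads only; no paired-end rescue.
* No base-quality-aware alignment scoring; no BAQ or realignment in the
  caller; numerical agreement with samtools is not claimed.
* The aligner indexes exact k-mers; highly repetitive references would
  need masking (irrelevant for i.i.d. surrogates).
* The k-mer-classification approach to deconvolution (Xenome-style
  read classes) is acknowledged via the pluggable SAM interface but not
  implemented.
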