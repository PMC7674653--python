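# Methods

## The analysis in one paragraph

Clonal resequencing of a mutagenised bacterial strain against its parent's
assembly yields a small number of true, (nearly) fixed mutations and a much
larger number of artifact calls. The pipeline's central idea is that the
parent strain's own resequencing run, called against its own assembly, is a
pure false-positive sample: every statistic observed there is noise, so the
maxima of those statistics — relative site coverage and supporting-read
fraction — become filter thresholds that true, population-fixed mutations
comfortably exceed. The package implements that calibration and the stages
around it: read simulation, quality trimming, mapping, duplicate marking,
pileup calling, comparative-coverage CNV detection, codon-level effect
annotation, and recurrence clustering across strains.

## Synthetic data generator

The generator emulates the study's sequencing design at desk scale and its
defaults are the study conditions, not tuning knobs.

* **Reference**: random sequence at a configurable GC fraction (default
  0.30, the AT-rich regime typical of solventogenic clostridia) with
  non-overlapping stranded genes placed one per equal-width slot. Every CDS
  starts with ATG, ends with a stop, has length a multiple of 3, and
  contains no in-frame internal stop on its coding strand; codons are
  sampled from the 61 non-stop codons with base probabilities matching the
  GC target. A small fraction of features are labelled pseudogene / rRNA /
  tRNA to exercise the annotation paths. Genomes are emitted linear; the
  real chromosome is circular, but origin-spanning reads are irrelevant at
  these scales, and truth mutations are kept ≥ 1 kb from the sequence ends
  where linearisation thins the coverage.
* **Mutants**: explicit mutation specs (SNP, ≤ 10 bp insertion/deletion,
  multi-kb tandem duplication, sub-kb segment deletion) applied
  right-to-left so coordinates stay valid; the finalized truth table is
  VCF-style anchored and left-aligned, so truth and calls can be compared
  allele-exactly. Larger indels must be expressed as duplication /
  segment-deletion events, mirroring the split between the short-indel
  table and the structural tables in the source study.
* **Reads**: `round(coverage × L / (2 × read_length))` pairs, uniform
  fragment starts, Normal(400, 50) fragment lengths, mate 2
  reverse-complemented. Default coverage 150× (the study reports
  115–221×); the recovery study runs at 120×. Substitution errors are
  injected independently per base (default 0.5%); per-base qualities are a
  truncated Normal(35, 3) on [2, 41], matching the reported average Q ≈ 35,
  and 5% of mates get a low-quality 3' tail (≤ 15 bases at Q2) so the
  trimming stage has real work. Qualities and errors are deliberately
  independent — the caller does not weight by quality, so coupling them
  would add complexity without changing any downstream decision.

What the simulator does **not** model: PCR duplicates (duplicate marking is
still exercised by coincidental fragment collisions), GC bias,
quality-by-cycle decay, adapter contamination, indel sequencing errors, and
systematic context-dependent errors. The last omission matters for
interpreting the tests: a real wild-type self-run yields a handful of
recurrent false calls (the study saw 18), while the simulated one is
usually clean, so calibration typically falls back to the published
25.9% / 30.8% thresholds rather than deriving fresh ones. Passing tests
therefore demonstrate the machinery, not the noise structure of a real
NextSeq run.

## Trimming

Trimmomatic-style parameters (window 4, mean quality 15, minimum length 36
— the tool's commonly documented defaults; the study names the tool but not
its settings). Leading bases below Q3 are removed; the read is then cropped
just after the 3'-most sliding window whose mean quality meets the
threshold (a read shorter than one window is treated as a single window).
Pairs lose both mates if either mate is dropped — no singletons survive.

## Mapping

A seed-and-extend aligner specialised for near-identical clonal data: four
exact 21-mers per read vote by diagonal on both strands; candidate
diagonals are extended ungapped, and if more than 6 mismatches remain, a
banded single-gap rescue tries every gap size 1–10 and every split point
(cost = mismatches + gap length; ties prefer the smaller, leftmost gap, so
placements are canonical). A read whose two best placements tie in score is
flagged ambiguous and excluded from pileups — the moral equivalent of
discarding mapping-quality-zero reads without modelling MAPQ. Reads that
cross structural-variant junctions fail both the ungapped and single-gap
models and go unmapped, which is intentional: their misaligned tails would
otherwise plant high-fraction artifact alleles at junction edges. Duplicate
marking groups pairs by (mate-1 five-prime, mate-2 five-prime, orientation)
and keeps the pair with the highest summed base quality.

## Calling and the empirical-null filter

Pileup columns count bases, deletion spans and anchored insertion/deletion
events per reference position. The raw caller is deliberately permissive
(depth ≥ 10, allele count ≥ 3, allele fraction ≥ 0.10, one allele per site,
highest count wins with lexicographic tie-break): the design puts the
burden of specificity on the null filter, reproducing the two-stage shape
of the original analysis (tens of raw calls reduced to a handful). Indels
are anchored on the preceding base and left-aligned.

Filtering order: shared-with-wild-type subtraction (allele-exact), then
relative coverage, then population fraction. The coverage comparison is
strict (`>`) and the fraction inclusive (`>=`), following the wording of
the published rules ("more than" / "at least"); this convention also makes
calibration self-consistent — applying thresholds calibrated from a
false-positive set back to that set passes nothing, because the maximal
false call fails its own strict bound. Calibration uses the maximum (not a
quantile) of the false-call statistics; the "population fraction" of a
variant is computed as its alternate-allele read fraction, the only reading
computable from read data, since reads sample cells of the clonal
population.

## CNV detection

Purely depth-comparative (no reassembly or read-pair evidence): per-window
copy ratio = (mutant window depth / mutant mean) / (WTS window depth / WTS
mean), windows with zero WTS depth masked. Defaults: window 100 bp, gain
threshold 1.75, loss threshold 0.25, minimum run 5 windows; a fine-window
mode (25 bp, 4 windows) targets sub-kilobase losses. Two numerical choices
harden run detection against sampling noise, which at 120× gives the window
ratio a ~8–9% sd so a true 2.0× duplication dips below 1.75 in roughly 7%
of windows:

* **Hysteresis merging** — runs separated by up to `min_windows − 1`
  windows merge when every intervening window stays beyond the midpoint
  between the threshold and 1 (1.375 for gains, 0.625 for losses). A window
  may dip below the calling threshold without splitting an event, but only
  while it still leans toward the event; background at ratio ≈ 1 can never
  bridge two separate events.
* **Smoothed refinement** — boundaries are refined by scanning the
  per-position ratio, smoothed with a 15 bp moving mean so single-position
  sampling dips do not stop the edge scans; refined fragments closer than
  one window are coalesced (below the detector's resolution they are one
  event).

The reported copy ratio is the median window ratio over the call. Note the
mean-normalisation bias: a gain occupying fraction f of the genome inflates
the mutant mean by ≈ f, so an 8 kb duplication on a 100 kb genome reads
≈ 1.85 rather than 2.0 — negligible on a real megabase chromosome.
Boundaries are accurate to about a window; junction-read loss ramps the
depth over ~one read length at event edges, so refined edges sit a few tens
of bases inside/outside the true breakpoints. Breakpoint sequence
resolution and novel insertions are out of scope.

## Effect annotation

Each passing variant is located in the unique containing feature
(annotations are required non-overlapping; overlap raises). Coding SNPs are
annotated by extracting the affected codon on the coding strand (frame from
the annotated start/end) and translating reference and alternate codons
with the bacterial/archaeal code (table 11, `*` = stop): synonymous,
missense, nonsense, stop-lost. Coding indels are frameshift or in-frame by
length arithmetic, with amino-acid fields left empty. Pseudogenes are
annotated as if coding, because the source study reports amino-acid changes
inside them; rRNA/tRNA variants get no amino acids (the study's 16S rows do
print letters, but that convention is undefined and not reproduced). No
start-codon special-casing: annotated CDSs are assumed in-frame.

## Recurrence and clustering

The gene × strain matrix marks presence of ≥ 1 passing variant per locus
(coding, pseudogene and rRNA/tRNA loci; intergenic records are excluded;
indel and SNP records count equally). Distance is the asymmetric binary
measure (b + c)/(a + b + c) — one minus Jaccard, joint absences carrying no
signal — with simple matching available as an option. Complete-linkage
agglomeration is authored here rather than delegated to scipy because the
package guarantees a deterministic tie-break (lexicographically smallest
pair of cluster representative labels); scipy and a brute-force
agglomerator serve as independent cross-checks in the tests. Merge heights
are invariant to label permutation; leaf order is a rendering choice, not a
result.

## Problem sizes and determinism

The packaged recovery study runs a 100 kb genome with 30 genes at 120×
(wild-type and mutant runs ≈ 160 k mates total), which keeps a full
pipeline execution around half a minute while preserving the study's
coverage regime, error rate and event sizes; the published tables are
recomputed exactly from the shipped fixtures at trivial cost. Every random
stage takes an explicit seed and the whole pipeline is reproducible
byte-for-byte from `PipelineConfig.seed`.

## Known limitations

* The mapper drops reads whose indel sits inside the first seed's span
  (~first 21 bases); indel support loses a modest fraction of reads but
  remains ample at study coverage.
* Multi-allelic sites are not emitted (clonal haploid samples; the source
  tables never show them).
* The CNV detector cannot distinguish tandem from dispersed duplications
  and does not call events shorter than `min_windows × window` except
  through the small-indel caller or fine-window mode.
* Re-processing real sequencing runs is supported through the SAM entry
  point, but BAM/CRAM and full MAPQ semantics are out of scope.
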