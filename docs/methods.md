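# Methods

`capmeth` implements the computational core of a dual-purpose targeted
sequence-capture assay for polyploids: a single capture enrichment whose
eluate is split and sequenced twice — once directly (genotype) and once
after bisulphite treatment (epitype) — so that sample genotypes can correct
the methylation analysis and homoeologous variants can route both readouts
to sub-genomes. The package consumes SAM alignments and reimplements the
assay's filters and statistics; it does not run external aligners.

## The analysis model

### Alignment filtering and the polyploid caller

Alignments pass the standard filters before any counting: mapped, mapping
quality ≥ 10 (strictly-below-10 removed), no duplicate flag, unique hits
only. Pileup columns carry per-base counts in reference orientation and
the arithmetic mean mapping quality of contributing reads.

A polyploid genome cannot be genotyped with a diploid likelihood model: a
single-sub-genome variant in a hexaploid appears at an allele frequency
near 1/6–1/3 of the collapsed-reference column. The caller therefore
reports any position with

- depth ≥ `min_cov` (default 5),
- column mean mapping quality strictly above `min_mean_mapq` (default 15),
- some non-reference base at frequency strictly greater than `min_maf`
  (default 0.1), with frequency = count / post-filter column depth.

The MAF denominator is the post-filter depth (the raw-depth alternative is
not recoverable from filtered input and is not offered). All three
thresholds are exposed on the CLI.

### Homoeologous SNP lists and sub-genome routing

A homoeologous SNP is a position where the three sub-genome copies of a
collapsed gene representative carry different bases; its allele→genome map
is what lets a read declare its sub-genome of origin. Two routes build the
list:

1. **Haplotype route** — coordinate-matched sub-genome sequences are
   compared column by column; every non-identical column yields a record.
   This is deterministic and, on simulated data, reproduces the
   generator's truth table exactly.
2. **Read route** — reads are first assigned a genome of origin by perfect
   full-length matching (either orientation) against the sub-genome
   sequences; hits to one or two genomes are kept, hits to zero or all
   three are uninformative and tallied. The polyploid caller then runs on
   assigned reads and each allele at a called position is attributed to
   the union of the genome sets of the reads carrying it; positions whose
   alleles resolve to at least two distinct groups become records.

### Methylation extraction

Bisulphite deaminates unmethylated cytosine to uracil (read T) and leaves
5-methylcytosine intact. With sequences stored in reference orientation,
a top-strand fragment (genome-conversion tag `XG:Z:CT`) informs reference
C positions (read C = methylated, T = unmethylated) and a bottom-strand
fragment (`XG:Z:GA`) informs reference G positions (G/A). Other bases at a
cytosine site are tallied and ignored. Context is classified from the
reference: CpG, CHG, CHH with H ∈ {A, C, T}; sites too close to a contig
end to classify are labelled `truncated` and excluded from per-context
summaries. Records are kept per strand — symmetric CpG sites are *not*
merged across strands, since the assay profiles one strand at a time.

### Sub-genome attribution of methylation calls

A read's methylation calls are credited to a sub-genome when the read has
mapping quality strictly over 20 and overlaps at least one homoeologous
SNP whose observed allele identifies exactly one allele group. Bisulphite
chemistry is respected here: on a top-strand read an observed T may be a
converted C, and on a bottom-strand read an observed A may be a converted
G, so the compatible-allele set is widened accordingly and any base
compatible with more than one allele group is not diagnostic. By default
only singleton genome groups attribute counts (a {B,D} allele assigns
nothing); reads whose diagnostic alleles conflict are discarded and
tallied. This ambiguity-first rule is what makes attribution error-free
on clean data — a read is skipped rather than guessed.

### Conversion efficiency

The control genome (the chloroplast stand-in) is assumed unmethylated, so
every read base at one of its cytosine sites is a Bernoulli observation of
the conversion chemistry. Efficiency = 100 × #converted / (#converted +
#unconverted), i.e. T/(C+T) on top strands and A/(G+A) on bottom strands,
with mean depth and percent coverage of the control genome reported
alongside. Zero observations give an undefined (None) estimate.

### Differential methylation

Positions covered ≥ `min_depth` (default 5) in *both* samples are tested
with a two-sided Fisher's exact test (minimum-likelihood convention, as in
standard statistical practice) on the 2×2 methylated/unmethylated table.
Significance requires p < `alpha` (default 0.01) *and* an absolute
methylation difference ≥ `min_diff` percentage points. `min_diff` defaults
to 25 but is an explicit, required concept: the assay's own documentation
uses both 25 and 50 in different places, so the threshold is never
implicit. No multiple-testing correction is applied (pairwise raw-p
design); a q-value machinery is out of scope. The pairwise comparisons
between two samples are intended per sub-genome (A–A, B–B, D–D) on
attributed counts — comparing pooled collapsed-reference records instead
mixes sub-genomes with different methylation states at the same reference
coordinate and carries an irreducible false-positive floor (~0.1% at 30×
in our simulations); `per_subgenome_records` exists precisely to avoid
that.

### Genotype-aware correction

Sample variants interact with bisulphite calling in two directions:

- **C→T / G→A** variants are indistinguishable from fully unmethylated
  cytosines and, unidentified, flood the methylome with false
  unmethylated calls. They are masked (and the sample base substituted
  into the corrected reference).
- **A/T→C/G** variants are cytosines the reference does not know about;
  substituting them adds new analysable sites, with context recomputed
  from the corrected sequence.
- **C↔G swaps** move a cytosine across strands: mask on the lost strand,
  add on the gained strand.

Only calls whose primary alternate allele (highest frequency, alphabetical
tie-break) reaches frequency ≥ 0.9 are applied — reference correction must
not encode heterozygous states. Site bookkeeping follows the base change
itself, so the set identity *corrected = (original − masked) ∪ added*
holds exactly for every category (including C→A/G→T losses outside the
named classes). The accounting report divides the C/G→T/A count by the
number of cytosine records covered ≥ 10× ("up to" semantics: not every
such variant necessarily reaches the depth cutoff itself) and reports the
A/T→C/G ratio the same way; on the assay's published counts this
arithmetic gives 11.3% eliminated and 13.1% added. We report the directly
computable added-fraction and do not attempt to reproduce the looser
"about one fifth" figure quoted elsewhere for that quantity.

### Probe design

Candidates of `probe_len` (default 120 bp) are tiled at `step` (default
40 bp): a contig of length L yields ⌊(L − 120)/40⌋ + 1 candidates.
Annotations are alignment identity, overlapping homoeologous and varietal
SNP counts, prior capture depth and GC. The assay describes the
annotations but not the weighting, so the rank score is a transparent
weighted sum, monotone in each criterion, with configurable weights
(default 1,1,1,1): identity as-is, SNP counts normalised by their maxima,
and prior depth scored by closeness to the median depth (unknown depth is
neutral, 0.5). Selection forces priority intervals first (tiled
end-to-end at step = probe length, with a final probe flush to the
interval end when the length is not a multiple), then optionally takes
the best candidate of every contig before any contig receives a second
probe, then fills remaining slots by descending score with a
deterministic (contig, offset) tie-break — making the output a
permutation-invariant function of the candidate set. Boosting duplicates
probes strictly above the selected set's mean GC, highest first,
round-robin, until the extra capacity is spent.

### Capture-efficiency reporting

Per contig: covered bases (depth ≥ 1), percent covered, and mean depth
*over covered positions* (the all-positions denominator is available as a
configuration of the same quantity; the covered-positions reading is the
default and is documented as such). The aggregate row reports percent of
records aligned against a caller-supplied pre-filter total (individual
records, not pairs), means over mapped contigs, contigs mapped, and total
base-space mapped (Σ covered bases). Bait profiling returns the fraction
of baits above twice the overall mean depth and the fraction below 5×.
Window tracks count features per half-open window (default 1 Mbp) and
min-max normalise to [0, 1] across the whole track (one genome-wide
minimum and maximum, matching how a single pre-normalisation maximum is
quoted for such plots); a flat track normalises to zeros, and the
normalisation is idempotent and scale-invariant.

## The synthetic-data generator

The generator emulates the data shape the pipeline is built for, so every
stage is testable without external data or aligners.

- **Genome.** Random uniform-composition contigs (default 8 × 3 kb) act as
  the collapsed capture reference; three coordinate-matched haplotypes
  (A/B/D, no indels by default) are derived from it. Homoeologous SNPs
  (rate 0.01/bp, the density needed for most 125 bp reads to span a
  diagnostic allele) mostly deviate in one sub-genome (90%) and
  occasionally in all three. Varietal SNPs (rate 0.002/bp, a SNP-dense
  accession against the reference variety) are applied to *all three*
  haplotypes at positions disjoint from homoeologous ones — a varietal
  difference is accession-vs-reference, not sub-genome-vs-sub-genome, so
  inter-haplotype differences remain exactly the homoeologous truth table
  and varietal alleles are homozygous in sample reads.
- **Methylation.** Each haplotype cytosine site draws a binary methylation
  state once, at its context rate (defaults CpG 0.80, CHG 0.50, CHH 0.05 —
  typical of plant genic sequence), so per-site levels are bimodal as in
  real methylomes and the pooled per-context level recovers the rate.
  Partial (intermediate) per-site methylation is not modelled.
- **Reads.** Single-end fragments of 125 bp (the pipeline maps read pairs
  as fragments), drawn uniformly over haplotypes and length-weighted
  contigs; the on-target count is set so realised on-target depth equals
  the request. Off-target reads split between the unmethylated control
  genome (default 5 kb) and unmappable random background; the achieved
  on-target fraction of a real capture is not identifiable from the
  assay's public numbers, so it is a free parameter (default 0.5).
  Uniform substitution errors (default 0.001), duplicate flags (default
  0.05) and a configurable MAPQ distribution (default mass at 60 with
  tails at 20 and 5, so every MAPQ filter is exercisable) complete the
  records. Quality strings, adapters, insert sizes and paired-end records
  are deliberately out of scope.
- **Bisulphite conversion.** Applied on the strand the fragment derives
  from: unmethylated cytosines convert with probability
  `conversion_efficiency` (C→T in reference orientation on top strands,
  G→A on bottom strands); methylated cytosines are protected. Control and
  background reads are unmethylated everywhere. Non-directional mode
  labels half the output as PCR complements (CTOT/CTOB); their
  reference-orientation substitution pattern — and the genome-conversion
  tag the extractor keys on — matches their template strand, which is
  exactly how complement reads behave in reference-oriented SAM.
- **Determinism.** One top-level seed feeds named substreams
  (genome / control / methylation / reads / bisulphite); identical
  configuration and seed give byte-identical FASTA/FASTQ/SAM/TSV outputs.

What passing tests on this generator do *not* show: robustness to indel
variation, alignment ambiguity from a real aligner, non-uniform error
profiles, M-bias, or capture chemistry biases. The generator's truth
tables make correctness exactly checkable; they do not make the simulated
data realistic in those dimensions.

## Numerical and design choices

- Strict vs non-strict thresholds follow the assay's wording: MAPQ "< 10
  removed" keeps 10; mean mapping quality "above 15" and MAF "greater
  than 0.1" are strict; attribution "over 20" is strict; caller minimum
  coverage 5 and DM/report depth minima are inclusive.
- Coordinates are 1-based in SAM/TSV interfaces and 0-based half-open in
  BED and probe offsets.
- Ties everywhere break lexicographically (contig, then position/offset);
  primary alternate alleles break frequency ties alphabetically.
- Degenerate inputs are explicit: zero conversion observations → None;
  zero analysable cytosines → undefined, flagged; empty bait list →
  flagged; flat window track → zeros; contig shorter than the read length
  or probe length → rejected/empty.
- CIGARs are restricted to match operations; indel CIGARs raise a clear
  error rather than being silently mis-piled (the simulator emits none,
  and indel realignment is out of scope).
- The diploid (GATK-style, quality-50, homozygous-only) calling path is
  intentionally not implemented; the package is the polyploid pipeline.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run desk-scale versions of the
study conditions: genomes of 4–8 contigs × 1–3 kb (plus one 100 kb contig
for the SNP-rate bound), read depths 10–60×, ≥ 100,000 control-genome
cytosine observations for the conversion-efficiency recovery, ~1,000
random pileup columns for the caller oracle, and all 2×2 tables with row
margins ≤ 12 for the Fisher oracle. These sizes were chosen so the full
suite completes in well under a minute while every bound asserted is a
property of the method, not of a particular seed.
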