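# Methods

This note documents the models, rules and numerical conventions implemented
in `chromamp`, the parameters that matter, and what the synthetic-data
generator does and does not emulate.

## Coordinate and format conventions

Internally every interval is 0-based half-open. On disk, segment and
mutation TSVs are 1-based inclusive (the convention of allele-specific
copy-number caller outputs); BEDPE keeps its native 0-based convention.
Chromosome names are accepted with or without the `chr` prefix and
normalised to the prefixed form. The structural-variant class of a junction
is always recomputed from the strand pair — intrachromosomal `+/-` is a
deletion-type junction, `-/+` tandem-duplication-type, `+/+` and `-/-`
inversion-type, and any interchromosomal junction a translocation — and
never trusted from the input file. Junction loci are ordered canonically by
(chromosome, position) with plain lexicographic chromosome order; the
orientation encoding is this package's convention, since segment/junction
files in the wild do not agree on one.

Consequence annotation is an input, not something this package computes; a
synonym map normalises common annotation-pipeline terms (`frameshift` →
`out_of_frame_indel`, `stop_gained` → `truncating_substitution`, …) onto a
closed vocabulary.

## Ploidy

Samples are classed diploid or tetraploid by the length-weighted mean total
copy number over all segments, with cutoff **≥ 3.0 → tetraploid**. Real
pipelines take ploidy from the copy-number caller; a fixed documented cutoff
keeps the rule reproducible on bare segment files. The cutoff is exposed in
`DriverRuleConfig.tetraploid_mean_cn_cutoff`.

## Driver-curation rules

Defaults in `DriverRuleConfig`:

| parameter | default | meaning |
|---|---|---|
| `focality_threshold` | 1,000,000 bp | focal events must span strictly less |
| `min_amp_cn_diploid` | 5 copies | total CN needed for oncogene amplification |
| `min_amp_cn_tetraploid` | 9 copies | same, tetraploid genomes |
| `truncating_consequences` | truncating substitution, out-of-frame indel, splice-disrupting | point classes that truncate a recessive gene |
| `significant_gain_extra_copies` | 2 | extra major-allele copies flagged significant in allele-specific reports |

Interpretation choices that were genuinely open, and how they were fixed:

* The amplification thresholds are read as **total** copy number of the
  locus; the allele-specific report is a separate view in which gains are
  counted as extra **major-allele** copies above one. The threshold basis is
  configurable.
* A gene footprint spanning several segments takes the **minimum** CN across
  them — amplification of the *intact* gene requires the whole footprint at
  threshold, and a gain report should not exceed what every base of the gene
  carries.
* Focality is measured on the maximal contiguous run of qualifying
  (CN ≥ threshold) segments containing the gene, strict `< 1 Mb`. Note the
  rule is monotone in the CN threshold only for thresholds above the
  background ploidy; below it the background joins the qualifying run and
  focality removes calls.
* Homozygous deletion requires a total-CN-0 segment shorter than 1 Mb
  overlapping (not necessarily containing) the footprint.
* A disruptive breakpoint is any junction end with position in
  `[gene.start, gene.end)`; for translocations either end counts.
* Events are deduplicated per (sample, gene, mechanism) with evidence lists
  concatenated, and returned in deterministic (gene, mechanism) order.
* LOH in the allele-specific report requires minor-allele CN 0 over the
  **full** footprint (partial LOH renders as no-call).

## Rearrangement profiling

No quantitative community definition of chromothripsis exists; the detector
uses operational criteria in the spirit of published chromothripsis scoring,
fully configurable in `ChromothripsisParams` and validated against the
simulator, not against any manual call set:

* ≥ `min_breakpoints` (10) junction ends on the chromosome;
* the copy-number profile oscillates among ≤ `max_cn_states` (3) distinct
  total-CN values, counted over segments ≥ 10 kb (tiny segments are
  noise-prone state inflators) and **excluding** segments at or above the
  ploidy-specific amplification threshold — in combined
  chromothripsis-amplification the amplicons ride on top of the oscillating
  baseline and would otherwise defeat any state cap;
* the longest run of consecutive segments with alternating (pairwise
  different) CN spans ≥ `min_oscillating_segments` (10).

A chromothriptic chromosome is upgraded to chromothripsis-amplification when
≥ `amp_interleave_min` (1) segments reach the amplification threshold
(5 diploid / 9 tetraploid, shared with the driver rules). Genome class takes
the maximum over chromosomes (amplification > chromothripsis); otherwise the
genome is quiet when ≤ `quiet_genome_max_breakpoints` (5) junction ends
exist genome-wide, and is reported as "quiet (rearranged,
non-chromothriptic)" — distinctly, never silently folded into quiet — above
that. A focal amplification on an otherwise quiet chromosome is class
`none`: amplification without chromothripsis is not
chromothripsis-amplification.

The rearranged-region extent of a chromosome (used for recurrence analysis)
is the span from its first to its last junction end.

## Cohort aggregation

Per sample/chromosome, 1 Mb bins carry
`log2(length-weighted mean total CN in bin / sample ploidy)`, with gaps
imputed at ploidy and a floor of CN 0.5 so homozygous-deleted bins stay
finite. Normalisation is by each sample's own ploidy (a `ploidy` argument;
callers can pass 2 to normalise all samples to diploid instead). Across
samples, bins are summarised by the mean and the first/third quartiles with
**linear interpolation** between order statistics (the numpy default; other
quantile conventions differ by at most one order-statistic gap).
Recurrently chromothripsis-amplified regions are maximal runs of adjacent
bins overlapped by the rearranged regions of ≥ `min_samples` CA-classed
chromosomes, reported as half-open intervals annotated with overlapping
panel genes.

## Expression-variance test

Per region and sample the TPM values of the region's genes (≥ `min_genes`,
default 5) are reduced to quartiles Q1/Q2/Q3 (linear interpolation) and then
to the sample variance of those three values (denominator n − 1 = 2). This
"variance of the TPM quartiles" is taken literally as a three-number
variance; the alternative reading (quartiles of per-gene variances) is not
implemented. Per region, the median of this statistic among
chromothripsis-amplified samples is compared with the median among
copy-number-neutral samples (chromosome classed `none` and region CN within
0.25 of ploidy); exact ties drop the region from the count — the
conservative sign-test convention. The cohort statistic is the exact
one-sided binomial tail p = Σ_{i=k..n} C(n,i)(1/2)^n, authored here as the
explicit tail sum and cross-checked in the tests against an independent
exact-test implementation and against full enumeration of all 2^n sign
patterns for n ≤ 15.

The null hypothesis is that expression variability is *uncorrelated with
copy-number state*. The matching null simulator therefore disables both the
extra dispersion (δ = 0) **and** dosage coupling: with coupling on, copy
number oscillation alone inflates the quartile variance in amplified
regions, which is a real effect, not a null. Calibration cohorts use 30
regions per cohort because the exact test is discrete: at n = 30 the
attainable size at nominal α = 0.05 is 4.94%, the closest to nominal in the
practical range (at n = 20 it would be 2.1%, making any calibration check
meaningless).

## Synthetic-data generator

The generator's defaults are the study conditions the rest of the package is
validated under: 40 genomes split 4 quiet / 11 chromothripsis / 25
chromothripsis-amplification (the proportions of the motivating 37-genome
cohort, at a round desk-scale size), 25% tetraploid, on an 8-chromosome
genome (GRCh37 lengths) carrying a 10-gene panel at real footprints.

* **Quiet chromosome**: one segment at ploidy, no junctions.
* **Chromothripsis**: a contiguous region of 24 segments with log-uniform
  lengths (60 kb – 2 Mb; no generative model is published for segment sizes,
  and any distribution satisfying the oscillation invariant serves), total
  CN alternating strictly between a retained state (ploidy) and a loss state
  (ploidy − 1), flanked by ploidy; junction ends are the segment boundaries,
  paired at random with random strands.
* **Chromothripsis-amplification**: the same, with 4 non-adjacent segments
  replaced by amplicons of width 100–900 kb (strictly focal) at total CN
  10–25 (above both ploidy thresholds). Amplicons do not consume oscillation
  states: the alternation is maintained across them.
* Rearranged regions are placed to avoid panel-gene footprints (± 1.5 Mb),
  and passenger mutations avoid footprints and are never truncating — so
  the planted drivers are provably the *only* rule-satisfying events and
  the truth set is an exact recovery oracle. This is a deliberate departure
  from biology (real chromothripsis hits genes); it trades realism for an
  exact ground truth.
* **Planted drivers** are realised as rule-satisfying edits: focal amplicon
  carves covering the gene, CN-0 carves wider than the footprint (so carve
  junctions do not double as disruptive breakpoints), junctions inside
  footprints, truncating or hotspot point mutations.
* **Expression**: `tpm(g, s) = baseline(g) · (CN(g,s)/ploidy(s)) ·
  exp(N(0, σ²))` with per-gene baselines log-normal (ln-mean 3, ln-sd 1,
  ≈ 20 TPM median), σ = 0.3, and σ + δ (δ = 0.4) for genes inside
  chromothripsis-amplified regions. Multiplicative log-normal noise is
  chosen for TPM positivity; no noise model is published. Expression is
  emitted for every sample (the motivating study had RNA for a subset; at
  desk scale full coverage exercises the test harder).

A single integer seed drives one `numpy` generator for all draws; identical
seeds give byte-identical output files.

What the generator does **not** emulate: read-level data, junction
sequences and microhomology, subclonality and purity, genes hit by the
shattering itself, correlated passenger structure, and RNA library-size
effects. Passing recovery tests therefore demonstrates the correctness of
the rule and detection logic under the stated generative model, not
performance on real tumour genomes, where thresholds would face noisy
segmentation and ambiguous manual calls.

## Problem sizes used by the packaged checks

Recovery runs use three 40-genome cohorts (120 genomes, ~150 planted
drivers); calibration uses 1,000 region-level null cohorts (30 regions ×
16 samples × 12 genes); power uses 100 dosage-coupled cohorts (20 regions ×
16 samples × 30 genes). These sizes were chosen as the smallest that make
the stochastic checks statistically meaningful (binomial standard error
< 0.7 percentage points for calibration).

## Known limitations

* Chromothripsis criteria are thresholds on counts, not a probabilistic
  model; borderline real profiles (e.g. 9 junction ends) fall to the
  conservative side by construction.
* The amplification rule's focality interacts with dense qualifying
  neighbourhoods: adjacent independently amplified segments merge into one
  run and can defeat focality.
* The recurrence analysis treats a chromosome's whole junction span as its
  rearranged region; a sparse long-range junction inflates the region.
* `compare_region` is across samples; a paired within-tumour design is not
  implemented.
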