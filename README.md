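# chromamp

Rule-based somatic driver curation, chromothripsis / chromothripsis-amplification
profiling, cohort-aggregate copy-number analysis and dosage-coupled
expression-variance testing for cancer genome cohorts.

## What problem this addresses

Osteosarcoma and other rearrangement-driven cancers carry few recurrent point
mutations; their driver landscape is dominated by structural variation —
focal amplification of oncogenes, homozygous deletion and breakpoint
disruption of tumour suppressors — often generated by catastrophic
rearrangement processes. Two such configurations matter here:

* **chromothripsis** — a shattered chromosome whose total copy number
  oscillates between a small number of states across many clustered
  breakpoints;
* **chromothripsis amplification** — the same oscillating pattern with
  interleaved focal (< 1 Mb) segments amplified to high copy number, a
  process that can co-generate several driver events in one region.

`chromamp` provides, as a tested library plus CLI, the analysis layer that
sits downstream of variant calling:

1. **Driver curation** over a cancer-gene panel. A variant is a driver when
   it hits an established cancer gene under conservative rules: recessive
   genes by truncating point mutations (truncating substitutions,
   out-of-frame indels, splice-disrupting changes), focal (< 1 Mb)
   homozygous deletions, or breakpoints inserted into the gene footprint;
   oncogenes by canonical-hotspot point mutations or focal (< 1 Mb)
   amplification of the intact gene to ≥ 5 total copies in diploid or ≥ 9 in
   tetraploid genomes.
2. **Allele-specific target-gene reporting**: oncogenes as extra
   major-allele copies (+*N*, gains of ≥ 2 extra copies flagged
   significant), tumour suppressors as LOH (minor allele 0 across the
   footprint) and/or BP (breakpoint inside the footprint).
3. **Rearrangement profiling** of chromosomes and genomes into
   quiet / chromothripsis / chromothripsis-amplification, using explicit,
   configurable criteria (≥ 10 clustered junction ends, ≤ 3 oscillating
   copy-number states over ≥ 10 alternating segments, plus interleaved
   segments at the ploidy-specific amplification threshold for the upgrade).
4. **Cohort aggregation**: per-bin mean / Q1 / Q3 of
   log2(copy number / ploidy) across samples, and recurrently
   chromothripsis-amplified regions with their target genes.
5. **Expression-variance testing**: per region and sample, the variance
   (denominator 2) of the three TPM quartiles (Q1, Q2, Q3) over the region's
   genes; per region, an indicator of whether the median variance among
   chromothripsis-amplified samples exceeds that of copy-number-neutral
   samples; across regions, the exact one-sided binomial sign test
   p = Σ_{i≥k} C(n,i) (1/2)^n of the null that expression variability is
   uncorrelated with copy-number state.
6. **A synthetic-cohort generator** that plants all of the above — genome
   classes, driver events of every mechanism, dosage-coupled TPM with extra
   dispersion in chromothripsis-amplified regions — with a machine-readable
   truth set, so the whole pipeline is testable without restricted data.

## Worked example

```bash
chromamp demo --seed 7 --n-samples 40 --out-dir chromamp_demo
```

prints (output of this exact command):

```
genome classes recovered: 40/40
planted drivers recovered: 52/52; false positives: 0
recurrent CA regions: 3
  chr12:4000000-107000000 in 10 samples (CCND2,CDK4,MDM2)
  chr17:7000000-74000000 in 12 samples (COPS3,NF1,TP53)
  chr5:1000000-146000000 in 10 samples (RICTOR,TERT)
expression variance: CA higher in 2/3 regions, binomial p = 0.5
```

Reading this: a 40-genome cohort was simulated (4 quiet, 11 chromothripsis,
25 chromothripsis-amplification) and re-analysed blind; every genome class
and every planted driver event was recovered with no false calls. The three
recurrently amplified regions land on chromosomes 5, 12 and 17 and contain
the planted target oncogenes (TERT/RICTOR, CCND2/CDK4/MDM2, COPS3). With
only three testable regions the sign test has no power (p = 0.5) — the
dedicated calibration/power machinery below uses region-level cohorts.

The same stages are available as `chromamp simulate / drivers / classify /
aggregate / expr-test / run-all`, all reading and writing documented TSV /
BEDPE / BED+YAML schemas (see `src/chromamp/io_formats.py`).

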