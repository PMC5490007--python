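"""Independent brute-force re-statement of the driver-curation rules.

Enumerates every (gene, record) pair and applies each rule literally, using a
merge-intervals formulation for amplification focality rather than the
package's run-growing code path. Used only as a cross-check oracle.
"""

TRUNCATING = {"truncating_substitution", "out_of_frame_indel", "splice_disrupting"}
MB = 1_000_000


def _merge_qualifying(segments, threshold):
    """Merged maximal intervals of contiguous segments with total CN >= threshold."""
    merged = []
    for s in sorted(segments, key=lambda s: (s.chrom, s.start)):
        if s.total_cn < threshold:
            continue
        if merged and merged[-1][0] == s.chrom and merged[-1][2] == s.start:
            merged[-1][2] = s.end
        else:
            merged.append([s.chrom, s.start, s.end])
    return merged


def brute_force_drivers(segments, breakpoints, mutations, panel):
    """Set of (sample, gene, mechanism) triples per the literal rule text."""
    samples = sorted(
        {r.sample_id for r in segments}
    )
    events = set()
    for sample in samples:
        segs = [s for s in segments if s.sample_id == sample]
        bps = [b for b in breakpoints if b.sample_id == sample]
        muts = [m for m in mutations if m.sample_id == sample]
        genome = sum(s.length for s in segs)
        mean_cn = sum(s.total_cn * s.length for s in segs) / genome
        threshold = 9 if mean_cn >= 3.0 else 5

        for gene in panel:
            if gene.role == "recessive":
                for m in muts:
                    in_gene = (
                        m.chrom == gene.chrom and gene.start <= m.position < gene.end
                    ) or m.gene == gene.gene
                    if in_gene and m.consequence in TRUNCATING:
                        events.add((sample, gene.gene, "truncating_point"))
                for s in segs:
                    overlaps = (
                        s.chrom == gene.chrom and s.start < gene.end and gene.start < s.end
                    )
                    if s.total_cn == 0 and s.length < MB and overlaps:
                        events.add((sample, gene.gene, "homozygous_deletion"))
                for b in bps:
                    for locus in (b.locus1, b.locus2):
                        if locus.chrom == gene.chrom and gene.start <= locus.position < gene.end:
                            events.add((sample, gene.gene, "disruptive_breakpoint"))
            else:
                for m in muts:
                    if (m.position, m.alt) in set(gene.hotspots):
                        events.add((sample, gene.gene, "hotspot_point"))
                for chrom, lo, hi in _merge_qualifying(segs, threshold):
                    whole_gene_inside = (
                        chrom == gene.chrom and lo <= gene.start and gene.end <= hi
                    )
                    if whole_gene_inside and hi - lo < MB:
                        events.add((sample, gene.gene, "amplification"))
    return events
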