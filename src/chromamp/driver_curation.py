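"""Rule-based somatic driver curation over an established cancer-gene panel.

The rules mirror conservative manual curation practice for high-rearrangement
tumour genomes:

* recessive genes are hit by truncating point mutations (truncating
  substitutions, out-of-frame indels, splice-disrupting changes), by focal
  (<1 Mb) homozygous deletions, or by rearrangement breakpoints inserted into
  the gene footprint;
* oncogenes are hit by point mutations at configured canonical hotspots or by
  focal (<1 Mb) amplification of the intact gene to at least 5 total copies in
  diploid and 9 in tetraploid genomes.

The allele-specific report is a separate view used for target-gene tables:
oncogenes report extra major-allele copies above one (gains of >= 2 extra
copies flagged significant), recessive genes report loss of heterozygosity
(minor allele zero across the whole footprint) and breakpoint presence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import (
    CopyNumberSegment,
    GenePanelEntry,
    PointMutation,
    RearrangementBreakpoint,
    segments_on,
)

TRUNCATING_CONSEQUENCES = frozenset(
    {"truncating_substitution", "out_of_frame_indel", "splice_disrupting"}
)

MECHANISMS = (
    "hotspot_point",
    "truncating_point",
    "amplification",
    "homozygous_deletion",
    "disruptive_breakpoint",
)

ROLE_MECHANISMS = {
    "oncogene": {"hotspot_point", "amplification"},
    "recessive": {"truncating_point", "homozygous_deletion", "disruptive_breakpoint"},
}


@dataclass(frozen=True)
class DriverRuleConfig:
    """Thresholds of the curation rules; defaults are the published values."""

    focality_threshold: int = 1_000_000  # bases, strict <
    min_amp_cn_diploid: int = 5  # total copies
    min_amp_cn_tetraploid: int = 9
    truncating_consequences: frozenset = TRUNCATING_CONSEQUENCES
    significant_gain_extra_copies: int = 2  # extra major-allele copies
    tetraploid_mean_cn_cutoff: float = 3.0  # length-weighted mean total CN, >=

    def __post_init__(self) -> None:
        if self.focality_threshold <= 0:
            raise ValueError("focality_threshold must be positive")
        if not (0 < self.min_amp_cn_diploid < self.min_amp_cn_tetraploid):
            raise ValueError("need 0 < diploid threshold < tetraploid threshold")

    def min_amp_cn(self, ploidy_class: str) -> int:
        return (
            self.min_amp_cn_tetraploid
            if ploidy_class == "tetraploid"
            else self.min_amp_cn_diploid
        )


@dataclass(frozen=True)
class PloidyClass:
    sample_id: str
    ploidy_class: str  # 'diploid' | 'tetraploid'
    mean_cn: float

    @property
    def nominal_cn(self) -> int:
        return 4 if self.ploidy_class == "tetraploid" else 2


@dataclass(frozen=True)
class DriverEvent:
    sample_id: str
    gene: str
    mechanism: str
    evidence: tuple = ()

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")

    @property
    def key(self):
        return (self.sample_id, self.gene, self.mechanism)


@dataclass(frozen=True)
class AlleleSpecificCall:
    """One Table-style cell: gain report for oncogenes, LOH/BP for recessives."""

    sample_id: str
    gene: str
    role: str
    extra_major_copies: int | None = None  # oncogene
    significant: bool = False
    loh: bool = False  # recessive
    breakpoint_in_footprint: bool = False

    def render(self) -> str:
        """The printed cell: '+N' / 'LOH' / 'BP' / 'LOH+BP' / '-'."""
        if self.role == "oncogene":
            if self.extra_major_copies and self.extra_major_copies > 0:
                return f"+{self.extra_major_copies}"
            return "-"
        flags = [f for f, on in (("LOH", self.loh), ("BP", self.breakpoint_in_footprint)) if on]
        return "+".join(flags) if flags else "-"


# ---------------------------------------------------------------------------
# ploidy

def classify_ploidy(
    segments: list, sample_id: str | None = None, rules: DriverRuleConfig | None = None
) -> PloidyClass:
    """Classify a sample genome as diploid or tetraploid.

    Uses the length-weighted mean total copy number over all segments; mean
    >= ``tetraploid_mean_cn_cutoff`` (default 3.0) reads tetraploid.
    """
    rules = rules or DriverRuleConfig()
    if not segments:
        raise ValueError("cannot classify ploidy from an empty segment set")
    sample_id = sample_id or segments[0].sample_id
    total_len = sum(s.length for s in segments)
    mean_cn = sum(s.total_cn * s.length for s in segments) / total_len
    cls = "tetraploid" if mean_cn >= rules.tetraploid_mean_cn_cutoff else "diploid"
    return PloidyClass(sample_id=sample_id, ploidy_class=cls, mean_cn=mean_cn)


# ---------------------------------------------------------------------------
# per-gene calls

def _footprint_segments(gene: GenePanelEntry, segments: list) -> list:
    return [s for s in segments_on(segments, gene.chrom) if s.overlaps(gene.chrom, gene.start, gene.end)]


def _covers_footprint(gene: GenePanelEntry, overlapping: list) -> bool:
    """True if the overlapping segments tile the gene footprint without gaps."""
    if not overlapping:
        return False
    pos = gene.start
    for s in overlapping:  # sorted, non-overlapping
        if s.start > pos:
            return False
        pos = max(pos, s.end)
        if pos >= gene.end:
            return True
    return pos >= gene.end


def call_amplification(
    gene: GenePanelEntry,
    segments: list,
    ploidy: PloidyClass,
    rules: DriverRuleConfig | None = None,
) -> DriverEvent | None:
    """Focal amplification of the intact oncogene.

    The whole footprint must lie in segments at total CN >= the ploidy-specific
    threshold, and the maximal contiguous run of such qualifying segments
    containing the gene must span < focality_threshold (strict).
    """
    rules = rules or DriverRuleConfig()
    if gene.role != "oncogene":
        raise ValueError(f"{gene.gene} is not an oncogene")
    threshold = rules.min_amp_cn(ploidy.ploidy_class)
    chrom_segs = segments_on(segments, gene.chrom)
    overlapping = [s for s in chrom_segs if s.overlaps(gene.chrom, gene.start, gene.end)]
    if not _covers_footprint(gene, overlapping):
        return None
    if any(s.total_cn < threshold for s in overlapping):
        return None
    # grow the contiguous qualifying run outwards from the gene's segments
    idx = [i for i, s in enumerate(chrom_segs) if s in overlapping]
    lo, hi = idx[0], idx[-1]
    while (
        lo > 0
        and chrom_segs[lo - 1].total_cn >= threshold
        and chrom_segs[lo - 1].end == chrom_segs[lo].start
    ):
        lo -= 1
    while (
        hi + 1 < len(chrom_segs)
        and chrom_segs[hi + 1].total_cn >= threshold
        and chrom_segs[hi + 1].start == chrom_segs[hi].end
    ):
        hi += 1
    run_span = chrom_segs[hi].end - chrom_segs[lo].start
    if run_span >= rules.focality_threshold:
        return None
    evidence = tuple(
        f"segment:{s.chrom}:{s.start + 1}-{s.end}:cn{s.total_cn}"
        for s in chrom_segs[lo : hi + 1]
    )
    return DriverEvent(ploidy.sample_id, gene.gene, "amplification", evidence)


def call_homozygous_deletion(
    gene: GenePanelEntry, segments: list, rules: DriverRuleConfig | None = None
) -> DriverEvent | None:
    """Focal (<1 Mb) total-CN-zero segment truncating a recessive gene."""
    rules = rules or DriverRuleConfig()
    if gene.role != "recessive":
        raise ValueError(f"{gene.gene} is not a recessive cancer gene")
    for s in _footprint_segments(gene, segments):
        if s.total_cn == 0 and s.length < rules.focality_threshold:
            return DriverEvent(
                s.sample_id,
                gene.gene,
                "homozygous_deletion",
                (f"segment:{s.chrom}:{s.start + 1}-{s.end}:cn0",),
            )
    return None


def call_disruptive_breakpoint(
    gene: GenePanelEntry, breakpoints: list
) -> DriverEvent | None:
    """Any rearrangement end inside [gene.start, gene.end) disrupts the gene."""
    if gene.role != "recessive":
        raise ValueError(f"{gene.gene} is not a recessive cancer gene")
    evidence = []
    sample = None
    for bp in breakpoints:
        for locus in (bp.locus1, bp.locus2):
            if gene.contains(locus.chrom, locus.position):
                sample = bp.sample_id
                evidence.append(
                    f"breakpoint:{locus.chrom}:{locus.position + 1}:{bp.sv_class}"
                )
    if not evidence:
        return None
    return DriverEvent(sample, gene.gene, "disruptive_breakpoint", tuple(evidence))


def call_point_driver(
    gene: GenePanelEntry, mutations: list, rules: DriverRuleConfig | None = None
) -> DriverEvent | None:
    """Truncating mutation (recessive gene) or canonical hotspot (oncogene)."""
    rules = rules or DriverRuleConfig()
    in_gene = [
        m for m in mutations if gene.contains(m.chrom, m.position) or m.gene == gene.gene
    ]
    evidence = []
    sample = None
    for m in in_gene:
        if gene.role == "recessive":
            hit = m.consequence in rules.truncating_consequences
            mech = "truncating_point"
        else:
            hit = (m.position, m.alt) in set(gene.hotspots)
            mech = "hotspot_point"
        if hit:
            sample = m.sample_id
            evidence.append(f"mutation:{m.chrom}:{m.position + 1}:{m.ref}>{m.alt}:{m.consequence}")
    if not evidence:
        return None
    return DriverEvent(sample, gene.gene, mech, tuple(evidence))


def curate_drivers(
    segments: list,
    breakpoints: list,
    mutations: list,
    panel: list,
    rules: DriverRuleConfig | None = None,
    ploidy: PloidyClass | None = None,
) -> list:
    """All driver events for one sample: union of the four call types.

    Events are deduplicated per (gene, mechanism) and returned in a
    deterministic (gene, mechanism) order.
    """
    rules = rules or DriverRuleConfig()
    if ploidy is None:
        ploidy = classify_ploidy(segments, rules=rules)
    events: dict = {}

    def add(ev: DriverEvent | None) -> None:
        if ev is None:
            return
        if ev.key in events:
            prev = events[ev.key]
            events[ev.key] = DriverEvent(
                ev.sample_id, ev.gene, ev.mechanism, prev.evidence + ev.evidence
            )
        else:
            events[ev.key] = ev

    for gene in panel:
        add(call_point_driver(gene, mutations, rules))
        if gene.role == "oncogene":
            add(call_amplification(gene, segments, ploidy, rules))
        else:
            add(call_homozygous_deletion(gene, segments, rules))
            add(call_disruptive_breakpoint(gene, breakpoints))
    return sorted(events.values(), key=lambda e: (e.gene, e.mechanism))


# ---------------------------------------------------------------------------
# allele-specific target-gene report

def allele_specific_report(
    genes: list,
    segments: list,
    breakpoints: list,
    sample_id: str,
    rules: DriverRuleConfig | None = None,
) -> list:
    """Allele-specific calls for target genes in one sample.

    Oncogenes: extra major-allele copies above one; when the footprint spans
    segments of unequal major CN the minimum is used (a gain must hold over the
    intact gene). Gains of >= ``significant_gain_extra_copies`` are flagged.
    Recessive genes: LOH iff minor CN is zero over the full footprint; BP iff
    any junction end falls inside the footprint.
    """
    rules = rules or DriverRuleConfig()
    calls = []
    for gene in genes:
        overlapping = _footprint_segments(gene, segments)
        covered = _covers_footprint(gene, overlapping)
        has_bp = any(
            gene.contains(l.chrom, l.position)
            for bp in breakpoints
            for l in (bp.locus1, bp.locus2)
        )
        if gene.role == "oncogene":
            if not covered:
                calls.append(AlleleSpecificCall(sample_id, gene.gene, "oncogene"))
                continue
            major = min(s.major_cn for s in overlapping)
            extra = max(major - 1, 0)
            calls.append(
                AlleleSpecificCall(
                    sample_id,
                    gene.gene,
                    "oncogene",
                    extra_major_copies=extra,
                    significant=extra >= rules.significant_gain_extra_copies,
                )
            )
        else:
            loh = covered and all(s.minor_cn == 0 for s in overlapping)
            calls.append(
                AlleleSpecificCall(
                    sample_id,
                    gene.gene,
                    "recessive",
                    loh=loh,
                    breakpoint_in_footprint=has_bp,
                )
            )
    return calls
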