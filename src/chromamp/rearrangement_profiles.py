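"""Chromosome- and genome-level rearrangement classification.

Three cytogenetic configurations are distinguished:

* **quiet** — few or no rearrangements genome-wide;
* **chromothripsis** — one or more chromosomes carrying many clustered
  breakpoints whose copy-number profile oscillates among a small number of
  total-CN states;
* **chromothripsis_amplification** — chromothripsis with interleaved segments
  amplified to the ploidy-specific driver-amplification copy number.

The literature gives no single quantitative definition of chromothripsis, so
the detector uses explicit operational criteria (breakpoint count, number of
oscillating CN states, number of alternating segments), all configurable in
:class:`ChromothripsisParams`. Amplified segments are excluded from the
oscillation-state count: in combined chromothripsis-amplification the
amplicons are interleaved *on top of* the oscillating baseline and would
otherwise inflate the state count past any sensible cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .driver_curation import DriverRuleConfig, PloidyClass
from .io_formats import breakpoint_loci_on, segments_on

CLASS_ORDER = {"none": 0, "chromothripsis": 1, "chromothripsis_amplification": 2}
GENOME_CLASS_ORDER = {"quiet": 0, "chromothripsis": 1, "chromothripsis_amplification": 2}


@dataclass(frozen=True)
class ChromothripsisParams:
    min_breakpoints: int = 10  # junction ends on the chromosome
    max_cn_states: int = 3  # distinct total-CN values in the oscillation
    min_oscillating_segments: int = 10  # longest alternating run
    quiet_genome_max_breakpoints: int = 5  # genome-wide ends
    amp_interleave_min: int = 1  # amplified segments needed for the upgrade
    min_state_segment_length: int = 10_000  # ignore tinier segments

    def __post_init__(self) -> None:
        for name in (
            "min_breakpoints",
            "max_cn_states",
            "min_oscillating_segments",
            "quiet_genome_max_breakpoints",
            "amp_interleave_min",
            "min_state_segment_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ChromosomeProfile:
    sample_id: str
    chrom: str
    classification: str  # none | chromothripsis | chromothripsis_amplification
    n_breakpoints: int
    n_cn_states: int
    n_oscillating_segments: int
    amplified_segment_count: int
    region: tuple | None = None  # (start, end) span of the rearranged region


@dataclass(frozen=True)
class GenomeProfile:
    sample_id: str
    classification: str  # quiet | chromothripsis | chromothripsis_amplification
    rearranged_non_chromothriptic: bool
    n_breakpoints: int
    chromosomes: tuple = ()

    @property
    def label(self) -> str:
        if self.rearranged_non_chromothriptic:
            return "quiet (rearranged, non-chromothriptic)"
        return self.classification


def count_cn_states(
    segments: list,
    min_length: int = 10_000,
    amp_cn_threshold: int | None = None,
) -> int:
    """Distinct total-CN values on one chromosome.

    Segments shorter than ``min_length`` are ignored (noise guard), as are
    segments at or above ``amp_cn_threshold`` when one is given (they belong
    to the amplicon component, not the oscillation).
    """
    values = {
        s.total_cn
        for s in segments
        if s.length >= min_length
        and (amp_cn_threshold is None or s.total_cn < amp_cn_threshold)
    }
    return len(values)


def _longest_alternating_run(cn_values: list) -> int:
    """Length of the longest run where each value differs from its predecessor."""
    best = run = 1 if cn_values else 0
    for prev, cur in zip(cn_values, cn_values[1:]):
        run = run + 1 if cur != prev else 1
        best = max(best, run)
    return best


def detect_chromothripsis(
    segments: list,
    breakpoints: list,
    chrom: str,
    params: ChromothripsisParams | None = None,
    amp_cn_threshold: int | None = None,
    sample_id: str | None = None,
) -> ChromosomeProfile:
    """Profile one chromosome; class chromothripsis iff all criteria hold.

    Criteria: >= ``min_breakpoints`` junction ends on the chromosome; the
    (non-amplified) segment CN values oscillate among <= ``max_cn_states``
    states; and the longest alternating run covers >= ``min_oscillating_segments``
    segments. Counts are reported whether or not the class is assigned.
    """
    params = params or ChromothripsisParams()
    chrom_segs = segments_on(segments, chrom)
    loci = breakpoint_loci_on(breakpoints, chrom)
    if sample_id is None:
        sample_id = (
            chrom_segs[0].sample_id
            if chrom_segs
            else (breakpoints[0].sample_id if breakpoints else "")
        )

    informative = [
        s for s in chrom_segs if s.length >= params.min_state_segment_length
    ]
    osc = [
        s
        for s in informative
        if amp_cn_threshold is None or s.total_cn < amp_cn_threshold
    ]
    amplified = [
        s
        for s in informative
        if amp_cn_threshold is not None and s.total_cn >= amp_cn_threshold
    ]
    n_states = len({s.total_cn for s in osc})
    n_alt = _longest_alternating_run([s.total_cn for s in osc])
    n_bp = len(loci)

    is_ct = (
        n_bp >= params.min_breakpoints
        and 0 < n_states <= params.max_cn_states
        and n_alt >= params.min_oscillating_segments
    )
    region = None
    if loci:
        region = (loci[0].position, loci[-1].position + 1)
    return ChromosomeProfile(
        sample_id=sample_id,
        chrom=chrom,
        classification="chromothripsis" if is_ct else "none",
        n_breakpoints=n_bp,
        n_cn_states=n_states,
        n_oscillating_segments=n_alt,
        amplified_segment_count=len(amplified),
        region=region,
    )


def detect_chromothripsis_amplification(
    segments: list,
    breakpoints: list,
    chrom: str,
    ploidy: PloidyClass,
    rules: DriverRuleConfig | None = None,
    params: ChromothripsisParams | None = None,
) -> ChromosomeProfile:
    """Profile one chromosome including the amplification upgrade.

    A chromothriptic chromosome is upgraded to chromothripsis_amplification
    iff at least ``amp_interleave_min`` segments inside the rearranged region
    reach the ploidy-specific amplification threshold (5 copies diploid,
    9 tetraploid by default).
    """
    rules = rules or DriverRuleConfig()
    params = params or ChromothripsisParams()
    threshold = rules.min_amp_cn(ploidy.ploidy_class)
    profile = detect_chromothripsis(
        segments, breakpoints, chrom, params,
        amp_cn_threshold=threshold, sample_id=ploidy.sample_id,
    )
    if (
        profile.classification == "chromothripsis"
        and profile.amplified_segment_count >= params.amp_interleave_min
    ):
        profile = ChromosomeProfile(
            sample_id=profile.sample_id,
            chrom=profile.chrom,
            classification="chromothripsis_amplification",
            n_breakpoints=profile.n_breakpoints,
            n_cn_states=profile.n_cn_states,
            n_oscillating_segments=profile.n_oscillating_segments,
            amplified_segment_count=profile.amplified_segment_count,
            region=profile.region,
        )
    return profile


def classify_genome(
    profiles: list, params: ChromothripsisParams | None = None, sample_id: str | None = None
) -> GenomeProfile:
    """Genome class from per-chromosome profiles.

    Precedence: chromothripsis_amplification > chromothripsis. Otherwise the
    genome is quiet when genome-wide junction ends stay at or below
    ``quiet_genome_max_breakpoints``; above that it is reported quiet with an
    explicit "rearranged, non-chromothriptic" flag rather than silently folded
    in.
    """
    params = params or ChromothripsisParams()
    if sample_id is None:
        sample_id = profiles[0].sample_id if profiles else ""
    n_bp = sum(p.n_breakpoints for p in profiles)
    best = max(
        (p.classification for p in profiles),
        key=lambda c: CLASS_ORDER[c],
        default="none",
    )
    if best != "none":
        cls, flag = best, False
    elif n_bp <= params.quiet_genome_max_breakpoints:
        cls, flag = "quiet", False
    else:
        cls, flag = "quiet", True
    return GenomeProfile(
        sample_id=sample_id,
        classification=cls,
        rearranged_non_chromothriptic=flag,
        n_breakpoints=n_bp,
        chromosomes=tuple(sorted(profiles, key=lambda p: p.chrom)),
    )


def profile_genome(
    segments: list,
    breakpoints: list,
    ploidy: PloidyClass,
    rules: DriverRuleConfig | None = None,
    params: ChromothripsisParams | None = None,
) -> GenomeProfile:
    """Convenience wrapper: profile every chromosome of one sample, then the genome."""
    params = params or ChromothripsisParams()
    chroms = sorted(
        {s.chrom for s in segments} | {l.chrom for bp in breakpoints for l in (bp.locus1, bp.locus2)}
    )
    profiles = [
        detect_chromothripsis_amplification(
            segments, breakpoints, chrom, ploidy, rules, params
        )
        for chrom in chroms
    ]
    return classify_genome(profiles, params, sample_id=ploidy.sample_id)
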