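"""Synthetic tumour-cohort generator with planted ground truth.

The generator emulates the study conditions of a whole-genome osteosarcoma
cohort at desk scale: a mix of diploid and tetraploid genomes in which each
chromosome is planted as one of three configurations —

* **quiet**: a single segment at the background ploidy, no rearrangement;
* **chromothripsis**: a contiguous multi-megabase region shattered into many
  segments whose total copy number oscillates between a retained and a lost
  state, with clustered junction ends at the segment boundaries;
* **chromothripsis_amplification**: the same oscillating region with
  interleaved focal (<1 Mb) segments amplified to high copy number.

Driver events of every curation-rule class are planted on top (focal oncogene
amplification, homozygous deletion, disruptive breakpoint, truncating point
mutation, hotspot point mutation), and gene expression is simulated as TPM
proportional to copy dosage with multiplicative log-normal noise, with extra
dispersion for genes inside chromothripsis-amplified regions.

Rearranged regions deliberately avoid panel-gene footprints so that the only
rule-satisfying events in a cohort are the planted ones; this makes the truth
set an exact oracle for driver recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .driver_curation import classify_ploidy
from .io_formats import (
    BreakpointLocus,
    CopyNumberSegment,
    ExpressionMatrix,
    GenePanelEntry,
    PointMutation,
    RearrangementBreakpoint,
    write_breakpoints,
    write_expression,
    write_gene_panel,
    write_mutations,
    write_segments,
)

PLANTED_CLASSES = ("quiet", "chromothripsis", "chromothripsis_amplification")

#: Chromosome subset used by the default synthetic genome (GRCh37 lengths).
DEFAULT_CHROM_LENGTHS = {
    "chr1": 249_250_621,
    "chr2": 243_199_373,
    "chr3": 198_022_430,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr12": 133_851_895,
    "chr15": 102_531_392,
    "chr17": 81_195_210,
}


def default_panel() -> list:
    """The default cancer-gene panel (GRCh37 footprints)."""
    return [
        GenePanelEntry("TERT", "chr5", 1_253_287, 1_295_162, "oncogene"),
        GenePanelEntry("RICTOR", "chr5", 38_938_021, 39_074_510, "oncogene"),
        GenePanelEntry("IGF2R", "chr6", 160_390_130, 160_534_539, "recessive"),
        GenePanelEntry("CCND2", "chr12", 4_382_902, 4_414_516, "oncogene"),
        GenePanelEntry(
            "CDK4", "chr12", 58_141_510, 58_149_796, "oncogene",
            hotspots=((58_145_429, "T"),),
        ),
        GenePanelEntry("MDM2", "chr12", 69_201_952, 69_239_214, "oncogene"),
        GenePanelEntry("IGF1R", "chr15", 99_192_200, 99_507_759, "oncogene"),
        GenePanelEntry("TP53", "chr17", 7_571_720, 7_590_868, "recessive"),
        GenePanelEntry("COPS3", "chr17", 17_109_756, 17_139_778, "oncogene"),
        GenePanelEntry("NF1", "chr17", 29_421_945, 29_704_695, "recessive"),
    ]


@dataclass(frozen=True)
class CTParams:
    """Chromothripsis-region generator settings."""

    n_segments: int = 24  # oscillating segments in the shattered region
    n_states: int = 2  # CN states in the oscillation (excl. amplicons)
    min_segment_length: int = 60_000
    max_segment_length: int = 2_000_000  # log-uniform draw between the two


@dataclass(frozen=True)
class AmpParams:
    """Interleaved-amplicon settings for chromothripsis-amplification."""

    n_amplicons: int = 4
    cn_range: tuple = (10, 25)  # total CN, inclusive; >= both ploidy thresholds
    min_width: int = 100_000
    max_width: int = 900_000  # strictly under the 1 Mb focality threshold


@dataclass(frozen=True)
class ExprParams:
    baseline_log_mean: float = 3.0  # ln-TPM location of per-gene baselines
    baseline_log_sd: float = 1.0
    sigma: float = 0.3  # multiplicative log-normal noise sd
    delta: float = 0.4  # extra dispersion in chromothripsis-amplified regions
    dosage_coupled: bool = True  # TPM scales with total CN / ploidy


@dataclass
class SimulationConfig:
    n_samples: int = 40
    fraction_tetraploid: float = 0.25
    chrom_lengths: dict = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    #: sample id -> {chrom: planted class}; chromosomes absent are quiet
    profile_assignment: dict = field(default_factory=dict)
    ct_params: CTParams = field(default_factory=CTParams)
    amp_params: AmpParams = field(default_factory=AmpParams)
    #: list of (sample_id, gene, mechanism)
    planted_drivers: list = field(default_factory=list)
    expr_params: ExprParams = field(default_factory=ExprParams)
    n_passenger_mutations: int = 30  # per sample
    expression_genes_spacing: int = 1_500_000  # tiled expression-gene grid
    allow_quiet_focal_amp: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        if not 0 <= self.fraction_tetraploid <= 1:
            raise ValueError("fraction_tetraploid must lie in [0, 1]")
        if self.amp_params.max_width >= 1_000_000:
            raise ValueError("amplicon max width must stay below the 1 Mb focality threshold")


@dataclass
class TruthSet:
    genome_class: dict = field(default_factory=dict)  # sample -> class
    chromosome_class: dict = field(default_factory=dict)  # sample -> {chrom: class}
    drivers: list = field(default_factory=list)  # (sample, gene, mechanism)
    ca_regions: dict = field(default_factory=dict)  # sample -> [(chrom, start, end)]
    ploidy: dict = field(default_factory=dict)  # sample -> 'diploid'|'tetraploid'

    def to_json(self, path) -> None:
        payload = {
            "genome_class": self.genome_class,
            "chromosome_class": self.chromosome_class,
            "drivers": [list(d) for d in self.drivers],
            "ca_regions": {
                s: [[c, int(a), int(b)] for c, a, b in regions]
                for s, regions in self.ca_regions.items()
            },
            "ploidy": self.ploidy,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @staticmethod
    def from_json(path) -> "TruthSet":
        d = json.loads(Path(path).read_text())
        return TruthSet(
            genome_class=d["genome_class"],
            chromosome_class={s: dict(v) for s, v in d["chromosome_class"].items()},
            drivers=[tuple(x) for x in d["drivers"]],
            ca_regions={
                s: [(c, a, b) for c, a, b in v] for s, v in d["ca_regions"].items()
            },
            ploidy=d["ploidy"],
        )


# ---------------------------------------------------------------------------
# chromosome simulation

def _log_uniform(rng, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def _oscillation_states(nominal: int, n_states: int) -> list:
    """(major, minor) pairs cycled through the shattered region.

    The first state is a loss relative to ploidy so the region differs from
    its flanks; with n_states=2 the region alternates loss/retained.
    """
    if nominal == 2:
        states = [(1, 0), (1, 1), (2, 1)]
    else:
        states = [(2, 1), (2, 2), (3, 2)]
    if not 1 <= n_states <= len(states):
        raise ValueError(f"n_states must be in 1..{len(states)}")
    return states[:n_states]


def _masked_intervals(chrom: str, panel: list, pad: int = 50_000) -> list:
    return [
        (g.start - pad, g.end + pad) for g in panel if g.chrom == chrom
    ]


def _overlaps_any(start: int, end: int, intervals: list) -> bool:
    return any(start < b and a < end for a, b in intervals)


def simulate_chromosome(
    planted_class: str,
    sample_id: str,
    chrom: str,
    chrom_length: int,
    nominal_cn: int,
    rng: np.random.Generator,
    ct_params: CTParams | None = None,
    amp_params: AmpParams | None = None,
    avoid: list = (),
) -> tuple:
    """Segments and breakpoints for one chromosome of one sample.

    ``nominal_cn`` is 2 (diploid) or 4 (tetraploid). ``avoid`` is a list of
    (start, end) intervals the rearranged region must not overlap (panel-gene
    footprints). Returns ``(segments, breakpoints)`` with segments tiling
    ``[0, chrom_length)``.
    """
    ct_params = ct_params or CTParams()
    amp_params = amp_params or AmpParams()
    base = (nominal_cn // 2, nominal_cn // 2)

    if planted_class == "quiet":
        seg = CopyNumberSegment(sample_id, chrom, 0, chrom_length, *base)
        return [seg], []
    if planted_class not in PLANTED_CLASSES:
        raise ValueError(f"unknown planted class {planted_class!r}")

    lengths = _log_uniform(
        rng, ct_params.min_segment_length, ct_params.max_segment_length,
        size=ct_params.n_segments,
    ).astype(int)
    region_len = int(lengths.sum())
    margin = 2_000_000
    if chrom_length < region_len + 2 * margin:
        raise ValueError(f"{chrom} too short for a {region_len} bp shattered region")
    for _ in range(200):
        region_start = int(rng.integers(margin, chrom_length - region_len - margin))
        if not _overlaps_any(region_start, region_start + region_len, list(avoid)):
            break
    else:
        raise ValueError(f"could not place rearranged region on {chrom} clear of panel genes")

    states = _oscillation_states(nominal_cn, ct_params.n_states)
    amp_idx: set = set()
    if planted_class == "chromothripsis_amplification":
        # interleave amplicons, never adjacent, so the oscillating baseline
        # separates them and each stays an independent focal unit
        candidates = list(range(1, ct_params.n_segments - 1, 2))
        chosen = rng.choice(
            len(candidates), size=min(amp_params.n_amplicons, len(candidates)),
            replace=False,
        )
        amp_idx = {candidates[i] for i in sorted(chosen)}

    segments = []
    pos = region_start
    boundaries = []
    state_i = 0  # advanced only by oscillating segments so the oscillation
    # stays strictly alternating even where amplicons are interleaved
    for i, ln in enumerate(lengths):
        if i in amp_idx:
            ln = int(_log_uniform(rng, amp_params.min_width, amp_params.max_width))
            cn = int(rng.integers(amp_params.cn_range[0], amp_params.cn_range[1] + 1))
            major, minor = cn - 1, 1
        else:
            major, minor = states[state_i % len(states)]
            state_i += 1
        segments.append(CopyNumberSegment(sample_id, chrom, pos, pos + int(ln), major, minor))
        boundaries.append(pos)
        pos += int(ln)
    boundaries.append(pos)
    region_end = pos

    out = [CopyNumberSegment(sample_id, chrom, 0, region_start, *base)]
    out += segments
    out.append(CopyNumberSegment(sample_id, chrom, region_end, chrom_length, *base))

    # junction ends at the shattered-segment boundaries, paired at random
    ends = list(boundaries)
    rng.shuffle(ends)
    if len(ends) % 2:
        ends.append(int(rng.choice(boundaries[:-1])))
    breakpoints = []
    strands = rng.choice(["+", "-"], size=len(ends))
    for j in range(0, len(ends), 2):
        l1 = BreakpointLocus(chrom, int(ends[j]), str(strands[j]))
        l2 = BreakpointLocus(chrom, int(ends[j + 1]), str(strands[j + 1]))
        if l1.position == l2.position:
            l2 = BreakpointLocus(chrom, l2.position + 1, l2.strand)
        breakpoints.append(RearrangementBreakpoint.make(sample_id, l1, l2))
    return out, breakpoints


# ---------------------------------------------------------------------------
# planted driver realisation

def _carve_segment(
    segments: list, sample_id: str, chrom: str, start: int, end: int,
    major: int, minor: int,
) -> list:
    """Replace ``[start, end)`` within a segment tiling by a new CN state."""
    out = []
    for s in segments:
        if s.chrom != chrom or s.end <= start or s.start >= end:
            out.append(s)
            continue
        if s.start < start:
            out.append(CopyNumberSegment(s.sample_id, chrom, s.start, start, s.major_cn, s.minor_cn))
        if s.end > end:
            out.append(CopyNumberSegment(s.sample_id, chrom, end, s.end, s.major_cn, s.minor_cn))
    out.append(CopyNumberSegment(sample_id, chrom, start, end, major, minor))
    return sorted(out, key=lambda s: (s.chrom, s.start))


def _plant_driver(
    mechanism: str,
    gene: GenePanelEntry,
    sample_id: str,
    segments_by_chrom: dict,
    breakpoints: list,
    mutations: list,
    nominal_cn: int,
    rng: np.random.Generator,
    amp_params: AmpParams,
) -> None:
    """Realise one planted driver by editing the sample's records in place."""
    chrom = gene.chrom
    if mechanism == "amplification":
        pad_total = int(rng.integers(50_000, 400_000))
        width = (gene.end - gene.start) + pad_total
        if width >= 1_000_000:
            raise ValueError(f"planted amplicon for {gene.gene} would not be focal")
        start = gene.start - int(rng.integers(10_000, pad_total - 10_000))
        cn = int(rng.integers(amp_params.cn_range[0], amp_params.cn_range[1] + 1))
        segments_by_chrom[chrom] = _carve_segment(
            segments_by_chrom[chrom], sample_id, chrom, start, start + width, cn - 1, 1
        )
        breakpoints.append(
            RearrangementBreakpoint.make(
                sample_id,
                BreakpointLocus(chrom, start, "-"),
                BreakpointLocus(chrom, start + width, "+"),
            )
        )
    elif mechanism == "homozygous_deletion":
        # wider than the footprint so the carve junctions land outside the
        # gene and do not double as disruptive breakpoints
        min_width = max(100_000, (gene.end - gene.start) + 40_000)
        width = int(rng.integers(min_width, max(600_000, min_width + 100_000)))
        start = gene.start + (gene.end - gene.start) // 2 - width // 2
        segments_by_chrom[chrom] = _carve_segment(
            segments_by_chrom[chrom], sample_id, chrom, start, start + width, 0, 0
        )
        breakpoints.append(
            RearrangementBreakpoint.make(
                sample_id,
                BreakpointLocus(chrom, start, "+"),
                BreakpointLocus(chrom, start + width, "-"),
            )
        )
    elif mechanism == "disruptive_breakpoint":
        inside = int(rng.integers(gene.start, gene.end))
        partner_chrom = "chr2" if chrom != "chr2" else "chr3"
        breakpoints.append(
            RearrangementBreakpoint.make(
                sample_id,
                BreakpointLocus(chrom, inside, "+"),
                BreakpointLocus(partner_chrom, int(rng.integers(10_000_000, 90_000_000)), "-"),
            )
        )
    elif mechanism == "truncating_point":
        pos = int(rng.integers(gene.start, gene.end))
        cons = str(rng.choice(["truncating_substitution", "out_of_frame_indel"]))
        ref, alt = ("C", "T") if cons == "truncating_substitution" else ("CA", "C")
        mutations.append(
            PointMutation(sample_id, chrom, pos, ref, alt, cons, gene.gene)
        )
    elif mechanism == "hotspot_point":
        if not gene.hotspots:
            raise ValueError(f"gene {gene.gene} has no configured hotspots")
        pos, alt = gene.hotspots[0]
        mutations.append(
            PointMutation(sample_id, chrom, pos, "C", alt, "missense", gene.gene)
        )
    else:
        raise ValueError(f"unknown planted mechanism {mechanism!r}")


# ---------------------------------------------------------------------------
# expression

def gene_cn(segments: list, chrom: str, start: int, end: int) -> float:
    """Length-weighted mean total CN over a footprint; error if uncovered."""
    total = 0.0
    covered = 0
    for s in segments:
        if s.chrom != chrom or s.end <= start or s.start >= end:
            continue
        ov = min(s.end, end) - max(s.start, start)
        total += s.total_cn * ov
        covered += ov
    if covered < end - start:
        raise ValueError(f"footprint {chrom}:{start}-{end} not fully covered by segments")
    return total / covered


def simulate_expression(
    segments_by_sample: dict,
    genes: list,
    params: ExprParams,
    rng: np.random.Generator,
    ca_regions_by_sample: dict | None = None,
) -> ExpressionMatrix:
    """Dosage-coupled TPM matrix over ``genes`` for every sample.

    ``tpm(g, s) = baseline(g) * (CN(g, s) / ploidy(s)) * exp(N(0, sd^2))`` with
    ``sd = sigma`` normally and ``sigma + delta`` for genes inside a
    chromothripsis-amplified region of the sample. With ``dosage_coupled``
    False the dosage factor is fixed at 1 (expression independent of copy
    state — the null of the variance test).
    """
    ca_regions_by_sample = ca_regions_by_sample or {}
    samples = sorted(segments_by_sample)
    baselines = np.exp(
        rng.normal(params.baseline_log_mean, params.baseline_log_sd, size=len(genes))
    )
    tpm = np.zeros((len(genes), len(samples)))
    for j, sample in enumerate(samples):
        segs = segments_by_sample[sample]
        ploidy = classify_ploidy(segs).nominal_cn
        ca = ca_regions_by_sample.get(sample, [])
        by_chrom: dict = {}
        for s in segs:
            by_chrom.setdefault(s.chrom, []).append(s)
        for i, g in enumerate(genes):
            cn = gene_cn(by_chrom.get(g.chrom, []), g.chrom, g.start, g.end)
            dosage = cn / ploidy if params.dosage_coupled else 1.0
            sd = params.sigma
            if any(c == g.chrom and g.start < b and a < g.end for c, a, b in ca):
                sd = params.sigma + params.delta
            tpm[i, j] = baselines[i] * dosage * np.exp(rng.normal(0.0, sd))
    return ExpressionMatrix([g.gene for g in genes], samples, tpm)


def expression_gene_grid(chrom_lengths: dict, spacing: int = 1_500_000) -> list:
    """Tiled synthetic expression genes (20 kb footprints every ``spacing``)."""
    genes = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        k = 0
        pos = spacing
        while pos + 20_000 < length - spacing:
            genes.append(
                GenePanelEntry(
                    f"EXPR_{chrom}_{k:04d}", chrom, pos, pos + 20_000, "oncogene"
                )
            )
            k += 1
            pos += spacing
    return genes


# ---------------------------------------------------------------------------
# cohort assembly

def default_profile_assignment(
    sample_ids: list,
    rng: np.random.Generator,
    n_quiet: int = 4,
    n_ct: int = 11,
) -> dict:
    """Planted genome classes at the study's proportions (4 quiet, 11
    chromothripsis, remainder chromothripsis-amplification)."""
    ct_chrom_pool = ["chr1", "chr2", "chr3", "chr6", "chr15"]
    ca_chrom_pool = ["chr5", "chr12", "chr17"]
    assignment = {}
    for i, sid in enumerate(sample_ids):
        if i < n_quiet:
            assignment[sid] = {}
        elif i < n_quiet + n_ct:
            k = int(rng.integers(1, 3))
            chroms = rng.choice(ct_chrom_pool, size=k, replace=False)
            assignment[sid] = {str(c): "chromothripsis" for c in chroms}
        else:
            k = int(rng.integers(1, 3))
            chroms = rng.choice(ca_chrom_pool, size=k, replace=False)
            assignment[sid] = {str(c): "chromothripsis_amplification" for c in chroms}
    return assignment


def default_planted_drivers(assignment: dict, rng: np.random.Generator) -> list:
    """One oncogene amplification per chromothripsis-amplified chromosome,
    plus recessive-gene and point drivers sprinkled across the cohort."""
    amp_targets = {
        "chr5": ["RICTOR", "TERT"],
        "chr12": ["MDM2", "CDK4", "CCND2"],
        "chr17": ["COPS3"],
    }
    drivers = []
    samples = sorted(assignment)
    for sid in samples:
        for chrom, cls in sorted(assignment[sid].items()):
            if cls == "chromothripsis_amplification":
                gene = str(rng.choice(amp_targets[chrom]))
                drivers.append((sid, gene, "amplification"))
    # recessive and point drivers on a rotating subset of samples
    extra_cycle = [
        ("TP53", "disruptive_breakpoint"),
        ("TP53", "truncating_point"),
        ("NF1", "disruptive_breakpoint"),
        ("IGF2R", "truncating_point"),
        ("TP53", "homozygous_deletion"),
        ("CDK4", "hotspot_point"),
    ]
    for i, sid in enumerate(samples):
        if i % 3 == 0:
            drivers.append((sid,) + extra_cycle[(i // 3) % len(extra_cycle)])
    return sorted(set(drivers))


def build_default_config(n_samples: int = 40, seed: int = 0, **overrides) -> SimulationConfig:
    """Study-condition defaults: 40 genomes split 4 quiet / 11 chromothripsis /
    25 chromothripsis-amplification, planted drivers of every mechanism."""
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    n_quiet = min(4, n_samples)
    n_ct = min(11, max(n_samples - n_quiet, 0))
    assignment = default_profile_assignment(sample_ids, rng, n_quiet, n_ct)
    drivers = default_planted_drivers(assignment, rng)
    cfg = SimulationConfig(
        n_samples=n_samples,
        profile_assignment=assignment,
        planted_drivers=drivers,
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def simulate_cohort(config: SimulationConfig, out_dir=None) -> tuple:
    """Simulate a full cohort.

    Returns ``(data, truth)`` where ``data`` is a dict with keys ``segments``
    (list), ``breakpoints`` (list), ``mutations`` (list), ``expression``
    (ExpressionMatrix), ``panel`` (list); when ``out_dir`` is given the
    io_formats files plus ``truth.json`` are also written there.
    """
    rng = np.random.default_rng(config.seed)
    panel = default_panel()
    panel = [g for g in panel if g.chrom in config.chrom_lengths]
    by_gene = {g.gene: g for g in panel}

    sample_ids = sorted(config.profile_assignment) or [
        f"S{i:03d}" for i in range(config.n_samples)
    ]
    sample_ids = sample_ids[: config.n_samples] if config.n_samples else []
    planted_by_sample: dict = {sid: [] for sid in sample_ids}
    for sid, gene, mech in config.planted_drivers:
        if sid not in planted_by_sample:
            raise ValueError(f"planted driver for unknown sample {sid!r}")
        planted_by_sample[sid].append((gene, mech))

    truth = TruthSet()
    all_segments: list = []
    all_breakpoints: list = []
    all_mutations: list = []
    segments_by_sample: dict = {}

    n_tetra = int(round(config.fraction_tetraploid * len(sample_ids)))
    tetra_ids = set(sample_ids[:n_tetra])  # deterministic given ordering

    for sid in sample_ids:
        nominal = 4 if sid in tetra_ids else 2
        truth.ploidy[sid] = "tetraploid" if nominal == 4 else "diploid"
        assignment = config.profile_assignment.get(sid, {})
        for cls in assignment.values():
            if cls not in PLANTED_CLASSES:
                raise ValueError(f"unknown planted class {cls!r}")
        segments_by_chrom: dict = {}
        breakpoints: list = []
        mutations: list = []
        chrom_classes = {}
        ca_regions = []
        for chrom in sorted(config.chrom_lengths):
            cls = assignment.get(chrom, "quiet")
            # wide pad keeps planted-driver carves (amplicons, deletions, all
            # < 1 Mb around a footprint) clear of the shattered region
            avoid = _masked_intervals(chrom, panel, pad=1_500_000)
            segs, bps = simulate_chromosome(
                cls, sid, chrom, config.chrom_lengths[chrom], nominal, rng,
                config.ct_params, config.amp_params, avoid=avoid,
            )
            segments_by_chrom[chrom] = segs
            breakpoints += bps
            chrom_classes[chrom] = cls
            if cls == "chromothripsis_amplification":
                shattered = [s for s in segs if (s.major_cn, s.minor_cn) != (nominal // 2, nominal // 2)]
                ca_regions.append(
                    (chrom, min(s.start for s in shattered), max(s.end for s in shattered))
                )
        # planted drivers
        for gene_name, mech in sorted(planted_by_sample[sid]):
            gene = by_gene.get(gene_name)
            if gene is None:
                raise ValueError(f"planted driver names unknown panel gene {gene_name!r}")
            cls = chrom_classes.get(gene.chrom, "quiet")
            if (
                mech == "amplification"
                and cls == "quiet"
                and not config.allow_quiet_focal_amp
            ):
                raise ValueError(
                    f"planted amplification of {gene_name} on a quiet {gene.chrom} "
                    "requires allow_quiet_focal_amp=True"
                )
            _plant_driver(
                mech, gene, sid, segments_by_chrom, breakpoints, mutations,
                nominal, rng, config.amp_params,
            )
            truth.drivers.append((sid, gene_name, mech))
        # passenger mutations: never truncating, never inside panel footprints
        chroms = sorted(config.chrom_lengths)
        for _ in range(config.n_passenger_mutations):
            for _try in range(50):
                chrom = str(rng.choice(chroms))
                pos = int(rng.integers(1_000_000, config.chrom_lengths[chrom] - 1_000_000))
                if not _overlaps_any(pos, pos + 1, _masked_intervals(chrom, panel, pad=0)):
                    break
            cons = str(rng.choice(["missense", "synonymous", "other"], p=[0.6, 0.3, 0.1]))
            ref, alt = (str(x) for x in rng.choice(["A", "C", "G", "T"], size=2, replace=False))
            mutations.append(PointMutation(sid, chrom, pos, ref, alt, cons, ""))

        sample_segments = [s for chrom in sorted(segments_by_chrom) for s in segments_by_chrom[chrom]]
        segments_by_sample[sid] = sample_segments
        all_segments += sample_segments
        all_breakpoints += breakpoints
        all_mutations += mutations
        truth.chromosome_class[sid] = chrom_classes
        truth.ca_regions[sid] = ca_regions
        classes = set(chrom_classes.values())
        if "chromothripsis_amplification" in classes:
            truth.genome_class[sid] = "chromothripsis_amplification"
        elif "chromothripsis" in classes:
            truth.genome_class[sid] = "chromothripsis"
        else:
            truth.genome_class[sid] = "quiet"

    expr_genes = expression_gene_grid(config.chrom_lengths, config.expression_genes_spacing)
    if segments_by_sample:
        expression = simulate_expression(
            segments_by_sample, expr_genes, config.expr_params, rng,
            ca_regions_by_sample=truth.ca_regions,
        )
    else:
        expression = ExpressionMatrix([g.gene for g in expr_genes], [], np.zeros((len(expr_genes), 0)))

    data = {
        "segments": all_segments,
        "breakpoints": all_breakpoints,
        "mutations": all_mutations,
        "expression": expression,
        "expression_genes": expr_genes,
        "panel": panel,
        "segments_by_sample": segments_by_sample,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_segments(all_segments, out / "segments.tsv")
        write_breakpoints(all_breakpoints, out / "breakpoints.bedpe")
        write_mutations(all_mutations, out / "mutations.tsv")
        write_expression(expression, out / "expression.tsv")
        write_gene_panel(panel, out / "panel.bed", out / "panel.yaml")
        with open(out / "expr_genes.bed", "w") as fh:
            for g in expr_genes:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene}\n")
        truth.to_json(out / "truth.json")
    return data, truth


# ---------------------------------------------------------------------------
# lightweight region-level cohorts for calibration / power studies

def simulate_region_cohort(
    n_regions: int,
    n_ca: int,
    n_neutral: int,
    genes_per_region: int,
    params: ExprParams,
    rng: np.random.Generator,
):
    """Region-level expression draws for calibration and power experiments.

    Builds, without a full genome simulation, an :class:`ExpressionMatrix`
    over ``n_regions`` independent regions with ``n_ca`` chromothripsis-
    amplified and ``n_neutral`` copy-number-neutral samples. With
    ``params.dosage_coupled`` False and ``params.delta == 0`` both groups are
    exchangeable — the null of the variance test. When coupled, CA samples
    draw per-gene copy numbers from an oscillation-plus-amplicon state mix
    while neutral samples sit at diploid.

    Returns ``(expression, region_genes, region_groups)`` ready for
    :func:`chromamp.expression_variance.run_expression_test`.
    """
    ca_samples = [f"CA{i:02d}" for i in range(n_ca)]
    neutral_samples = [f"NEU{i:02d}" for i in range(n_neutral)]
    samples = ca_samples + neutral_samples
    gene_names = []
    region_genes = {}
    for r in range(n_regions):
        names = [f"R{r:03d}_G{g:02d}" for g in range(genes_per_region)]
        region_genes[f"region_{r:03d}"] = names
        gene_names += names
    baselines = np.exp(
        rng.normal(params.baseline_log_mean, params.baseline_log_sd, size=len(gene_names))
    )
    # CA copy-state mix: oscillation between 1 and 2 plus occasional amplicons
    ca_states = np.array([1, 2, 12, 20])
    ca_probs = np.array([0.4, 0.4, 0.1, 0.1])
    tpm = np.zeros((len(gene_names), len(samples)))
    for j, sample in enumerate(samples):
        is_ca = j < n_ca
        if params.dosage_coupled and is_ca:
            cn = rng.choice(ca_states, size=len(gene_names), p=ca_probs)
        else:
            cn = np.full(len(gene_names), 2)
        sd = params.sigma + (params.delta if is_ca else 0.0)
        dosage = cn / 2.0 if params.dosage_coupled else 1.0
        tpm[:, j] = baselines * dosage * np.exp(rng.normal(0.0, sd, size=len(gene_names)))
    expression = ExpressionMatrix(gene_names, samples, tpm)
    region_groups = {rid: (ca_samples, neutral_samples) for rid in region_genes}
    return expression, region_genes, region_groups
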