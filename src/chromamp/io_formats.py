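"""Typed records and file I/O for the pipeline.

All genomic intervals are held internally as 0-based half-open ``[start, end)``.
Every on-disk TSV uses 1-based inclusive coordinates, the convention of
segment files emitted by allele-specific copy-number callers. The conversion
is ``start_disk = start_internal + 1``, ``end_disk = end_internal`` and is its
own inverse.

Rearrangement breakpoints travel as standard BEDPE (0-based half-open on
disk already, per the BEDPE spec). The structural-variant class is always
recomputed from the strand pair, never trusted from the file:

    intrachromosomal, locus1 < locus2:
        +/-  -> deletion            (joins low-end tail to high-end head)
        -/+  -> tandem_duplication
        +/+  -> inversion
        -/-  -> inversion
    interchromosomal -> translocation (any strands)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """A file violated the documented schema or an invariant."""


# ---------------------------------------------------------------------------
# chromosome naming

def normalize_chrom(chrom: str) -> str:
    """Accept names with or without the ``chr`` prefix; return prefixed form."""
    c = str(chrom).strip()
    if not c:
        raise FormatError("empty chromosome name")
    return c if c.startswith("chr") else "chr" + c


# ---------------------------------------------------------------------------
# domain types

VALID_SV_CLASSES = ("deletion", "tandem_duplication", "inversion", "translocation")

VALID_CONSEQUENCES = (
    "truncating_substitution",
    "out_of_frame_indel",
    "in_frame_indel",
    "missense",
    "synonymous",
    "splice_disrupting",
    "other",
)

#: Synonyms accepted on input (VEP/annotation-pipeline style) -> canonical term.
CONSEQUENCE_SYNONYMS = {
    "frameshift": "out_of_frame_indel",
    "frameshift_variant": "out_of_frame_indel",
    "stop_gained": "truncating_substitution",
    "nonsense": "truncating_substitution",
    "splice_acceptor_variant": "splice_disrupting",
    "splice_donor_variant": "splice_disrupting",
    "essential_splice": "splice_disrupting",
    "inframe_insertion": "in_frame_indel",
    "inframe_deletion": "in_frame_indel",
    "missense_variant": "missense",
    "synonymous_variant": "synonymous",
}


@dataclass(frozen=True, order=True)
class CopyNumberSegment:
    """Allele-specific copy number over ``[start, end)`` for one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(
                f"segment end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.minor_cn > self.major_cn:
            raise FormatError(
                f"minor_cn {self.minor_cn} > major_cn {self.major_cn} at "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        if self.minor_cn < 0:
            raise FormatError("negative copy number")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass(frozen=True)
class BreakpointLocus:
    chrom: str
    position: int  # 0-based
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be + or -, got {self.strand!r}")
        if self.position < 0:
            raise FormatError(f"negative breakpoint position {self.position}")


@dataclass(frozen=True)
class RearrangementBreakpoint:
    """A paired-end rearrangement junction; loci ordered canonically."""

    sample_id: str
    locus1: BreakpointLocus
    locus2: BreakpointLocus

    @property
    def sv_class(self) -> str:
        return classify_sv(self.locus1, self.locus2)

    def __post_init__(self) -> None:
        k1 = (self.locus1.chrom, self.locus1.position)
        k2 = (self.locus2.chrom, self.locus2.position)
        if k1 > k2:
            raise FormatError("breakpoint loci not in canonical order")

    @staticmethod
    def make(sample_id: str, l1: BreakpointLocus, l2: BreakpointLocus) -> "RearrangementBreakpoint":
        """Construct with automatic canonical ordering of the two loci."""
        if (l1.chrom, l1.position) > (l2.chrom, l2.position):
            l1, l2 = l2, l1
        return RearrangementBreakpoint(sample_id, l1, l2)


def classify_sv(l1: BreakpointLocus, l2: BreakpointLocus) -> str:
    """Structural-variant class from the orientation table in the module docs."""
    if l1.chrom != l2.chrom:
        return "translocation"
    strands = (l1.strand, l2.strand)
    if strands == ("+", "-"):
        return "deletion"
    if strands == ("-", "+"):
        return "tandem_duplication"
    return "inversion"


@dataclass(frozen=True)
class PointMutation:
    sample_id: str
    chrom: str
    position: int  # 0-based
    ref: str
    alt: str
    consequence: str
    gene: str = ""

    @property
    def variant_type(self) -> str:
        return "substitution" if len(self.ref) == len(self.alt) else "indel"

    def __post_init__(self) -> None:
        if self.consequence not in VALID_CONSEQUENCES:
            raise FormatError(
                f"unknown consequence {self.consequence!r}; allowed: "
                f"{', '.join(VALID_CONSEQUENCES)}"
            )


@dataclass(frozen=True)
class GenePanelEntry:
    """A cancer gene with genomic footprint ``[start, end)`` and curation role."""

    gene: str
    chrom: str
    start: int
    end: int
    role: str  # 'oncogene' or 'recessive'
    hotspots: tuple = ()  # ((position, alt), ...) — oncogenes only

    def __post_init__(self) -> None:
        if self.role not in ("oncogene", "recessive"):
            raise FormatError(f"role must be oncogene or recessive, got {self.role!r}")
        if self.end <= self.start:
            raise FormatError(f"gene {self.gene}: end must exceed start")

    def contains(self, chrom: str, position: int) -> bool:
        return self.chrom == chrom and self.start <= position < self.end


@dataclass
class ExpressionMatrix:
    """Gene-by-sample TPM matrix."""

    genes: list
    samples: list
    tpm: np.ndarray

    def __post_init__(self) -> None:
        self.tpm = np.asarray(self.tpm, dtype=float)
        if self.tpm.shape != (len(self.genes), len(self.samples)):
            raise FormatError(
                f"tpm shape {self.tpm.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if np.any(self.tpm < 0) or not np.all(np.isfinite(self.tpm)):
            raise FormatError("TPM values must be finite and >= 0")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene labels")
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("duplicate sample labels")

    def values_for(self, genes: Sequence[str], sample: str) -> np.ndarray:
        gi = {g: i for i, g in enumerate(self.genes)}
        si = self.samples.index(sample)
        return self.tpm[[gi[g] for g in genes], si]


# ---------------------------------------------------------------------------
# segment TSV

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "major_cn", "minor_cn"]


def _check_columns(df: pd.DataFrame, required: list, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}; found {list(df.columns)}")


def read_segments(path) -> list:
    """Read a copy-number segment TSV (1-based inclusive on disk).

    Returns segments in canonical (sample, chrom, start) order with the
    non-overlap invariant enforced per sample/chromosome.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _check_columns(df, SEGMENT_COLUMNS, path)
    segments = []
    for idx, row in df.iterrows():
        try:
            seg = CopyNumberSegment(
                sample_id=str(row["sample"]),
                chrom=normalize_chrom(row["chrom"]),
                start=int(row["start"]) - 1,
                end=int(row["end"]),
                major_cn=int(row["major_cn"]),
                minor_cn=int(row["minor_cn"]),
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path} row {idx + 2}: {exc}") from exc
        segments.append((idx, seg))
    segments.sort(key=lambda t: (t[1].sample_id, t[1].chrom, t[1].start))
    for (i_prev, prev), (i_cur, cur) in zip(segments, segments[1:]):
        if (
            prev.sample_id == cur.sample_id
            and prev.chrom == cur.chrom
            and cur.start < prev.end
        ):
            raise FormatError(
                f"{path}: overlapping segments for {cur.sample_id}/{cur.chrom} "
                f"(rows {i_prev + 2} and {i_cur + 2}): "
                f"{prev.start + 1}-{prev.end} and {cur.start + 1}-{cur.end}"
            )
    return [seg for _, seg in segments]


def write_segments(segments: Iterable[CopyNumberSegment], path) -> None:
    rows = [
        {
            "sample": s.sample_id,
            "chrom": s.chrom,
            "start": s.start + 1,
            "end": s.end,
            "major_cn": s.major_cn,
            "minor_cn": s.minor_cn,
        }
        for s in sorted(segments)
    ]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BEDPE breakpoints

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
]


def read_breakpoints(path) -> list:
    """Read rearrangement junctions from BEDPE (``name`` column = sample id)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 10:
        raise FormatError(f"{path}: BEDPE needs 10 columns, found {df.shape[1]}")
    df = df.iloc[:, :10]
    df.columns = BEDPE_COLUMNS
    out = []
    for idx, row in df.iterrows():
        try:
            l1 = BreakpointLocus(
                normalize_chrom(row["chrom1"]), int(row["start1"]), str(row["strand1"])
            )
            l2 = BreakpointLocus(
                normalize_chrom(row["chrom2"]), int(row["start2"]), str(row["strand2"])
            )
            bp = RearrangementBreakpoint.make(str(row["name"]), l1, l2)
        except (ValueError, TypeError, FormatError) as exc:
            raise FormatError(f"{path} row {idx + 1}: {exc}") from exc
        out.append(bp)
    out.sort(key=_breakpoint_key)
    return out


def _breakpoint_key(bp: RearrangementBreakpoint):
    return (
        bp.sample_id,
        bp.locus1.chrom, bp.locus1.position, bp.locus1.strand,
        bp.locus2.chrom, bp.locus2.position, bp.locus2.strand,
    )


def write_breakpoints(breakpoints: Iterable[RearrangementBreakpoint], path) -> None:
    rows = []
    for bp in sorted(breakpoints, key=_breakpoint_key):
        rows.append(
            {
                "chrom1": bp.locus1.chrom,
                "start1": bp.locus1.position,
                "end1": bp.locus1.position + 1,
                "chrom2": bp.locus2.chrom,
                "start2": bp.locus2.position,
                "end2": bp.locus2.position + 1,
                "name": bp.sample_id,
                "score": ".",
                "strand1": bp.locus1.strand,
                "strand2": bp.locus2.strand,
            }
        )
    pd.DataFrame(rows, columns=BEDPE_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# mutations TSV

MUTATION_COLUMNS = ["sample", "chrom", "position", "ref", "alt", "consequence", "gene"]


def read_mutations(path) -> list:
    """Read consequence-annotated point mutations (1-based positions on disk)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _check_columns(df, MUTATION_COLUMNS, path)
    out = []
    for idx, row in df.iterrows():
        cons = str(row["consequence"]).strip().lower()
        cons = CONSEQUENCE_SYNONYMS.get(cons, cons)
        try:
            mut = PointMutation(
                sample_id=str(row["sample"]),
                chrom=normalize_chrom(row["chrom"]),
                position=int(row["position"]) - 1,
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                consequence=cons,
                gene=str(row["gene"]),
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path} row {idx + 2}: {exc}") from exc
        out.append(mut)
    out.sort(key=lambda m: (m.sample_id, m.chrom, m.position, m.alt))
    return out


def write_mutations(mutations: Iterable[PointMutation], path) -> None:
    rows = [
        {
            "sample": m.sample_id,
            "chrom": m.chrom,
            "position": m.position + 1,
            "ref": m.ref,
            "alt": m.alt,
            "consequence": m.consequence,
            "gene": m.gene,
        }
        for m in sorted(mutations, key=lambda m: (m.sample_id, m.chrom, m.position, m.alt))
    ]
    pd.DataFrame(rows, columns=MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene panel: BED + YAML roles/hotspots

def read_gene_panel(bed_path, config_path) -> list:
    """Read the cancer-gene panel.

    ``bed_path``: 4-column BED (chrom, start, end, gene; 0-based half-open).
    ``config_path``: YAML mapping gene -> {role, hotspots: [[position, alt], ...]}
    with 1-based hotspot positions.
    """
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene"], dtype=str,
    )
    entries = []
    for idx, row in bed.iterrows():
        gene = str(row["gene"])
        gcfg = cfg.get(gene)
        if gcfg is None:
            raise FormatError(f"{config_path}: no role config for panel gene {gene}")
        hotspots = tuple(
            (int(pos) - 1, str(alt)) for pos, alt in gcfg.get("hotspots", []) or []
        )
        if hotspots and gcfg["role"] != "oncogene":
            raise FormatError(f"gene {gene}: hotspots only apply to oncogenes")
        try:
            entries.append(
                GenePanelEntry(
                    gene=gene,
                    chrom=normalize_chrom(row["chrom"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    role=str(gcfg["role"]),
                    hotspots=hotspots,
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{bed_path} row {idx + 1}: {exc}") from exc
    entries.sort(key=lambda g: (g.chrom, g.start, g.gene))
    return entries


def write_gene_panel(entries: Iterable[GenePanelEntry], bed_path, config_path) -> None:
    entries = sorted(entries, key=lambda g: (g.chrom, g.start, g.gene))
    bed_rows = [
        {"chrom": g.chrom, "start": g.start, "end": g.end, "gene": g.gene}
        for g in entries
    ]
    pd.DataFrame(bed_rows).to_csv(bed_path, sep="\t", index=False, header=False)
    cfg = {
        g.gene: {
            "role": g.role,
            "hotspots": [[pos + 1, alt] for pos, alt in g.hotspots],
        }
        for g in entries
    }
    with open(config_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# expression TSV

def read_expression(path) -> ExpressionMatrix:
    """Read a gene-by-sample TPM table (first column ``gene``)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene":
        raise FormatError(f"{path}: first column must be 'gene', got {df.columns[0]!r}")
    df = df.set_index("gene")
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        bad = np.argwhere(values < 0)[0]
        raise FormatError(
            f"{path}: negative TPM for gene {df.index[bad[0]]!r}, "
            f"sample {df.columns[bad[1]]!r}"
        )
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        tpm=values,
    )


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(matrix.tpm, index=matrix.genes, columns=matrix.samples)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# grouping helpers used throughout the pipeline

def group_by_sample(records) -> dict:
    out: dict = {}
    for r in records:
        out.setdefault(r.sample_id, []).append(r)
    return out


def segments_on(segments, chrom: str) -> list:
    return sorted(
        (s for s in segments if s.chrom == chrom), key=lambda s: s.start
    )


def breakpoint_loci_on(breakpoints, chrom: str) -> list:
    """All junction ends falling on ``chrom``, position-sorted."""
    loci = [bp.locus1 for bp in breakpoints if bp.locus1.chrom == chrom]
    loci += [bp.locus2 for bp in breakpoints if bp.locus2.chrom == chrom]
    return sorted(loci, key=lambda l: l.position)
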