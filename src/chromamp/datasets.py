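"""Reference fixture: allele-specific target-gene states in
chromothripsis-amplified osteosarcoma genomes.

``TARGET_GENE_TABLE`` encodes, per tumour sample, the reported allele-specific
state of putative target genes on chromosomes 5 (TERT, RICTOR), 12 (CCND2,
MDM2, CDK4) and 17 (TP53, COPS3, NF1): oncogenes as extra major-allele copies
('+N', '-' for no gain), tumour suppressors as minor-allele status ('LOH',
'BP' for a breakpoint inside the gene footprint, 'LOH+BP', '-'). ``bold``
marks entries reported as significant copy-number gain.

``build_target_gene_cohort`` reconstructs a *synthetic* segment/breakpoint
cohort realising exactly those states, so the allele-specific reporter can be
regression-tested cell by cell. Only the per-gene states are encoded; all
surrounding copy-number structure is synthetic.
"""

from __future__ import annotations

from .io_formats import BreakpointLocus, CopyNumberSegment, RearrangementBreakpoint
from .synthetic_data import DEFAULT_CHROM_LENGTHS, default_panel

#: sample -> gene -> cell string as printed
TARGET_GENE_TABLE = {
    "PD13486a": {"TERT": "-", "RICTOR": "+3"},
    "PD7190a": {"TERT": "+1", "RICTOR": "+6"},
    "PD9962a": {"TERT": "+5", "RICTOR": "+2"},
    "PD13490a": {"TERT": "+4", "RICTOR": "+7", "TP53": "LOH", "COPS3": "+13", "NF1": "BP"},
    "PD13478a": {"CCND2": "+1", "MDM2": "+20", "CDK4": "+22"},
    "PD13495a": {"CCND2": "+1", "MDM2": "+5", "CDK4": "-"},
    "PD7401a": {"CCND2": "+6", "MDM2": "+10", "CDK4": "+8"},
    "PD7508a": {"CCND2": "+2", "MDM2": "+17", "CDK4": "+23"},
    "PD13492a": {"CCND2": "+1", "MDM2": "-", "CDK4": "+15", "TP53": "LOH+BP", "COPS3": "+16", "NF1": "-"},
    "PD13476a": {"TP53": "LOH+BP", "COPS3": "+16", "NF1": "LOH"},
    "PD7513a": {"TP53": "LOH+BP", "COPS3": "+25", "NF1": "LOH"},
    "PD9056a": {"TP53": "LOH+BP", "COPS3": "+26", "NF1": "-"},
}

#: (sample, gene) entries reported as significant gain (bold in the source table)
BOLD_CELLS = frozenset(
    {
        ("PD13486a", "RICTOR"),
        ("PD7190a", "RICTOR"),
        ("PD9962a", "TERT"),
        ("PD9962a", "RICTOR"),
        ("PD13490a", "TERT"),
        ("PD13490a", "RICTOR"),
        ("PD13490a", "COPS3"),
        ("PD13478a", "MDM2"),
        ("PD13478a", "CDK4"),
        ("PD13495a", "MDM2"),
        ("PD7401a", "CCND2"),
        ("PD7401a", "MDM2"),
        ("PD7401a", "CDK4"),
        ("PD7508a", "CCND2"),
        ("PD7508a", "MDM2"),
        ("PD7508a", "CDK4"),
        ("PD13492a", "CDK4"),
        ("PD13492a", "COPS3"),
        ("PD13476a", "COPS3"),
        ("PD7513a", "COPS3"),
        ("PD9056a", "COPS3"),
    }
)

PAD = 10_000  # synthetic carve margin around each gene footprint


def table_panel() -> dict:
    """Panel entries for the eight target genes, keyed by symbol."""
    wanted = {"TERT", "RICTOR", "CCND2", "MDM2", "CDK4", "TP53", "COPS3", "NF1"}
    return {g.gene: g for g in default_panel() if g.gene in wanted}


def build_target_gene_cohort() -> tuple:
    """Synthetic (segments, breakpoints) realising every table cell.

    Each sample's involved chromosomes are tiled at a diploid background
    (major 1, minor 1) with a carve over each reported gene: '+N' sets the
    major allele to N+1 copies, 'LOH' zeroes the minor allele, and 'BP' adds
    a rearrangement junction end inside the footprint.
    """
    panel = table_panel()
    segments = []
    breakpoints = []
    for sample, cells in TARGET_GENE_TABLE.items():
        chroms = sorted({panel[g].chrom for g in cells})
        for chrom in chroms:
            length = DEFAULT_CHROM_LENGTHS[chrom]
            genes = sorted(
                (panel[g] for g in cells if panel[g].chrom == chrom),
                key=lambda g: g.start,
            )
            pos = 0
            for gene in genes:
                cell = cells[gene.gene]
                major, minor = 1, 1
                if gene.role == "oncogene":
                    if cell.startswith("+"):
                        major = int(cell[1:]) + 1
                else:
                    if "LOH" in cell:
                        minor = 0
                    if "BP" in cell:
                        mid = (gene.start + gene.end) // 2
                        breakpoints.append(
                            RearrangementBreakpoint.make(
                                sample,
                                BreakpointLocus(chrom, mid, "+"),
                                BreakpointLocus(chrom, gene.end + 5_000_000, "-"),
                            )
                        )
                carve_start, carve_end = gene.start - PAD, gene.end + PAD
                if carve_start > pos:
                    segments.append(
                        CopyNumberSegment(sample, chrom, pos, carve_start, 1, 1)
                    )
                segments.append(
                    CopyNumberSegment(sample, chrom, carve_start, carve_end, major, minor)
                )
                pos = carve_end
            segments.append(CopyNumberSegment(sample, chrom, pos, length, 1, 1))
    return segments, breakpoints
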