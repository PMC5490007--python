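"""End-to-end orchestration: drivers, profiles, aggregation, expression test.

This is the glue the command-line interface and the acceptance machinery run;
each step is a thin call into the corresponding analysis module, with TSV
emission for every stage output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_aggregation as agg
from . import driver_curation as dc
from . import expression_variance as ev
from . import rearrangement_profiles as rp
from .io_formats import group_by_sample, segments_on
from .synthetic_data import gene_cn


@dataclass
class PipelineResult:
    ploidy: dict
    drivers: dict  # sample -> [DriverEvent]
    genome_profiles: dict  # sample -> GenomeProfile
    chromosome_profiles: list
    recurrent_regions: list
    aggregate_profiles: dict  # chrom -> AggregateProfile
    expression_test: "ev.ExpressionTestResult | None"


def infer_chrom_lengths(segments: list) -> dict:
    lengths: dict = {}
    for s in segments:
        lengths[s.chrom] = max(lengths.get(s.chrom, 0), s.end)
    return lengths


def _neutral_over(sample_segments: list, chrom: str, start: int, end: int, nominal: int) -> bool:
    try:
        cn = gene_cn(segments_on(sample_segments, chrom), chrom, start, end)
    except ValueError:
        return False
    return abs(cn - nominal) < 0.25


def run_pipeline(
    segments: list,
    breakpoints: list,
    mutations: list,
    panel: list,
    expression=None,
    expression_genes: list | None = None,
    rules: dc.DriverRuleConfig | None = None,
    params: rp.ChromothripsisParams | None = None,
    min_recurrent_samples: int = 3,
    min_region_genes: int = 5,
    bin_size: int = 1_000_000,
) -> PipelineResult:
    """Run every analysis stage over an in-memory cohort."""
    rules = rules or dc.DriverRuleConfig()
    params = params or rp.ChromothripsisParams()
    seg_by_sample = group_by_sample(segments)
    bp_by_sample = group_by_sample(breakpoints)
    mut_by_sample = group_by_sample(mutations)
    samples = sorted(seg_by_sample)
    chrom_lengths = infer_chrom_lengths(segments)

    ploidy = {s: dc.classify_ploidy(seg_by_sample[s], rules=rules) for s in samples}
    drivers = {
        s: dc.curate_drivers(
            seg_by_sample[s],
            bp_by_sample.get(s, []),
            mut_by_sample.get(s, []),
            panel,
            rules,
            ploidy[s],
        )
        for s in samples
    }
    genome_profiles = {}
    chromosome_profiles = []
    for s in samples:
        gp = rp.profile_genome(
            seg_by_sample[s], bp_by_sample.get(s, []), ploidy[s], rules, params
        )
        genome_profiles[s] = gp
        chromosome_profiles += list(gp.chromosomes)

    regions = agg.recurrent_ca_regions(
        chromosome_profiles, chrom_lengths, min_recurrent_samples, panel, bin_size
    )

    aggregate_profiles = {}
    for chrom in sorted(chrom_lengths):
        matrix = np.vstack(
            [
                agg.bin_log_ratio(
                    segments_on(seg_by_sample[s], chrom),
                    ploidy[s].nominal_cn,
                    chrom_lengths[chrom],
                    bin_size,
                )
                for s in samples
            ]
        ) if samples else np.zeros((0, 0))
        if len(samples):
            aggregate_profiles[chrom] = agg.aggregate_profile(matrix, chrom, bin_size)

    expression_test = None
    if expression is not None and expression_genes and regions:
        region_genes = {}
        region_groups = {}
        for i, r in enumerate(regions):
            rid = f"{r.chrom}:{r.start}-{r.end}"
            genes = [
                g.gene
                for g in expression_genes
                if g.chrom == r.chrom and g.start < r.end and r.start < g.end
            ]
            ca_samples = sorted(
                {
                    p.sample_id
                    for p in chromosome_profiles
                    if p.chrom == r.chrom
                    and p.classification == "chromothripsis_amplification"
                    and p.region is not None
                    and p.region[0] < r.end
                    and r.start < p.region[1]
                    and p.sample_id in expression.samples
                }
            )
            neutral_samples = sorted(
                s
                for s in samples
                if s in expression.samples
                and s not in ca_samples
                and all(
                    p.classification == "none"
                    for p in genome_profiles[s].chromosomes
                    if p.chrom == r.chrom
                )
                and _neutral_over(
                    seg_by_sample[s], r.chrom, r.start, r.end, ploidy[s].nominal_cn
                )
            )
            region_genes[rid] = genes
            region_groups[rid] = (ca_samples, neutral_samples)
        expression_test = ev.run_expression_test(
            expression, region_genes, region_groups, min_genes=min_region_genes
        )

    return PipelineResult(
        ploidy=ploidy,
        drivers=drivers,
        genome_profiles=genome_profiles,
        chromosome_profiles=chromosome_profiles,
        recurrent_regions=regions,
        aggregate_profiles=aggregate_profiles,
        expression_test=expression_test,
    )


# ---------------------------------------------------------------------------
# TSV emission

def write_outputs(result: PipelineResult, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    rows = [
        {
            "sample": e.sample_id,
            "gene": e.gene,
            "mechanism": e.mechanism,
            "evidence": ";".join(e.evidence),
        }
        for s in sorted(result.drivers)
        for e in result.drivers[s]
    ]
    paths["drivers"] = out / "drivers.tsv"
    pd.DataFrame(rows, columns=["sample", "gene", "mechanism", "evidence"]).to_csv(
        paths["drivers"], sep="\t", index=False
    )

    rows = [
        {
            "sample": s,
            "genome_class": result.genome_profiles[s].label,
            "ploidy": result.ploidy[s].ploidy_class,
            "mean_cn": f"{result.ploidy[s].mean_cn:.3f}",
            "n_breakpoints": result.genome_profiles[s].n_breakpoints,
        }
        for s in sorted(result.genome_profiles)
    ]
    paths["profiles"] = out / "profiles.tsv"
    pd.DataFrame(
        rows, columns=["sample", "genome_class", "ploidy", "mean_cn", "n_breakpoints"]
    ).to_csv(paths["profiles"], sep="\t", index=False)

    rows = [
        {
            "sample": p.sample_id,
            "chrom": p.chrom,
            "class": p.classification,
            "n_breakpoints": p.n_breakpoints,
            "n_cn_states": p.n_cn_states,
            "n_oscillating_segments": p.n_oscillating_segments,
            "amplified_segments": p.amplified_segment_count,
        }
        for p in sorted(result.chromosome_profiles, key=lambda p: (p.sample_id, p.chrom))
    ]
    paths["chromosomes"] = out / "chromosome_profiles.tsv"
    pd.DataFrame(
        rows,
        columns=[
            "sample", "chrom", "class", "n_breakpoints", "n_cn_states",
            "n_oscillating_segments", "amplified_segments",
        ],
    ).to_csv(paths["chromosomes"], sep="\t", index=False)

    rows = [
        {
            "chrom": r.chrom,
            "start": r.start + 1,
            "end": r.end,
            "n_samples_ca": r.n_samples_ca,
            "target_genes": ",".join(r.target_genes),
        }
        for r in result.recurrent_regions
    ]
    paths["regions"] = out / "regions.tsv"
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_samples_ca", "target_genes"]
    ).to_csv(paths["regions"], sep="\t", index=False)

    rows = []
    for chrom in sorted(result.aggregate_profiles):
        p = result.aggregate_profiles[chrom]
        for i in range(len(p.starts)):
            rows.append(
                {
                    "chrom": chrom,
                    "bin_start": int(p.starts[i]) + 1,
                    "mean_log2": f"{p.mean[i]:.4f}",
                    "q1_log2": f"{p.q1[i]:.4f}",
                    "q3_log2": f"{p.q3[i]:.4f}",
                }
            )
    paths["aggregate"] = out / "aggregate.tsv"
    pd.DataFrame(
        rows, columns=["chrom", "bin_start", "mean_log2", "q1_log2", "q3_log2"]
    ).to_csv(paths["aggregate"], sep="\t", index=False)

    rows = []
    if result.expression_test is not None:
        for c in result.expression_test.comparisons:
            rows.append(
                {
                    "region": c.region_id,
                    "n_ca": c.n_ca,
                    "n_neutral": c.n_neutral,
                    "median_var_ca": f"{c.median_var_ca:.5g}",
                    "median_var_neutral": f"{c.median_var_neutral:.5g}",
                    "ca_higher": "" if c.indicator is None else c.indicator,
                }
            )
    paths["expr_test"] = out / "expr_test.tsv"
    pd.DataFrame(
        rows,
        columns=["region", "n_ca", "n_neutral", "median_var_ca", "median_var_neutral", "ca_higher"],
    ).to_csv(paths["expr_test"], sep="\t", index=False)
    return paths
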