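"""Cohort-aggregate copy-number profiles and recurrent amplification regions.

Per sample and chromosome, total copy number is binned (1 Mb default) as
``log2(length-weighted mean CN in bin / sample ploidy)``; gaps between
segments are imputed at ploidy. Across the cohort the per-bin mean, first and
third quartile form the aggregate profile, the standard visual summary of a
tumour type's copy-number landscape.

Recurrently chromothripsis-amplified regions are maximal runs of bins that at
least ``min_samples`` samples' chromothripsis-amplification regions overlap,
annotated with the panel genes they contain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AggregateProfile:
    chrom: str
    bin_size: int
    starts: np.ndarray  # bin start positions, 0-based
    mean: np.ndarray
    q1: np.ndarray
    q3: np.ndarray


@dataclass(frozen=True)
class RecurrentRegion:
    chrom: str
    start: int
    end: int  # half-open
    n_samples_ca: int
    target_genes: tuple = ()


def bin_log_ratio(
    segments: list,
    ploidy: float,
    chrom_length: int,
    bin_size: int = 1_000_000,
    floor_cn: float = 0.5,
) -> np.ndarray:
    """Per-bin log2(mean total CN / ploidy) for one sample and chromosome.

    ``segments`` are the (sorted, non-overlapping) segments of the chromosome;
    uncovered bases are imputed at ploidy. Bins whose weighted mean CN falls
    below ``floor_cn`` are clamped there so fully deleted bins stay finite.
    """
    n_bins = int(np.ceil(chrom_length / bin_size))
    cn_sum = np.full(n_bins, 0.0)
    covered = np.zeros(n_bins)
    edges = np.arange(n_bins + 1) * bin_size
    edges[-1] = chrom_length
    for s in segments:
        lo, hi = max(s.start, 0), min(s.end, chrom_length)
        if hi <= lo:
            continue
        first, last = lo // bin_size, (hi - 1) // bin_size
        for b in range(first, last + 1):
            ov = min(hi, edges[b + 1]) - max(lo, edges[b])
            cn_sum[b] += s.total_cn * ov
            covered[b] += ov
    widths = np.diff(edges).astype(float)
    mean_cn = (cn_sum + ploidy * (widths - covered)) / widths
    mean_cn = np.maximum(mean_cn, floor_cn)
    return np.log2(mean_cn / ploidy)


def aggregate_profile(
    bin_matrix: np.ndarray, chrom: str, bin_size: int = 1_000_000
) -> AggregateProfile:
    """Per-bin mean, Q1 and Q3 across samples (rows = samples, cols = bins).

    Quartiles use linear interpolation between order statistics.
    """
    m = np.atleast_2d(np.asarray(bin_matrix, dtype=float))
    if m.shape[0] < 1:
        raise ValueError("need at least one sample")
    n_bins = m.shape[1]
    return AggregateProfile(
        chrom=chrom,
        bin_size=bin_size,
        starts=np.arange(n_bins) * bin_size,
        mean=m.mean(axis=0),
        q1=np.quantile(m, 0.25, axis=0, method="linear"),
        q3=np.quantile(m, 0.75, axis=0, method="linear"),
    )


def recurrent_ca_regions(
    chromosome_profiles: list,
    chrom_lengths: dict,
    min_samples: int,
    panel: list = (),
    bin_size: int = 1_000_000,
) -> list:
    """Maximal intervals recurrently hit by chromothripsis-amplification.

    A bin qualifies when >= ``min_samples`` distinct samples carry a
    chromothripsis_amplification profile whose rearranged region overlaps the
    bin; adjacent qualifying bins are merged into half-open intervals.
    """
    per_chrom: dict = {}
    for p in chromosome_profiles:
        if p.classification != "chromothripsis_amplification" or p.region is None:
            continue
        per_chrom.setdefault(p.chrom, []).append(p)
    regions = []
    for chrom in sorted(per_chrom):
        length = chrom_lengths[chrom]
        n_bins = int(np.ceil(length / bin_size))
        counts = np.zeros(n_bins, dtype=int)
        for p in per_chrom[chrom]:
            lo, hi = p.region
            b0 = max(lo // bin_size, 0)
            b1 = min((hi - 1) // bin_size, n_bins - 1)
            counts[b0 : b1 + 1] += 1
        qualifying = counts >= min_samples
        b = 0
        while b < n_bins:
            if not qualifying[b]:
                b += 1
                continue
            b_end = b
            while b_end + 1 < n_bins and qualifying[b_end + 1]:
                b_end += 1
            start = b * bin_size
            end = min((b_end + 1) * bin_size, length)
            genes = tuple(
                sorted(
                    g.gene
                    for g in panel
                    if g.chrom == chrom and g.start < end and start < g.end
                )
            )
            regions.append(
                RecurrentRegion(
                    chrom=chrom,
                    start=start,
                    end=end,
                    n_samples_ca=int(counts[b : b_end + 1].max()),
                    target_genes=genes,
                )
            )
            b = b_end + 1
    return regions


def plot_aggregate(profile: AggregateProfile, ax=None):
    """Mean line with a Q1–Q3 band, the standard aggregate-landscape figure."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    x = (profile.starts + profile.bin_size / 2) / 1e6
    ax.fill_between(x, profile.q1, profile.q3, alpha=0.35, label="Q1–Q3")
    ax.plot(x, profile.mean, color="black", lw=1, label="mean")
    ax.axhline(0.0, color="grey", lw=0.5, ls=":")
    ax.set_xlabel(f"{profile.chrom} position (Mb)")
    ax.set_ylabel("copy number change (log2)")
    ax.legend(frameon=False, fontsize=8)
    return ax
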