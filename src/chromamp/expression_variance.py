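"""TPM-quartile-variance comparison and the cohort binomial sign test.

For each recurrently chromothripsis-amplified region and each sample, the
expression variability of the region is summarised as the sample variance
(denominator n-1 = 2) of the three TPM quartiles (Q1, Q2, Q3, linear
interpolation) over the region's genes. Per region, the median of this
variance among chromothripsis-amplified samples is compared with the median
among copy-number-neutral samples; under the null hypothesis that expression
variability is uncorrelated with copy-number state, either group wins with
probability one half. The number of regions where the amplified group is more
variable is referred to an exact one-sided binomial test at p0 = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np


@dataclass(frozen=True)
class RegionVariance:
    region_id: str
    sample_id: str
    q1: float
    q2: float
    q3: float
    variance: float


@dataclass(frozen=True)
class RegionComparison:
    region_id: str
    n_ca: int
    n_neutral: int
    median_var_ca: float
    median_var_neutral: float
    indicator: int | None  # 1 CA higher, 0 neutral higher, None = tie/excluded


@dataclass(frozen=True)
class BinomialSignResult:
    n_regions_tested: int
    k_ca_higher: int
    p_value: float
    null_probability: float = 0.5


def tpm_quartile_variance(
    values, region_id: str = "", sample_id: str = "", min_genes: int = 5
) -> RegionVariance | None:
    """Variance of the TPM quartiles of one region in one sample.

    Returns None (region skipped) when fewer than ``min_genes`` genes are
    available; raises on negative TPMs.
    """
    v = np.asarray(values, dtype=float)
    if v.size < min_genes:
        return None
    if np.any(v < 0):
        raise ValueError("TPM values must be >= 0")
    q1, q2, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
    variance = float(np.var([q1, q2, q3], ddof=1))
    return RegionVariance(region_id, sample_id, float(q1), float(q2), float(q3), variance)


def compare_region(
    region_id: str, ca_variances, neutral_variances
) -> RegionComparison | None:
    """Median-variance comparison for one region.

    Returns None when either group is empty. Exact ties give indicator None
    (the region drops out of the binomial count, the conservative sign-test
    convention).
    """
    ca = [rv.variance if isinstance(rv, RegionVariance) else float(rv) for rv in ca_variances]
    neu = [rv.variance if isinstance(rv, RegionVariance) else float(rv) for rv in neutral_variances]
    if not ca or not neu:
        return None
    m_ca = float(np.median(ca))
    m_neu = float(np.median(neu))
    if m_ca > m_neu:
        ind: int | None = 1
    elif m_ca < m_neu:
        ind = 0
    else:
        ind = None
    return RegionComparison(region_id, len(ca), len(neu), m_ca, m_neu, ind)


def binomial_sign_test(k: int, n: int) -> BinomialSignResult:
    """Exact one-sided binomial sign test: P(X >= k), X ~ Binomial(n, 1/2)."""
    if n < 1:
        raise ValueError("nothing tested: n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    p = sum(comb(n, i) for i in range(k, n + 1)) / 2**n
    return BinomialSignResult(n_regions_tested=n, k_ca_higher=k, p_value=float(p))


@dataclass
class ExpressionTestResult:
    status: str  # 'ok' | 'no test performed'
    comparisons: list
    result: BinomialSignResult | None
    skipped_regions: list


def run_expression_test(
    expression,
    region_genes: dict,
    region_groups: dict,
    min_genes: int = 5,
) -> ExpressionTestResult:
    """Full per-region pipeline and cohort sign test.

    ``region_genes``: region id -> list of gene symbols in the region (must be
    rows of ``expression``). ``region_groups``: region id -> (ca_samples,
    neutral_samples). Regions with too few genes, an empty group, or a tied
    median are excluded from the binomial count but reported.
    """
    comparisons = []
    skipped = []
    k = n = 0
    for region_id in sorted(region_genes):
        genes = [g for g in region_genes[region_id] if g in set(expression.genes)]
        if len(genes) < min_genes:
            skipped.append((region_id, f"only {len(genes)} genes (< {min_genes})"))
            continue
        ca_samples, neutral_samples = region_groups[region_id]
        ca_rv = [
            tpm_quartile_variance(
                expression.values_for(genes, s), region_id, s, min_genes
            )
            for s in ca_samples
        ]
        neu_rv = [
            tpm_quartile_variance(
                expression.values_for(genes, s), region_id, s, min_genes
            )
            for s in neutral_samples
        ]
        cmp = compare_region(
            region_id,
            [rv for rv in ca_rv if rv is not None],
            [rv for rv in neu_rv if rv is not None],
        )
        if cmp is None:
            skipped.append((region_id, "empty comparison group"))
            continue
        comparisons.append(cmp)
        if cmp.indicator is None:
            skipped.append((region_id, "tied medians"))
        else:
            n += 1
            k += cmp.indicator
    if n == 0:
        return ExpressionTestResult("no test performed", comparisons, None, skipped)
    return ExpressionTestResult("ok", comparisons, binomial_sign_test(k, n), skipped)
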