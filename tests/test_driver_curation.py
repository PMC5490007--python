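"""Driver-curation rules: ploidy, amplification, deletion, breakpoints, points."""

import pytest

from chromamp.driver_curation import (
    DriverRuleConfig,
    allele_specific_report,
    call_amplification,
    call_disruptive_breakpoint,
    call_homozygous_deletion,
    call_point_driver,
    classify_ploidy,
    curate_drivers,
)
from chromamp.io_formats import (
    BreakpointLocus,
    CopyNumberSegment,
    GenePanelEntry,
    PointMutation,
    RearrangementBreakpoint,
)

MB = 1_000_000
ONC = GenePanelEntry("ONC1", "chr5", 10_200_000, 10_300_000, "oncogene",
                     hotspots=((10_250_000, "A"),))
REC = GenePanelEntry("REC1", "chr17", 7_000_000, 7_050_000, "recessive")


def seg(start, end, major, minor, chrom="chr5", sample="S1"):
    return CopyNumberSegment(sample, chrom, start, end, major, minor)


def tile(chrom, length, carves, sample="S1", base=(1, 1)):
    """Background tiling at `base` with (start, end, major, minor) carves."""
    carves = sorted(carves)
    out, pos = [], 0
    for start, end, major, minor in carves:
        if start > pos:
            out.append(seg(pos, start, *base, chrom=chrom, sample=sample))
        out.append(seg(start, end, major, minor, chrom=chrom, sample=sample))
        pos = end
    if pos < length:
        out.append(seg(pos, length, *base, chrom=chrom, sample=sample))
    return out


class TestPloidy:
    def test_uniform_diploid(self):
        p = classify_ploidy([seg(0, 100 * MB, 1, 1)])
        assert p.ploidy_class == "diploid" and p.mean_cn == 2.0

    def test_uniform_tetraploid(self):
        p = classify_ploidy([seg(0, 100 * MB, 2, 2)])
        assert p.ploidy_class == "tetraploid" and p.mean_cn == 4.0

    def test_boundary_mean_three_reads_tetraploid(self):
        p = classify_ploidy([seg(0, 50 * MB, 1, 1), seg(50 * MB, 100 * MB, 2, 2)])
        assert p.mean_cn == 3.0 and p.ploidy_class == "tetraploid"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_ploidy([])


class TestAmplification:
    def test_focal_high_cn_segment_qualifies(self):
        segs = tile("chr5", 180 * MB, [(10_000_000, 10_400_000, 11, 1)])
        ploidy = classify_ploidy(segs)
        ev = call_amplification(ONC, segs, ploidy)
        assert ev is not None and ev.mechanism == "amplification"

    def test_exact_one_mb_run_fails_strict_focality(self):
        segs = tile("chr5", 180 * MB, [(10_000_000, 11_000_000, 11, 1)])
        assert call_amplification(ONC, segs, classify_ploidy(segs)) is None

    def test_contiguous_qualifying_run_measured_across_segments(self):
        # two adjacent qualifying segments jointly spanning >= 1 Mb
        segs = tile(
            "chr5", 180 * MB,
            [(9_900_000, 10_400_000, 11, 1), (10_400_000, 10_900_001, 8, 1)],
        )
        assert call_amplification(ONC, segs, classify_ploidy(segs)) is None

    def test_tetraploid_needs_nine_copies(self):
        segs = tile("chr5", 180 * MB, [(10_000_000, 10_400_000, 7, 1)], base=(2, 2))
        ploidy = classify_ploidy(segs)
        assert ploidy.ploidy_class == "tetraploid"
        assert call_amplification(ONC, segs, ploidy) is None  # 8 < 9
        segs = tile("chr5", 180 * MB, [(10_000_000, 10_400_000, 8, 1)], base=(2, 2))
        assert call_amplification(ONC, segs, classify_ploidy(segs)) is not None

    def test_partial_footprint_coverage_not_amplified(self):
        # amplicon covers only half of the gene
        segs = tile("chr5", 180 * MB, [(10_000_000, 10_250_000, 11, 1)])
        assert call_amplification(ONC, segs, classify_ploidy(segs)) is None

    def test_monotone_in_threshold(self):
        segs = tile("chr5", 180 * MB, [(10_000_000, 10_400_000, 6, 1)])
        ploidy = classify_ploidy(segs)
        # monotone for thresholds above the background ploidy (below it the
        # background joins the qualifying run and focality intervenes)
        hits = [
            call_amplification(
                ONC, segs, ploidy,
                DriverRuleConfig(min_amp_cn_diploid=t, min_amp_cn_tetraploid=t + 4),
            )
            is not None
            for t in range(3, 12)
        ]
        # once lost by raising the threshold, never regained
        assert hits == sorted(hits, reverse=True)


class TestHomozygousDeletion:
    def test_focal_cn0_overlapping_gene(self):
        segs = tile("chr17", 81 * MB, [(7_040_000, 7_240_000, 0, 0)], sample="S1")
        ev = call_homozygous_deletion(REC, segs)
        assert ev is not None and ev.mechanism == "homozygous_deletion"

    def test_broad_cn0_not_focal(self):
        segs = tile("chr17", 81 * MB, [(6 * MB, 8 * MB, 0, 0)])
        assert call_homozygous_deletion(REC, segs) is None

    def test_cn0_elsewhere_ignored(self):
        segs = tile("chr17", 81 * MB, [(20 * MB, 20_200_000, 0, 0)])
        assert call_homozygous_deletion(REC, segs) is None


class TestDisruptiveBreakpoint:
    def bp(self, pos, chrom="chr17", partner=("chr2", 50 * MB)):
        return RearrangementBreakpoint.make(
            "S1",
            BreakpointLocus(chrom, pos, "+"),
            BreakpointLocus(partner[0], partner[1], "-"),
        )

    def test_locus_inside_footprint_disrupts(self):
        assert call_disruptive_breakpoint(REC, [self.bp(7_010_000)]) is not None

    def test_one_bp_upstream_misses(self):
        assert call_disruptive_breakpoint(REC, [self.bp(6_999_999)]) is None
        assert call_disruptive_breakpoint(REC, [self.bp(7_000_000)]) is not None
        assert call_disruptive_breakpoint(REC, [self.bp(7_049_999)]) is not None
        assert call_disruptive_breakpoint(REC, [self.bp(7_050_000)]) is None

    def test_translocation_partner_in_footprint_counts(self):
        bp = RearrangementBreakpoint.make(
            "S1",
            BreakpointLocus("chr2", 5 * MB, "+"),
            BreakpointLocus("chr17", 7_020_000, "-"),
        )
        assert bp.sv_class == "translocation"
        assert call_disruptive_breakpoint(REC, [bp]) is not None


class TestPointDrivers:
    def test_frameshift_in_recessive_gene(self):
        m = PointMutation("S1", "chr17", 7_010_000, "CA", "C", "out_of_frame_indel", "REC1")
        ev = call_point_driver(REC, [m])
        assert ev is not None and ev.mechanism == "truncating_point"

    def test_oncogene_missense_off_hotspot_ignored(self):
        m = PointMutation("S1", "chr5", 10_250_001, "C", "A", "missense", "ONC1")
        assert call_point_driver(ONC, [m]) is None

    def test_oncogene_hotspot_hit(self):
        m = PointMutation("S1", "chr5", 10_250_000, "C", "A", "missense", "ONC1")
        ev = call_point_driver(ONC, [m])
        assert ev is not None and ev.mechanism == "hotspot_point"

    def test_recessive_missense_ignored(self):
        m = PointMutation("S1", "chr17", 7_010_000, "C", "A", "missense", "REC1")
        assert call_point_driver(REC, [m]) is None


class TestCurateDrivers:
    def test_empty_panel_empty_list(self):
        segs = tile("chr5", 180 * MB, [])
        assert curate_drivers(segs, [], [], []) == []

    def test_same_gene_two_mechanisms_two_events(self):
        segs = tile("chr17", 81 * MB, [])
        m = PointMutation("S1", "chr17", 7_010_000, "C", "T", "truncating_substitution", "REC1")
        bp = RearrangementBreakpoint.make(
            "S1", BreakpointLocus("chr17", 7_020_000, "+"), BreakpointLocus("chr17", 30 * MB, "-")
        )
        events = curate_drivers(segs, [bp], [m], [REC])
        assert {e.mechanism for e in events} == {"truncating_point", "disruptive_breakpoint"}

    def test_evidence_concatenated_on_duplicate_mechanism(self):
        segs = tile("chr17", 81 * MB, [])
        bps = [
            RearrangementBreakpoint.make(
                "S1", BreakpointLocus("chr17", 7_010_000, "+"), BreakpointLocus("chr17", 40 * MB, "-")
            ),
            RearrangementBreakpoint.make(
                "S1", BreakpointLocus("chr17", 7_020_000, "-"), BreakpointLocus("chr17", 50 * MB, "+")
            ),
        ]
        events = curate_drivers(segs, bps, [], [REC])
        (ev,) = events
        assert ev.mechanism == "disruptive_breakpoint" and len(ev.evidence) == 2


class TestAlleleSpecificReport:
    def test_high_major_gain_significant(self):
        segs = tile("chr17", 81 * MB, [(17_100_000, 17_150_000, 14, 1)])
        gene = GenePanelEntry("COPS3", "chr17", 17_109_756, 17_139_778, "oncogene")
        (call,) = allele_specific_report([gene], segs, [], "S1")
        assert call.render() == "+13" and call.significant

    def test_single_extra_copy_not_significant(self):
        segs = tile("chr5", 180 * MB, [(1_200_000, 1_300_000, 2, 1)])
        gene = GenePanelEntry("TERT", "chr5", 1_253_287, 1_295_162, "oncogene")
        (call,) = allele_specific_report([gene], segs, [], "S1")
        assert call.render() == "+1" and not call.significant

    def test_minimum_major_over_split_footprint(self):
        gene = GenePanelEntry("G", "chr5", 10 * MB, 11 * MB, "oncogene")
        segs = tile(
            "chr5", 180 * MB,
            [(9 * MB, 10_500_000, 8, 1), (10_500_000, 12 * MB, 5, 1)],
        )
        (call,) = allele_specific_report([gene], segs, [], "S1")
        assert call.extra_major_copies == 4  # min(8, 5) - 1

    def test_loh_plus_breakpoint_flags(self):
        gene = GenePanelEntry("TP53", "chr17", 7_571_720, 7_590_868, "recessive")
        # LOH carve stops inside the footprint -> not full-footprint LOH
        segs = tile("chr17", 81 * MB, [(6_900_000, 7_580_000, 1, 0)])
        (call,) = allele_specific_report([gene], segs, [], "S1")
        assert call.render() == "-"
        bp = RearrangementBreakpoint.make(
            "S1", BreakpointLocus("chr17", 7_580_000, "+"), BreakpointLocus("chr17", 20 * MB, "-")
        )
        segs_full = tile("chr17", 81 * MB, [(7_500_000, 7_600_000, 1, 0)])
        (call,) = allele_specific_report([gene], segs_full, [bp], "S1")
        assert call.render() == "LOH+BP"
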