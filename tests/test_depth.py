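"""Windowed depth, CNV classification, cohort logic, Table-1 analytics."""

import numpy as np
import pytest

import subtelcnv as sc
from subtelcnv.depth import (CallerParams, CNVCall, DepthProfile,
                             estimate_copy_number, flag_heterozygotes,
                             summarize_cnv_table)
from subtelcnv.io import PafRecord


def paf(tname, tstart, tend, q="r"):
    span = tend - tstart
    return PafRecord(q, span, 0, span, "+", tname, 10 ** 6, tstart, tend,
                     span, span, 60)


def make_profile(ratios, window=5000, background=30.0):
    ratios = np.asarray(ratios, float)
    counts = (ratios * background * window).astype(np.int64)
    p = DepthProfile("chr", len(ratios) * window, window, counts)
    p.background = background
    p.ratio = p.raw / background
    return p


class TestWindowDepth:
    def test_no_alignments_all_zero(self):
        profs = sc.window_depth([], {"chr": 20_000}, CallerParams())
        assert (profs["chr"].base_counts == 0).all()

    def test_ten_reads_covering_one_window(self):
        recs = [paf("chr", 5000, 10_000, f"r{i}") for i in range(10)]
        profs = sc.window_depth(recs, {"chr": 20_000}, CallerParams())
        assert profs["chr"].raw[1] == 10.0
        assert profs["chr"].raw[0] == 0.0

    def test_read_split_across_two_windows(self):
        recs = [paf("chr", 2000, 7000)]
        profs = sc.window_depth(recs, {"chr": 10_000}, CallerParams())
        assert profs["chr"].raw[0] == pytest.approx(0.6)
        assert profs["chr"].raw[1] == pytest.approx(0.4)

    def test_short_terminal_window_length_corrected(self):
        recs = [paf("chr", 0, 12_000)]
        profs = sc.window_depth(recs, {"chr": 12_000}, CallerParams())
        p = profs["chr"]
        assert p.last_window_short and p.window_lengths[-1] == 2000
        assert (p.raw == 1.0).all()

    def test_conservation_window_sums_equal_aligned_bases(self, desk_genome):
        rs = sc.simulate_long_reads(desk_genome, "R1",
                                    sc.ReadParams(depth=3, seed=1))
        aln = sc.project_to_reference(desk_genome, rs)
        profs = sc.window_depth(aln, desk_genome.reference_lengths,
                                CallerParams(window=500))
        total = sum(int(p.base_counts.sum()) for p in profs.values())
        assert total == aln.total_aligned_bases()

    def test_unknown_sequence_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="unknown"):
            profs = sc.window_depth([paf("nope", 0, 100)], {"chr": 10_000})
        assert (profs["chr"].base_counts == 0).all()

    def test_sam_input_primary_only(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr\tLN:20000\n"
            "r1\t0\tchr\t5001\t60\t5000M\t*\t0\t0\t" + "A" * 5000 + "\t*\n"
            "r1\t2048\tchr\t1\t60\t1000M4000H\t*\t0\t0\t*\t*\n")
        profs = sc.depth.window_depth_bam(sam, {"chr": 20_000}, CallerParams())
        assert profs["chr"].raw[1] == 1.0
        assert profs["chr"].raw[0] == 0.0    # supplementary excluded


class TestNormalize:
    def test_uniform_coverage_ratio_one(self):
        p = DepthProfile("chr", 100_000, 5000,
                         np.full(20, 30 * 5000, dtype=np.int64))
        sc.normalize_depth(p)
        assert p.background == 30.0
        assert np.allclose(p.ratio, 1.0)

    def test_single_high_window_does_not_move_background(self):
        counts = np.full(50, 30 * 5000, dtype=np.int64)
        counts[10] *= 4
        p = DepthProfile("chr", 250_000, 5000, counts)
        sc.normalize_depth(p)
        assert p.background == 30.0
        assert p.ratio[10] == pytest.approx(4.0)

    def test_too_few_windows_rejected(self):
        p = DepthProfile("chr", 50_000, 5000,
                         np.full(10, 1000, dtype=np.int64))
        with pytest.raises(ValueError, match="20 windows"):
            sc.normalize_depth(p)

    def test_zero_background_rejected(self):
        p = DepthProfile("chr", 150_000, 5000, np.zeros(30, dtype=np.int64))
        with pytest.raises(ValueError, match="background"):
            sc.normalize_depth(p)


class TestCallCnv:
    def test_threshold_classification(self):
        p = make_profile([1, 1, 5.0, 1, 0.2, 1, 3.0, 1])
        calls = sc.call_cnv(p, CallerParams())
        classes = {(c.start // 5000): c.cnv_class for c in calls}
        assert classes == {2: "duplication", 4: "deletion"}

    def test_insignificant_windows_dropped(self):
        # tiny absolute counts: ratio passes but the Poisson tail does not
        # (1 observed base against an expectation of 0.2)
        p = make_profile([1, 5.0, 1], background=4e-5)
        assert sc.call_cnv(p, CallerParams()) == []

    def test_adjacent_windows_merge(self):
        p = make_profile([1, 6, 6, 6, 1, 1, 6, 1])
        calls = sc.call_cnv(p, CallerParams())
        spans = [(c.start, c.end, c.n_windows) for c in calls]
        assert spans == [(5000, 20_000, 3), (30_000, 35_000, 1)]

    def test_raising_dup_ratio_never_adds_duplicated_windows(self):
        """Raising the duplication threshold shrinks the called territory:
        neither the total length nor the window count of duplication calls
        grows (run merging means call *numbers* can fluctuate)."""
        rng = np.random.default_rng(0)
        p = make_profile(rng.uniform(0.5, 8, 60))
        prev_w, prev_len = np.inf, np.inf
        for dup in (2.0, 4.0, 6.0, 8.0):
            calls = [c for c in sc.call_cnv(p, CallerParams(dup_ratio=dup))
                     if c.cnv_class == "duplication"]
            n_windows = sum(c.n_windows for c in calls)
            tot = sum(c.end - c.start for c in calls)
            assert n_windows <= prev_w and tot <= prev_len
            prev_w, prev_len = n_windows, tot


def call(chrom, start, end, cls="duplication"):
    return CNVCall(chrom, start, end, cls, 5.0, 1e-9, 1)


class TestIntersectCohort:
    def test_identical_interval_all_resistant(self):
        gr = [[call("c", 100, 200)], [call("c", 100, 200)]]
        assert sc.intersect_cohort(gr, []) == [("c", 100, 200)]

    def test_partial_overlap_minus_susceptible(self):
        gr = [[call("c", 100, 200)], [call("c", 150, 250)]]
        gs = [[call("c", 180, 260)]]
        assert sc.intersect_cohort(gr, gs) == [("c", 150, 180)]

    def test_one_empty_resistant_individual_empties_result(self):
        gr = [[call("c", 100, 200)], []]
        assert sc.intersect_cohort(gr, []) == []

    def test_deletions_ignored(self):
        gr = [[call("c", 100, 200), call("c", 300, 400, "deletion")]] * 2
        assert sc.intersect_cohort(gr, []) == [("c", 100, 200)]

    def test_empty_resistant_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sc.intersect_cohort([], [])


class TestRegionDepthAndZygosity:
    def test_weighted_mean_over_windows(self):
        p = make_profile([1, 20, 24, 1])
        per, mean = sc.mean_region_depth({"i1": {"chr": p}},
                                         ("chr", 5000, 15_000))
        assert per["i1"] == pytest.approx(22.0)
        assert mean == pytest.approx(22.0)

    def test_interval_outside_profile_rejected(self):
        p = make_profile([1, 1])
        with pytest.raises(ValueError, match="outside"):
            sc.mean_region_depth({"i": {"chr": p}}, ("chr", 0, 99_999))

    def test_published_ratio_pattern_flags_exactly_r14(self):
        ratios = dict(zip("abcdefgh", [29, 27, 25, 28, 26, 29, 27, 8]))
        flags = flag_heterozygotes(ratios)
        assert [k for k, v in flags.items() if v == "het"] == ["h"]

    def test_all_equal_flags_none(self):
        flags = flag_heterozygotes({"a": 20, "b": 20, "c": 20})
        assert set(flags.values()) == {"hom"}

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            flag_heterozygotes({"a": 1, "b": 2})

    def test_copy_number_from_ratio(self):
        assert estimate_copy_number(1.0) == 2
        assert estimate_copy_number(4.0) == 8
        with pytest.raises(ValueError):
            estimate_copy_number(-1)


class TestSimulatedRecovery:
    def test_planted_22_copy_region_ratio(self):
        """A 44-copy diploid region reads out at ~22x the background."""
        spec, cas = sc.desk_scale(seed=21, tandem_copies=21)
        g = sc.build_genome(spec, cas, [sc.IndividualDesign("R1", (21, 0))])
        rs = sc.simulate_long_reads(g, "R1", sc.ReadParams(depth=30, seed=21))
        profs = sc.window_depth(sc.project_to_reference(g, rs),
                                g.reference_lengths, CallerParams(window=500))
        sc.normalize_depth(profs)
        a = cas.native_a
        per, _ = sc.mean_region_depth(
            {"R1": profs}, (a[0], a[1], a[1] + cas.len_a))
        assert abs(per["R1"] - 22) <= 2.2

    def test_sixteen_copy_estimate_within_one(self):
        spec, cas = sc.desk_scale(seed=3, tandem_copies=7)
        g = sc.build_genome(spec, cas, [sc.IndividualDesign("R1", (4, 3))])
        hits = 0
        for rep in range(20):
            rs = sc.simulate_long_reads(g, "R1",
                                        sc.ReadParams(depth=30, seed=rep))
            profs = sc.window_depth(sc.project_to_reference(g, rs),
                                    g.reference_lengths,
                                    CallerParams(window=500))
            sc.normalize_depth(profs)
            a = cas.native_a
            per, _ = sc.mean_region_depth(
                {"R1": profs}, (a[0], a[1], a[1] + cas.len_a))
            hits += abs(estimate_copy_number(per["R1"]) - 16) <= 1
        assert hits >= 18

    def test_heterozygote_flagged_in_most_replicates(self):
        """Cassette on one haplotype among homozygotes: flagged >= 95% of
        200 replicates."""
        spec, cas = sc.desk_scale(seed=31, tandem_copies=4)
        cohort = [sc.IndividualDesign(f"R{i}", (4, 4)) for i in range(3)]
        cohort.append(sc.IndividualDesign("H", (2, 0)))
        g = sc.build_genome(spec, cas, cohort)
        a = cas.native_a
        region = (a[0], a[1], a[1] + cas.len_a)
        flagged = 0
        for rep in range(200):
            per = {}
            for d in cohort:
                rs = sc.simulate_long_reads(
                    g, d.name, sc.ReadParams(depth=20, seed=7000 + rep))
                profs = sc.window_depth(sc.project_to_reference(g, rs),
                                        g.reference_lengths,
                                        CallerParams(window=500))
                sc.normalize_depth(profs)
                per.update(sc.mean_region_depth({d.name: profs}, region)[0])
            flags = flag_heterozygotes(per)
            flagged += (flags["H"] == "het"
                        and all(v == "hom" for k, v in flags.items() if k != "H"))
        assert flagged >= 190


class TestCnvTable:
    def test_fixture_totals(self):
        rows = sc.load_fixture("cnv_table")
        s = summarize_cnv_table(rows)
        assert (s["total"], s["chromosomes"], s["scaffolds"]) == (34, 15, 19)

    def test_high_depth_scaffold_events(self):
        rows = sc.load_fixture("cnv_table")
        s = summarize_cnv_table(rows, depth_cutoff=20)
        assert s["above_cutoff"]["scaffolds"] == ["CNV21", "CNV26", "CNV29",
                                                  "CNV30"]

    def test_lengths_validate_against_coordinates(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("event\tseqname\tstart\tstop\tlength\tdepth_gr\n"
                       "CNVX\tChr1\t100\t200\t150\t3.0\n")
        with pytest.raises(ValueError, match="CNVX"):
            sc.parse_cnv_table(bad)

    def test_empty_table_zero_counts(self, tmp_path):
        empty = tmp_path / "empty.tsv"
        empty.write_text("event\tseqname\tstart\tstop\tlength\tdepth_gr\n")
        s = summarize_cnv_table(sc.parse_cnv_table(empty))
        assert s["total"] == 0 and s["above_cutoff"]["scaffolds"] == []
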