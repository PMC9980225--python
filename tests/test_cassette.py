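"""Cassette model, junction support, ratio test, self-alignment."""

from collections import Counter

import numpy as np
import pytest

import subtelcnv as sc
from subtelcnv import cassette as cas
from subtelcnv.simulate import decode_seq, revcomp


@pytest.fixture(scope="module")
def cspec():
    return sc.desk_scale()[1]


@pytest.fixture(scope="module")
def model(cspec):
    return cas.build_cassette_model(cspec, 452)


class TestModel:
    def test_forward_half_segment_order(self, cspec):
        m = cas.build_cassette_model(cspec, 452, full=False)
        assert [s.name for s in m.segments] == \
            ["ST_flank", "A", "B1", "I", "B2", "ST_short"]

    def test_total_length_additivity(self, cspec, model):
        arrays = (sum(cspec.flank_array) * 2 + sum(cspec.short_array)) * 452
        genes = 2 * (cspec.len_a + cspec.len_b1 + cspec.len_i + cspec.len_b2)
        assert model.total_length == arrays + genes

    def test_bed_round_trip_lossless(self, model):
        m2 = cas.CassetteModel.from_bed(model.to_bed())
        assert [(s.name, s.length, s.strand, s.inversion_offset)
                for s in m2.segments] == \
               [(s.name, s.length, s.strand, s.inversion_offset)
                for s in model.segments]

    def test_zero_length_segment_rejected(self):
        with pytest.raises(ValueError):
            cas.Segment("A", 0)


class TestJunctions:
    def test_forward_half_junction_ids(self, cspec):
        m = cas.build_cassette_model(cspec, 452, full=False)
        ids = {j.id for j in cas.enumerate_junctions(m)}
        assert ids == {"ST-A", "A-B", "B-I", "I-B", "B-ST"}

    def test_single_segment_no_junctions(self):
        m = cas.CassetteModel([cas.Segment("A", 100)])
        assert cas.enumerate_junctions(m) == []

    def test_full_model_each_id_twice_plus_inversion(self, model):
        counts = Counter(j.id for j in cas.enumerate_junctions(model))
        assert counts == {"ST-A": 2, "A-B": 2, "B-I": 2, "I-B": 2, "B-ST": 2,
                          "inversion-point": 1}

    def test_ids_invariant_under_reverse_complement(self, model):
        rev = model.reversed()
        c1 = Counter(j.id for j in cas.enumerate_junctions(model))
        c2 = Counter(j.id for j in cas.enumerate_junctions(rev))
        assert c1 == c2
        pos1 = sorted(j.position for j in cas.enumerate_junctions(model))
        pos2 = sorted(model.total_length - j.position
                      for j in cas.enumerate_junctions(rev))
        assert pos1 == pos2


def paf_at(tstart, tend, q="r", tlen=100_000):
    from subtelcnv.io import PafRecord
    span = tend - tstart
    return PafRecord(q, span, 0, span, "+", "cassette", tlen, tstart, tend,
                     span, span, 60)


class TestSpanningReads:
    def test_no_alignments_zero_counts(self, model):
        juncs = cas.enumerate_junctions(model)
        sup = cas.count_spanning_reads([], juncs, reference_length=model.total_length)
        assert all(s.count == 0 for s in sup)

    def test_overhang_arithmetic(self):
        juncs = [cas.Junction("A-B", 10_000, "A", "B")]
        rec = [paf_at(9850, 10_200)]
        assert cas.count_spanning_reads(rec, juncs, 100)[0].count == 1
        assert cas.count_spanning_reads(rec, juncs, 200)[0].count == 0

    def test_read_counted_once_per_junction_id(self):
        juncs = [cas.Junction("ST-A", 5_000, "ST", "A"),
                 cas.Junction("ST-A", 9_000, "A", "ST")]
        sup = cas.count_spanning_reads([paf_at(4000, 10_000, "long")], juncs, 100)
        assert sup[0].count == 1

    def test_junction_outside_reference_rejected(self, model):
        bad = [cas.Junction("X-Y", model.total_length + 5, "X", "Y")]
        with pytest.raises(ValueError, match="outside"):
            cas.count_spanning_reads([paf_at(0, 100, tlen=model.total_length)],
                                     bad)


class TestRatioTest:
    def test_published_counts_consistent_with_two(self):
        sup = [cas.JunctionSupport(i, c, tuple(f"r{k}" for k in range(c)), 100)
               for i, c in [("ST-A", 545), ("A-B", 466), ("B-I", 466),
                            ("I-B", 466), ("B-ST", 545),
                            ("inversion-point", 265)]]
        rt = cas.junction_ratio_test(sup)
        assert rt.ratio == pytest.approx(497.6 / 265, abs=1e-6)
        assert rt.consistent_with_2

    def test_equal_counts_not_consistent_with_two(self):
        sup = [cas.JunctionSupport(i, 400, tuple(f"r{k}" for k in range(400)),
                                   100)
               for i in ["ST-A", "A-B", "B-I", "I-B", "B-ST",
                         "inversion-point"]]
        rt = cas.junction_ratio_test(sup)
        assert rt.ratio == pytest.approx(1.0)
        assert not rt.consistent_with_2

    def test_zero_inversion_count_rejected(self):
        sup = [cas.JunctionSupport("A-B", 10, tuple(f"r{k}" for k in range(10)), 100),
               cas.JunctionSupport("inversion-point", 0, (), 100)]
        with pytest.raises(ValueError, match="undefined|unsupported"):
            cas.junction_ratio_test(sup)


@pytest.fixture(scope="module")
def locus_sim():
    spec, cspec = sc.desk_scale(seed=3, tandem_copies=3)
    g = sc.build_genome(spec, cspec, [sc.IndividualDesign("R1", (3, 3))])
    model = cas.build_cassette_model(cspec, 452)
    juncs = cas.enumerate_junctions(model)
    return g, model, juncs


class TestSimulatedJunctions:
    def test_domain_junction_counts_within_25pct(self, locus_sim):
        g, model, juncs = locus_sim
        rs = sc.simulate_long_reads(
            g, "R1", sc.ReadParams(depth=30, sub_rate=0, ins_rate=0,
                                   del_rate=0, seed=5))
        sup = cas.count_spanning_reads(sc.project_to_cassette(g, rs), juncs)
        counts = [s.count for s in sup if s.junction_id != "inversion-point"]
        assert min(counts) >= 0.75 * max(counts)

    def test_inversion_half_coverage_over_replicates(self, locus_sim):
        """Aggregate support over 100 replicates: non-inversion/inversion
        ratio consistent with 2, and per-replicate ratio in [1.6, 2.4]
        >= 95% of the time."""
        g, model, juncs = locus_sim
        agg = Counter()
        in_band = 0
        for rep in range(100):
            rs = sc.simulate_long_reads(
                g, "R1", sc.ReadParams(depth=30, sub_rate=0, ins_rate=0,
                                       del_rate=0, seed=900 + rep))
            sup = cas.count_spanning_reads(sc.project_to_cassette(g, rs),
                                           juncs)
            for s in sup:
                agg[s.junction_id] += s.count
            rt = cas.junction_ratio_test(sup)
            in_band += 1.6 <= rt.ratio <= 2.4
        assert in_band >= 95
        inv = agg.pop("inversion-point")
        ratio = np.mean(list(agg.values())) / inv
        se = ratio * np.sqrt(1 / sum(agg.values()) + 1 / inv)
        assert abs(ratio - 2) <= 3 * se


class TestVariantCopies:
    def test_published_fraction_gives_one_copy(self):
        assert cas.estimate_variant_copies(0.12, 8).mutant_copies == 1

    def test_zero_fraction(self):
        assert cas.estimate_variant_copies(0.0, 8).mutant_copies == 0

    def test_standard_error_formula(self):
        est = cas.estimate_variant_copies(0.5, 8, n_reads=1000)
        assert est.mutant_copies == 4
        assert est.se_copies == pytest.approx(np.sqrt(0.25 / 1000) * 8)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cas.estimate_variant_copies(1.2, 8)


class TestSelfAlign:
    def test_random_sequence_no_long_segments(self, rng):
        seq = decode_seq(rng.integers(0, 4, 10_000, dtype=np.uint8))
        assert cas.self_align(seq) == []

    def test_palindrome_single_reverse_segment(self, rng):
        x = decode_seq(rng.integers(0, 4, 5_000, dtype=np.uint8))
        segs = [m for m in cas.self_align(x + revcomp(x))
                if m.start1 <= m.start2]
        assert len(segs) == 1
        m = segs[0]
        assert m.strand == "-" and abs(m.length - 5000) <= 20
        assert abs((m.end1 + m.start2) / 2 - 5000) <= 10

    def test_tandem_lags_at_unit_multiples(self, rng):
        unit = decode_seq(rng.integers(0, 4, 452, dtype=np.uint8))
        segs = cas.self_align(unit * 10)
        lags = sorted({m.lag for m in segs if m.strand == "+" and m.lag > 0})
        assert lags == [452 * j for j in range(1, 10)]

    def test_symmetry(self, rng):
        unit = decode_seq(rng.integers(0, 4, 300, dtype=np.uint8))
        seq = unit * 3 + decode_seq(rng.integers(0, 4, 1000, dtype=np.uint8))
        segs = set((m.start1, m.start2, m.length, m.strand)
                   for m in cas.self_align(seq))
        assert all((s2, s1, ln, st) in segs for s1, s2, ln, st in segs)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            cas.self_align("ACGT", k=15)


class TestMacrostructure:
    def test_no_segments_no_detections(self):
        ms = cas.infer_macrostructure([], 10_000)
        assert ms.tandem_arrays == [] and ms.inverted_duplications == []

    def test_short_array_copies_and_strands(self, rng):
        unit = decode_seq(rng.integers(0, 4, 452, dtype=np.uint8))
        seq = unit * 12 + revcomp(unit) * 31
        ms = cas.infer_macrostructure(cas.self_align(seq), len(seq))
        got = sorted((a.copies, a.unit_length, a.strand)
                     for a in ms.tandem_arrays)
        assert got == [(12, 452, "+"), (31, 452, "-")]

    @pytest.mark.parametrize("copies", [3, 5, 12, 31, 50])
    def test_copy_count_exact_recovery(self, rng, copies):
        unit = decode_seq(rng.integers(0, 4, 452, dtype=np.uint8))
        seq = unit * copies
        ms = cas.infer_macrostructure(cas.self_align(seq), len(seq))
        assert [(a.unit_length, a.copies) for a in ms.tandem_arrays] == \
            [(452, copies)]

    def test_full_cassette_inversion_midpoint(self):
        spec, cspec = sc.desk_scale(seed=3, tandem_copies=1)
        g = sc.build_genome(spec, cspec, [sc.IndividualDesign("R1", (1, 1))])
        lp = g.locus_params("R1")
        locus = g.sequence("R1", "Chr3")[lp["start"]:lp["end"]]
        ms = cas.infer_macrostructure(cas.self_align(locus), len(locus))
        assert ms.inverted_duplications
        short_start = lp["flank_len"] + cspec.len_a + cspec.len_b1 \
            + cspec.len_i + cspec.len_b2
        true_center = short_start + sum(cspec.short_array) * 452 / 2
        best = ms.inverted_duplications[0]
        assert abs(best.midpoint - true_center) <= 452

    def test_boundary_truncated_array_flagged_minimum(self, rng):
        unit = decode_seq(rng.integers(0, 4, 452, dtype=np.uint8))
        ms = cas.infer_macrostructure(cas.self_align(unit * 8), 8 * 452)
        assert ms.tandem_arrays[0].is_minimum
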