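"""Core interval engine: BED I/O, half-open semantics, oracle agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from chromlink import (
    Genome,
    GenomicInterval,
    IntervalSet,
    count_flanking,
    filter_by_score,
    nearest_distance,
    overlap_pairs,
    read_bed,
    subtract_condition,
    window_intersect,
)
from chromlink.intervals import pairs_within
from conftest import random_intervals


def iset(genome, rows):
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), genome)


class TestBedIO:
    def test_bed3_parse(self, toy_genome, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        s = read_bed(p, toy_genome)
        assert len(s) == 1 and s[0] == GenomicInterval("chr1", 100, 200)

    def test_inverted_span_rejected(self, toy_genome, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(ValueError, match="bad.bed:1"):
            read_bed(p, toy_genome)

    def test_bed6_fields_preserved(self, toy_genome, tmp_path):
        p = tmp_path / "b.bed"
        p.write_text("chr1\t10\t20\tpeak1\t3.2\t+\n")
        iv = read_bed(p, toy_genome)[0]
        assert (iv.name, iv.score, iv.strand) == ("peak1", 3.2, "+")

    def test_unknown_chrom_skips_with_warning_or_strict_error(self, toy_genome, tmp_path):
        p = tmp_path / "c.bed"
        p.write_text("chrZ\t0\t10\nchr1\t5\t9\n")
        with pytest.warns(UserWarning, match="chrZ"):
            s = read_bed(p, toy_genome)
        assert len(s) == 1
        with pytest.raises(ValueError, match="chrZ"):
            read_bed(p, toy_genome, strict=True)

    def test_out_of_bounds_rejected(self, toy_genome, tmp_path):
        p = tmp_path / "d.bed"
        p.write_text("chr3\t0\t600000\n")
        with pytest.raises(ValueError, match="exceeds chromosome length"):
            read_bed(p, toy_genome)

    def test_bed6_round_trip_byte_identical(self, toy_genome, tmp_path):
        text = "chr1\t10\t20\tpeak1\t3.2\t+\nchr1\t30\t40\tpeak2\t5\t-\nchr2\t5\t9\tpeak3\t.\t.\n"
        p1, p2 = tmp_path / "r1.bed", tmp_path / "r2.bed"
        p1.write_text(text)
        read_bed(p1, toy_genome).write_bed(p2)
        assert p2.read_text() == text


class TestHalfOpenSemantics:
    def test_touching_intervals_do_not_overlap(self, toy_genome):
        a = iset(toy_genome, [("chr1", 100, 200)])
        b = iset(toy_genome, [("chr1", 200, 300)])
        assert len(overlap_pairs(a, b)) == 0

    def test_overlap_amount(self, toy_genome):
        a = iset(toy_genome, [("chr1", 100, 200)])
        b = iset(toy_genome, [("chr1", 150, 250)])
        pairs = overlap_pairs(a, b)
        assert len(pairs) == 1 and pairs["overlap_bp"].iloc[0] == 50

    def test_nearest_gap_and_overlap(self, toy_genome):
        q = iset(toy_genome, [("chr1", 100, 200), ("chr1", 350, 360)])
        s = iset(toy_genome, [("chr1", 300, 400)])
        nn = nearest_distance(q, s)
        assert nn["distance_bp"].tolist() == [100.0, 0.0]

    def test_no_same_chromosome_subject_flagged(self, toy_genome):
        q = iset(toy_genome, [("chr2", 10, 20)])
        s = iset(toy_genome, [("chr1", 10, 20)])
        nn = nearest_distance(q, s)
        assert nn["subject_index"].iloc[0] == -1 and np.isnan(nn["distance_bp"].iloc[0])


class TestSubtraction:
    def test_removes_overlapped_keeps_rest(self, toy_genome):
        control = iset(toy_genome, [("chr1", 0, 100), ("chr1", 500, 600)])
        case = iset(toy_genome, [("chr1", 50, 80)])
        out = subtract_condition(control, case)
        assert [(iv.start, iv.end) for iv in out] == [(500, 600)]

    def test_empty_case_is_identity(self, toy_genome):
        control = iset(toy_genome, [("chr1", 0, 100)])
        case = IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]), toy_genome)
        assert len(subtract_condition(control, case)) == 1

    def test_output_subset_of_control_and_disjoint_from_case(self, toy_genome):
        rng = np.random.default_rng(5)
        control = random_intervals(rng, toy_genome, 300)
        case = random_intervals(rng, toy_genome, 300)
        out = subtract_condition(control, case)
        control_keys = {(iv.chrom, iv.start, iv.end) for iv in control}
        assert all((iv.chrom, iv.start, iv.end) in control_keys for iv in out)
        assert len(overlap_pairs(out, case)) == 0


class TestWindowIntersect:
    def test_embedded_site_retained_at_window_zero(self, toy_genome):
        sites = iset(toy_genome, [("chr1", 150, 152)])
        regions = iset(toy_genome, [("chr1", 100, 200)])
        assert len(window_intersect(sites, regions, 0)) == 1

    def test_window_semantics_nearby_site(self, toy_genome):
        sites = iset(toy_genome, [("chr1", 88, 90)])  # 10 bp left of region
        regions = iset(toy_genome, [("chr1", 100, 200)])
        assert len(window_intersect(sites, regions, 0)) == 0
        assert len(window_intersect(sites, regions, 50)) == 1


class TestScoreFilter:
    def test_strictly_greater(self, toy_genome):
        df = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [0, 10, 20], "end": [5, 15, 25],
             "score": [1.9, 2.0, 2.1]}
        )
        out = filter_by_score(IntervalSet(df, toy_genome), 2.0)
        assert len(out) == 1 and out[0].score == 2.1

    def test_missing_score_errors_with_interval(self, toy_genome):
        df = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [5], "name": ["p"]})
        with pytest.raises(ValueError, match="chr1:0-5"):
            filter_by_score(IntervalSet(df, toy_genome), 2.0)


class TestFlanking:
    def test_two_peaks_one_site(self, toy_genome):
        sites = iset(toy_genome, [("chr1", 50_000, 50_002)])
        peaks = iset(toy_genome, [("chr1", 53_000, 53_400), ("chr1", 58_000, 58_400)])
        assert count_flanking(sites, peaks, 10_000) == (1, 2)

    def test_no_peaks_in_window(self, toy_genome):
        sites = iset(toy_genome, [("chr1", 50_000, 50_002)])
        peaks = iset(toy_genome, [("chr1", 80_000, 80_400)])
        assert count_flanking(sites, peaks, 10_000) == (0, 0)

    def test_shared_peak_counts_once_per_site(self, toy_genome):
        # a single peak within the window of k sites contributes k occasions
        sites = iset(toy_genome, [("chr1", 50_000, 50_002), ("chr1", 52_000, 52_002)])
        peaks = iset(toy_genome, [("chr1", 51_000, 51_100)])
        assert count_flanking(sites, peaks, 10_000) == (2, 2)


@pytest.mark.parametrize("seed", range(5))
class TestOracleAgreement:
    """Randomized instances against the all-vs-all reference scans."""

    def test_overlap_pairs(self, toy_genome, seed):
        rng = np.random.default_rng(seed)
        a = random_intervals(rng, toy_genome, 200)
        b = random_intervals(rng, toy_genome, 200)
        min_ov = int(rng.integers(1, 500))
        got = overlap_pairs(a, b, min_ov)
        assert sorted(zip(got["a_index"], got["b_index"], got["overlap_bp"])) == \
            oracles.overlap_pairs(a, b, min_ov)

    def test_pairs_within(self, toy_genome, seed):
        rng = np.random.default_rng(100 + seed)
        a = random_intervals(rng, toy_genome, 150)
        b = random_intervals(rng, toy_genome, 150)
        g = int(rng.integers(0, 20_000))
        got = pairs_within(a, b, g)
        assert sorted(zip(got["a_index"], got["b_index"], got["gap_bp"])) == \
            oracles.pairs_within(a, b, g)

    def test_nearest_distance(self, toy_genome, seed):
        rng = np.random.default_rng(200 + seed)
        q = random_intervals(rng, toy_genome, 300)
        s = random_intervals(rng, toy_genome, 100)
        got = nearest_distance(q, s)["distance_bp"]
        expected = oracles.nearest(q, s)
        for g, e in zip(got, expected):
            assert (e is None and np.isnan(g)) or g == e

    def test_subtract(self, toy_genome, seed):
        rng = np.random.default_rng(300 + seed)
        control = random_intervals(rng, toy_genome, 500)
        case = random_intervals(rng, toy_genome, 500)
        got = subtract_condition(control, case)
        exp_idx = oracles.subtract(control, case)
        assert [(iv.chrom, iv.start, iv.end) for iv in got] == [
            (control[i].chrom, control[i].start, control[i].end) for i in exp_idx
        ]

    def test_count_flanking(self, toy_genome, seed):
        rng = np.random.default_rng(400 + seed)
        sites = random_intervals(rng, toy_genome, 100, max_len=10)
        peaks = random_intervals(rng, toy_genome, 200, max_len=500)
        assert count_flanking(sites, peaks, 10_000) == oracles.flanking(sites, peaks, 10_000)

    def test_window_intersect(self, toy_genome, seed):
        rng = np.random.default_rng(500 + seed)
        sites = random_intervals(rng, toy_genome, 200, max_len=10)
        regions = random_intervals(rng, toy_genome, 50, max_len=3_000)
        window = int(rng.choice([0, 100, 5_000]))
        got = window_intersect(sites, regions, window)
        exp = oracles.window_sites(sites, regions, window)
        assert [(iv.chrom, iv.start) for iv in got] == [
            (sites[i].chrom, sites[i].start) for i in exp
        ]


@settings(max_examples=30, deadline=None)
@given(
    data_a=st.lists(
        st.tuples(st.integers(0, 9_000), st.integers(1, 800)), min_size=1, max_size=40
    ),
    data_b=st.lists(
        st.tuples(st.integers(0, 9_000), st.integers(1, 800)), min_size=1, max_size=40
    ),
    min_ov=st.integers(1, 100),
)
def test_overlap_pairs_symmetry_property(data_a, data_b, min_ov):
    """overlap_pairs(a, b) mirrors overlap_pairs(b, a) with swapped roles."""
    genome = Genome({"chr1": 10_000})

    def build(data):
        df = pd.DataFrame(
            {"chrom": "chr1", "start": [s for s, _ in data],
             "end": [min(s + l, 10_000) for s, l in data]}
        )
        return IntervalSet(df, genome)

    a, b = build(data_a), build(data_b)
    ab = overlap_pairs(a, b, min_ov)
    ba = overlap_pairs(b, a, min_ov)
    assert sorted(zip(ab["a_index"], ab["b_index"])) == sorted(zip(ba["b_index"], ba["a_index"]))
    assert sorted(ab["overlap_bp"]) == sorted(ba["overlap_bp"])
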