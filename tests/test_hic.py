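"""Hi-C contact filtering and area-1/area-2 mining."""

import numpy as np
import pandas as pd
import pytest

import oracles
from chromlink import IntervalSet, area2_profile, contact_summary, filter_contacts, find_area1
from chromlink.hic import ContactSet, read_bedpe
from conftest import random_intervals


def write_bedpe_text(path, rows):
    path.write_text("".join(
        f"{c1}\t{s1}\t{e1}\t{c2}\t{s2}\t{e2}\t{name}\t{score}\n"
        for c1, s1, e1, c2, s2, e2, name, score in rows
    ))


@pytest.fixture
def contacts(toy_genome, tmp_path):
    rows = [
        ("chr1", 10_000, 11_000, "chr1", 200_000, 201_000, "c1", 5.0),
        ("chr1", 500_000, 501_000, "chr1", 400_000, 401_000, "c2", 4.0),  # reversed
        ("chr1", 10_000, 11_000, "chr1", 200_000, 201_000, "dup", 3.0),   # duplicate coords
        ("chr1", 10_000, 11_000, "chr2", 20_000, 21_000, "inter", 2.0),   # dropped
        ("chr1", 50_000, 51_000, "chr1", 50_300, 51_300, "near", 1.0),    # sep 300
    ]
    p = tmp_path / "contacts.bedpe"
    write_bedpe_text(p, rows)
    return read_bedpe(p, toy_genome)


class TestReadBedpe:
    def test_canonical_orientation_dedup_and_intra_only(self, contacts):
        assert len(contacts) == 3  # c1, c2 (reoriented), near; dup + inter dropped
        c2 = contacts.df[contacts.df["name"] == "c2"].iloc[0]
        assert c2["start1"] == 400_000 and c2["start2"] == 500_000
        assert (contacts.df["separation"] > 0).all()

    def test_separation_is_midpoint_distance(self, contacts):
        c1 = contacts.df[contacts.df["name"] == "c1"].iloc[0]
        assert c1["separation"] == 190_000.0


class TestFilterContacts:
    def test_bounds_inclusive_and_short_dropped(self, contacts):
        kept = filter_contacts(contacts, 1_000, 10_000_000)
        assert sorted(kept.df["name"]) == ["c1", "c2"]  # "near" at 300 bp dropped

    def test_exact_bound_retained(self, toy_genome, tmp_path):
        p = tmp_path / "b.bedpe"
        write_bedpe_text(p, [("chr1", 0, 1_000, "chr1", 10_000, 11_000, "x", 1.0)])
        cs = read_bedpe(p, toy_genome)
        assert cs.df["separation"].iloc[0] == 10_000.0
        assert len(filter_contacts(cs, 1_000, 10_000)) == 1

    def test_idempotent(self, contacts):
        once = filter_contacts(contacts)
        twice = filter_contacts(once)
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_predicate_matches_oracle_on_random_pairs(self, toy_genome, tmp_path):
        rng = np.random.default_rng(41)
        rows = []
        for i in range(1_000):
            s1 = int(rng.integers(0, 500_000))
            sep = int(rng.integers(100, 900_000))
            rows.append(("chr1", s1, s1 + 1_000, "chr1", s1 + sep, s1 + sep + 1_000, f"r{i}", 1.0))
        p = tmp_path / "r.bedpe"
        write_bedpe_text(p, rows)
        cs = read_bedpe(p, toy_genome)
        kept = filter_contacts(cs, 1_000, 500_000)
        expected = {f"r{i}" for i, r in enumerate(rows)
                    if 1_000 <= (r[4] + r[5]) / 2 - (r[1] + r[2]) / 2 <= 500_000}
        assert set(kept.df["name"]) == expected


class TestArea1:
    def prcas(self, genome, rows, names):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df["name"] = names
        return IntervalSet(df, genome)

    def test_window_rule(self, toy_genome, tmp_path):
        p = tmp_path / "a.bedpe"
        write_bedpe_text(p, [
            ("chr1", 10_000, 11_000, "chr1", 300_000, 301_000, "hit800", 1.0),
            ("chr1", 40_000, 41_000, "chr1", 600_000, 601_000, "miss1200", 1.0),
        ])
        cs = read_bedpe(p, toy_genome)
        prcas = self.prcas(toy_genome, [("chr1", 11_800, 12_100), ("chr1", 42_200, 42_500)],
                           ["p1", "p2"])
        hits = find_area1(cs, prcas, 1_000)
        assert hits["contact_id"].tolist() == ["hit800"]
        assert hits["distance_bp"].tolist() == [800]

    def test_both_anchor_match_yields_two_hits(self, toy_genome, tmp_path):
        p = tmp_path / "b.bedpe"
        write_bedpe_text(p, [("chr1", 10_000, 11_000, "chr1", 300_000, 301_000, "c", 1.0)])
        cs = read_bedpe(p, toy_genome)
        prcas = self.prcas(toy_genome, [("chr1", 10_200, 10_500), ("chr1", 300_200, 300_500)],
                           ["p1", "p2"])
        hits = find_area1(cs, prcas, 1_000)
        assert len(hits) == 2 and sorted(hits["anchor"]) == [1, 2]
        single = find_area1(cs, prcas, 1_000, both_anchors=False)
        assert len(single) == 1 and single["anchor"].iloc[0] == 1


class TestArea2Profile:
    def test_counts_window_strict_and_nearest(self, toy_genome, tmp_path):
        p = tmp_path / "c.bedpe"
        write_bedpe_text(p, [("chr1", 10_000, 11_000, "chr1", 500_000, 501_000, "c", 1.0)])
        cs = read_bedpe(p, toy_genome)
        prcas = TestArea1().prcas(toy_genome, [("chr1", 10_100, 10_400)], ["p1"])
        hits = find_area1(cs, prcas, 1_000)
        ircas = TestArea1().prcas(
            toy_genome,
            [("chr1", 511_000, 512_000), ("chr1", 521_000, 522_000), ("chr1", 561_000, 562_000)],
            ["i1", "i2", "i3"],
        )  # gaps 10k, 20k, 60k from area-2 end
        hsites = TestArea1().prcas(toy_genome, [("chr2", 100, 102)], ["h1"])
        prof = area2_profile(cs, hits, ircas, hsites, 50_000)
        row = prof.iloc[0]
        assert row["n_irca_within"] == 2 and row["nearest_irca_bp"] == 10_000
        assert np.isnan(row["nearest_hsite_bp"]) and row["n_hsite_within"] == 0

    def test_profiles_match_all_pairs_oracle(self, toy_genome, tmp_path):
        rng = np.random.default_rng(42)
        rows = []
        for i in range(60):
            s1 = int(rng.integers(0, 200_000))
            sep = int(rng.integers(50_000, 700_000))
            rows.append(("chr1", s1, s1 + 1_000, "chr1", s1 + sep, s1 + sep + 1_000, f"r{i}", 1.0))
        p = tmp_path / "d.bedpe"
        write_bedpe_text(p, rows)
        cs = read_bedpe(p, toy_genome)
        prcas = random_intervals(rng, toy_genome, 60, max_len=400)
        hits = find_area1(cs, prcas, 1_000)
        ircas = random_intervals(rng, toy_genome, 120)
        hsites = random_intervals(rng, toy_genome, 120, max_len=5)
        prof = area2_profile(cs, hits, ircas, hsites, 50_000)
        area2_rows = list(zip(["chr1"] * len(prof), prof["area2_start"], prof["area2_end"]))
        for feats, near_col, cnt_col in (
            (ircas, "nearest_irca_bp", "n_irca_within"),
            (hsites, "nearest_hsite_bp", "n_hsite_within"),
        ):
            exp = oracles.area2_counts(area2_rows, feats, 50_000)
            for k, (best, cnt) in enumerate(exp):
                got_near = prof[near_col].iloc[k]
                assert (best is None and np.isnan(got_near)) or got_near == best
                assert prof[cnt_col].iloc[k] == cnt
                assert cnt <= len(feats)


class TestContactSummary:
    def test_mean_separation_and_gene_join(self, toy_genome, tmp_path):
        p = tmp_path / "e.bedpe"
        write_bedpe_text(p, [
            ("chr1", 10_000, 11_000, "chr1", 110_000, 111_000, "c1", 1.0),  # sep 100k
            ("chr1", 10_000, 11_000, "chr1", 310_000, 311_000, "c2", 1.0),  # sep 300k
        ])
        cs = read_bedpe(p, toy_genome)
        prcas = TestArea1().prcas(toy_genome, [("chr1", 10_100, 10_400)], ["p1"])
        hits = find_area1(cs, prcas, 1_000)
        ircas = TestArea1().prcas(toy_genome, [("chr1", 120_000, 121_000)], ["i1"])
        hsites = TestArea1().prcas(toy_genome, [("chr2", 100, 102)], ["h1"])
        prof = area2_profile(cs, hits, ircas, hsites, 50_000)
        pairing = pd.DataFrame({"prca_name": ["p1"], "gene_id": ["gA"]})
        summary = contact_summary(hits, prof, pairing)
        assert summary["mean_separation_bp"] == pytest.approx(200_000.0)
        gt = summary["gene_table"]
        assert gt["gene_id"].tolist() == ["gA"]
        assert gt["n_areas2"].iloc[0] == 2
        # only c1's area-2 has an i-RCA within the window
        assert gt["n_areas2_with_irca"].iloc[0] == 1 and bool(gt["has_irca_support"].iloc[0])
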