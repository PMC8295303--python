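"""Density correlations, pairing, TAD contingency and chi-square."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import oracles
from chromlink import (
    CooccurrenceTable,
    Genome,
    IntervalSet,
    chi_square_2x2,
    chromosome_density,
    density_correlation,
    pair_prca_with_downregulated,
    tad_cooccurrence,
)
from conftest import random_intervals


def iset(genome, rows, names=None):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if names:
        df["name"] = names
    return IntervalSet(df, genome)


class TestDensity:
    def test_per_mbp_arithmetic(self):
        g = Genome({"chrA": 10_000_000})
        feats = iset(g, [("chrA", i * 1000, i * 1000 + 10) for i in range(10)])
        assert chromosome_density(feats, g).tolist() == [1.0]

    def test_empty_set_all_zero(self, toy_genome):
        feats = IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]), toy_genome)
        assert chromosome_density(feats, toy_genome).tolist() == [0.0, 0.0, 0.0]

    def test_counts_match_tally(self, toy_genome):
        rng = np.random.default_rng(21)
        feats = random_intervals(rng, toy_genome, 333)
        dens = chromosome_density(feats, toy_genome)
        for chrom in toy_genome.names:
            expected = sum(1 for iv in feats if iv.chrom == chrom) / (toy_genome[chrom] / 1e6)
            assert dens[chrom] == expected


class TestSpearman:
    def idx(self, n):
        return pd.Index([f"chr{i}" for i in range(n)])

    def test_monotone_transform_gives_r_one(self):
        a = pd.Series([1.0, 3.0, 2.0, 5.0, 4.0, 7.0], index=self.idx(6))
        b = np.exp(a)
        r, p = density_correlation(a, b)
        assert r == pytest.approx(1.0)
        # only the identity and the full reversal reach |r| = 1 among 6! pairings
        assert p == pytest.approx(2 / math.factorial(6), abs=1e-12)

    def test_reversed_ranks_give_minus_one(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=self.idx(5))
        b = pd.Series([9.0, 7.0, 5.0, 3.0, 1.0], index=self.idx(5))
        r, _ = density_correlation(a, b)
        assert r == pytest.approx(-1.0)

    def test_exact_p_equals_full_enumeration(self):
        rng = np.random.default_rng(22)
        n = 8
        a = pd.Series(rng.normal(size=n), index=self.idx(n))
        b = pd.Series(rng.normal(size=n), index=self.idx(n))
        r_obs, p = density_correlation(a, b)
        ra, rb = sps.rankdata(a), sps.rankdata(b)
        hits = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(ra, rb[list(perm)])[0, 1]
            if abs(r) >= abs(r_obs) - 1e-12:
                hits += 1
        assert p == pytest.approx(hits / math.factorial(n), abs=1e-12)

    def test_asymptotic_branch_matches_scipy(self):
        rng = np.random.default_rng(23)
        n = 20
        a = pd.Series(rng.normal(size=n), index=self.idx(n))
        b = pd.Series(a.to_numpy() + rng.normal(size=n), index=self.idx(n))
        r, p = density_correlation(a, b)
        ref = sps.spearmanr(a, b)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_zero_variance_errors(self):
        a = pd.Series([1.0] * 5, index=self.idx(5))
        b = pd.Series(range(5), index=self.idx(5), dtype=float)
        with pytest.raises(ValueError, match="zero-variance"):
            density_correlation(a, b)


class TestPairing:
    def test_pair_within_cap_and_closed_boundary(self, toy_genome):
        prcas = iset(toy_genome, [("chr1", 10_000, 10_300), ("chr1", 50_000, 50_300)],
                     ["p1", "p2"])
        genes = iset(
            toy_genome,
            [("chr1", 12_300, 20_000), ("chr1", 55_301, 60_000)],
            ["gA", "gB"],
        )  # gaps: 2000 (pair) and 5001 (excluded)
        res = pair_prca_with_downregulated(prcas, genes, 5_000)
        assert len(res.pairs) == 1
        row = res.pairs.iloc[0]
        assert (row["prca_name"], row["gene_id"], row["distance_bp"]) == ("p1", "gA", 2000)

    def test_many_to_many_counts(self, toy_genome):
        prcas = iset(toy_genome, [("chr1", 10_000, 10_100), ("chr1", 11_000, 11_100)],
                     ["p1", "p2"])
        genes = iset(toy_genome, [("chr1", 9_000, 9_500), ("chr1", 12_000, 12_500)],
                     ["gA", "gB"])
        res = pair_prca_with_downregulated(prcas, genes, 5_000)
        assert len(res.pairs) == 4
        assert res.n_unique_genes == 2 and res.n_unique_prcas == 2


class TestTadCooccurrence:
    def test_four_tads_one_per_cell(self, toy_genome):
        tads = iset(toy_genome, [("chr1", 0, 100_000), ("chr1", 100_000, 200_000),
                                 ("chr1", 200_000, 300_000), ("chr1", 300_000, 400_000)])
        a = iset(toy_genome, [("chr1", 10, 20), ("chr1", 100_010, 100_020)])
        b = iset(toy_genome, [("chr1", 30, 40), ("chr1", 200_010, 200_020)])
        t = tad_cooccurrence(tads, a, b)
        assert (t.n_both, t.n_a_only, t.n_b_only, t.n_neither) == (1, 1, 1, 1)

    def test_empty_set_b(self, toy_genome):
        tads = iset(toy_genome, [("chr1", 0, 100_000)])
        a = iset(toy_genome, [("chr1", 10, 20)])
        b = IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]), toy_genome)
        t = tad_cooccurrence(tads, a, b)
        assert (t.n_both, t.n_b_only) == (0, 0)

    def test_cells_match_per_tad_oracle_and_sum(self, toy_genome):
        rng = np.random.default_rng(31)
        tads = iset(
            toy_genome,
            [("chr1", i * 5_000, (i + 1) * 5_000) for i in range(200)],
        )
        a = random_intervals(rng, toy_genome, 150)
        b = random_intervals(rng, toy_genome, 150)
        t = tad_cooccurrence(tads, a, b)
        assert (t.n_both, t.n_a_only, t.n_b_only, t.n_neither) == oracles.tad_table(tads, a, b)
        assert t.n == 200

    def test_spanning_feature_counts_for_both_tads(self, toy_genome):
        tads = iset(toy_genome, [("chr1", 0, 100_000), ("chr1", 100_000, 200_000)])
        a = iset(toy_genome, [("chr1", 99_000, 101_000)])
        b = IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]), toy_genome)
        t = tad_cooccurrence(tads, a, b)
        assert t.n_a_only == 2

    def test_containment_flag_excludes_spanning(self, toy_genome):
        tads = iset(toy_genome, [("chr1", 0, 100_000), ("chr1", 100_000, 200_000)])
        a = iset(toy_genome, [("chr1", 99_000, 101_000)])
        b = IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]), toy_genome)
        t = tad_cooccurrence(tads, a, b, containment=True)
        assert t.n_a_only == 0


class TestChiSquare:
    def test_independent_table_is_zero(self):
        chi2, p, odds = chi_square_2x2(CooccurrenceTable(10, 10, 10, 10))
        assert chi2 == 0.0 and p == pytest.approx(1.0) and odds == 1.0

    def test_matches_cellwise_oracle_on_random_tables(self):
        rng = np.random.default_rng(32)
        for _ in range(100):
            cells = rng.integers(1, 500, size=4)
            t = CooccurrenceTable(*[int(c) for c in cells])
            chi2, _, _ = chi_square_2x2(t)
            assert chi2 == pytest.approx(oracles.chi2_from_observed(cells), abs=1e-9)
            assert chi2 >= 0

    def test_zero_iff_ad_equals_bc(self):
        chi2, _, _ = chi_square_2x2(CooccurrenceTable(6, 3, 4, 2))  # 12 == 12
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_scipy_uncorrected(self):
        t = CooccurrenceTable(278, 194, 399, 2667)
        chi2, p, _ = chi_square_2x2(t)
        ref = sps.chi2_contingency(t.as_array(), correction=False)
        assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_infinite_odds_flagged(self):
        chi2, _, odds = chi_square_2x2(CooccurrenceTable(5, 0, 3, 7))
        assert odds == math.inf

    def test_degenerate_margins_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi_square_2x2(CooccurrenceTable(0, 0, 5, 5))
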