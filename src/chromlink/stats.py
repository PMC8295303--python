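"""Chromosome-density correlations, promoter-RCA/gene pairing, and the
TAD co-occurrence contingency test.

The central inference step asks whether promoter RCAs and intergenic
RCAs co-localize within the same topologically associating domains
(TADs): every TAD is scored for overlap with either feature set, the
resulting 2x2 table (both / A only / B only / neither) is tested with
an uncorrected Pearson chi-square on 1 df, and the odds ratio ad/bc
summarizes the association strength.  No continuity correction is
applied (the corrected statistic does not reproduce the reference
computation; see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import Genome
from .intervals import IntervalSet, overlap_pairs, pairs_within

EXACT_SPEARMAN_MAX_N = 9


def chromosome_density(features: IntervalSet, genome: Genome) -> pd.Series:
    """Features per Mbp for every chromosome of the genome.

    Chromosomes without features get density 0, so two density vectors
    over the same genome always align.
    """
    counts = features.df["chrom"].value_counts()
    out = {}
    for chrom in genome.names:
        out[chrom] = counts.get(chrom, 0) / (genome[chrom] / 1e6)
    return pd.Series(out, name="density_per_mbp")


def density_correlation(a: pd.Series, b: pd.Series) -> tuple[float, float]:
    """Spearman rank correlation between two chromosome-density vectors.

    Ties receive average ranks.  The two-tailed p-value is an exact
    permutation probability for n <= 9 (full enumeration over rank
    assignments) and the usual t-approximation for larger n.  Raises on
    zero-variance input, where the coefficient is undefined.
    """
    if not a.index.equals(b.index):
        raise ValueError("density vectors are not aligned on chromosome")
    n = len(a)
    if n < 4:
        raise ValueError("need >= 4 chromosomes")
    x = a.to_numpy(float)
    y = b.to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance density vector; correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_MAX_N:
        p = _exact_spearman_p(rx, ry, r)
    else:
        t = r * math.sqrt((n - 2) / max(1 - r * r, 1e-300))
        p = float(2 * sps.t.sf(abs(t), n - 2))
    return r, min(p, 1.0)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    """Two-tailed permutation p: fraction of the n! pairings with
    |r| >= |r_obs| (up to float tolerance)."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    target = abs(r_obs) * denom - 1e-9
    hits = 0
    total = 0
    for perm in permutations(range(len(ry))):
        total += 1
        if abs(float(rx @ ry[list(perm)])) >= target:
            hits += 1
    return hits / total


@dataclass(frozen=True)
class CooccurrenceTable:
    """TAD-level 2x2 contingency counts."""

    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int

    def __post_init__(self) -> None:
        for v in (self.n_both, self.n_a_only, self.n_b_only, self.n_neither):
            if v < 0:
                raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_both + self.n_a_only + self.n_b_only + self.n_neither

    def as_array(self) -> np.ndarray:
        return np.array([[self.n_both, self.n_a_only], [self.n_b_only, self.n_neither]], float)


def tad_cooccurrence(
    tads: IntervalSet, set_a: IntervalSet, set_b: IntervalSet, containment: bool = False
) -> CooccurrenceTable:
    """Classify every TAD by overlap with set A and/or set B.

    Membership is any >= 1 bp overlap by default; ``containment=True``
    demands the feature to lie fully inside the TAD (bedops
    element-of-style).  A feature spanning two adjacent TADs counts for
    both under the default rule.  Cells always sum to |tads|.
    """
    has_a = _tad_membership(tads, set_a, containment)
    has_b = _tad_membership(tads, set_b, containment)
    return CooccurrenceTable(
        int((has_a & has_b).sum()),
        int((has_a & ~has_b).sum()),
        int((~has_a & has_b).sum()),
        int((~has_a & ~has_b).sum()),
    )


def _tad_membership(tads: IntervalSet, features: IntervalSet, containment: bool) -> np.ndarray:
    has = np.zeros(len(tads), dtype=bool)
    if len(features) == 0:
        return has
    hits = overlap_pairs(tads, features, 1)
    if containment and len(hits):
        tstart = tads.df["start"].to_numpy()[hits["a_index"]]
        tend = tads.df["end"].to_numpy()[hits["a_index"]]
        fstart = features.df["start"].to_numpy()[hits["b_index"]]
        fend = features.df["end"].to_numpy()[hits["b_index"]]
        hits = hits[(fstart >= tstart) & (fend <= tend)]
    has[np.unique(hits["a_index"].to_numpy(np.int64))] = True
    return has


def chi_square_2x2(table: CooccurrenceTable) -> tuple[float, float, float]:
    """Uncorrected Pearson chi-square for a 2x2 table.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) with 1 df; the odds
    ratio is ad/bc (+inf when bc = 0).  Degenerate margins (an all-zero
    row or column, i.e. an expected cell of 0) raise.
    """
    a, b = float(table.n_both), float(table.n_a_only)
    c, d = float(table.n_b_only), float(table.n_neither)
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise ValueError("degenerate margins: an expected cell is 0")
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(sps.chi2.sf(chi2, df=1))
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return float(chi2), p, odds


@dataclass
class PairingResult:
    """Promoter-RCA to downregulated-gene pairs within a distance cap."""

    pairs: pd.DataFrame  # columns: prca_index, prca_name, gene_id, distance_bp
    n_unique_genes: int
    n_unique_prcas: int

    def write_tsv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


def pair_prca_with_downregulated(
    p_rcas: IntervalSet, n_rna: IntervalSet, max_dist_bp: int = 5000
) -> PairingResult:
    """All (p-RCA, downregulated gene region) pairs with edge distance
    <= max_dist_bp (closed bound).

    ``n_rna`` intervals must be named by gene id.  A p-RCA may pair with
    several genes and vice versa; unique counts are reported alongside
    the pair list.
    """
    hits = pairs_within(p_rcas, n_rna, max_dist_bp)
    names = p_rcas.df["name"].to_numpy(object)
    gene_ids = n_rna.df["name"].to_numpy(object)
    pairs = pd.DataFrame(
        {
            "prca_index": hits["a_index"].to_numpy(np.int64),
            "prca_name": names[hits["a_index"].to_numpy(np.int64)],
            "gene_id": gene_ids[hits["b_index"].to_numpy(np.int64)],
            "distance_bp": hits["gap_bp"].to_numpy(np.int64),
        }
    )
    return PairingResult(
        pairs, int(pairs["gene_id"].nunique()), int(pairs["prca_index"].nunique())
    )
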