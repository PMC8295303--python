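"""Seeded generator of all pipeline inputs with known ground truth.

The generator plants the statistical structure the analysis assumes and
records every planted association in a manifest, so each pipeline stage
can be verified end-to-end without the original sequencing data:

* a mouse-like genome (chr1..chr19, chrX) partitioned into
  non-overlapping TADs;
* TAD-level co-occurrence of promoter RCAs (set A) and intergenic RCAs
  (set B) with a tunable odds ratio;
* downregulated genes whose promoters carry the paired p-RCAs (the
  p-RCA:n-RNA-seq configuration, <= 5 kbp apart);
* Hi-C contacts anchored at paired p-RCAs, separations lognormal with
  mean ~324 kbp, the distal anchor neighbored by an i-RCA;
* H-sites spatially clustered around i-RCAs (half-normal edge gaps,
  mean ~0.8 * sd), a subset embedded in knockout-only H3K9me3 peaks
  (HH-sites) and flanked by T3-TR peaks within 10 kbp;
* a signal table whose per-class count rates reproduce the intended
  five-way RCA classification, with CTCF/Rad21 peaks planting the
  CAC/CNC insulator layout.

Feature placement is rejection-sampled against a per-chromosome
occupancy index with per-feature margins, so unintended proximities
(extra pairings, extra area-1 hits, extra embedded sites) cannot occur
and discrete recovery tests can demand exact agreement.  A fixed seed
reproduces every output byte-identically.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_right
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, write_gene_tsv
from .genome import Genome
from .intervals import IntervalSet
from .stats import CooccurrenceTable, chi_square_2x2

# geometry constants (bp)
_GENE_MIN, _GENE_MAX = 8_000, 40_000
_PRCA_W = 300          # promoter RCA width
_IRCA_W = 1_500        # intergenic RCA width
_GRCA_W = 500          # genic (exon/intron) RCA width
_SHARED_W = 600        # shared open-chromatin peak width
_ANCHOR_W = 1_000      # Hi-C anchor width
_MARGIN = 3_000        # default half-gap between claimed features
_EXON_W = 2_000

PAIRED_CLASS_SPLIT = {"promoter": 100, "enhancer": 20}  # insulators fill the rest of 154
CLASS_PROBS = {
    "promoter": 0.30, "enhancer": 0.30, "weak_promoter": 0.15,
    "insulator": 0.15, "weak_insulator": 0.10,
}
# per-class (k4me3, k4me1, atac) count rates; promoter/enhancer symmetric so
# track totals balance and TPM ratios track raw count ratios
CLASS_RATES = {
    "promoter": (20.0, 1.0, 10.0),
    "enhancer": (1.0, 20.0, 10.0),
    "weak_promoter": (10.0, 10.0, 10.0),
    "insulator": (0.0, 0.0, 10.0),
    "weak_insulator": (0.0, 0.0, 0.0),  # signal-free: the ATAC==K4me1 tie rule applies
}


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic genome.

    Defaults mirror the analysis conditions: 1,508 H-sites, 1,551
    promoter / 2,426 intergenic RCAs, 1,363 downregulated of 3,000
    genes, 154 p-RCA:gene pairings over 146 genes, 86 HH-sites, a
    30/4 CAC/CNC insulator layout and Hi-C separations averaging
    ~324 kbp.
    """

    seed: int = 0
    n_chroms: int = 20
    chrom_length: int = 60_000_000          # base length; per-chrom 1.5x..0.5x
    mean_tad_size: int = 700_000
    n_tads_with_pairing: int = 146          # one paired gene per pairing TAD
    cooccurrence_odds_ratio: float = 9.6
    prca_tad_frac: float = 0.133            # P(TAD carries p-RCAs)
    irca_tad_frac: float = 0.191            # P(TAD carries i-RCAs)
    n_prcas: int = 1551
    n_ircas: int = 2426
    n_other_rcas: int = 1000                # exon/intron RCAs
    n_hsites: int = 1508
    hsite_clustering_sd: float = 27_500.0   # half-normal edge gap, mean ~22 kbp
    n_genes: int = 3000
    frac_downregulated: float = 0.4543      # -> 1363 genes
    frac_upregulated: float = 0.054         # -> 162 genes
    n_paired_genes: int = 146
    n_paired_prcas: int = 154
    n_hic_genes: int = 120                  # paired genes with planted contacts
    n_contacts: int = 500
    contact_sep_lognormal: tuple[float, float] = (12.366, 0.8)  # mean ~324 kbp
    n_hh_sites: int = 86
    n_t3_occasions: int = 69
    n_utr_occasions: int = 7
    n_cac: int = 30
    n_cnc: int = 4
    n_demeth_overlap: int = 25
    n_demeth_noise: int = 3000
    n_shared_peaks: int = 3000
    n_k9_noise_peaks: int = 400
    n_tr_noise_peaks: int = 300
    noise_frac_hsites: float = 0.15         # H-sites placed uniformly, no parent
    noise_frac_contacts: float = 0.5        # contacts with no planted association
    signal_depth: float = 60.0              # counts per (rate * kb)

    def __post_init__(self) -> None:
        if self.n_paired_prcas < self.n_paired_genes:
            raise ValueError("n_paired_prcas must be >= n_paired_genes")
        if self.n_hic_genes > self.n_paired_genes:
            raise ValueError("n_hic_genes cannot exceed n_paired_genes")
        if self.n_cac + self.n_cnc > self.n_paired_prcas:
            raise ValueError("CAC+CNC insulators cannot exceed paired p-RCAs")
        if self.cooccurrence_odds_ratio <= 0:
            raise ValueError("odds ratio must be > 0")
        if not (0 <= self.noise_frac_hsites <= 1 and 0 <= self.noise_frac_contacts <= 1):
            raise ValueError("noise fractions must be in [0, 1]")


@dataclass
class GroundTruthManifest:
    """Planted associations, sufficient to predict every recovery test."""

    data: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruthManifest":
        with open(path) as fh:
            return cls(json.load(fh))

    def __getitem__(self, key: str):
        return self.data[key]


class _Occupancy:
    """Disjoint claimed spans (expanded by per-claim margins) per chromosome."""

    def __init__(self) -> None:
        self._starts: list[int] = []
        self._ends: list[int] = []

    def try_claim(self, start: int, end: int, margin: int) -> bool:
        s, e = start - margin, end + margin
        i = bisect_right(self._starts, s)
        if i > 0 and self._ends[i - 1] > s:
            return False
        if i < len(self._starts) and self._starts[i] < e:
            return False
        self._starts.insert(i, s)
        self._ends.insert(i, e)
        return True


def cooccurrence_probs(p_a: float, p_b: float, odds_ratio: float) -> np.ndarray:
    """Joint (both, A only, B only, neither) cell probabilities with the
    given margins and odds ratio."""
    if not (0 < p_a < 1 and 0 < p_b < 1):
        raise ValueError("margins must be in (0, 1)")
    if odds_ratio == 1.0:
        p11 = p_a * p_b
    else:
        k = odds_ratio - 1.0
        b = 1.0 + (p_a + p_b) * k
        p11 = (b - math.sqrt(b * b - 4.0 * odds_ratio * k * p_a * p_b)) / (2.0 * k)
    cells = np.array([p11, p_a - p11, p_b - p11, 1.0 - p_a - p_b + p11])
    if (cells < -1e-12).any():
        raise ValueError("margins and odds ratio are inconsistent")
    return np.clip(cells, 0.0, 1.0) / cells.sum()


def _genome(cfg: SimConfig) -> Genome:
    names = [f"chr{i}" for i in range(1, cfg.n_chroms)] + ["chrX"]
    n = cfg.n_chroms
    lengths = [int(round(cfg.chrom_length * (1.5 - i / max(n - 1, 1)))) for i in range(n)]
    return Genome(list(zip(names, lengths)))


def _partition_tads(rng: np.random.Generator, genome: Genome, mean_size: int) -> pd.DataFrame:
    rows = []
    for chrom in genome.names:
        pos = 0
        length = genome[chrom]
        while pos < length:
            size = int(rng.uniform(0.5, 1.5) * mean_size)
            end = min(pos + size, length)
            if length - end < mean_size // 7:  # fold a tiny remainder into the last TAD
                end = length
            rows.append((chrom, pos, end))
            pos = end
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"tad_{i:05d}" for i in range(len(df))]
    return df


def generate(cfg: SimConfig, outdir: str | Path) -> tuple[dict[str, Path], GroundTruthManifest]:
    """Write every pipeline input plus the ground-truth manifest to *outdir*.

    Returns (file-path map, manifest).  Raises when the requested feature
    load cannot be packed into the configured genome.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genome = _genome(cfg)
    occ = {c: _Occupancy() for c in genome.names}
    chrom_names = np.array(genome.names)
    chrom_lengths = np.array([genome[c] for c in genome.names], dtype=float)
    chrom_weights = chrom_lengths / chrom_lengths.sum()

    tads = _partition_tads(rng, genome, cfg.mean_tad_size)

    # --- TAD roles -----------------------------------------------------
    big = tads.index[(tads["end"] - tads["start"]) >= 500_000].to_numpy()
    if len(big) < cfg.n_tads_with_pairing:
        raise ValueError(
            f"only {len(big)} TADs >= 500 kbp for {cfg.n_tads_with_pairing} pairings; "
            "increase chrom_length or mean_tad_size"
        )
    pairing_tads = rng.choice(big, size=cfg.n_tads_with_pairing, replace=False)
    rest = np.setdiff1d(tads.index.to_numpy(), pairing_tads)
    probs = cooccurrence_probs(cfg.prca_tad_frac, cfg.irca_tad_frac, cfg.cooccurrence_odds_ratio)
    cats = rng.choice(4, size=len(rest), p=probs)  # 0 both, 1 A only, 2 B only, 3 neither
    tad_label = {}
    for t in pairing_tads:
        tad_label[tads.at[t, "name"]] = "pairing"
    for t, c in zip(rest, cats):
        tad_label[tads.at[t, "name"]] = ("both", "a_only", "b_only", "neither")[c]

    # --- gene census ---------------------------------------------------
    n_down = int(round(cfg.frac_downregulated * cfg.n_genes))
    n_up = int(round(cfg.frac_upregulated * cfg.n_genes))
    n_hosts = cfg.n_prcas - cfg.n_paired_prcas
    n_normal = cfg.n_genes - n_down - n_up
    if n_hosts > n_normal:
        raise ValueError(
            f"{n_hosts} host genes needed for non-paired p-RCAs but only "
            f"{n_normal} non-differential genes available; raise n_genes"
        )
    if cfg.n_paired_genes > n_down:
        raise ValueError("n_paired_genes exceeds the downregulated gene count")

    gene_counter = 0

    def next_gene_id() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"gene{gene_counter:04d}"

    genes: list[GeneModel] = []
    gene_role: dict[str, str] = {}

    def make_gene(chrom: str, gs: int, glen: int, strand: str, role: str) -> GeneModel:
        gid = next_gene_id()
        exons = ((gs, gs + _EXON_W), (gs + glen - _EXON_W, gs + glen))
        g = GeneModel(gid, chrom, strand, gs, gs + glen, exons)
        genes.append(g)
        gene_role[gid] = role
        return g

    def prca_coords(g: GeneModel, slot: int) -> tuple[int, int]:
        # slot 0: upstream of the TSS; slot 1: just inside the body
        tss = g.tss
        if g.strand == "+":
            return (tss - 350, tss - 50) if slot == 0 else (tss + 50, tss + 350)
        return (tss + 51, tss + 351) if slot == 0 else (tss - 350, tss - 50)

    rca_rows: list[tuple] = []     # (chrom, start, end, name) for all RCA peaks
    planted_class: dict[str, str] = {}
    prca_of_gene: dict[str, list[str]] = {}
    prca_counter = 0

    def add_prca(g: GeneModel, slot: int) -> str:
        nonlocal prca_counter
        prca_counter += 1
        name = f"pRCA_{prca_counter:05d}"
        s, e = prca_coords(g, slot)
        rca_rows.append((g.chrom, s, e, name))
        prca_of_gene.setdefault(g.gene_id, []).append(name)
        return name

    # --- paired genes in pairing TADs ---------------------------------
    n_double = cfg.n_paired_prcas - cfg.n_paired_genes
    paired_gene_ids: list[str] = []
    anchor1_of_gene: dict[str, tuple[int, int]] = {}
    pairing_tad_of_gene: dict[str, str] = {}
    gene_tads = [pairing_tads[i % len(pairing_tads)] for i in range(cfg.n_paired_genes)]
    for i, t in enumerate(gene_tads):
        chrom = tads.at[t, "chrom"]
        ts, te = int(tads.at[t, "start"]), int(tads.at[t, "end"])
        glen = int(rng.integers(_GENE_MIN, _GENE_MAX))
        placed = False
        for _ in range(200):
            gs = int(rng.integers(max(ts + 1_000, 1_000), max(te - glen - 1_000, ts + 2_000)))
            lo, hi = gs - 800, gs + glen + 800  # room for promoter RCA + anchor
            if 0 < lo and hi < genome[chrom] and occ[chrom].try_claim(lo, hi, _MARGIN):
                placed = True
                break
        if not placed:
            raise ValueError("could not pack paired gene; increase chrom_length")
        g = make_gene(chrom, gs, glen, "+" if rng.random() < 0.5 else "-", "paired_down")
        paired_gene_ids.append(g.gene_id)
        pairing_tad_of_gene[g.gene_id] = tads.at[t, "name"]
        add_prca(g, 0)
        if i < n_double:
            add_prca(g, 1)
        # Hi-C anchor-1 centered on the upstream p-RCA
        s0, e0 = prca_coords(g, 0)
        mid = (s0 + e0) // 2
        anchor1_of_gene[g.gene_id] = (mid - _ANCHOR_W // 2, mid + _ANCHOR_W // 2)

    # planted chromatin classes for the paired p-RCAs
    paired_prca_names = [n for gid in paired_gene_ids for n in prca_of_gene[gid]]
    n_insul = cfg.n_cac + cfg.n_cnc
    class_seq = (
        ["insulator"] * n_insul
        + ["promoter"] * PAIRED_CLASS_SPLIT["promoter"]
        + ["enhancer"] * PAIRED_CLASS_SPLIT["enhancer"]
    )
    if len(class_seq) < len(paired_prca_names):
        class_seq += ["promoter"] * (len(paired_prca_names) - len(class_seq))
    class_seq = class_seq[: len(paired_prca_names)]
    perm = rng.permutation(len(paired_prca_names))
    for j, name in enumerate(paired_prca_names):
        planted_class[name] = class_seq[perm[j]]
    paired_insulators = [n for n in paired_prca_names if planted_class[n] == "insulator"]
    cac_names = paired_insulators[: cfg.n_cac]
    cnc_names = paired_insulators[cfg.n_cac:]

    # --- host genes with non-paired p-RCAs in A-labeled TADs -----------
    a_tads = [t for t in rest[cats <= 1]]  # both or a_only
    if not a_tads:
        raise ValueError("no TADs assigned to carry p-RCAs; raise prca_tad_frac")
    host_positions = [a_tads[i % len(a_tads)] for i in range(n_hosts)]
    for t in host_positions:
        chrom = tads.at[t, "chrom"]
        ts, te = int(tads.at[t, "start"]), int(tads.at[t, "end"])
        glen = int(rng.integers(_GENE_MIN, _GENE_MAX))
        placed = False
        for _ in range(80):
            span = te - ts - glen - 2_000
            if span <= 0:
                break
            gs = int(rng.integers(ts + 1_000, ts + 1_000 + span))
            lo, hi = gs - 800, gs + glen + 800
            if 0 < lo and hi < genome[chrom] and occ[chrom].try_claim(lo, hi, _MARGIN):
                placed = True
                break
        if not placed:  # fall back to anywhere on a random chromosome
            g = _place_gene_anywhere(rng, genome, occ, chrom_names, chrom_weights, glen)
            if g is None:
                raise ValueError("could not pack host gene; increase chrom_length")
            chrom, gs = g
        gm = make_gene(chrom, gs, glen, "+" if rng.random() < 0.5 else "-", "host")
        add_prca(gm, 0)

    # --- remaining genes: other downregulated, upregulated, filler -----
    roles = (
        ["other_down"] * (n_down - cfg.n_paired_genes)
        + ["up"] * n_up
        + ["normal"] * (n_normal - n_hosts)
    )
    for role in roles:
        glen = int(rng.integers(_GENE_MIN, _GENE_MAX))
        g = _place_gene_anywhere(rng, genome, occ, chrom_names, chrom_weights, glen)
        if g is None:
            raise ValueError("could not pack gene; increase chrom_length or lower n_genes")
        chrom, gs = g
        make_gene(chrom, gs, glen, "+" if rng.random() < 0.5 else "-", role)

    # --- genic (exon/intron) RCAs inside non-paired gene bodies --------
    eligible = [g for g in genes if gene_role[g.gene_id] in ("host", "normal", "up")]
    picks = rng.choice(len(eligible), size=min(cfg.n_other_rcas, len(eligible)), replace=False)
    for j, k in enumerate(picks):
        g = eligible[int(k)]
        if rng.random() < 0.5:  # intron
            mid = (g.start + g.end) // 2
            s, e = mid - _GRCA_W // 2, mid + _GRCA_W // 2
        else:  # inside the terminal exon
            s, e = g.end - 1_500, g.end - 1_500 + _GRCA_W
        rca_rows.append((g.chrom, s, e, f"gRCA_{j + 1:05d}"))

    # --- intergenic RCAs -----------------------------------------------
    b_tads = [t for t in rest[(cats == 0) | (cats == 2)]]  # both or b_only
    if not b_tads:
        raise ValueError("no TADs assigned to carry i-RCAs; raise irca_tad_frac")
    irca_rows: list[tuple] = []
    irca_counter = 0

    def add_irca(chrom: str, s: int) -> str | None:
        nonlocal irca_counter
        if not (0 < s and s + _IRCA_W < genome[chrom]):
            return None
        if not occ[chrom].try_claim(s, s + _IRCA_W, 500):
            return None
        irca_counter += 1
        name = f"iRCA_{irca_counter:05d}"
        irca_rows.append((chrom, s, s + _IRCA_W, name))
        return name

    n_area2_ircas = int(round(cfg.n_contacts * (1 - cfg.noise_frac_contacts)))
    n_base_ircas = max(cfg.n_ircas - n_area2_ircas, 0)
    bpos = [b_tads[i % len(b_tads)] for i in range(n_base_ircas)]
    for t in bpos:
        chrom = tads.at[t, "chrom"]
        ts, te = int(tads.at[t, "start"]), int(tads.at[t, "end"])
        for _ in range(60):
            s = int(rng.integers(ts, max(te - _IRCA_W, ts + 1)))
            if add_irca(chrom, s):
                break

    # --- Hi-C contacts --------------------------------------------------
    mu, sigma = cfg.contact_sep_lognormal
    hic_gene_ids = list(rng.choice(paired_gene_ids, size=cfg.n_hic_genes, replace=False))
    n_planted = n_area2_ircas
    per_gene = np.zeros(cfg.n_hic_genes, dtype=int)
    per_gene += n_planted // cfg.n_hic_genes
    per_gene[: n_planted % cfg.n_hic_genes] += 1
    contact_rows: list[tuple] = []
    contact_truth: list[dict] = []
    contact_counter = 0
    for gid, k in zip(hic_gene_ids, per_gene):
        chrom = next(g.chrom for g in genes if g.gene_id == gid)
        a1s, a1e = anchor1_of_gene[gid]
        mid1 = (a1s + a1e) // 2
        for _ in range(int(k)):
            placed = False
            for _try in range(200):
                sep = int(np.clip(rng.lognormal(mu, sigma), 20_000, 2_400_000))
                side = 1 if rng.random() < 0.5 else -1
                for direction in (side, -side):
                    mid2 = mid1 + direction * sep
                    s2, e2 = mid2 - _ANCHOR_W // 2, mid2 + _ANCHOR_W // 2
                    if not (0 < s2 and e2 < genome[chrom]):
                        continue
                    if not occ[chrom].try_claim(s2, e2, _MARGIN):
                        continue
                    # plant an i-RCA within < 50 kbp of the area-2
                    irca_name = None
                    for _i in range(60):
                        gap = int(rng.uniform(4_000, 40_000))
                        iside = 1 if rng.random() < 0.5 else -1
                        istart = e2 + gap if iside > 0 else s2 - gap - _IRCA_W
                        irca_name = add_irca(chrom, istart)
                        if irca_name:
                            break
                    contact_counter += 1
                    cid = f"hic_{contact_counter:05d}"
                    contact_rows.append(
                        (chrom, a1s, a1e, chrom, s2, e2, cid, round(float(rng.uniform(2, 10)), 3))
                    )
                    contact_truth.append(
                        {
                            "contact": cid,
                            "gene": gid,
                            "prca": prca_of_gene[gid][0],
                            "irca": irca_name,
                            "separation": abs(mid2 - mid1),
                        }
                    )
                    placed = True
                    break
                if placed:
                    break
            if not placed:
                raise ValueError("could not place Hi-C contact; increase chrom_length")

    n_noise_contacts = cfg.n_contacts - n_planted
    for _ in range(n_noise_contacts):
        for _try in range(300):
            ci = rng.choice(len(chrom_names), p=chrom_weights)
            chrom = str(chrom_names[ci])
            sep = int(np.clip(rng.lognormal(mu, sigma), 20_000, 2_400_000))
            m1 = int(rng.integers(_ANCHOR_W, genome[chrom] - sep - _ANCHOR_W))
            s1, e1 = m1 - _ANCHOR_W // 2, m1 + _ANCHOR_W // 2
            s2, e2 = s1 + sep, e1 + sep
            if occ[chrom].try_claim(s1, e1, _MARGIN):
                if occ[chrom].try_claim(s2, e2, _MARGIN):
                    contact_counter += 1
                    contact_rows.append(
                        (chrom, s1, e1, chrom, s2, e2, f"hic_{contact_counter:05d}",
                         round(float(rng.uniform(2, 10)), 3))
                    )
                    break
        else:
            raise ValueError("could not place noise contact")

    # --- H-sites ---------------------------------------------------------
    n_noise_h = int(round(cfg.n_hsites * cfg.noise_frac_hsites))
    n_clustered = cfg.n_hsites - n_noise_h
    irca_arr = pd.DataFrame(irca_rows, columns=["chrom", "start", "end", "name"])
    hsite_rows: list[tuple] = []
    hsite_truth: dict[str, dict] = {}
    parents = rng.integers(0, len(irca_arr), size=n_clustered)
    for j in range(n_clustered):
        prow = irca_arr.iloc[int(parents[j])]
        name = f"H{j + 1:04d}"
        placed = False
        for _ in range(40):
            gap = max(int(abs(rng.normal(0.0, cfg.hsite_clustering_sd))), 100)
            side = 1 if rng.random() < 0.5 else -1
            s = int(prow["end"]) + gap if side > 0 else int(prow["start"]) - gap - 2
            if 0 < s and s + 2 < genome[prow["chrom"]] and occ[prow["chrom"]].try_claim(s, s + 2, 50):
                hsite_rows.append((prow["chrom"], s, s + 2, name))
                hsite_truth[name] = {"parent": prow["name"], "gap": gap}
                placed = True
                break
        if not placed:
            # fall back to an unclustered site rather than under-filling
            pos = _uniform_site(rng, genome, occ, chrom_names, chrom_weights)
            hsite_rows.append((pos[0], pos[1], pos[1] + 2, name))
            hsite_truth[name] = {"parent": None, "gap": None}
    for j in range(n_noise_h):
        name = f"H{n_clustered + j + 1:04d}"
        pos = _uniform_site(rng, genome, occ, chrom_names, chrom_weights)
        hsite_rows.append((pos[0], pos[1], pos[1] + 2, name))
        hsite_truth[name] = {"parent": None, "gap": None}

    # --- HH-sites: KO-only H3K9me3 peaks covering isolated H-sites ------
    hs_df = pd.DataFrame(hsite_rows, columns=["chrom", "start", "end", "name"])
    hh_names = _select_isolated(hs_df, rng, cfg.n_hh_sites, iso_bp=1_200, pair_bp=21_000)
    if len(hh_names) < cfg.n_hh_sites:
        raise ValueError(
            f"only {len(hh_names)} isolated H-sites for {cfg.n_hh_sites} HH-sites; "
            "lower n_hh_sites or raise chrom_length"
        )
    k9_rows: list[tuple] = []
    hh_set = hs_df.set_index("name")
    for j, name in enumerate(hh_names):
        row = hh_set.loc[name]
        k9_rows.append(
            (row["chrom"], int(row["start"]) - 500, int(row["end"]) + 500,
             f"k9_{j + 1:04d}", round(float(rng.uniform(2.5, 8.0)), 3))
        )
    # noise K9 peaks, never containing an H-site; half fail the score filter
    h_by_chrom = {c: g[["start", "end"]].to_numpy() for c, g in hs_df.groupby("chrom")}
    for j in range(cfg.n_k9_noise_peaks):
        chrom, s = _uniform_site(rng, genome, occ, chrom_names, chrom_weights, claim=False,
                                 width=1_000, clear_of=h_by_chrom, clear_bp=700)
        score = rng.uniform(0.5, 2.0) if j % 2 == 0 else rng.uniform(2.01, 8.0)
        k9_rows.append((chrom, s, s + 1_000, f"k9n_{j + 1:04d}", round(float(score), 3)))

    # --- TR peaks flanking HH-sites --------------------------------------
    t3_rows = _flanking_peaks(rng, genome, hh_set, hh_names, cfg.n_t3_occasions, "t3tr")
    utr_rows = _flanking_peaks(rng, genome, hh_set, hh_names, cfg.n_utr_occasions, "utr")
    hh_arr = {c: g.loc[g.index.intersection(hh_names)][["start", "end"]].to_numpy()
              for c, g in hs_df.set_index("name").groupby("chrom")}
    for rows, tag in ((t3_rows, "t3n"), (utr_rows, "utrn")):
        for j in range(cfg.n_tr_noise_peaks):
            chrom, s = _uniform_site(rng, genome, occ, chrom_names, chrom_weights, claim=False,
                                     width=400, clear_of=hh_arr, clear_bp=12_000)
            rows.append((chrom, s, s + 400, f"{tag}_{j + 1:04d}"))

    # --- normally-demethylated sites -------------------------------------
    demeth_rows: list[tuple] = []
    overlap_pick = rng.choice(len(hs_df), size=cfg.n_demeth_overlap, replace=False)
    for j, k in enumerate(sorted(int(x) for x in overlap_pick)):
        r = hs_df.iloc[k]
        demeth_rows.append((r["chrom"], int(r["start"]), int(r["end"]), f"dm_{j + 1:04d}"))
    demeth_overlap_names = [hs_df.iloc[int(k)]["name"] for k in sorted(int(x) for x in overlap_pick)]
    for j in range(cfg.n_demeth_noise):
        chrom, s = _uniform_site(rng, genome, occ, chrom_names, chrom_weights, claim=False,
                                 width=2, clear_of=h_by_chrom, clear_bp=1_000)
        demeth_rows.append((chrom, s, s + 2, f"dmn_{j + 1:04d}"))

    # --- shared open-chromatin peaks (present in both conditions) -------
    shared_rows: list[tuple] = []
    for j in range(cfg.n_shared_peaks):
        placed = False
        for _ in range(100):
            ci = rng.choice(len(chrom_names), p=chrom_weights)
            chrom = str(chrom_names[ci])
            s = int(rng.integers(1_000, genome[chrom] - _SHARED_W - 1_000))
            if occ[chrom].try_claim(s, s + _SHARED_W, _MARGIN):
                shared_rows.append((chrom, s, s + _SHARED_W, f"open_{j + 1:05d}"))
                placed = True
                break
        if not placed:
            raise ValueError("could not place shared peak; genome too crowded")

    # --- signal table and CTCF/Rad21 peaks -------------------------------
    all_rca = pd.DataFrame(rca_rows + irca_rows, columns=["chrom", "start", "end", "name"])
    classes = []
    class_names = list(CLASS_PROBS)
    class_p = np.array([CLASS_PROBS[c] for c in class_names])
    draw = rng.choice(len(class_names), size=len(all_rca), p=class_p)
    for name, d in zip(all_rca["name"], draw):
        cls = planted_class.get(name, class_names[d])
        planted_class[name] = cls
        classes.append(cls)
    lengths = (all_rca["end"] - all_rca["start"]).to_numpy()
    counts = {t: np.zeros(len(all_rca), dtype=np.int64) for t in ("k4me3", "k4me1", "atac")}
    for i, cls in enumerate(classes):
        r3, r1, ra = CLASS_RATES[cls]
        lkb = lengths[i] / 1000.0
        counts["k4me3"][i] = rng.poisson(r3 * lkb * cfg.signal_depth) if r3 else 0
        counts["k4me1"][i] = rng.poisson(r1 * lkb * cfg.signal_depth) if r1 else 0
        counts["atac"][i] = rng.poisson(ra * lkb * cfg.signal_depth) if ra else 0
        if cls == "insulator" and counts["atac"][i] == 0:
            counts["atac"][i] = 1  # the insulator rule needs ATAC > H3K4me1
    signal = pd.DataFrame(
        {
            "region_id": all_rca["name"],
            "chrom": all_rca["chrom"],
            "start": all_rca["start"],
            "end": all_rca["end"],
            "length_bp": lengths,
            "count_atac": counts["atac"],
            "count_k4me1": counts["k4me1"],
            "count_k4me3": counts["k4me3"],
        }
    )

    rca_by_name = all_rca.set_index("name")
    ctcf_rows: list[tuple] = []
    rad_rows: list[tuple] = []
    for j, name in enumerate(cac_names):
        r = rca_by_name.loc[name]
        ctcf_rows.append((r["chrom"], int(r["start"]) - 50, int(r["end"]) + 50, f"ctcf_{j + 1:04d}"))
    for j, name in enumerate(cac_names + cnc_names):
        r = rca_by_name.loc[name]
        rad_rows.append((r["chrom"], int(r["start"]) - 80, int(r["end"]) + 80, f"rad_{j + 1:04d}"))
    # background CTCF/Rad21 peaks away from every RCA region
    rca_arr = {c: g[["start", "end"]].to_numpy() for c, g in all_rca.groupby("chrom")}
    for j in range(300):
        chrom, s = _uniform_site(rng, genome, occ, chrom_names, chrom_weights, claim=False,
                                 width=400, clear_of=rca_arr, clear_bp=2_000)
        ctcf_rows.append((chrom, s, s + 400, f"ctcfn_{j + 1:04d}"))
        chrom, s = _uniform_site(rng, genome, occ, chrom_names, chrom_weights, claim=False,
                                 width=400, clear_of=rca_arr, clear_bp=2_000)
        rad_rows.append((chrom, s, s + 400, f"radn_{j + 1:04d}"))

    # --- Pol-II promoter peaks ------------------------------------------
    pol2_rows = []
    for g in genes:
        s = max(g.tss - 250, 0)
        pol2_rows.append((g.chrom, s, min(g.tss + 250, genome[g.chrom]), f"pol2_{g.gene_id}"))

    # --- differential expression ----------------------------------------
    de_rows = []
    for g in genes:
        role = gene_role[g.gene_id]
        if role in ("paired_down", "other_down"):
            fc = -float(1.3 + rng.exponential(0.8))
            p = float(rng.uniform(1e-6, 0.01))
        elif role == "up":
            fc = float(1.3 + rng.exponential(0.8))
            p = float(rng.uniform(1e-6, 0.01))
        else:
            fc = float(rng.uniform(1.0, 1.6)) * (1 if rng.random() < 0.5 else -1)
            p = float(rng.uniform(0.1, 1.0))  # never significant
        de_rows.append((g.gene_id, round(fc, 4), round(p, 8)))

    # --- write files -----------------------------------------------------
    paths: dict[str, Path] = {}

    def _bed(key: str, rows: list[tuple], cols: list[str]) -> None:
        df = pd.DataFrame(rows, columns=cols)
        path = outdir / f"{key}.bed"
        IntervalSet(df, genome, validate=True).write_bed(path)
        paths[key] = path

    paths["genome"] = outdir / "genome.tsv"
    genome.write_tsv(paths["genome"])
    _bed("tads", list(zip(tads["chrom"], tads["start"], tads["end"], tads["name"])),
         ["chrom", "start", "end", "name"])
    shared_named = [(c, s, e, n) for c, s, e, n in shared_rows]
    control_rows = shared_named + [(c, s, e, n) for c, s, e, n in rca_rows] + [
        (c, s, e, n) for c, s, e, n in irca_rows
    ]
    _bed("atac_control", control_rows, ["chrom", "start", "end", "name"])
    _bed("atac_ko", shared_named, ["chrom", "start", "end", "name"])
    _bed("hsites", hsite_rows, ["chrom", "start", "end", "name"])
    _bed("k9_ko_unique", [(c, s, e, n, sc) for c, s, e, n, sc in k9_rows],
         ["chrom", "start", "end", "name", "score"])
    _bed("t3_tr", t3_rows, ["chrom", "start", "end", "name"])
    _bed("utr", utr_rows, ["chrom", "start", "end", "name"])
    _bed("ctcf", ctcf_rows, ["chrom", "start", "end", "name"])
    _bed("rad21", rad_rows, ["chrom", "start", "end", "name"])
    _bed("pol2", pol2_rows, ["chrom", "start", "end", "name"])
    _bed("demethylated", demeth_rows, ["chrom", "start", "end", "name"])

    paths["genes"] = outdir / "genes.tsv"
    write_gene_tsv(genes, paths["genes"])
    paths["de"] = outdir / "de.tsv"
    with open(paths["de"], "w") as fh:
        fh.write("gene_id\tfold_change\tp_value\n")
        for gid, fc, p in de_rows:
            fh.write(f"{gid}\t{fc:g}\t{p:g}\n")
    paths["signal"] = outdir / "signal.tsv"
    signal.to_csv(paths["signal"], sep="\t", index=False)
    paths["contacts"] = outdir / "contacts.bedpe"
    with open(paths["contacts"], "w") as fh:
        for c1, s1, e1, c2, s2, e2, name, score in contact_rows:
            fh.write(f"{c1}\t{s1}\t{e1}\t{c2}\t{s2}\t{e2}\t{name}\t{score:g}\n")

    manifest = GroundTruthManifest(
        {
            "config": asdict(cfg),
            "counts": {
                "genes": len(genes),
                "down_genes": sum(1 for r in gene_role.values() if r.endswith("down")),
                "up_genes": sum(1 for r in gene_role.values() if r == "up"),
                "prcas": prca_counter,
                "ircas": irca_counter,
                "other_rcas": len(picks),
                "hsites": len(hsite_rows),
                "contacts": len(contact_rows),
                "tads": len(tads),
            },
            "tad_labels": tad_label,
            "paired": [
                {"gene": gid, "prcas": prca_of_gene[gid], "tad": pairing_tad_of_gene[gid]}
                for gid in paired_gene_ids
            ],
            "hic": contact_truth,
            "hic_genes": hic_gene_ids,
            "hh_sites": list(hh_names),
            "cac": cac_names,
            "cnc": cnc_names,
            "demethylated_overlap": demeth_overlap_names,
            "hsites": hsite_truth,
            "planted_classes": planted_class,
            "down_gene_ids": [g for g, r in gene_role.items() if r.endswith("down")],
            "flanking": {
                "t3_occasions": cfg.n_t3_occasions,
                "utr_occasions": cfg.n_utr_occasions,
            },
            "target_mean_separation_bp": float(math.exp(mu + sigma**2 / 2)),
            "expected_hsite_gap_bp": float(cfg.hsite_clustering_sd * math.sqrt(2 / math.pi)),
        }
    )
    paths["manifest"] = outdir / "manifest.json"
    manifest.save(paths["manifest"])
    return paths, manifest


def _place_gene_anywhere(rng, genome, occ, chrom_names, chrom_weights, glen):
    for _ in range(200):
        ci = rng.choice(len(chrom_names), p=chrom_weights)
        chrom = str(chrom_names[ci])
        s = int(rng.integers(1_000, genome[chrom] - glen - 1_000))
        if occ[chrom].try_claim(s - 800, s + glen + 800, _MARGIN):
            return chrom, s
    return None


def _uniform_site(rng, genome, occ, chrom_names, chrom_weights, claim=True, width=2,
                  clear_of=None, clear_bp=0):
    """Uniform random placement, optionally claiming occupancy and/or
    keeping ``clear_bp`` away from per-chromosome coordinate arrays."""
    for _ in range(500):
        ci = rng.choice(len(chrom_names), p=chrom_weights)
        chrom = str(chrom_names[ci])
        s = int(rng.integers(1_000, genome[chrom] - width - 1_000))
        if clear_of is not None and chrom in clear_of and len(clear_of[chrom]):
            arr = clear_of[chrom]
            gap = np.maximum(np.maximum(arr[:, 0] - (s + width), s - arr[:, 1]), 0)
            if (gap <= clear_bp).any():  # gap 0 covers overlaps too
                continue
        if not claim or occ[chrom].try_claim(s, s + width, 50):
            return chrom, s
    raise ValueError("could not place feature; genome too crowded")


def _select_isolated(hs_df: pd.DataFrame, rng, n: int, iso_bp: int, pair_bp: int) -> list[str]:
    """Choose n H-sites each >= iso_bp from every other H-site and
    pairwise >= pair_bp apart (so flanking-peak windows cannot collide)."""
    chosen: list[str] = []
    chosen_pos: dict[str, list[int]] = {}
    order = rng.permutation(len(hs_df))
    starts_by_chrom = {c: g["start"].to_numpy() for c, g in hs_df.groupby("chrom")}
    for k in order:
        row = hs_df.iloc[int(k)]
        arr = starts_by_chrom[row["chrom"]]
        d = np.abs(arr - row["start"])
        if (d[d > 0] < iso_bp).any():
            continue
        prev = chosen_pos.get(row["chrom"], [])
        if any(abs(p - row["start"]) < pair_bp for p in prev):
            continue
        chosen.append(row["name"])
        chosen_pos.setdefault(row["chrom"], []).append(int(row["start"]))
        if len(chosen) == n:
            break
    return chosen


def _flanking_peaks(rng, genome: Genome, hh_set: pd.DataFrame, hh_names: list[str],
                    n_occasions: int, tag: str) -> list[tuple]:
    """One peak within 10 kbp of each of n_occasions distinct HH-sites."""
    if n_occasions > len(hh_names):
        raise ValueError("more flanking occasions than HH-sites")
    pick = rng.choice(len(hh_names), size=n_occasions, replace=False)
    rows = []
    for j, k in enumerate(sorted(int(x) for x in pick)):
        row = hh_set.loc[hh_names[k]]
        gap = int(rng.uniform(500, 9_000))
        side = 1 if rng.random() < 0.5 else -1
        s = int(row["end"]) + gap if side > 0 else int(row["start"]) - gap - 400
        s = min(max(s, 0), genome[row["chrom"]] - 400)  # clamp keeps it within 10 kbp
        rows.append((row["chrom"], s, s + 400, f"{tag}_{j + 1:04d}"))
    return rows


def null_resample(cfg: SimConfig, n_reps: int, seed: int | None = None) -> pd.DataFrame:
    """Calibration harness for the TAD co-occurrence test.

    Requires ``cooccurrence_odds_ratio == 1``.  Each replicate draws
    per-TAD feature presence independently at the configured margins,
    builds the 2x2 table and applies the chi-square test; the result
    frame carries one (chi2, p) row per replicate.  Use
    :func:`rejection_rate` for the empirical alpha.
    """
    if cfg.cooccurrence_odds_ratio != 1:
        raise ValueError("null_resample requires cooccurrence_odds_ratio == 1")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genome = _genome(cfg)
    n_tads = int(sum(genome[c] for c in genome.names) // cfg.mean_tad_size)
    probs = cooccurrence_probs(cfg.prca_tad_frac, cfg.irca_tad_frac, 1.0)
    cells = rng.multinomial(n_tads, probs, size=n_reps)
    out = []
    for row in cells:
        table = CooccurrenceTable(int(row[0]), int(row[1]), int(row[2]), int(row[3]))
        try:
            chi2, p, _ = chi_square_2x2(table)
        except ValueError:  # degenerate margins: cannot test, never a rejection
            chi2, p = float("nan"), 1.0
        out.append((chi2, p))
    return pd.DataFrame(out, columns=["chi2", "p"])


def rejection_rate(null_df: pd.DataFrame, alpha: float = 0.05) -> tuple[float, float]:
    """(empirical rejection rate at alpha, binomial standard error)."""
    n = len(null_df)
    rate = float((null_df["p"] < alpha).mean())
    se = math.sqrt(alpha * (1 - alpha) / n)
    return rate, se
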