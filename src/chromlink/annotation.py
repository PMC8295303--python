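"""Gene models, genomic-context annotation and downregulated-gene regions.

Intervals are labeled with exactly one of ``promoter``, ``exon``,
``intron``, ``intergenic`` with that precedence.  Two promoter windows
coexist in the analysis conventions: a 200 bp window around the TSS for
ATAC-peak annotation, and a 1 kb window for methylation-site/promoter
calls; both live in :class:`AnnotationConfig` and each pipeline stage
names which it uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Genome
from .intervals import GenomicInterval, IntervalSet, overlap_pairs, pairs_within

CATEGORIES = ("promoter", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: body span, strand-aware TSS and exon blocks."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: invalid gene body {self.start}-{self.end}")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon {s}-{e} outside gene body")

    @property
    def tss(self) -> int:
        """Transcription start site: body start on +, body end - 1 on -."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.gene_id, strand=self.strand)


@dataclass(frozen=True)
class DERecord:
    """One differential-expression test result.

    ``fold_change`` is signed: negative means lower in the knockout.
    Ratio-style values in (0, 1) are converted to -1/ratio on load.
    """

    gene_id: str
    fold_change: float
    p_value: float

    def __post_init__(self) -> None:
        if self.fold_change == 0:
            raise ValueError(f"{self.gene_id}: fold change must be nonzero")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"{self.gene_id}: p-value {self.p_value} outside (0, 1]")


@dataclass(frozen=True)
class AnnotationConfig:
    promoter_window_bp: int = 200       # ATAC-peak / RCA annotation window
    promoter_window_alt_bp: int = 1000  # methylation-site promoter calls

    def __post_init__(self) -> None:
        if self.promoter_window_bp <= 0 or self.promoter_window_alt_bp <= 0:
            raise ValueError("promoter windows must be > 0")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_gene_tsv(path: str | Path, genome: Genome) -> list[GeneModel]:
    """Read the simplified 6-column gene table.

    Columns: gene_id, chrom, strand, start, end, exon-blocks
    (comma-separated ``start-end`` spans, or ``.`` for none).
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            gene_id, chrom, strand = fields[0], fields[1], fields[2]
            if chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            start, end = int(fields[3]), int(fields[4])
            exons: tuple[tuple[int, int], ...] = ()
            if fields[5] != ".":
                exons = tuple(
                    (int(s), int(e))
                    for s, e in (block.split("-") for block in fields[5].split(","))
                )
            genes.append(GeneModel(gene_id, chrom, strand, start, end, exons))
    return genes


def write_gene_tsv(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\tstart\tend\texons\n")
        for g in genes:
            blocks = ",".join(f"{s}-{e}" for s, e in g.exons) if g.exons else "."
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}\t{blocks}\n")


def read_de_tsv(path: str | Path) -> list[DERecord]:
    """Read a (gene_id, fold_change, p_value) table; ratio fold changes in
    (0, 1) are converted to the signed convention (-1/ratio)."""
    records: list[DERecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            fc = float(fields[1])
            if 0 < fc < 1:
                fc = -1.0 / fc
            records.append(DERecord(fields[0], fc, float(fields[2])))
    return records


def write_de_tsv(records: list[DERecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfold_change\tp_value\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.fold_change:g}\t{r.p_value:g}\n")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _tss_set(genes: list[GeneModel], genome: Genome) -> IntervalSet:
    df = pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.tss for g in genes],
            "end": [g.tss + 1 for g in genes],
            "name": [g.gene_id for g in genes],
        }
    )
    return IntervalSet(df, genome, validate=False)


def _exon_set(genes: list[GeneModel], genome: Genome) -> IntervalSet:
    rows = [(g.chrom, s, e, g.gene_id) for g in genes for s, e in g.exons]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return IntervalSet(df, genome, validate=False)


def _body_set(genes: list[GeneModel], genome: Genome) -> IntervalSet:
    df = pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "name": [g.gene_id for g in genes],
        }
    )
    return IntervalSet(df, genome, validate=False)


def annotate_regions(
    intervals: IntervalSet,
    genes: list[GeneModel],
    cfg: AnnotationConfig = AnnotationConfig(),
    promoter_window_bp: int | None = None,
) -> pd.Series:
    """Assign each interval one genomic-context label.

    Precedence is promoter > exon > intron > intergenic.  *Promoter*
    means within ``promoter_window_bp`` (default ``cfg.promoter_window_bp``)
    of any TSS, symmetric on both sides of the strand-aware TSS position.
    Returns a Series of labels aligned to the interval-set row index.
    """
    if not genes:
        raise ValueError("gene list is empty")
    window = cfg.promoter_window_bp if promoter_window_bp is None else promoter_window_bp
    labels = pd.Series(["intergenic"] * len(intervals), dtype=object)

    body_hits = overlap_pairs(intervals, _body_set(genes, intervals.genome), 1)
    labels.iloc[np.unique(body_hits["a_index"].to_numpy(np.int64))] = "intron"
    exons = _exon_set(genes, intervals.genome)
    if len(exons):
        exon_hits = overlap_pairs(intervals, exons, 1)
        labels.iloc[np.unique(exon_hits["a_index"].to_numpy(np.int64))] = "exon"
    prom_hits = pairs_within(intervals, _tss_set(genes, intervals.genome), window)
    labels.iloc[np.unique(prom_hits["a_index"].to_numpy(np.int64))] = "promoter"
    return labels


def annotation_summary(labels: pd.Series) -> pd.DataFrame:
    counts = labels.value_counts().reindex(CATEGORIES, fill_value=0)
    return pd.DataFrame(
        {"category": CATEGORIES, "count": counts.to_numpy(), "fraction": counts.to_numpy() / max(len(labels), 1)}
    )


def select_downregulated(
    de: list[DERecord], min_fold: float = 1.2, max_p: float = 0.05
) -> list[str]:
    """Gene ids with |fold change| strictly > min_fold, p strictly < max_p,
    and direction down (negative fold change)."""
    if min_fold <= 0 or max_p <= 0:
        raise ValueError("thresholds must be > 0")
    return [
        r.gene_id
        for r in de
        if r.fold_change < 0 and abs(r.fold_change) > min_fold and r.p_value < max_p
    ]


def n_rna_regions(down_genes: list[str], genes: list[GeneModel], genome: Genome) -> IntervalSet:
    """One interval per downregulated gene spanning its gene body.

    The reduced-expression region of a downregulated gene is proxied by
    its annotated gene body (sub-gene coverage-dip coordinates are not
    modeled); intervals are named by gene_id.
    """
    by_id = {g.gene_id: g for g in genes}
    missing = [gid for gid in down_genes if gid not in by_id]
    if missing:
        raise KeyError(f"unknown gene ids: {missing}")
    rows = [(by_id[g].chrom, by_id[g].start, by_id[g].end, g, np.nan, by_id[g].strand) for g in down_genes]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    return IntervalSet(df, genome, validate=False)
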