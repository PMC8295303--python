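"""End-to-end orchestration: load inputs, run every stage, emit reports.

The pipeline composes the stages in the order the analysis runs them:

1.  score-filter knockout-unique H3K9me3 peaks and call HH-sites
    (H-sites embedded in those peaks); cross-check H-sites against the
    normally-demethylated site set;
2.  call RCAs by overlap subtraction of knockout from control ATAC
    peaks, annotate them (promoter/exon/intron/intergenic, 200 bp TSS
    window) and split out p-RCAs and i-RCAs;
3.  TPM-classify RCAs into the five chromatin states and sub-type the
    paired insulators against CTCF/Rad21 (CAC/CNC);
4.  select downregulated genes, build their gene-body regions and pair
    them with p-RCAs within 5 kbp;
5.  per-chromosome density Spearman correlations, distance-bracket
    histograms and an anchored heat-map matrix;
6.  TAD co-occurrence contingency table and uncorrected chi-square;
7.  Hi-C contact filtering (1 kbp - 10 Mbp), area-1 mining around the
    paired p-RCAs, area-2 neighborhood profiling and the per-gene
    contact report.

Every threshold lives in :class:`PipelineConfig`; stage logic never
hard-codes one.  Reports are plain TSV plus one machine-readable
``summary.json``; identical inputs and config produce byte-identical
bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import annotation as ann
from . import hic, proximity, rca, stats
from .genome import Genome
from .intervals import (
    IntervalSet, count_flanking, filter_by_score, read_bed, subtract_condition,
    window_intersect,
)

logger = logging.getLogger(__name__)

INPUT_KEYS = (
    "genome", "tads", "atac_control", "atac_ko", "hsites", "k9_ko_unique",
    "t3_tr", "utr", "ctcf", "rad21", "pol2", "demethylated", "genes", "de",
    "signal", "contacts",
)


@dataclass
class PipelineConfig:
    """All inputs and thresholds for a pipeline run.

    Threshold defaults are the analysis values: -log10(p) > 2 peak
    filter, 200 bp promoter window (1 kbp alternative for
    methylation-site promoter calls), |fold| > 1.2 and p < 0.05 DE
    cut, 5 kbp pairing cap, 1 kbp-10 Mbp contact separations, 1 kbp
    area-1 and 50 kbp area-2 windows, 10 kbp flanking window.
    """

    inputs: dict[str, str]
    outdir: str = "chromlink_out"
    promoter_window_bp: int = 200
    promoter_window_alt_bp: int = 1000
    k9_min_score: float = 2.0
    hh_window_bp: int = 0
    de_min_fold: float = 1.2
    de_max_p: float = 0.05
    pairing_max_dist_bp: int = 5000
    min_contact_sep_bp: int = 1000
    max_contact_sep_bp: int = 10_000_000
    area1_window_bp: int = 1000
    area2_window_bp: int = 50_000
    flank_window_bp: int = 10_000
    brackets_kbp: tuple[float, ...] = proximity.DEFAULT_BRACKETS_KBP
    heatmap_halfwidth_bp: int = 5000
    heatmap_binsize_bp: int = 500
    strict: bool = False

    def validate(self) -> None:
        missing = [k for k in INPUT_KEYS if k not in self.inputs]
        if missing:
            raise ValueError(f"missing input paths: {missing}")
        absent = [k for k in INPUT_KEYS if not Path(self.inputs[k]).exists()]
        if absent:
            raise FileNotFoundError(
                f"input files not found: {[(k, self.inputs[k]) for k in absent]}"
            )
        for name in (
            "promoter_window_bp", "promoter_window_alt_bp", "pairing_max_dist_bp",
            "area1_window_bp", "area2_window_bp", "flank_window_bp",
            "heatmap_halfwidth_bp", "heatmap_binsize_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.hh_window_bp < 0:
            raise ValueError("hh_window_bp must be >= 0")
        if self.min_contact_sep_bp < 0 or self.max_contact_sep_bp < self.min_contact_sep_bp:
            raise ValueError("invalid contact separation bounds")
        if self.de_min_fold <= 0 or not (0 < self.de_max_p <= 1):
            raise ValueError("invalid DE thresholds")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "brackets_kbp" in raw:
            raw["brackets_kbp"] = tuple(raw["brackets_kbp"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["brackets_kbp"] = list(self.brackets_kbp)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_simulated(cls, paths: dict[str, Path], outdir: str | Path) -> "PipelineConfig":
        return cls(
            inputs={k: str(paths[k]) for k in INPUT_KEYS}, outdir=str(outdir)
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: PipelineConfig) -> dict:
    """Execute every stage; write the report bundle; return the summary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums = {k: _sha256(config.inputs[k]) for k in INPUT_KEYS}
    logger.info("inputs: %s", checksums)

    genome = Genome.read_tsv(config.inputs["genome"])
    strict = config.strict
    tads = read_bed(config.inputs["tads"], genome, strict)
    atac_control = read_bed(config.inputs["atac_control"], genome, strict)
    atac_ko = read_bed(config.inputs["atac_ko"], genome, strict)
    hsites = read_bed(config.inputs["hsites"], genome, strict)
    k9 = read_bed(config.inputs["k9_ko_unique"], genome, strict)
    t3_tr = read_bed(config.inputs["t3_tr"], genome, strict)
    utr = read_bed(config.inputs["utr"], genome, strict)
    ctcf = read_bed(config.inputs["ctcf"], genome, strict)
    rad21 = read_bed(config.inputs["rad21"], genome, strict)
    pol2 = read_bed(config.inputs["pol2"], genome, strict)
    demeth = read_bed(config.inputs["demethylated"], genome, strict)
    genes = ann.read_gene_tsv(config.inputs["genes"], genome)
    de = ann.read_de_tsv(config.inputs["de"])
    signal = rca.SignalTable.read_tsv(config.inputs["signal"])
    contacts = hic.read_bedpe(config.inputs["contacts"], genome, strict)

    summary: dict = {"input_checksums": checksums, "thresholds": {
        "promoter_window_bp": config.promoter_window_bp,
        "promoter_window_alt_bp": config.promoter_window_alt_bp,
        "k9_min_score": config.k9_min_score,
        "hh_window_bp": config.hh_window_bp,
        "de_min_fold": config.de_min_fold,
        "de_max_p": config.de_max_p,
        "pairing_max_dist_bp": config.pairing_max_dist_bp,
        "contact_sep_bp": [config.min_contact_sep_bp, config.max_contact_sep_bp],
        "area1_window_bp": config.area1_window_bp,
        "area2_window_bp": config.area2_window_bp,
        "flank_window_bp": config.flank_window_bp,
    }}

    # 1. HH-sites and the demethylation cross-check -----------------------
    k9_filtered = filter_by_score(k9, config.k9_min_score)
    hh_sites = window_intersect(hsites, k9_filtered, config.hh_window_bp)
    hh_sites.write_bed(outdir / "hh_sites.bed")
    demeth_overlap = window_intersect(hsites, demeth, 0)
    n_flanked_t3, occ_t3 = count_flanking(hh_sites, t3_tr, config.flank_window_bp)
    n_flanked_utr, occ_utr = count_flanking(hh_sites, utr, config.flank_window_bp)
    summary["hsites"] = {
        "n_hsites": len(hsites),
        "n_k9_peaks_kept": len(k9_filtered),
        "n_hh_sites": len(hh_sites),
        "n_normally_demethylated_overlap": len(demeth_overlap),
        "t3_tr_flanking": {"n_flanked_sites": n_flanked_t3, "n_occasions": occ_t3},
        "utr_flanking": {"n_flanked_sites": n_flanked_utr, "n_occasions": occ_utr},
    }

    # 2. RCA detection and annotation ------------------------------------
    rcas = subtract_condition(atac_control, atac_ko)
    labels = ann.annotate_regions(
        rcas, genes, ann.AnnotationConfig(config.promoter_window_bp, config.promoter_window_alt_bp)
    )
    rcas.write_bed(outdir / "rca.bed")
    ann.annotation_summary(labels).to_csv(outdir / "rca_annotation.tsv", sep="\t", index=False)
    p_rcas = rcas.subset(np.flatnonzero((labels == "promoter").to_numpy()))
    i_rcas = rcas.subset(np.flatnonzero((labels == "intergenic").to_numpy()))
    summary["rca"] = {
        "n_control_peaks": len(atac_control),
        "n_ko_peaks": len(atac_ko),
        "n_rca": len(rcas),
        "by_category": {c: int((labels == c).sum()) for c in ann.CATEGORIES},
    }

    # 3. classification ----------------------------------------------------
    rca_names = rcas.df["name"]
    missing = set(rca_names) - set(signal.region_ids)
    if missing:
        raise ValueError(f"signal table lacks {len(missing)} RCA regions (e.g. {sorted(missing)[:3]})")
    sub = rca.SignalTable(signal.df.loc[rca_names])
    classes = rca.classify_table(sub)
    rca.classified_bed(rcas, classes, outdir / "rca_classified.bed")
    rca.class_summary(classes).to_csv(outdir / "rca_class_summary.tsv", sep="\t", index=False)
    summary["classification"] = {
        c: int((classes == c).sum()) for c in rca.RCA_CLASSES
    }

    # 4. downregulated genes and pairing ----------------------------------
    down = ann.select_downregulated(de, config.de_min_fold, config.de_max_p)
    n_rna = ann.n_rna_regions(down, genes, genome)
    pairing = stats.pair_prca_with_downregulated(p_rcas, n_rna, config.pairing_max_dist_bp)
    pairing.write_tsv(outdir / "prca_gene_pairs.tsv")
    paired_prcas = p_rcas.subset(np.unique(pairing.pairs["prca_index"].to_numpy(np.int64)))
    summary["pairing"] = {
        "n_downregulated": len(down),
        "n_pairs": int(len(pairing.pairs)),
        "n_unique_genes": pairing.n_unique_genes,
        "n_unique_prcas": pairing.n_unique_prcas,
    }

    # insulator sub-typing of the paired p-RCAs
    paired_classes = classes.loc[paired_prcas.df["name"]]
    insulators = paired_prcas.subset(np.flatnonzero((paired_classes == "insulator").to_numpy()))
    ins_types = rca.classify_insulator_cohesin(insulators, ctcf, rad21)
    summary["insulators"] = {
        "n_paired_insulators": len(insulators),
        "n_cac": int((ins_types == "CAC").sum()),
        "n_cnc": int((ins_types == "CNC").sum()),
        "n_neither": int((ins_types == "neither").sum()),
    }
    with open(outdir / "insulator_types.tsv", "w") as fh:
        fh.write("region_id\tinsulator_type\n")
        for name, t in zip(insulators.df["name"], ins_types):
            fh.write(f"{name}\t{t}\n")

    # 5. densities, correlations, proximity --------------------------------
    dens = {
        "hsites": stats.chromosome_density(hsites, genome),
        "prca": stats.chromosome_density(p_rcas, genome),
        "irca": stats.chromosome_density(i_rcas, genome),
        "rca_all": stats.chromosome_density(rcas, genome),
    }
    corr_pairs = [
        ("hsites", "rca_all"), ("hsites", "prca"), ("hsites", "irca"), ("irca", "prca")
    ]
    corr_rows = []
    for a, b in corr_pairs:
        r, p = stats.density_correlation(dens[a], dens[b])
        corr_rows.append({"a": a, "b": b, "spearman_r": round(r, 6), "p_two_tailed": float(p)})
    with open(outdir / "density_correlations.tsv", "w") as fh:
        fh.write("a\tb\tspearman_r\tp_two_tailed\n")
        for row in corr_rows:
            fh.write(f"{row['a']}\t{row['b']}\t{row['spearman_r']:g}\t{row['p_two_tailed']:.6g}\n")
    summary["density_correlations"] = corr_rows

    hist_h_pol2 = proximity.bracket_histogram(hsites, pol2, config.brackets_kbp)
    hist_h_pol2.write_tsv(outdir / "hist_hsites_vs_pol2.tsv")
    hist_prca_h = proximity.bracket_histogram(paired_prcas, hsites, config.brackets_kbp)
    hist_prca_h.write_tsv(outdir / "hist_paired_prca_vs_hsites.tsv")
    hist_irca_h = proximity.bracket_histogram(i_rcas, hsites, config.brackets_kbp)
    hist_irca_h.write_tsv(outdir / "hist_irca_vs_hsites.tsv")
    matrix = proximity.anchored_matrix(
        t3_tr, hsites, config.heatmap_halfwidth_bp, config.heatmap_binsize_bp
    )
    matrix.write_tsv(outdir / "matrix_hsites_around_t3tr.tsv")
    summary["proximity"] = {
        "hsites_vs_pol2": {
            "labels": hist_h_pol2.labels,
            "counts": [int(c) for c in hist_h_pol2.counts],
            "no_neighbor": hist_h_pol2.n_no_neighbor,
        },
        "matrix_total": matrix.total(),
    }

    # 6. TAD co-occurrence --------------------------------------------------
    table = stats.tad_cooccurrence(tads, p_rcas, i_rcas)
    chi2, p, odds = stats.chi_square_2x2(table)
    summary["tad"] = {
        "n_tads": table.n,
        "cells": {
            "both": table.n_both, "prca_only": table.n_a_only,
            "irca_only": table.n_b_only, "neither": table.n_neither,
        },
        "chi2": round(chi2, 4),
        "p": float(p),
        "odds_ratio": (None if odds == float("inf") else round(odds, 4)),
    }
    with open(outdir / "tad_cooccurrence.tsv", "w") as fh:
        fh.write("both\tprca_only\tirca_only\tneither\tchi2\tp\todds_ratio\n")
        fh.write(
            f"{table.n_both}\t{table.n_a_only}\t{table.n_b_only}\t{table.n_neither}"
            f"\t{chi2:.4f}\t{p:.6g}\t{odds:.4f}\n"
        )

    # 7. Hi-C mining ---------------------------------------------------------
    filtered = hic.filter_contacts(contacts, config.min_contact_sep_bp, config.max_contact_sep_bp)
    hits = hic.find_area1(filtered, paired_prcas, config.area1_window_bp)
    profiles = hic.area2_profile(filtered, hits, i_rcas, hsites, config.area2_window_bp)
    contact_sum = hic.contact_summary(hits, profiles, pairing.pairs)
    hits.to_csv(outdir / "area1_hits.tsv", sep="\t", index=False)
    profiles.to_csv(outdir / "area2_profiles.tsv", sep="\t", index=False)
    gene_table = contact_sum.pop("gene_table")
    gene_table.to_csv(outdir / "gene_contact_report.tsv", sep="\t", index=False)
    summary["hic"] = {
        "n_contacts_input": len(contacts),
        "n_contacts_filtered": len(filtered),
        **{k: (round(v, 4) if isinstance(v, float) else v) for k, v in contact_sum.items()},
        "n_genes_with_area1": int(len(gene_table)),
        "n_genes_with_irca_support": int(gene_table["has_irca_support"].sum()) if len(gene_table) else 0,
    }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, allow_nan=True)
    return summary
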