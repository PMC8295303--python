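"""TPM over RCA regions and the 5-way chromatin-state classification.

Regions of reduced chromatin accessibility (RCAs) are typed from the
relative strengths of H3K4me3 (promoter mark), H3K4me1 (primed-enhancer
mark) and ATAC signal, all normalized as transcripts-per-kilobase-million
(TPM) over the RCA region set itself:

* max(TPM_K4me3, TPM_K4me1) > 4 gates the "marked" branch; there the
  ratio r = TPM_K4me3 / TPM_K4me1 gives ``promoter`` (r > 1.5),
  ``enhancer`` (r < 0.67) or ``weak_promoter`` (intermediate, ties
  included).
* Otherwise ATAC > H3K4me1 gives ``insulator``, else ``weak_insulator``
  (equality falls to weak_insulator: the rule uses a strict ">").

Insulator RCAs are sub-typed against CTCF and cohesin (Rad21) peaks:
``CAC`` overlaps both, ``CNC`` cohesin only, else ``neither``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import IntervalSet, overlap_pairs

logger = logging.getLogger(__name__)

RCA_CLASSES = ("promoter", "weak_promoter", "enhancer", "insulator", "weak_insulator")
TRACKS = ("atac", "k4me1", "k4me3")

TPM_GATE = 4.0
PROMOTER_RATIO = 1.5
ENHANCER_RATIO = 0.67


class SignalTable:
    """Per-region raw counts and lengths for the ATAC/H3K4me1/H3K4me3 tracks.

    Backed by a DataFrame indexed by region_id with columns
    ``chrom, start, end, length_bp, count_atac, count_k4me1, count_k4me3``.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"length_bp"} | {f"count_{t}" for t in TRACKS}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"signal table missing columns: {sorted(missing)}")
        if df.index.duplicated().any():
            raise ValueError("region ids are not unique")
        if (df["length_bp"] <= 0).any():
            raise ValueError("region lengths must be > 0")
        for t in TRACKS:
            if (df[f"count_{t}"] < 0).any():
                raise ValueError(f"negative counts in track {t}")
        self.df = df.copy()

    def __len__(self) -> int:
        return len(self.df)

    @property
    def region_ids(self) -> pd.Index:
        return self.df.index

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SignalTable":
        df = pd.read_csv(path, sep="\t", index_col="region_id")
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="region_id")


def compute_tpm(table: SignalTable, track: str) -> pd.Series:
    """TPM per region for one track, normalized over the region set.

    TPM_i = (c_i / L_i[kb]) / sum_j (c_j / L_j[kb]) * 1e6, so the track
    sums to 1e6 over the table.  An all-zero track has no defined
    normalization and raises.
    """
    if track not in TRACKS:
        raise ValueError(f"unknown track {track!r}; expected one of {TRACKS}")
    if len(table) == 0:
        raise ValueError("signal table is empty")
    rate = table.df[f"count_{track}"] / (table.df["length_bp"] / 1000.0)
    total = rate.sum()
    if total == 0:
        raise ValueError(f"track {track!r} is all zero; TPM normalization undefined")
    return rate / total * 1e6


def classify_rca(
    tpm_k4me3: pd.Series, tpm_k4me1: pd.Series, atac_signal: pd.Series
) -> pd.Series:
    """Assign each region exactly one of the five RCA classes.

    All three inputs must be aligned on region id.  A zero H3K4me1 TPM in
    the marked branch makes the ratio +inf (promoter) and is logged.
    """
    if not (tpm_k4me3.index.equals(tpm_k4me1.index) and tpm_k4me3.index.equals(atac_signal.index)):
        raise ValueError("inputs are not aligned on region_id")
    k3 = tpm_k4me3.to_numpy(float)
    k1 = tpm_k4me1.to_numpy(float)
    at = atac_signal.to_numpy(float)

    marked = np.maximum(k3, k1) > TPM_GATE
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(k1 > 0, k3 / np.where(k1 > 0, k1, 1.0), np.inf)
    n_zero_den = int((marked & (k1 == 0)).sum())
    if n_zero_den:
        logger.warning("%d marked regions have zero H3K4me1 TPM; ratio treated as +inf", n_zero_den)

    labels = np.where(
        marked,
        np.where(ratio > PROMOTER_RATIO, "promoter",
                 np.where(ratio < ENHANCER_RATIO, "enhancer", "weak_promoter")),
        np.where(at > k1, "insulator", "weak_insulator"),
    )
    return pd.Series(labels, index=tpm_k4me3.index, name="rca_class")


def classify_table(table: SignalTable) -> pd.Series:
    """Convenience: TPM-normalize all three tracks and classify.

    The ATAC signal used in the unmarked branch is TPM-normalized the
    same way as the histone tracks so the comparison is unit-consistent.
    """
    return classify_rca(
        compute_tpm(table, "k4me3"), compute_tpm(table, "k4me1"), compute_tpm(table, "atac")
    )


def class_summary(labels: pd.Series) -> pd.DataFrame:
    counts = labels.value_counts().reindex(RCA_CLASSES, fill_value=0)
    return pd.DataFrame(
        {
            "rca_class": RCA_CLASSES,
            "count": counts.to_numpy(),
            "fraction": counts.to_numpy() / max(len(labels), 1),
        }
    )


def classify_insulator_cohesin(
    insulators: IntervalSet, ctcf: IntervalSet, rad21: IntervalSet
) -> pd.Series:
    """Type insulator RCAs by CTCF/cohesin occupancy.

    CAC: overlaps >=1 Rad21 peak AND >=1 CTCF peak (structural insulator,
    modulates 3D contacts); CNC: Rad21 only (local barrier); otherwise
    ``neither``.  Returns a Series aligned to the insulator rows.
    """
    has_ctcf = np.zeros(len(insulators), dtype=bool)
    has_rad = np.zeros(len(insulators), dtype=bool)
    if len(ctcf):
        has_ctcf[np.unique(overlap_pairs(insulators, ctcf, 1)["a_index"].to_numpy(np.int64))] = True
    if len(rad21):
        has_rad[np.unique(overlap_pairs(insulators, rad21, 1)["a_index"].to_numpy(np.int64))] = True
    labels = np.where(has_rad & has_ctcf, "CAC", np.where(has_rad, "CNC", "neither"))
    return pd.Series(labels, name="insulator_type")


def classified_bed(regions: IntervalSet, labels: pd.Series, path: str | Path) -> None:
    """Write regions as BED6 plus a class column (TSV)."""
    df = regions.df.copy()
    df["rca_class"] = labels.to_numpy()
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            name = row.name if isinstance(row.name, str) else "."
            score = "." if np.isnan(row.score) else f"{row.score:g}"
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t{score}\t{row.strand}\t{row.rca_class}\n"
            )
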