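"""Hi-C contact filtering and area-1 / area-2 mining.

Significant intra-chromosomal contacts are consumed as BEDPE anchor
pairs.  An anchor that lies within 1 kbp (<= 1000 bp edge distance) of a
promoter RCA becomes an *area-1*; its partner anchor is the *area-2*,
whose neighborhood is profiled for intergenic RCAs and hypermethylation
sites within a 50 kbp window (strictly < 50 kbp, i.e. <= 49,999 bp edge
distance, following the source criterion's wording).  Both anchors of a
contact are eligible as area-1; a contact whose two anchors both match
promoter RCAs yields two hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Genome
from .intervals import IntervalSet, nearest_distance, pairs_within

MIN_SEPARATION_BP = 1_000
MAX_SEPARATION_BP = 10_000_000
AREA1_WINDOW_BP = 1_000
AREA2_WINDOW_BP = 50_000

_BEDPE_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"]


@dataclass
class ContactSet:
    """Canonical intra-chromosomal contact pairs.

    One row per contact: anchors oriented so that anchor1's midpoint is
    the smaller; ``separation`` is the midpoint distance in bp.
    """

    df: pd.DataFrame
    genome: Genome

    def __len__(self) -> int:
        return len(self.df)

    def anchor_set(self, which: int) -> IntervalSet:
        """Anchors 1 or 2 as an IntervalSet named by contact id.

        The IntervalSet re-sorts rows; use interval names (contact ids)
        to join back to contacts.
        """
        s, e = (f"start{which}", f"end{which}")
        df = pd.DataFrame(
            {
                "chrom": self.df["chrom1"],
                "start": self.df[s],
                "end": self.df[e],
                "name": self.df["name"],
            }
        )
        return IntervalSet(df, self.genome, validate=False)


def read_bedpe(path: str | Path, genome: Genome, strict: bool = False) -> ContactSet:
    """Read BEDPE contacts; canonicalize, deduplicate, drop inter-chromosomal.

    Anchors are swapped where needed so midpoint1 < midpoint2; duplicate
    coordinate pairs are dropped; pairs with coincident midpoints have
    no defined separation and are rejected.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BEDPE fields")
            c1, s1, e1 = f[0], int(f[1]), int(f[2])
            c2, s2, e2 = f[3], int(f[4]), int(f[5])
            name = f[6] if len(f) > 6 and f[6] != "." else f"contact_{lineno}"
            score = float(f[7]) if len(f) > 7 and f[7] != "." else np.nan
            if not (0 <= s1 < e1) or not (0 <= s2 < e2):
                raise ValueError(f"{path}:{lineno}: invalid anchor span")
            if c1 not in genome or c2 not in genome:
                if strict:
                    raise ValueError(f"{path}:{lineno}: unknown chromosome")
                warnings.warn(f"{path}:{lineno}: skipping unknown chromosome", stacklevel=2)
                continue
            if c1 != c2:
                continue  # inter-chromosomal pairs are always dropped
            m1, m2 = (s1 + e1) / 2, (s2 + e2) / 2
            if m1 == m2:
                raise ValueError(f"{path}:{lineno}: coincident anchor midpoints")
            if m1 > m2:
                s1, e1, s2, e2 = s2, e2, s1, e1
            rows.append((c1, s1, e1, c1, s2, e2, name, score))
    df = pd.DataFrame(rows, columns=_BEDPE_COLS)
    df = df.drop_duplicates(subset=["chrom1", "start1", "end1", "start2", "end2"], keep="first")
    df["separation"] = ((df["start2"] + df["end2"]) - (df["start1"] + df["end1"])) / 2.0
    df = df.reset_index(drop=True)
    return ContactSet(df, genome)


def write_bedpe(contacts: ContactSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in contacts.df.itertuples(index=False):
            score = "." if np.isnan(row.score) else f"{row.score:g}"
            fh.write(
                f"{row.chrom1}\t{row.start1}\t{row.end1}\t{row.chrom2}\t{row.start2}\t{row.end2}\t{row.name}\t{score}\n"
            )


def filter_contacts(
    contacts: ContactSet,
    min_sep_bp: int = MIN_SEPARATION_BP,
    max_sep_bp: int = MAX_SEPARATION_BP,
) -> ContactSet:
    """Retain contacts with min_sep <= midpoint separation <= max_sep.

    Both bounds inclusive; idempotent by construction.
    """
    sep = contacts.df["separation"]
    keep = (sep >= min_sep_bp) & (sep <= max_sep_bp)
    return ContactSet(contacts.df[keep].reset_index(drop=True), contacts.genome)


def find_area1(
    contacts: ContactSet,
    p_rcas: IntervalSet,
    window_bp: int = AREA1_WINDOW_BP,
    both_anchors: bool = True,
) -> pd.DataFrame:
    """Contacts whose anchor lies within ``window_bp`` of a promoter RCA.

    Returns one hit per (contact, anchor) match with columns
    ``contact_index, contact_id, anchor`` (1 or 2), ``prca_index,
    prca_name, distance_bp, separation``; when an anchor matches several
    p-RCAs the nearest (then lowest-coordinate) one is recorded.  With
    ``both_anchors`` (default) either anchor may be the area-1, so a
    contact matching at both ends yields two hits.
    """
    frames = []
    anchors = (1, 2) if both_anchors else (1,)
    prca_names = p_rcas.df["name"].to_numpy(object)
    for which in anchors:
        aset = contacts.anchor_set(which)
        # IntervalSet rows are re-sorted: map set rows back to contact rows
        contact_row = {n: i for i, n in enumerate(contacts.df["name"])}
        hits = pairs_within(aset, p_rcas, window_bp)
        if not len(hits):
            continue
        hits = hits.sort_values(["a_index", "gap_bp", "b_index"], kind="stable")
        hits = hits.drop_duplicates(subset="a_index", keep="first")
        anames = aset.df["name"].to_numpy(object)
        frames.append(
            pd.DataFrame(
                {
                    "contact_index": [contact_row[anames[i]] for i in hits["a_index"]],
                    "contact_id": anames[hits["a_index"].to_numpy(np.int64)],
                    "anchor": which,
                    "prca_index": hits["b_index"].to_numpy(np.int64),
                    "prca_name": prca_names[hits["b_index"].to_numpy(np.int64)],
                    "distance_bp": hits["gap_bp"].to_numpy(np.int64),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "contact_index", "contact_id", "anchor", "prca_index",
                "prca_name", "distance_bp", "separation",
            ]
        )
    out = pd.concat(frames, ignore_index=True)
    out["separation"] = contacts.df["separation"].to_numpy()[out["contact_index"]]
    return out.sort_values(["contact_index", "anchor"], kind="stable").reset_index(drop=True)


def area2_profile(
    contacts: ContactSet,
    hits: pd.DataFrame,
    i_rcas: IntervalSet,
    h_sites: IntervalSet,
    window_bp: int = AREA2_WINDOW_BP,
) -> pd.DataFrame:
    """Neighborhood profile of each area-2 (the partner of a matched anchor).

    Per hit: nearest i-RCA and H-site edge distances (NaN when the
    chromosome holds none) and counts within the window (strict
    < window_bp).  Returns one row per hit, aligned to ``hits``.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    if not len(hits):
        return pd.DataFrame(
            columns=[
                "contact_index", "contact_id", "area2_start", "area2_end",
                "nearest_irca_bp", "n_irca_within", "nearest_hsite_bp", "n_hsite_within",
            ]
        )
    cdf = contacts.df
    area2_anchor = 3 - hits["anchor"].to_numpy()  # partner anchor
    starts = np.where(area2_anchor == 1, cdf["start1"].to_numpy()[hits["contact_index"]],
                      cdf["start2"].to_numpy()[hits["contact_index"]])
    ends = np.where(area2_anchor == 1, cdf["end1"].to_numpy()[hits["contact_index"]],
                    cdf["end2"].to_numpy()[hits["contact_index"]])
    a2 = IntervalSet(
        pd.DataFrame(
            {
                "chrom": cdf["chrom1"].to_numpy()[hits["contact_index"]],
                "start": starts,
                "end": ends,
                "name": [str(i) for i in range(len(hits))],  # hit ordinal
            }
        ),
        contacts.genome,
        validate=False,
    )
    hit_of_row = a2.df["name"].astype(int).to_numpy()

    def _profile(feats: IntervalSet) -> tuple[np.ndarray, np.ndarray]:
        nn = nearest_distance(a2, feats)
        near = np.full(len(hits), np.nan)
        near[hit_of_row] = nn["distance_bp"].to_numpy()
        within = pairs_within(a2, feats, window_bp - 1)  # strict "< window"
        cnt_rows = np.bincount(within["a_index"].to_numpy(np.int64), minlength=len(a2))
        counts = np.zeros(len(hits), dtype=np.int64)
        counts[hit_of_row] = cnt_rows
        return near, counts

    near_i, cnt_i = _profile(i_rcas)
    near_h, cnt_h = _profile(h_sites)
    return pd.DataFrame(
        {
            "contact_index": hits["contact_index"].to_numpy(np.int64),
            "contact_id": hits["contact_id"].to_numpy(object),
            "area2_start": starts,
            "area2_end": ends,
            "nearest_irca_bp": near_i,
            "n_irca_within": cnt_i,
            "nearest_hsite_bp": near_h,
            "n_hsite_within": cnt_h,
        }
    )


def contact_summary(
    hits: pd.DataFrame,
    profiles: pd.DataFrame,
    prca_to_gene: pd.DataFrame | None = None,
) -> dict:
    """Aggregate the mined contacts.

    Returns mean/min/max area-1 to area-2 separation, areas-1/areas-2
    totals, i-RCA/H-site neighborhood summaries and, when the p-RCA to
    gene pairing is supplied (columns ``prca_name, gene_id``), a
    per-gene table with the number of interacting areas-2 and whether
    any of them has an i-RCA (criterion for remote-enhancer support)
    or an H-site within the window.
    """
    summary: dict = {
        "n_area1": int(len(hits)),
        "n_area2": int(len(profiles)),
        "n_prcas_matched": int(hits["prca_index"].nunique()) if len(hits) else 0,
    }
    if len(hits):
        sep = hits["separation"].to_numpy(float)
        summary.update(
            mean_separation_bp=float(sep.mean()),
            min_separation_bp=float(sep.min()),
            max_separation_bp=float(sep.max()),
        )
    if len(profiles):
        ni = profiles["nearest_irca_bp"].to_numpy(float)
        nh = profiles["nearest_hsite_bp"].to_numpy(float)
        summary.update(
            n_area2_with_irca_within=int((profiles["n_irca_within"] > 0).sum()),
            n_area2_with_hsite_within=int((profiles["n_hsite_within"] > 0).sum()),
            max_irca_per_area2=int(profiles["n_irca_within"].max()),
            mean_nearest_irca_bp=float(np.nanmean(ni)) if np.isfinite(ni).any() else float("nan"),
            mean_nearest_hsite_bp=float(np.nanmean(nh)) if np.isfinite(nh).any() else float("nan"),
        )
    gene_table = pd.DataFrame(
        columns=["gene_id", "n_areas2", "n_areas2_with_irca", "has_irca_support", "has_hsite_near_area2"]
    )
    if prca_to_gene is not None and len(hits):
        merged = hits.merge(profiles[["n_irca_within", "n_hsite_within"]], left_index=True, right_index=True)
        merged = merged.merge(prca_to_gene[["prca_name", "gene_id"]], on="prca_name", how="inner")
        # one contact may serve a gene through either anchor; count distinct
        # (gene, contact, anchor) hits as interacting areas-2
        grouped = merged.groupby("gene_id", sort=True)
        gene_table = pd.DataFrame(
            {
                "gene_id": list(grouped.groups),
                "n_areas2": grouped.size().to_numpy(np.int64),
                "n_areas2_with_irca": grouped["n_irca_within"].apply(lambda s: int((s > 0).sum())).to_numpy(np.int64),
                "has_irca_support": grouped["n_irca_within"].apply(lambda s: bool((s > 0).any())).to_numpy(),
                "has_hsite_near_area2": grouped["n_hsite_within"].apply(lambda s: bool((s > 0).any())).to_numpy(),
            }
        )
    summary["gene_table"] = gene_table
    return summary
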