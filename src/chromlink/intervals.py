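"""Genomic interval data model, BED I/O, and the interval operations the
pipeline is built on.

Conventions
-----------
* Coordinates are 0-based half-open (BED native): ``[start, end)``.
  Intervals ``[a, b)`` and ``[b, c)`` do not overlap.
* All distances are edge-to-edge gaps in bp, 0 when the intervals
  overlap or touch.
* Strand is carried through I/O but ignored by overlap/distance logic.

The :class:`IntervalSet` container keeps intervals sorted by genome
chromosome order then start; every operation preserves sortedness.
Searches run on per-chromosome sorted numpy arrays (binary search over
starts plus a running maximum over ends), so they stay near
O((n+m) log m + output) instead of the all-vs-all scan the test-suite
oracles use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .genome import Genome

_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open coordinate span with optional name/score/strand."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


class IntervalSet:
    """Sorted, genome-aware collection of intervals.

    Backed by a :class:`pandas.DataFrame` with columns
    ``chrom, start, end, name, score, strand``; the positional row index
    (0..n-1 after sorting) is the stable interval identifier used by all
    pairwise operations.
    """

    def __init__(self, df: pd.DataFrame, genome: Genome, validate: bool = True):
        df = df.copy()
        for col, default in (("name", None), ("score", np.nan), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[_BED_COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["score"] = df["score"].astype(float)
        if validate and len(df):
            if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
                bad = df[(df["start"] < 0) | (df["start"] >= df["end"])].iloc[0]
                raise ValueError(
                    f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']}"
                )
            unknown = set(df["chrom"]) - set(genome.names)
            if unknown:
                raise ValueError(f"chromosomes not in genome: {sorted(unknown)}")
            lengths = df["chrom"].map(dict(genome)).to_numpy()
            if (df["end"].to_numpy() > lengths).any():
                bad = df[df["end"].to_numpy() > lengths].iloc[0]
                raise ValueError(
                    f"interval {bad['chrom']}:{bad['start']}-{bad['end']} exceeds chromosome bounds"
                )
        rank = df["chrom"].map(genome.rank)
        df = df.iloc[np.lexsort((df["end"].to_numpy(), df["start"].to_numpy(), rank.to_numpy()))]
        df = df.reset_index(drop=True)
        self._df = df
        self.genome = genome
        # per-chromosome row slices for the search engine
        self._slices: dict[str, tuple[int, int]] = {}
        if len(df):
            chroms = df["chrom"].to_numpy()
            bounds = np.flatnonzero(np.r_[True, chroms[1:] != chroms[:-1], True])
            for i in range(len(bounds) - 1):
                self._slices[chroms[bounds[i]]] = (int(bounds[i]), int(bounds[i + 1]))

    # ------------------------------------------------------------------
    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval], genome: Genome) -> "IntervalSet":
        rows = [
            (iv.chrom, iv.start, iv.end, iv.name, np.nan if iv.score is None else iv.score, iv.strand)
            for iv in intervals
        ]
        df = pd.DataFrame(rows, columns=_BED_COLUMNS)
        return cls(df, genome)

    @property
    def df(self) -> pd.DataFrame:
        """The backing frame (do not mutate)."""
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self._df.itertuples(index=False):
            yield GenomicInterval(
                row.chrom,
                int(row.start),
                int(row.end),
                None if row.name is None or (isinstance(row.name, float) and np.isnan(row.name)) else row.name,
                None if np.isnan(row.score) else float(row.score),
                row.strand,
            )

    def __getitem__(self, i: int) -> GenomicInterval:
        row = self._df.iloc[i]
        name = row["name"]
        if isinstance(name, float) and np.isnan(name):
            name = None
        score = row["score"]
        return GenomicInterval(
            row["chrom"], int(row["start"]), int(row["end"]),
            name, None if np.isnan(score) else float(score), row["strand"],
        )

    def subset(self, indices: np.ndarray | list[int]) -> "IntervalSet":
        """New set from positional row indices (order is re-normalized)."""
        return IntervalSet(self._df.iloc[np.asarray(indices, dtype=np.int64)], self.genome, validate=False)

    def chroms(self) -> list[str]:
        return list(self._slices)

    def _arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, row-indices) for one chromosome, start-sorted."""
        if chrom not in self._slices:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty, empty
        lo, hi = self._slices[chrom]
        block = self._df.iloc[lo:hi]
        return (
            block["start"].to_numpy(),
            block["end"].to_numpy(),
            np.arange(lo, hi, dtype=np.int64),
        )

    # I/O ---------------------------------------------------------------
    def write_bed(self, path: str | Path) -> None:
        """Write BED3 or canonical BED6 (when any name/score/strand is set)."""
        df = self._df
        bed6 = bool(len(df)) and (
            df["name"].notna().any() or df["score"].notna().any() or (df["strand"] != ".").any()
        )
        with open(path, "w") as fh:
            for row in df.itertuples(index=False):
                if bed6:
                    name = row.name if isinstance(row.name, str) else "."
                    score = "." if np.isnan(row.score) else _fmt_score(row.score)
                    fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t{score}\t{row.strand}\n")
                else:
                    fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


def _fmt_score(score: float) -> str:
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def read_bed(path: str | Path, genome: Genome, strict: bool = False) -> IntervalSet:
    """Read a BED3/BED4/BED6 file into an :class:`IntervalSet`.

    Coordinates are taken as 0-based half-open.  Malformed lines raise
    with the offending line number.  Records on chromosomes absent from
    *genome* are skipped with a warning, or rejected when ``strict``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if not (0 <= start < end):
                raise ValueError(f"{path}:{lineno}: invalid span {start}-{end} (need 0 <= start < end)")
            if chrom not in genome:
                if strict:
                    raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                warnings.warn(f"{path}:{lineno}: skipping unknown chromosome {chrom!r}", stacklevel=2)
                continue
            if end > genome[chrom]:
                raise ValueError(
                    f"{path}:{lineno}: interval {chrom}:{start}-{end} exceeds chromosome length {genome[chrom]}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = np.nan
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric score {fields[4]!r}") from exc
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in _STRANDS:
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            rows.append((chrom, start, end, name, score, strand))
    df = pd.DataFrame(rows, columns=_BED_COLUMNS)
    return IntervalSet(df, genome, validate=False)


# ---------------------------------------------------------------------------
# pairwise search engine
# ---------------------------------------------------------------------------

def _pair_arrays(
    qstarts: np.ndarray, qends: np.ndarray, sstarts: np.ndarray, sends: np.ndarray,
    lo_key: np.ndarray, hi_key: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate (query, subject) index pairs on one chromosome.

    Subjects are start-sorted; candidates for query i are those with
    start < hi_key[i] and running-max(end) >= lo_key[i].  Callers apply
    the exact predicate afterwards.
    """
    if len(qstarts) == 0 or len(sstarts) == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    cmax = np.maximum.accumulate(sends)
    lo = np.searchsorted(cmax, lo_key, side="left")
    hi = np.searchsorted(sstarts, hi_key, side="right")
    counts = np.maximum(hi - lo, 0)
    total = int(counts.sum())
    if total == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    qidx = np.repeat(np.arange(len(qstarts)), counts)
    # concatenated ranges lo[i]..hi[i]
    offsets = np.concatenate(([0], np.cumsum(counts)))
    sidx = np.arange(total) - np.repeat(offsets[:-1], counts) + np.repeat(lo, counts)
    return qidx, sidx


def overlap_pairs(a: IntervalSet, b: IntervalSet, min_overlap_bp: int = 1) -> pd.DataFrame:
    """All (a, b) interval pairs overlapping by at least ``min_overlap_bp``.

    Returns a frame with columns ``a_index, b_index, overlap_bp`` holding
    positional row indices into each set, sorted by (a_index, b_index).
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    out_a, out_b, out_ov = [], [], []
    for chrom in a.chroms():
        qs, qe, qrow = a._arrays(chrom)
        ss, se, srow = b._arrays(chrom)
        qi, si = _pair_arrays(qs, qe, ss, se, qs + min_overlap_bp, qe - min_overlap_bp)
        if len(qi):
            ov = np.minimum(qe[qi], se[si]) - np.maximum(qs[qi], ss[si])
            keep = ov >= min_overlap_bp
            out_a.append(qrow[qi[keep]])
            out_b.append(srow[si[keep]])
            out_ov.append(ov[keep])
    if not out_a:
        return pd.DataFrame({"a_index": [], "b_index": [], "overlap_bp": []}).astype(np.int64)
    df = pd.DataFrame(
        {
            "a_index": np.concatenate(out_a),
            "b_index": np.concatenate(out_b),
            "overlap_bp": np.concatenate(out_ov),
        }
    )
    return df.sort_values(["a_index", "b_index"], kind="stable").reset_index(drop=True)


def pairs_within(a: IntervalSet, b: IntervalSet, max_gap_bp: int) -> pd.DataFrame:
    """All (a, b) pairs with edge-to-edge gap <= ``max_gap_bp`` (0 = overlap/touch).

    Returns columns ``a_index, b_index, gap_bp``.
    """
    if max_gap_bp < 0:
        raise ValueError("max_gap_bp must be >= 0")
    out_a, out_b, out_g = [], [], []
    for chrom in a.chroms():
        qs, qe, qrow = a._arrays(chrom)
        ss, se, srow = b._arrays(chrom)
        qi, si = _pair_arrays(qs, qe, ss, se, qs - max_gap_bp, qe + max_gap_bp)
        if len(qi):
            gap = np.maximum(np.maximum(ss[si] - qe[qi], qs[qi] - se[si]), 0)
            keep = gap <= max_gap_bp
            out_a.append(qrow[qi[keep]])
            out_b.append(srow[si[keep]])
            out_g.append(gap[keep])
    if not out_a:
        return pd.DataFrame({"a_index": [], "b_index": [], "gap_bp": []}).astype(np.int64)
    df = pd.DataFrame(
        {
            "a_index": np.concatenate(out_a),
            "b_index": np.concatenate(out_b),
            "gap_bp": np.concatenate(out_g),
        }
    )
    return df.sort_values(["a_index", "b_index"], kind="stable").reset_index(drop=True)


def subtract_condition(control: IntervalSet, case: IntervalSet, min_overlap_bp: int = 1) -> IntervalSet:
    """Whole control intervals with no case interval overlapping by >= min_overlap_bp.

    This is the differential-peak ("overlap subtraction") call: with
    control = control-condition ATAC peaks and case = knockout peaks, the
    result is the set of reduced-chromatin-accessibility (RCA) regions.
    Peaks are retained or dropped whole, never truncated.
    """
    hits = overlap_pairs(control, case, min_overlap_bp)
    drop = set(hits["a_index"].tolist())
    keep = [i for i in range(len(control)) if i not in drop]
    return control.subset(keep)


def nearest_distance(query: IntervalSet, subject: IntervalSet) -> pd.DataFrame:
    """Per-query nearest same-chromosome subject and edge-to-edge distance.

    Returns a frame indexed like *query* with columns ``subject_index``
    (-1 when the chromosome holds no subject) and ``distance_bp`` (NaN
    when no neighbor).  Overlapping or touching pairs have distance 0;
    ties are broken toward the lower coordinate.
    """
    n = len(query)
    subj = np.full(n, -1, dtype=np.int64)
    dist = np.full(n, np.nan)
    for chrom in query.chroms():
        qs, qe, qrow = query._arrays(chrom)
        ss, se, srow = subject._arrays(chrom)
        if len(ss) == 0:
            continue
        cmax = np.maximum.accumulate(se)
        attained = se >= cmax
        argc = np.where(attained, np.arange(len(se)), -1)
        argc = np.maximum.accumulate(argc)
        j = np.searchsorted(ss, qe, side="left")  # subjects with start < query end
        left_gap = np.full(len(qs), np.inf)
        left_idx = np.full(len(qs), -1, dtype=np.int64)
        has_left = j > 0
        if has_left.any():
            me = cmax[j[has_left] - 1]
            li = argc[j[has_left] - 1]
            left_gap[has_left] = np.maximum(qs[has_left] - me, 0)
            left_idx[has_left] = li
        right_gap = np.full(len(qs), np.inf)
        right_idx = np.full(len(qs), -1, dtype=np.int64)
        has_right = j < len(ss)
        if has_right.any():
            right_gap[has_right] = ss[j[has_right]] - qe[has_right]
            right_idx[has_right] = j[has_right]
        use_left = left_gap <= right_gap
        best_gap = np.where(use_left, left_gap, right_gap)
        best_idx = np.where(use_left, left_idx, right_idx)
        subj[qrow] = srow[best_idx]
        dist[qrow] = best_gap
    return pd.DataFrame({"subject_index": subj, "distance_bp": dist})


def window_intersect(sites: IntervalSet, regions: IntervalSet, window_bp: int) -> IntervalSet:
    """Sites within ``window_bp`` of (or, at window 0, overlapping) a region.

    ``window_bp == 0`` demands a true >=1 bp overlap ("embedded"), the
    rule used to call HH-sites from knockout-only H3K9me3 regions.  For
    positive windows a site is kept when its edge-to-edge gap to any
    region is <= window_bp.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if window_bp == 0:
        hits = overlap_pairs(sites, regions, 1)
    else:
        hits = pairs_within(sites, regions, window_bp)
    keep = np.unique(hits["a_index"].to_numpy(dtype=np.int64))
    return sites.subset(keep)


def filter_by_score(peaks: IntervalSet, min_score: float) -> IntervalSet:
    """Peaks with score strictly greater than ``min_score``.

    Used with min_score=2 on -log10(p) scored differential ChIP peaks.
    Every peak must carry a score.
    """
    scores = peaks.df["score"].to_numpy()
    if np.isnan(scores).any():
        i = int(np.flatnonzero(np.isnan(scores))[0])
        row = peaks.df.iloc[i]
        raise ValueError(
            f"peak {row['chrom']}:{row['start']}-{row['end']} (name={row['name']!r}) has no score"
        )
    return peaks.subset(np.flatnonzero(scores > min_score))


def count_flanking(sites: IntervalSet, peaks: IntervalSet, window_bp: int = 10000) -> tuple[int, int]:
    """(sites with >=1 peak within window, total site-peak proximity occasions).

    Each (site, peak) pair with edge gap <= window_bp counts once; a peak
    within the window of k sites therefore contributes k occasions.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    hits = pairs_within(sites, peaks, window_bp)
    return int(hits["a_index"].nunique()), int(len(hits))
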