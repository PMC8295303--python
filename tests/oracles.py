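"""Brute-force O(n*m) reference implementations.

These deliberately share no code with the package's search engine: all
answers come from exhaustive all-vs-all scans over the raw coordinate
arrays, so agreement is meaningful evidence of correctness.
"""

from __future__ import annotations

import numpy as np


def gap(qs: int, qe: int, ss: int, se: int) -> int:
    """Edge-to-edge gap between half-open intervals; 0 when overlapping."""
    return max(ss - qe, qs - se, 0)


def overlap(qs: int, qe: int, ss: int, se: int) -> int:
    return min(qe, se) - max(qs, ss)


def _rows(iset):
    return list(zip(iset.df["chrom"], iset.df["start"], iset.df["end"]))


def overlap_pairs(a, b, min_ov: int = 1):
    out = []
    for i, (ca, sa, ea) in enumerate(_rows(a)):
        for j, (cb, sb, eb) in enumerate(_rows(b)):
            if ca == cb and overlap(sa, ea, sb, eb) >= min_ov:
                out.append((i, j, overlap(sa, ea, sb, eb)))
    return sorted(out)


def pairs_within(a, b, max_gap: int):
    out = []
    for i, (ca, sa, ea) in enumerate(_rows(a)):
        for j, (cb, sb, eb) in enumerate(_rows(b)):
            if ca == cb and gap(sa, ea, sb, eb) <= max_gap:
                out.append((i, j, gap(sa, ea, sb, eb)))
    return sorted(out)


def subtract(control, case, min_ov: int = 1):
    """Indices of control intervals with no qualifying case overlap."""
    keep = []
    for i, (ca, sa, ea) in enumerate(_rows(control)):
        if not any(
            ca == cb and overlap(sa, ea, sb, eb) >= min_ov for cb, sb, eb in _rows(case)
        ):
            keep.append(i)
    return keep


def nearest(query, subject):
    """Per-query minimum edge gap over all same-chromosome subjects (None if none)."""
    out = []
    for cq, sq, eq in _rows(query):
        best = None
        for cs, ss, es in _rows(subject):
            if cq == cs:
                d = gap(sq, eq, ss, es)
                best = d if best is None else min(best, d)
        out.append(best)
    return out


def window_sites(sites, regions, window: int):
    """Indices of sites retained by the window rule (0 => true overlap)."""
    keep = []
    for i, (cq, sq, eq) in enumerate(_rows(sites)):
        for cs, ss, es in _rows(regions):
            if cq != cs:
                continue
            if window == 0:
                if overlap(sq, eq, ss, es) >= 1:
                    keep.append(i)
                    break
            elif gap(sq, eq, ss, es) <= window:
                keep.append(i)
                break
    return keep


def flanking(sites, peaks, window: int):
    flanked = set()
    occasions = 0
    for i, (cq, sq, eq) in enumerate(_rows(sites)):
        for cs, ss, es in _rows(peaks):
            if cq == cs and gap(sq, eq, ss, es) <= window:
                flanked.add(i)
                occasions += 1
    return len(flanked), occasions


def tad_table(tads, set_a, set_b):
    def member(ct, st, et, feats):
        return any(ct == cf and overlap(st, et, sf, ef) >= 1 for cf, sf, ef in _rows(feats))

    cells = [0, 0, 0, 0]  # both, a_only, b_only, neither
    for ct, st, et in _rows(tads):
        a = member(ct, st, et, set_a)
        b = member(ct, st, et, set_b)
        cells[0 if a and b else 1 if a else 2 if b else 3] += 1
    return tuple(cells)


def anchored_total(anchors, features, halfwidth: int) -> int:
    """Number of (anchor, feature) midpoint pairs with |offset| <= halfwidth."""
    total = 0
    for ca, sa, ea in _rows(anchors):
        for cf, sf, ef in _rows(features):
            if ca == cf and abs((sf + ef) / 2 - (sa + ea) / 2) <= halfwidth:
                total += 1
    return total


def chi2_from_observed(cells: np.ndarray) -> float:
    """Sum (O-E)^2/E over a 2x2 table with margin-product expectations."""
    obs = np.asarray(cells, float).reshape(2, 2)
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    return float(((obs - exp) ** 2 / exp).sum())


def area2_counts(area2_rows, feats, window: int):
    """Per-area2 (nearest gap or None, count with gap < window)."""
    out = []
    for ca, sa, ea in area2_rows:
        best, cnt = None, 0
        for cf, sf, ef in _rows(feats):
            if ca != cf:
                continue
            d = gap(sa, ea, sf, ef)
            best = d if best is None else min(best, d)
            if d < window:
                cnt += 1
        out.append((best, cnt))
    return out
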