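"""Shared half-open interval engine.

Every overlap operation in the package (gene/anchor/peak/region queries) goes
through these functions so the semantics — 0-based, half-open, overlap means
>= 1 bp of intersection — are identical everywhere.

Intervals are pandas DataFrames with at least ``chrom``, ``start``, ``end``.
The core query uses sorted starts plus a running maximum of ends per
chromosome, giving O((n + m) log n) overall.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["overlaps_any", "count_overlaps", "merge_intervals", "coverage_per_bin"]


def _validate(df: pd.DataFrame) -> None:
    if len(df) and (df["end"].to_numpy() <= df["start"].to_numpy()).any():
        raise ValueError("intervals must satisfy start < end (half-open)")


def _per_chrom_index(subject: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    index = {}
    for chrom, grp in subject.groupby("chrom", sort=False):
        order = np.argsort(grp["start"].to_numpy(), kind="stable")
        starts = grp["start"].to_numpy()[order]
        ends = np.maximum.accumulate(grp["end"].to_numpy()[order])
        index[chrom] = (starts, ends)
    return index


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: does it intersect any subject interval?"""
    _validate(query)
    _validate(subject)
    index = _per_chrom_index(subject)
    out = np.zeros(len(query), dtype=bool)
    for chrom, grp in query.groupby("chrom", sort=False):
        if chrom not in index:
            continue
        starts, cummax_end = index[chrom]
        qs = grp["start"].to_numpy()
        qe = grp["end"].to_numpy()
        # subjects with start < query end; among them, does any end > query start?
        k = np.searchsorted(starts, qe, side="left")
        hit = (k > 0) & (cummax_end[np.maximum(k - 1, 0)] > qs)
        out[grp.index.to_numpy()] = hit
    return out


def count_overlaps(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Number of subject intervals intersecting each query interval."""
    _validate(query)
    _validate(subject)
    out = np.zeros(len(query), dtype=int)
    for chrom, sgrp in subject.groupby("chrom", sort=False):
        qmask = query["chrom"] == chrom
        if not qmask.any():
            continue
        qs = query.loc[qmask, "start"].to_numpy()
        qe = query.loc[qmask, "end"].to_numpy()
        ss = np.sort(sgrp["start"].to_numpy())
        se = np.sort(sgrp["end"].to_numpy())
        # started before query end, minus already ended at/before query start
        n = np.searchsorted(ss, qe, side="left") - np.searchsorted(se, qs, side="right")
        out[np.flatnonzero(qmask.to_numpy())] = n
    return out


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: overlapping or book-ended runs collapsed per chrom."""
    _validate(df)
    rows = []
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def coverage_per_bin(bins, intervals: pd.DataFrame) -> np.ndarray:
    """Base pairs of interval union covering each bin of a BinTable.

    Overlapping intervals are merged first, so coverage never exceeds the bin
    width and total coverage equals the union's total length (clipped to the
    binned genome).
    """
    merged = merge_intervals(intervals)
    out = np.zeros(bins.n_bins, dtype=float)
    bs = bins.bin_size
    for chrom, grp in merged.groupby("chrom", sort=False):
        if chrom not in bins.chroms:
            continue
        sl = bins.chrom_slice(chrom)
        size = bins.chrom_sizes[bins.chroms.index(chrom)]
        for s, e in zip(grp["start"], grp["end"]):
            s = max(0, int(s))
            e = min(size, int(e))
            if e <= s:
                continue
            b0, b1 = s // bs, (e - 1) // bs
            for b in range(b0, b1 + 1):
                lo = max(s, b * bs)
                hi = min(e, (b + 1) * bs)
                out[sl.start + b] += hi - lo
    return out
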