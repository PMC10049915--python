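"""Insulation-score computation and TAD-boundary calling.

The insulation score of bin b is the mean balanced contact value in a diamond
window — contacts between the w bins left of b and the w bins right of b,
excluding b's own row and column — log2-normalized by the chromosome mean of
the diamond means.  TAD boundaries are strong local minima of the score;
boundary strength is the mean rise to the nearest flanking local maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .balance import BalancedMatrix
from .io import BinTable

__all__ = ["InsulationTrack", "insulation_track", "call_boundaries"]


@dataclass
class InsulationTrack:
    bins: BinTable
    score: np.ndarray       # log2 normalized; NaN where the window does not fit
    window_bp: int
    condition: str = ""


def insulation_track(
    bal: BalancedMatrix, window_bp: int = 200_000, condition: str = ""
) -> InsulationTrack:
    """Per-bin insulation score from a balanced matrix.

    Scores are defined only where the full window fits inside the chromosome;
    masked bins inside the diamond are ignored (mean over remaining pairs).
    The chromosome-mean normalization makes the mean of 2**score per
    chromosome 1, and any global rescaling of the matrix cancels exactly.
    """
    bins = bal.bins
    if window_bp % bins.bin_size != 0:
        raise ValueError("window_bp must be a multiple of the bin size")
    w = window_bp // bins.bin_size
    score = np.full(bins.n_bins, np.nan)
    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        n = sl.stop - sl.start
        if n < 2 * w + 1:
            warnings.warn(f"{chrom}: window larger than chromosome, skipped")
            continue
        dense = bal.dense_chrom(chrom)
        raw = np.full(n, np.nan)
        for b in range(w, n - w):
            diamond = dense[b - w : b, b + 1 : b + w + 1]
            m = np.nanmean(diamond) if np.isfinite(diamond).any() else np.nan
            raw[b] = m
        ok = np.isfinite(raw) & (raw > 0)
        if ok.sum() == 0:
            continue
        chrom_mean = raw[ok].mean()
        vals = np.full(n, np.nan)
        vals[ok] = np.log2(raw[ok] / chrom_mean)
        score[sl] = vals
    return InsulationTrack(bins, score, window_bp, condition)


@dataclass
class Boundary:
    chrom: str
    bin: int           # global bin index
    start: int
    end: int
    strength: float


def _smooth(s: np.ndarray, half: int) -> np.ndarray:
    """NaN-aware centred moving average with half-width ``half`` bins."""
    if half <= 0:
        return s.copy()
    out = np.full_like(s, np.nan)
    for b in range(len(s)):
        lo, hi = max(0, b - half), min(len(s), b + half + 1)
        win = s[lo:hi]
        if np.isfinite(win).any():
            out[b] = np.nanmean(win)
    out[~np.isfinite(s)] = np.nan
    return out


def call_boundaries(
    track: InsulationTrack,
    delta_window_bp: int = 100_000,
    min_strength: float = 0.1,
    smooth_bins: int = 2,
) -> tuple[list[Boundary], pd.DataFrame]:
    """Boundaries at strong local minima of the insulation score.

    The score is first denoised with a centred moving average of half-width
    ``smooth_bins``.  A bin is a candidate if its smoothed score is a local
    minimum (ties broken leftward).  Strength is the mean of (highest score
    within ``delta_window_bp`` on that side - minimum) over the two sides;
    candidates with strength >= ``min_strength`` are reported.  Of two
    boundaries closer than ``delta_window_bp`` only the deeper one is kept.
    TAD intervals are the spans between consecutive boundaries and chromosome
    ends, so they tile each chromosome.
    """
    if not np.isfinite(track.score).any():
        raise ValueError("empty insulation track")
    bins = track.bins
    dw = max(1, delta_window_bp // bins.bin_size)
    df = bins.to_dataframe()
    boundaries: list[Boundary] = []
    tad_rows = []
    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        s = _smooth(track.score[sl], smooth_bins)
        n = len(s)
        cand = []
        for b in range(n):
            if not np.isfinite(s[b]):
                continue
            left = s[b - 1] if b > 0 and np.isfinite(s[b - 1]) else np.inf
            right = s[b + 1] if b < n - 1 and np.isfinite(s[b + 1]) else np.inf
            if s[b] < left and s[b] <= right:
                cand.append(b)
        strong: list[tuple[int, float]] = []
        for b in cand:
            strengths = []
            for step in (-1, 1):
                lo = max(0, b - dw) if step < 0 else b + 1
                hi = b if step < 0 else min(n, b + dw + 1)
                win = s[lo:hi]
                if np.isfinite(win).any():
                    strengths.append(float(np.nanmax(win)) - s[b])
            if len(strengths) == 2 and float(np.mean(strengths)) >= min_strength:
                strong.append((b, float(np.mean(strengths))))
        # non-maximum suppression: keep the deeper of two close boundaries
        kept: list[tuple[int, float]] = []
        for b, strength in strong:
            if kept and b - kept[-1][0] < dw:
                if s[b] < s[kept[-1][0]]:
                    kept[-1] = (b, strength)
            else:
                kept.append((b, strength))
        for b, strength in kept:
            g = sl.start + b
            boundaries.append(
                Boundary(
                    chrom,
                    g,
                    int(df["start"].iloc[g]),
                    int(df["end"].iloc[g]),
                    strength,
                )
            )
        # TAD intervals between consecutive boundaries and chromosome ends
        chrom_bounds = sorted(b.bin - sl.start for b in boundaries if b.chrom == chrom)
        edges = [0] + chrom_bounds + [n]
        for a, z in zip(edges[:-1], edges[1:]):
            if z > a:
                tad_rows.append(
                    (
                        chrom,
                        int(df["start"].iloc[sl.start + a]),
                        int(df["end"].iloc[sl.start + z - 1]),
                    )
                )
    tads = pd.DataFrame(tad_rows, columns=["chrom", "start", "end"])
    return boundaries, tads
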