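"""A/B compartment calling from per-chromosome correlation maps and
condition-to-condition switch detection.

The compartment signal is the leading eigenvector (PC1) of each chromosome's
Pearson-correlation map of O/E profiles.  The eigenvector sign is arbitrary,
so each chromosome's PC1 is oriented so that it correlates positively with
gene density; bins with PC1 > 0 are A compartments, all others B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BinTable

__all__ = [
    "CompartmentTrack",
    "call_pc1_compartments",
    "compartment_summary",
    "compartment_switches",
]


@dataclass
class CompartmentTrack:
    """Oriented PC1 value and A/B label per bin (NaN/masked where undefined)."""

    bins: BinTable
    pc1: np.ndarray            # NaN on masked bins
    labels: np.ndarray         # 'A', 'B' or '' (masked)
    condition: str = ""

    def __post_init__(self) -> None:
        ok = self.labels != ""
        if not np.array_equal(self.labels[ok] == "A", self.pc1[ok] > 0):
            raise ValueError("labels must be A exactly where PC1 > 0")


def _leading_eigvec(corr: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(corr)
    return vecs[:, -1]


def call_pc1_compartments(
    corr_by_chrom: dict[str, np.ndarray],
    bins: BinTable,
    gene_density: np.ndarray,
    condition: str = "",
) -> CompartmentTrack:
    """Call compartments from correlation maps, oriented by gene density.

    PC1 is the eigenvector of the correlation matrix restricted to valid
    (non-NaN) bins.  Orientation: flip the sign when Pearson correlation with
    the per-bin gene density is negative (ties broken by making the vector sum
    non-negative), so A ends up the gene-rich class.  The A/B rule is strict:
    A iff PC1 > 0 (zero goes to B).
    """
    pc1 = np.full(bins.n_bins, np.nan)
    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        corr = corr_by_chrom[chrom]
        valid = ~np.all(np.isnan(corr), axis=0)
        sub = corr[np.ix_(valid, valid)]
        if valid.sum() < 3:
            warnings.warn(f"{chrom}: too few valid bins, chromosome masked")
            continue
        sub = np.nan_to_num(sub, nan=0.0)
        if np.allclose(sub, sub.flat[0]):
            warnings.warn(f"{chrom}: degenerate correlation matrix, masked")
            continue
        vec = _leading_eigvec(sub)
        dens = gene_density[sl][valid]
        if np.std(dens) > 0 and np.std(vec) > 0:
            r = np.corrcoef(vec, dens)[0, 1]
        else:
            r = 0.0
        if r < 0 or (r == 0 and vec.sum() < 0):
            vec = -vec
        out = np.full(sl.stop - sl.start, np.nan)
        out[valid] = vec
        pc1[sl] = out

    labels = np.where(np.isnan(pc1), "", np.where(pc1 > 0, "A", "B")).astype(object)
    return CompartmentTrack(bins, pc1, np.asarray(labels, dtype="<U1"), condition)


def compartment_summary(track: CompartmentTrack) -> dict:
    """Genome-wide and per-chromosome base-pair fractions of A and B."""
    df = track.bins.to_dataframe()
    width = (df["end"] - df["start"]).to_numpy().astype(float)
    out: dict = {"per_chrom": {}}
    for scope, sel in [("genome", np.ones(len(df), bool))] + [
        (chrom, (df["chrom"] == chrom).to_numpy()) for chrom in track.bins.chroms
    ]:
        lab = track.labels[sel]
        w = width[sel]
        denom = w[lab != ""].sum()
        fa = w[lab == "A"].sum() / denom if denom else float("nan")
        fb = w[lab == "B"].sum() / denom if denom else float("nan")
        entry = {"A_fraction": float(fa), "B_fraction": float(fb)}
        if scope == "genome":
            out.update(entry)
        else:
            out["per_chrom"][scope] = entry
    return out


def compartment_switches(
    track_ck: CompartmentTrack, track_pd: CompartmentTrack
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Regions whose label flips between conditions.

    Bins masked in either condition are excluded; maximal runs of adjacent
    same-direction switched bins are merged into one region (never across a
    chromosome boundary).  Returns the region table (chrom, start, end,
    direction, n_bins) and counts per direction.
    """
    if track_ck.bins != track_pd.bins:
        raise ValueError("tracks must share one bin table")
    bins = track_ck.bins
    a, b = track_ck.labels, track_pd.labels
    direction = np.where(
        (a == "A") & (b == "B"), "A2B", np.where((a == "B") & (b == "A"), "B2A", "")
    )
    df = bins.to_dataframe()
    rows = []
    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        d = direction[sl]
        start_bin = None
        for k in range(len(d) + 1):
            cur = d[k] if k < len(d) else ""
            prev = d[k - 1] if k > 0 else ""
            if cur != prev:
                if prev != "" and start_bin is not None:
                    rows.append(
                        (
                            chrom,
                            int(df["start"].iloc[sl.start + start_bin]),
                            int(df["end"].iloc[sl.start + k - 1]),
                            prev,
                            k - start_bin,
                        )
                    )
                start_bin = k if cur != "" else None
    regions = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "direction", "n_bins"]
    )
    counts = {
        "A2B": int((regions["direction"] == "A2B").sum()) if len(regions) else 0,
        "B2A": int((regions["direction"] == "B2A").sum()) if len(regions) else 0,
    }
    return regions, counts
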