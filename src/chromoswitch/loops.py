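"""Chromatin-loop detection by local-background enrichment and two-condition
differential classification.

The caller is a single-resolution donut filter: each cis pixel within the
distance cap is compared against four local neighbourhoods (donut annulus,
lower-left quadrant, horizontal and vertical stripes).  The local expected is
the neighbourhood's balanced sum divided by its decay-expected sum, times the
pixel's decay expected, rescaled through the balancing weights to the raw
scale; significance is the Poisson upper tail of the raw count, with BH-FDR
applied within log2-spaced distance strata separately per neighbourhood.  A
called pixel must be significant against all four backgrounds and enriched
over the donut and lower-left; adjacent called pixels merge to centroid loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve
from scipy.stats import poisson

from .balance import BalancedMatrix, OEMatrix
from .stats import bh_adjust

__all__ = [
    "call_loops",
    "merge_and_score",
    "classify_anchors",
    "loop_length_summary",
]

NEIGHBORHOODS = ("donut", "lower_left", "horizontal", "vertical")


def _kernels(outer: int, inner: int) -> dict[str, np.ndarray]:
    """0/1 masks over (di, dj) offsets in [-outer, outer]^2."""
    size = 2 * outer + 1
    di, dj = np.meshgrid(
        np.arange(-outer, outer + 1), np.arange(-outer, outer + 1), indexing="ij"
    )
    in_box = (np.abs(di) <= inner) & (np.abs(dj) <= inner)
    donut = ~in_box & (di != 0) & (dj != 0)
    lower_left = (di >= 1) & (di <= outer) & (dj <= -1) & (dj >= -outer) & ~in_box
    horizontal = (np.abs(di) <= 1) & (np.abs(dj) > inner)
    vertical = (np.abs(dj) <= 1) & (np.abs(di) > inner)
    return {
        "donut": donut.astype(float),
        "lower_left": lower_left.astype(float),
        "horizontal": horizontal.astype(float),
        "vertical": vertical.astype(float),
    }


def _neighborhood_sums(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Correlation of x with the offset mask (sum of x over each pixel's
    neighbourhood), zero-padded edges."""
    return fftconvolve(x, kernel[::-1, ::-1], mode="same")


@dataclass
class LoopCallParams:
    max_dist_bp: int = 2_000_000
    donut_outer: int = 5
    donut_inner: int = 2
    fdr: float = 0.1
    min_enrichment: float = 1.5   # over donut and lower-left
    min_dist_bins: int = 2
    # sparse far-diagonal strata can make near-zero local lambdas "significant"
    # at raw count 1; a raw-count floor removes those degenerate calls
    min_raw: float = 4.0


def call_loops(
    bal: BalancedMatrix,
    expected,
    params: LoopCallParams | None = None,
    condition: str = "",
) -> pd.DataFrame:
    """Call loops on a balanced matrix with its expected profile.

    Returns a BEDPE-like frame: chrom, bin1, bin2, start1, end1, start2, end2,
    raw count, balanced value, per-neighbourhood enrichment and q-value,
    cluster size.  Pixels whose neighbourhood geometry has no valid pixels
    (chromosome edge, fully masked surroundings) are skipped.
    """
    params = params or LoopCallParams()
    bins = bal.bins
    kernels = _kernels(params.donut_outer, params.donut_inner)
    max_d = max(params.min_dist_bins, params.max_dist_bp // bins.bin_size)

    records = []
    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        n = sl.stop - sl.start
        dense_bal = bal.dense_chrom(chrom)           # NaN on masked
        raw = bal.raw.dense_chrom(chrom)
        w = bal.balance.weights[sl]
        valid = np.isfinite(dense_bal)
        np.fill_diagonal(valid, False)
        W = np.where(valid, dense_bal, 0.0)

        ev = expected.values[chrom]
        i = np.arange(n)
        dmat = np.abs(i[:, None] - i[None, :])
        E = np.where(valid, np.where(dmat >= 1, ev[np.minimum(dmat, n - 1)], 0.0), 0.0)
        E = np.nan_to_num(E)

        iu, ju = np.triu_indices(n, k=params.min_dist_bins)
        d = ju - iu
        cand = d <= max_d
        iu, ju, d = iu[cand], ju[cand], d[cand]

        lam = {}
        enr = {}
        ok = np.ones(len(iu), dtype=bool)
        for name, K in kernels.items():
            num = _neighborhood_sums(W, K)[iu, ju]
            den = _neighborhood_sums(E, K)[iu, ju]
            good = den > 0
            ok &= good
            ratio = np.where(good, num / np.where(good, den, 1.0), np.nan)
            e_local_bal = ratio * ev[d]
            with np.errstate(divide="ignore", invalid="ignore"):
                lam[name] = e_local_bal / (w[iu] * w[ju])
                enr[name] = dense_bal[iu, ju] / e_local_bal
        ok &= np.isfinite(w[iu]) & np.isfinite(w[ju])
        for name in NEIGHBORHOODS:
            ok &= np.isfinite(lam[name]) & (lam[name] > 0)
        iu, ju, d = iu[ok], ju[ok], d[ok]
        if len(iu) == 0:
            continue
        lam = {k: v[ok] for k, v in lam.items()}
        enr = {k: v[ok] for k, v in enr.items()}
        obs = raw[iu, ju]

        qs = {}
        strata = np.floor(np.log2(d)).astype(int)
        for name in NEIGHBORHOODS:
            p = poisson.sf(obs - 1, lam[name])
            q = np.ones_like(p)
            for s in np.unique(strata):
                m = strata == s
                q[m] = bh_adjust(p[m])
            qs[name] = q

        called = np.ones(len(iu), dtype=bool)
        for name in NEIGHBORHOODS:
            called &= qs[name] <= params.fdr
        called &= enr["donut"] >= params.min_enrichment
        called &= enr["lower_left"] >= params.min_enrichment
        called &= obs >= params.min_raw
        if not called.any():
            continue

        # merge adjacent called pixels into centroid loops
        mask = np.zeros((n, n), dtype=bool)
        mask[iu[called], ju[called]] = True
        labels, n_clusters = ndimage.label(mask, structure=np.ones((3, 3), int))
        lab_at = labels[iu, ju]
        for c in range(1, n_clusters + 1):
            members = np.flatnonzero(called & (lab_at == c))
            weights_c = np.maximum(obs[members], 1e-9)
            ci = int(round(np.average(iu[members], weights=weights_c)))
            cj = int(round(np.average(ju[members], weights=weights_c)))
            rep = members[np.argmin(qs["donut"][members])]
            records.append(
                {
                    "chrom": chrom,
                    "bin1": sl.start + ci,
                    "bin2": sl.start + cj,
                    "start1": ci * bins.bin_size,
                    "end1": (ci + 1) * bins.bin_size,
                    "start2": cj * bins.bin_size,
                    "end2": (cj + 1) * bins.bin_size,
                    "raw": float(obs[rep]),
                    "balanced": float(W[iu[rep], ju[rep]]),
                    **{f"enr_{k}": float(enr[k][rep]) for k in NEIGHBORHOODS},
                    **{f"q_{k}": float(qs[k][rep]) for k in NEIGHBORHOODS},
                    "cluster_size": len(members),
                    "condition": condition,
                }
            )
    cols = [
        "chrom", "bin1", "bin2", "start1", "end1", "start2", "end2",
        "raw", "balanced",
        *[f"enr_{k}" for k in NEIGHBORHOODS],
        *[f"q_{k}" for k in NEIGHBORHOODS],
        "cluster_size", "condition",
    ]
    return pd.DataFrame(records, columns=cols)


def _footprint_oe(oe: OEMatrix, chrom: str, b1: int, b2: int, half: int) -> float:
    """Mean linear O/E over the (2*half+1)^2 footprint centred on (b1, b2)."""
    sl = oe.bins.chrom_slice(chrom)
    dense = oe.ratio_dense_chrom(chrom)
    i, j = b1 - sl.start, b2 - sl.start
    n = dense.shape[0]
    win = dense[
        max(0, i - half) : min(n, i + half + 1),
        max(0, j - half) : min(n, j + half + 1),
    ]
    if not np.isfinite(win).any():
        return float("nan")
    return float(np.nanmean(win))


def merge_and_score(
    loops_ck: pd.DataFrame,
    loops_pd: pd.DataFrame,
    oe_ck: OEMatrix,
    oe_pd: OEMatrix,
    cutoff: float = 1.0,
    match_tol_bins: int = 1,
    footprint_half: int = 0,
) -> pd.DataFrame:
    """Merged two-condition loop set with fold-change classes.

    Loops from the two call sets whose anchors lie within ``match_tol_bins``
    in both anchors are merged (coordinates from the CK call).  Per-condition
    loop strength is the mean linear O/E over a (2*footprint_half+1)^2 pixel
    footprint at the loop centre; log2FC = log2(OE_PD / OE_CK) and the class
    is enriched (>= cutoff), depleted (<= -cutoff) or stable.  ``origin``
    records the call-set partition: common / CK-specific / PD-specific.
    Loops without a finite positive OE in both conditions get class
    ``unscored``.
    """
    used_pd = np.zeros(len(loops_pd), dtype=bool)
    merged = []
    for row in loops_ck.itertuples():
        match = None
        for k, prow in enumerate(loops_pd.itertuples()):
            if used_pd[k] or prow.chrom != row.chrom:
                continue
            if (
                abs(prow.bin1 - row.bin1) <= match_tol_bins
                and abs(prow.bin2 - row.bin2) <= match_tol_bins
            ):
                match = k
                break
        if match is not None:
            used_pd[match] = True
            merged.append((row.chrom, row.bin1, row.bin2, "common"))
        else:
            merged.append((row.chrom, row.bin1, row.bin2, "CK-specific"))
    for k, prow in enumerate(loops_pd.itertuples()):
        if not used_pd[k]:
            merged.append((prow.chrom, prow.bin1, prow.bin2, "PD-specific"))

    bins = oe_ck.bins
    rows = []
    for chrom, b1, b2, origin in merged:
        v_ck = _footprint_oe(oe_ck, chrom, b1, b2, footprint_half)
        v_pd = _footprint_oe(oe_pd, chrom, b1, b2, footprint_half)
        if np.isfinite(v_ck) and np.isfinite(v_pd) and v_ck > 0 and v_pd > 0:
            fc = float(np.log2(v_pd / v_ck))
            cls = "enriched" if fc >= cutoff else "depleted" if fc <= -cutoff else "stable"
        elif np.isfinite(v_pd) and v_pd > 0 and v_ck == 0:
            # observed in PD only: infinitely enriched
            fc = float("inf")
            cls = "enriched"
        elif np.isfinite(v_ck) and v_ck > 0 and v_pd == 0:
            fc = float("-inf")
            cls = "depleted"
        else:
            fc = float("nan")
            cls = "unscored"
        rows.append(
            {
                "chrom": chrom,
                "bin1": b1,
                "bin2": b2,
                "start1": (b1 - bins.chrom_slice(chrom).start) * bins.bin_size,
                "end1": (b1 - bins.chrom_slice(chrom).start + 1) * bins.bin_size,
                "start2": (b2 - bins.chrom_slice(chrom).start) * bins.bin_size,
                "end2": (b2 - bins.chrom_slice(chrom).start + 1) * bins.bin_size,
                "oe_CK": v_ck,
                "oe_PD": v_pd,
                "log2fc": fc,
                "class": cls,
                "origin": origin,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "bin1", "bin2", "start1", "end1", "start2", "end2",
            "oe_CK", "oe_PD", "log2fc", "class", "origin",
        ],
    )


def classify_anchors(loops: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Anchor classes (proximal = overlaps a gene) and loop styles P-P/D-P/D-D."""
    from .intervals import overlaps_any

    if loops.empty:
        return loops.assign(anchor1_class=[], anchor2_class=[], style=[])
    a1 = loops[["chrom", "start1", "end1"]].rename(
        columns={"start1": "start", "end1": "end"}
    )
    a2 = loops[["chrom", "start2", "end2"]].rename(
        columns={"start2": "start", "end2": "end"}
    )
    p1 = overlaps_any(a1.reset_index(drop=True), genes)
    p2 = overlaps_any(a2.reset_index(drop=True), genes)
    c1 = np.where(p1, "proximal", "distal")
    c2 = np.where(p2, "proximal", "distal")
    style = []
    for x, y in zip(c1, c2):
        n_prox = (x == "proximal") + (y == "proximal")
        style.append({2: "P-P", 1: "D-P", 0: "D-D"}[n_prox])
    out = loops.copy()
    out["anchor1_class"] = c1
    out["anchor2_class"] = c2
    out["style"] = style
    return out


def loop_length_summary(merged: pd.DataFrame) -> pd.DataFrame:
    """Mean/median anchor distance (bp) per origin class (common/specific)."""
    if merged.empty:
        return pd.DataFrame(columns=["origin", "n", "mean_bp", "median_bp"])
    lengths = merged["start2"] - merged["start1"]
    df = merged.assign(length_bp=lengths)
    out = (
        df.groupby("origin")["length_bp"]
        .agg(n="size", mean_bp="mean", median_bp="median")
        .reset_index()
    )
    return out
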