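"""Cross-omics integration: compartment stratification of genes, expression
and histone marks; switch-region x differential-expression overlap;
condition-specific peaks; loop-anchor mark fractions; GO enrichment.

Differential-expression statistics are consumed from an input table (log2
fold change PD vs CK and an adjusted p-value per gene); the flag applied
throughout is |log2FC| >= 1 and adjusted p < 0.05.  All overlap queries share
the half-open interval engine in :mod:`chromoswitch.intervals`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import coverage_per_bin, overlaps_any
from .io import BinTable
from .stats import bh_adjust, hypergeom_sf, wilcoxon_rank_sum

__all__ = [
    "expression_prep",
    "de_flag",
    "ab_gene_stats",
    "ab_peak_stats",
    "region_de_overlap",
    "specific_peaks",
    "de_by_peak_group",
    "anchor_mark_fraction",
    "go_hypergeometric",
]

LOG2FC_CUTOFF = 1.0
PADJ_CUTOFF = 0.05


def expression_prep(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series,
    de_stats: pd.DataFrame,
) -> pd.DataFrame:
    """FPKM table with DE flags.

    FPKM = count * 1e9 / (gene length in bp * library size).  ``counts`` has
    gene_id plus one column per sample; ``library_sizes`` maps sample to total
    mapped fragments.  Genes without a length are dropped with a warning.
    ``de_stats`` must carry gene_id, log2fc, padj.
    """
    import warnings

    known = counts["gene_id"].isin(gene_lengths.index)
    if (~known).any():
        warnings.warn(f"{(~known).sum()} genes without length excluded")
        counts = counts[known]
    lengths = gene_lengths.loc[counts["gene_id"]].to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    out = pd.DataFrame({"gene_id": counts["gene_id"].to_numpy()})
    for sample in library_sizes.index:
        c = counts[sample].to_numpy(dtype=float)
        out[f"fpkm_{sample}"] = c * 1e9 / (lengths * float(library_sizes[sample]))
    out = out.merge(de_stats[["gene_id", "log2fc", "padj"]], on="gene_id", how="left")
    return de_flag(out)


def de_flag(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the DE cutoff |log2FC| >= 1 and adjusted p < 0.05 (strict)."""
    out = table.copy()
    is_de = (out["log2fc"].abs() >= LOG2FC_CUTOFF) & (out["padj"] < PADJ_CUTOFF)
    out["de"] = is_de.fillna(False)
    out["de_direction"] = np.where(
        out["de"], np.where(out["log2fc"] > 0, "up", "down"), ""
    )
    return out


def _gene_bins(bins: BinTable, genes: pd.DataFrame) -> np.ndarray:
    """Gene -> bin assignment by gene midpoint (deterministic)."""
    mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
    return np.array(
        [bins.bin_of(c, int(p)) for c, p in zip(genes["chrom"], mid)]
    )


def _mean_expression(expr: pd.DataFrame, condition: str) -> np.ndarray:
    cols = [c for c in expr.columns if c.startswith(f"fpkm_{condition}")]
    if not cols:
        raise ValueError(f"no FPKM columns for condition {condition}")
    return expr[cols].to_numpy(dtype=float).mean(axis=1)


def ab_gene_stats(
    track, genes: pd.DataFrame, expr: pd.DataFrame, condition: str
) -> dict:
    """Gene density and expression level stratified by compartment.

    Density compares per-bin gene counts between A and B bins; expression
    compares per-gene mean FPKM (genes assigned to a compartment by their
    midpoint bin).  Both use the two-sided Wilcoxon rank-sum test.
    """
    bins = track.bins
    gene_bin = _gene_bins(bins, genes)
    counts = np.zeros(bins.n_bins)
    np.add.at(counts, gene_bin, 1)
    lab = track.labels
    a_bins, b_bins = lab == "A", lab == "B"
    width_mb = bins.bin_size / 1e6

    fpkm = _mean_expression(
        expr.set_index("gene_id").loc[genes["name"]].reset_index(), condition
    )
    gene_lab = lab[gene_bin]
    expr_a, expr_b = fpkm[gene_lab == "A"], fpkm[gene_lab == "B"]
    out = {
        "gene_density_per_mb": {
            "A": float(counts[a_bins].sum() / (a_bins.sum() * width_mb))
            if a_bins.any() else float("nan"),
            "B": float(counts[b_bins].sum() / (b_bins.sum() * width_mb))
            if b_bins.any() else float("nan"),
        },
        "density_wilcoxon_p": wilcoxon_rank_sum(counts[a_bins], counts[b_bins])
        if a_bins.any() and b_bins.any() else float("nan"),
        "mean_fpkm": {
            "A": float(expr_a.mean()) if len(expr_a) else float("nan"),
            "B": float(expr_b.mean()) if len(expr_b) else float("nan"),
        },
        "n_genes": {"A": int(len(expr_a)), "B": int(len(expr_b))},
    }
    if len(expr_a) >= 2 and len(expr_b) >= 2:
        out["expression_wilcoxon_p"] = wilcoxon_rank_sum(expr_a, expr_b)
    else:
        out["expression_wilcoxon_p"] = float("nan")
    return out


def ab_peak_stats(track, peaks: pd.DataFrame) -> dict:
    """Histone-mark coverage (bp of peak per bin) compared between A and B bins."""
    if peaks.empty:
        raise ValueError("empty peak set")
    bins = track.bins
    cov = coverage_per_bin(bins, peaks)
    lab = track.labels
    a, b = cov[lab == "A"], cov[lab == "B"]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("no unmasked bins in one compartment class")
    return {
        "mean_coverage_bp": {"A": float(a.mean()), "B": float(b.mean())},
        "total_coverage_bp": {"A": float(a.sum()), "B": float(b.sum())},
        "wilcoxon_p": wilcoxon_rank_sum(a, b),
        "n_bins": {"A": int(len(a)), "B": int(len(b))},
    }


def region_de_overlap(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    expr: pd.DataFrame,
    direction_filter: str | None = None,
) -> pd.DataFrame:
    """Genes overlapping regions, filtered by DE direction.

    ``regions`` may carry a ``direction`` column (e.g. switch regions A2B/B2A)
    which is propagated; ``direction_filter`` restricts to 'up' or 'down'
    DE genes.  Returns one row per (region class, gene).
    """
    flagged = expr if "de" in expr.columns else de_flag(expr)
    gene_iv = genes.rename(columns={"name": "gene_id"})[
        ["chrom", "start", "end", "gene_id"]
    ].reset_index(drop=True)
    rows = []
    classes = (
        regions["direction"].unique().tolist()
        if "direction" in regions.columns and len(regions)
        else ["all"] if len(regions) else []
    )
    for cls in classes:
        sub = (
            regions[regions["direction"] == cls]
            if "direction" in regions.columns
            else regions
        )
        hit = overlaps_any(gene_iv, sub)
        hits = gene_iv[hit].merge(
            flagged[["gene_id", "log2fc", "padj", "de", "de_direction"]],
            on="gene_id",
            how="left",
        )
        hits = hits[hits["de"].fillna(False)]
        if direction_filter:
            hits = hits[hits["de_direction"] == direction_filter]
        for r in hits.itertuples():
            rows.append((cls, r.gene_id, r.de_direction, r.log2fc, r.padj))
    return pd.DataFrame(
        rows, columns=["region_class", "gene_id", "de_direction", "log2fc", "padj"]
    )


def specific_peaks(
    peaks_ck: pd.DataFrame, peaks_pd: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Overlap-based condition-specific peak partition.

    A peak is condition-specific iff it overlaps (>= 1 bp) no peak of the
    other condition; otherwise it is common.  The partition is exhaustive per
    input set and symmetric under swapping the inputs.
    """
    ck_hits = overlaps_any(peaks_ck.reset_index(drop=True), peaks_pd)
    pd_hits = overlaps_any(peaks_pd.reset_index(drop=True), peaks_ck)
    return {
        "CK_specific": peaks_ck.reset_index(drop=True)[~ck_hits],
        "PD_specific": peaks_pd.reset_index(drop=True)[~pd_hits],
        "common_CK": peaks_ck.reset_index(drop=True)[ck_hits],
        "common_PD": peaks_pd.reset_index(drop=True)[pd_hits],
    }


def de_by_peak_group(
    expr: pd.DataFrame,
    partition: dict[str, pd.DataFrame],
    genes: pd.DataFrame,
) -> dict:
    """Fold change of PD-responsive genes by condition-specific peak group.

    Among DE-flagged genes, the two groups are genes whose interval overlaps
    a PD-specific peak and genes overlapping a CK-specific peak (a gene with
    both kinds of peaks is counted in both groups).  Reports mean log2FC and
    mean |log2FC| per group and a two-sided rank-sum p on log2FC.
    """
    flagged = expr if "de" in expr.columns else de_flag(expr)
    gene_iv = genes.rename(columns={"name": "gene_id"})[
        ["chrom", "start", "end", "gene_id"]
    ].reset_index(drop=True)
    responsive = flagged[flagged["de"]]
    gene_iv = gene_iv[gene_iv["gene_id"].isin(responsive["gene_id"])].reset_index(
        drop=True
    )
    groups = {}
    for key in ("PD_specific", "CK_specific"):
        hit = overlaps_any(gene_iv, partition[key])
        ids = gene_iv[hit]["gene_id"]
        fc = responsive.set_index("gene_id").loc[ids, "log2fc"].to_numpy(dtype=float)
        groups[key] = fc
    out = {
        k: {
            "n": int(len(v)),
            "mean_log2fc": float(np.mean(v)) if len(v) else float("nan"),
            "mean_abs_log2fc": float(np.mean(np.abs(v))) if len(v) else float("nan"),
        }
        for k, v in groups.items()
    }
    if len(groups["PD_specific"]) and len(groups["CK_specific"]):
        out["rank_sum_p"] = wilcoxon_rank_sum(
            groups["PD_specific"], groups["CK_specific"]
        )
    else:
        out["rank_sum_p"] = float("nan")
    return out


def anchor_mark_fraction(
    loops: pd.DataFrame, peaks_by_mark: dict[str, pd.DataFrame]
) -> dict:
    """Fraction of unique loop anchors carrying either mark; of those, both.

    An anchor is "modified" by a mark iff its bin interval overlaps at least
    one peak of that mark.  Anchors shared by several loops count once.
    """
    if loops.empty:
        raise ValueError("no loops: anchor fractions undefined")
    anchors = pd.concat(
        [
            loops[["chrom", "start1", "end1"]].rename(
                columns={"start1": "start", "end1": "end"}
            ),
            loops[["chrom", "start2", "end2"]].rename(
                columns={"start2": "start", "end2": "end"}
            ),
        ],
        ignore_index=True,
    ).drop_duplicates().reset_index(drop=True)
    marks = list(peaks_by_mark)
    hit = {m: overlaps_any(anchors, peaks_by_mark[m]) for m in marks}
    either = np.zeros(len(anchors), dtype=bool)
    both = np.ones(len(anchors), dtype=bool)
    for m in marks:
        either |= hit[m]
        both &= hit[m]
    out = {
        "n_anchors": int(len(anchors)),
        "either_fraction": float(either.mean()),
        "per_mark_fraction": {m: float(hit[m].mean()) for m in marks},
    }
    out["both_of_either_fraction"] = (
        float(both.sum() / either.sum()) if either.any() else float("nan")
    )
    return out


def go_hypergeometric(
    query: set[str] | list[str],
    universe: set[str] | list[str],
    term_map: pd.DataFrame,
) -> pd.DataFrame:
    """GO-term enrichment of a gene list by the hypergeometric upper tail.

    ``term_map`` has columns gene_id, term_id (flat map, no DAG propagation).
    For each term with K >= 1 universe genes, p = P(X >= k) with population N
    = |universe|, K marked, n = |query| drawn; BH adjustment across tested
    terms; ``significant`` flags adjusted p < 0.05.
    """
    universe = set(universe)
    query = set(query)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    tm = term_map[term_map["gene_id"].isin(universe)]
    rows = []
    for term, grp in tm.groupby("term_id"):
        members = set(grp["gene_id"])
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        p = hypergeom_sf(k, len(universe), K, len(query))
        rows.append((term, len(universe), K, len(query), k, p))
    out = pd.DataFrame(
        rows, columns=["term_id", "N", "K", "n", "k", "p"]
    )
    if len(out):
        out["padj"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["padj"] < 0.05
        out = out.sort_values("p").reset_index(drop=True)
    else:
        out["padj"] = []
        out["significant"] = []
    return out
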