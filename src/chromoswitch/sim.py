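"""Two-condition synthetic Hi-C generator with planted ground truth.

The simulator emulates the data layout of a control (CK) vs phosphorus-deficient
(PD) chromatin-reorganization experiment: power-law distance decay, checkerboard
A/B compartmentalization with condition-specific switch regions, block TADs,
point loops, gene annotations denser in A compartments, expression shifted
upward in A, and histone-mark peaks enriched in A bins and at loop anchors.
Every planted feature is recorded in a :class:`TruthSet` for recovery scoring.

Generative model for cis counts at bin separation s (in bins, s >= 1):

    mu(i, j) = depth * s**(-alpha) * c(i, j) * t(i, j) * l(i, j)

where c multiplies same-compartment pairs by ``compartment_factor`` and divides
cross pairs by it, t multiplies within-TAD pairs by ``tad_factor``, l multiplies
planted anchor pixels by ``loop_factor``, and counts are Poisson.  Trans counts
are structureless Poisson with mean ``trans_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BinTable, ContactMatrix
from .util import atomic_write, child_seed

__all__ = [
    "SimConfig",
    "TruthSet",
    "plan_truth",
    "make_genome",
    "simulate_contacts",
    "simulate_genes_expression",
    "simulate_peaks",
    "write_truth",
    "read_truth",
]

CONDITIONS = ("CK", "PD")
MARKS = ("H3K4me3", "H3K27ac")


@dataclass
class SimConfig:
    """Study-condition knobs for the simulator.

    Defaults are the package's standard desk-scale genome: two 5 Mb
    chromosomes, 20 kb working resolution, unit decay exponent, moderate depth.
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 5_000_000
    bin_size_bp: int = 20_000
    decay_exponent: float = 1.0
    depth: float = 20.0          # mean cis counts per bin pair at s = 1
    trans_rate: float = 0.05     # mean trans counts per bin pair

    # compartments: alternating A/B blocks; a subset of sub-block regions
    # flips label under PD
    compartment_factor: float = 2.0
    comp_block_bp: int = 500_000
    n_switch_regions: int = 10
    switch_region_bp: int = 100_000

    # TADs: boundaries every tad_spacing_bp; within-block contacts boosted
    tad_factor: float = 3.0
    tad_spacing_bp: int = 300_000

    # loops: point anchor pairs; factors multiply the anchor pixel
    loop_factor: float = 8.0
    n_loops_common: int = 8
    n_loops_ck_only: int = 3
    n_loops_pd_only: int = 3
    loop_min_dist_bp: int = 50_000
    loop_max_dist_bp: int = 100_000
    loop_edge_margin_bp: int = 150_000   # keep anchors off low-coverage chrom ends

    # genes and expression
    gene_prob_a: float = 0.8     # per-bin gene probability in A compartments
    gene_prob_b: float = 0.4
    expr_base_log2: float = 5.0
    expr_sd_log2: float = 1.0
    expr_effect_log2: float = 1.0   # A-compartment mean shift
    expr_rep_sd_log2: float = 0.15
    n_replicates: int = 3
    n_extra_de: int = 40         # planted DE genes outside switch regions

    # histone-mark peaks
    peak_prob_b: float = 0.15    # per-bin peak probability in B compartments
    peak_enrichment: float = 3.0  # A-to-B placement-rate ratio
    anchor_peak_prob: float = 0.63      # P(anchor carries either mark)
    anchor_both_frac: float = 0.30      # of those, fraction carrying both

    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_length_bp % self.bin_size_bp != 0:
            raise ValueError(
                f"bin_size_bp={self.bin_size_bp} does not divide "
                f"chrom_length_bp={self.chrom_length_bp}"
            )
        for name in ("compartment_factor", "tad_factor", "loop_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if self.loop_max_dist_bp > 2_000_000:
            raise ValueError("loop anchors must be <= 2 Mb apart")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{k + 1}": self.chrom_length_bp for k in range(self.n_chromosomes)}

    def bins(self, bin_size_bp: int | None = None) -> BinTable:
        return BinTable.from_chrom_sizes(
            self.chrom_sizes, bin_size_bp or self.bin_size_bp
        )


@dataclass
class TruthSet:
    """Planted structure emitted by the simulator, used to score recovery.

    Interval frames are BED-like (chrom, start, end, ...), 0-based half-open.
    """

    compartments: dict[str, pd.DataFrame]   # per condition: chrom,start,end,label
    switch_regions: pd.DataFrame            # chrom,start,end,direction (A2B/B2A)
    tad_boundaries: pd.DataFrame            # chrom,pos (bp of the boundary)
    loops: pd.DataFrame                     # chrom,anchor1,anchor2 (bp),in_CK,in_PD
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)       # BED6
    de_genes: pd.DataFrame = field(default_factory=pd.DataFrame)    # gene_id,direction
    mark_enriched: pd.DataFrame = field(default_factory=pd.DataFrame)

    def labels(self, condition: str, bins: BinTable) -> np.ndarray:
        """Per-bin A/B label at an arbitrary resolution, by bin midpoint."""
        comp = self.compartments[condition]
        out = np.empty(bins.n_bins, dtype="<U1")
        df = bins.to_dataframe()
        mid = (df["start"] + df["end"]) // 2
        for chrom, grp in comp.groupby("chrom", sort=False):
            sel = df["chrom"] == chrom
            starts = grp["start"].to_numpy()
            labels = grp["label"].to_numpy()
            pos = np.searchsorted(starts, mid[sel].to_numpy(), side="right") - 1
            out[np.flatnonzero(sel.to_numpy())] = labels[pos]
        return out

    def boundary_bins(self, bins: BinTable) -> np.ndarray:
        """Global bin indices of planted TAD boundaries at a resolution."""
        idx = [
            bins.bin_of(chrom, int(pos))
            for chrom, pos in zip(self.tad_boundaries["chrom"], self.tad_boundaries["pos"])
        ]
        return np.array(sorted(idx), dtype=int)

    def loop_bins(self, condition: str, bins: BinTable) -> pd.DataFrame:
        """Planted loops of one condition as global bin-index anchor pairs."""
        sub = self.loops[self.loops[f"in_{condition}"]]
        rows = [
            (
                row.chrom,
                bins.bin_of(row.chrom, int(row.anchor1)),
                bins.bin_of(row.chrom, int(row.anchor2)),
            )
            for row in sub.itertuples()
        ]
        return pd.DataFrame(rows, columns=["chrom", "bin1", "bin2"])


def plan_truth(config: SimConfig) -> TruthSet:
    """Lay out the planted compartments, switches, TAD boundaries and loops."""
    rng = child_seed(config.seed, "plan")
    chroms = list(config.chrom_sizes)
    L = config.chrom_length_bp

    # alternating A/B blocks, A first
    block = config.comp_block_bp
    seg_rows = []
    for chrom in chroms:
        for k, start in enumerate(range(0, L, block)):
            seg_rows.append((chrom, start, min(start + block, L), "AB"[k % 2]))
    base = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "label"])

    # switch regions: sub-block intervals, centred inside blocks so runs of
    # flipped bins never merge with a neighbouring flip
    sw = config.switch_region_bp
    candidates = base[(base["end"] - base["start"]) >= sw + 2 * config.bin_size_bp]
    take = min(config.n_switch_regions, len(candidates))
    chosen = candidates.sample(n=take, random_state=int(rng.integers(2**31)))
    sw_rows = []
    for row in chosen.itertuples():
        mid = (row.start + row.end) // 2
        s = (mid - sw // 2) // config.bin_size_bp * config.bin_size_bp
        direction = "A2B" if row.label == "A" else "B2A"
        sw_rows.append((row.chrom, int(s), int(s + sw), direction))
    switches = pd.DataFrame(
        sw_rows, columns=["chrom", "start", "end", "direction"]
    ).sort_values(["chrom", "start"]).reset_index(drop=True)

    # PD compartments: base segmentation with switch intervals flipped
    def apply_switches(seg: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for row in seg.itertuples():
            cuts = switches[
                (switches["chrom"] == row.chrom)
                & (switches["start"] >= row.start)
                & (switches["end"] <= row.end)
            ]
            if cuts.empty:
                rows.append((row.chrom, row.start, row.end, row.label))
                continue
            pos = row.start
            flip = {"A": "B", "B": "A"}[row.label]
            for cut in cuts.sort_values("start").itertuples():
                if cut.start > pos:
                    rows.append((row.chrom, pos, cut.start, row.label))
                rows.append((row.chrom, cut.start, cut.end, flip))
                pos = cut.end
            if pos < row.end:
                rows.append((row.chrom, pos, row.end, row.label))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])

    comp = {"CK": base.copy(), "PD": apply_switches(base)}

    # TAD boundaries on a regular grid (interior positions only)
    tad_rows = [
        (chrom, pos)
        for chrom in chroms
        for pos in range(config.tad_spacing_bp, L, config.tad_spacing_bp)
    ]
    tads = pd.DataFrame(tad_rows, columns=["chrom", "pos"])

    # loops: cis anchor pairs on the bin grid, kept clear of each other
    b = config.bin_size_bp
    n_total = config.n_loops_common + config.n_loops_ck_only + config.n_loops_pd_only
    loop_rows: list[tuple] = []
    used: set[tuple[str, int]] = set()
    attempts = 0
    while len(loop_rows) < n_total and attempts < 10_000:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        margin = config.loop_edge_margin_bp
        a1 = int(
            rng.integers(margin // b, (L - margin - config.loop_max_dist_bp) // b)
        ) * b
        dist = int(
            rng.integers(config.loop_min_dist_bp // b, config.loop_max_dist_bp // b + 1)
        ) * b
        a2 = a1 + dist
        k1, k2 = (chrom, a1 // b), (chrom, a2 // b)
        clash = any(
            (c, x) in used
            for (c, x) in [k1, k2]
        ) or any(
            c == chrom and (abs(u - a1 // b) <= 2 or abs(u - a2 // b) <= 2)
            for (c, u) in used
        )
        if clash:
            continue
        used.update([k1, k2])
        loop_rows.append((chrom, a1, a2))
    kinds = (
        ["common"] * config.n_loops_common
        + ["CK"] * config.n_loops_ck_only
        + ["PD"] * config.n_loops_pd_only
    )[: len(loop_rows)]
    loops = pd.DataFrame(loop_rows, columns=["chrom", "anchor1", "anchor2"])
    loops["in_CK"] = [k in ("common", "CK") for k in kinds]
    loops["in_PD"] = [k in ("common", "PD") for k in kinds]
    loops = loops.sort_values(["chrom", "anchor1"]).reset_index(drop=True)

    mark_enriched = pd.concat(
        [
            base[base["label"] == "A"][["chrom", "start", "end"]].assign(mark=mark)
            for mark in MARKS
        ],
        ignore_index=True,
    )
    return TruthSet(comp, switches, tads, loops, mark_enriched=mark_enriched)


def make_genome(
    config: SimConfig, truth: TruthSet
) -> tuple[BinTable, pd.DataFrame]:
    """Bin table plus a BED6 gene annotation tiled over bins.

    Genes are placed per bin with probability ``gene_prob_a`` in CK
    A-compartment bins and ``gene_prob_b`` in B bins, each occupying the
    central half of its bin.
    """
    rng = child_seed(config.seed, "genes")
    bins = config.bins()
    labels = truth.labels("CK", bins)
    df = bins.to_dataframe()
    p = np.where(labels == "A", config.gene_prob_a, config.gene_prob_b)
    has_gene = rng.random(bins.n_bins) < p
    sel = df[has_gene]
    width = bins.bin_size // 2
    genes = pd.DataFrame(
        {
            "chrom": sel["chrom"].to_numpy(),
            "start": sel["start"].to_numpy() + bins.bin_size // 4,
            "end": sel["start"].to_numpy() + bins.bin_size // 4 + width,
            "name": [f"g{idx:05d}" for idx in sel["index"]],
            "score": 0,
            "strand": "+",
        }
    ).reset_index(drop=True)
    truth.genes = genes
    return bins, genes


def _cis_mu(
    config: SimConfig,
    truth: TruthSet,
    condition: str,
    bins: BinTable,
    chrom: str,
    depth: float,
) -> np.ndarray:
    sl = bins.chrom_slice(chrom)
    n = sl.stop - sl.start
    i = np.arange(n)
    s = np.abs(i[:, None] - i[None, :]).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = depth * s ** (-config.decay_exponent)
    np.fill_diagonal(mu, 0.0)
    mu = np.nan_to_num(mu)

    labels = truth.labels(condition, bins)[sl]
    same = labels[:, None] == labels[None, :]
    m = config.compartment_factor
    mu *= np.where(same, m, 1.0 / m)

    if config.tad_factor != 1.0:
        bbins = truth.tad_boundaries[truth.tad_boundaries["chrom"] == chrom]
        cuts = (bbins["pos"].to_numpy() // bins.bin_size).astype(int)
        block = np.searchsorted(cuts, i, side="right")
        mu *= np.where(block[:, None] == block[None, :], config.tad_factor, 1.0)

    loops = truth.loops[
        (truth.loops["chrom"] == chrom) & truth.loops[f"in_{condition}"]
    ]
    for row in loops.itertuples():
        b1 = int(row.anchor1) // bins.bin_size
        b2 = int(row.anchor2) // bins.bin_size
        mu[b1, b2] *= config.loop_factor
        mu[b2, b1] *= config.loop_factor
    return mu


def simulate_contacts(
    config: SimConfig,
    truth: TruthSet,
    condition: str,
    bin_size_bp: int | None = None,
    depth: float | None = None,
) -> ContactMatrix:
    """Poisson contact matrix for one condition at a chosen resolution.

    ``depth`` defaults to ``config.depth`` regardless of resolution so the
    distance-1 stratum keeps the configured mean count.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    bins = config.bins(bin_size_bp)
    depth = config.depth if depth is None else depth
    rng = child_seed(config.seed, f"contacts:{condition}:{bins.bin_size}")

    n = bins.n_bins
    ii, jj, cc = [], [], []
    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        mu = _cis_mu(config, truth, condition, bins, chrom, depth)
        nb = sl.stop - sl.start
        iu, ju = np.triu_indices(nb, k=1)
        counts = rng.poisson(mu[iu, ju])
        keep = counts > 0
        ii.append(iu[keep] + sl.start)
        jj.append(ju[keep] + sl.start)
        cc.append(counts[keep])
    # structureless trans background
    if config.trans_rate > 0 and len(bins.chroms) > 1:
        chrom_codes = bins.chrom_of_bins()
        iu, ju = np.triu_indices(n, k=1)
        trans = chrom_codes[iu] != chrom_codes[ju]
        counts = rng.poisson(config.trans_rate, size=int(trans.sum()))
        keep = counts > 0
        ii.append(iu[trans][keep])
        jj.append(ju[trans][keep])
        cc.append(counts[keep])
    if ii:
        i = np.concatenate(ii)
        j = np.concatenate(jj)
        c = np.concatenate(cc).astype(float)
    else:
        i = j = np.array([], dtype=int)
        c = np.array([])
    return ContactMatrix.from_triplets(bins, i, j, c, condition=condition)


def simulate_genes_expression(
    config: SimConfig,
    truth: TruthSet,
    effect: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression (FPKM per replicate per condition) and a DE-statistics table.

    Per-gene log2 expression is Normal with the A-compartment mean shifted by
    ``effect`` (per condition's own labels, so switch-region genes change with
    the flip).  The DE table is planted by construction: genes in B2A switch
    regions are up-regulated, A2B down-regulated, plus ``n_extra_de`` random
    DE genes elsewhere; all other genes receive sub-threshold statistics.
    """
    if truth.genes.empty:
        raise ValueError("run make_genome first: no gene annotation in truth")
    effect = config.expr_effect_log2 if effect is None else effect
    rng = child_seed(config.seed, "expression")
    bins = config.bins()
    genes = truth.genes
    mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
    gene_bin = np.array(
        [bins.bin_of(c, int(p)) for c, p in zip(genes["chrom"], mid)]
    )

    base = rng.normal(config.expr_base_log2, config.expr_sd_log2, size=len(genes))
    expr = {"gene_id": genes["name"].to_numpy()}
    for cond in CONDITIONS:
        is_a = truth.labels(cond, bins)[gene_bin] == "A"
        mean = base + effect * is_a
        for rep in range(1, config.n_replicates + 1):
            log2v = mean + rng.normal(0, config.expr_rep_sd_log2, size=len(genes))
            expr[f"fpkm_{cond}_{rep}"] = np.power(2.0, log2v)
    expr_df = pd.DataFrame(expr)

    # planted DE assignment
    from .intervals import overlaps_any

    gene_iv = genes.rename(columns={"name": "gene_id"})[
        ["chrom", "start", "end", "gene_id"]
    ]
    direction = np.array([""] * len(genes), dtype=object)
    for dirn in ("B2A", "A2B"):
        reg = truth.switch_regions[truth.switch_regions["direction"] == dirn]
        if len(reg):
            hit = overlaps_any(gene_iv, reg)
            direction[hit] = "up" if dirn == "B2A" else "down"
    free = np.flatnonzero(direction == "")
    n_extra = min(config.n_extra_de, len(free))
    extra = rng.choice(free, size=n_extra, replace=False)
    direction[extra] = np.where(rng.random(n_extra) < 0.5, "up", "down")

    is_de = direction != ""
    sign = np.where(direction == "up", 1.0, -1.0)
    log2fc = np.where(
        is_de,
        sign * (1.0 + np.abs(rng.normal(0, 0.5, size=len(genes)))),
        np.clip(rng.normal(0, 0.3, size=len(genes)), -0.95, 0.95),
    )
    padj = np.where(
        is_de,
        rng.uniform(1e-8, 0.01, size=len(genes)),
        rng.uniform(0.05, 1.0, size=len(genes)),
    )
    de_df = pd.DataFrame(
        {
            "gene_id": genes["name"].to_numpy(),
            "log2fc": log2fc,
            "padj": padj,
        }
    )
    truth.de_genes = pd.DataFrame(
        {"gene_id": genes["name"].to_numpy()[is_de], "direction": direction[is_de]}
    ).reset_index(drop=True)
    return expr_df, de_df


def simulate_peaks(
    config: SimConfig,
    truth: TruthSet,
    enrichment: float | None = None,
    anchor_peak_prob: float | None = None,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Histone-mark peak sets per mark per condition.

    Background peaks are placed per bin at rate ``peak_prob_b`` in B bins and
    ``peak_prob_b * enrichment`` in A bins (per condition's labels).  Loop
    anchors additionally carry a correlated pair of mark assignments so that a
    fraction ``anchor_peak_prob`` of anchors carries at least one mark and
    ``anchor_both_frac`` of those carries both.
    """
    enrichment = config.peak_enrichment if enrichment is None else enrichment
    p_either = (
        config.anchor_peak_prob if anchor_peak_prob is None else anchor_peak_prob
    )
    rng = child_seed(config.seed, "peaks")
    bins = config.bins()
    df = bins.to_dataframe()
    out: dict[str, dict[str, pd.DataFrame]] = {mark: {} for mark in MARKS}
    p_both = p_either * config.anchor_both_frac
    p_one = (p_either - p_both) / 2.0

    for cond in CONDITIONS:
        labels = truth.labels(cond, bins)
        p = np.clip(
            np.where(labels == "A", config.peak_prob_b * enrichment, config.peak_prob_b),
            0,
            1,
        )
        anchors = truth.loop_bins(cond, bins)
        anchor_bins = np.unique(
            np.concatenate([anchors["bin1"].to_numpy(), anchors["bin2"].to_numpy()])
        ) if len(anchors) else np.array([], dtype=int)
        u = rng.random(len(anchor_bins))
        anchor_marks = {
            MARKS[0]: (u < p_both + p_one),
            MARKS[1]: (u < p_both) | ((u >= p_both + p_one) & (u < p_either)),
        }
        for mark in MARKS:
            has_peak = rng.random(bins.n_bins) < p
            rows = []
            widths = rng.integers(
                bins.bin_size // 5, bins.bin_size // 2, size=bins.n_bins
            )
            offs = rng.integers(0, bins.bin_size // 2, size=bins.n_bins)
            for b in np.flatnonzero(has_peak):
                s = int(df["start"].iloc[b] + offs[b])
                rows.append((df["chrom"].iloc[b], s, s + int(widths[b]), mark))
            for b, carries in zip(anchor_bins, anchor_marks[mark]):
                if carries:
                    rows.append(
                        (
                            df["chrom"].iloc[b],
                            int(df["start"].iloc[b]),
                            int(df["end"].iloc[b]),
                            mark,
                        )
                    )
            peaks = (
                pd.DataFrame(rows, columns=["chrom", "start", "end", "mark"])
                .sort_values(["chrom", "start"])
                .reset_index(drop=True)
            )
            out[mark][cond] = peaks
    return out


# ---------------------------------------------------------------------------
# Truth persistence
# ---------------------------------------------------------------------------

def simulate_go_map(config: SimConfig, truth: TruthSet, n_terms: int = 10) -> pd.DataFrame:
    """Flat gene -> GO-term map with one term enriched for planted DE genes.

    Random background terms of ~50 genes each, plus a "response" term built
    from 60% of the planted DE genes and a few background genes, so GO
    enrichment of the DE list has a planted positive.
    """
    rng = child_seed(config.seed, "go")
    all_genes = truth.genes["name"].to_numpy()
    rows = []
    for t in range(n_terms):
        size = min(50, len(all_genes))
        members = rng.choice(all_genes, size=size, replace=False)
        rows += [(g, f"GO:{t:07d}") for g in members]
    de_ids = truth.de_genes["gene_id"].to_numpy()
    if len(de_ids):
        take = rng.choice(de_ids, size=max(1, int(0.6 * len(de_ids))), replace=False)
        bg = rng.choice(all_genes, size=min(20, len(all_genes)), replace=False)
        rows += [(g, "GO:RESPONSE") for g in np.unique(np.concatenate([take, bg]))]
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


def write_simulated_workspace(
    config: SimConfig, directory: str | Path
) -> Path:
    """Generate a complete two-condition input workspace and pipeline config.

    Writes HiC-Pro matrices at 20/10/5 kb per condition, the gene BED,
    expression/DE TSV, per-mark per-condition peak BEDs, a GO map, the truth
    files, and ``pipeline.yaml`` referencing them.  Returns the config path.
    """
    from .io import write_hicpro

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth = plan_truth(config)
    bins, genes = make_genome(config, truth)
    expr, de = simulate_genes_expression(config, truth)
    expr_full = expr.merge(de, on="gene_id")
    peaks = simulate_peaks(config, truth)
    go_map = simulate_go_map(config, truth)

    matrices: dict[str, dict[int, dict[str, str]]] = {}
    for cond in CONDITIONS:
        matrices[cond] = {}
        for res in (20_000, 10_000, 5_000):
            m = simulate_contacts(config, truth, cond, bin_size_bp=res)
            mp = directory / f"{cond}_{res}.matrix"
            bp = directory / f"{cond}_{res}.bed"
            write_hicpro(m, mp, bp)
            matrices[cond][res] = {"matrix": mp.name, "bed": bp.name}

    with atomic_write(directory / "genes.bed") as fh:
        genes.to_csv(fh, sep="\t", index=False)
    with atomic_write(directory / "expression.tsv") as fh:
        expr_full.to_csv(fh, sep="\t", index=False)
    peak_paths: dict[str, dict[str, str]] = {}
    for mark in MARKS:
        peak_paths[mark] = {}
        for cond in CONDITIONS:
            name = f"peaks_{mark}_{cond}.bed"
            with atomic_write(directory / name) as fh:
                peaks[mark][cond].to_csv(fh, sep="\t", index=False)
            peak_paths[mark][cond] = name
    with atomic_write(directory / "go_map.tsv") as fh:
        go_map.to_csv(fh, sep="\t", index=False)
    write_truth(truth, directory / "truth")

    cfg = {
        "seed": config.seed,
        "output_dir": "results",
        "matrices": matrices,
        "genes_bed": "genes.bed",
        "expression_tsv": "expression.tsv",
        "peaks": peak_paths,
        "go_map_tsv": "go_map.tsv",
    }
    import yaml

    cfg_path = directory / "pipeline.yaml"
    with atomic_write(cfg_path) as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return cfg_path


def write_truth(truth: TruthSet, directory: str | Path) -> None:
    """Write every planted track as TSV/BED; round-trips via read_truth."""
    directory = Path(directory)
    for cond in CONDITIONS:
        with atomic_write(directory / f"compartments_{cond}.bed") as fh:
            truth.compartments[cond].to_csv(fh, sep="\t", index=False)
    with atomic_write(directory / "switch_regions.bed") as fh:
        truth.switch_regions.to_csv(fh, sep="\t", index=False)
    with atomic_write(directory / "tad_boundaries.tsv") as fh:
        truth.tad_boundaries.to_csv(fh, sep="\t", index=False)
    with atomic_write(directory / "loops.tsv") as fh:
        truth.loops.to_csv(fh, sep="\t", index=False)
    with atomic_write(directory / "genes.bed") as fh:
        truth.genes.to_csv(fh, sep="\t", index=False)
    with atomic_write(directory / "de_genes.tsv") as fh:
        truth.de_genes.to_csv(fh, sep="\t", index=False)
    with atomic_write(directory / "mark_enriched.bed") as fh:
        truth.mark_enriched.to_csv(fh, sep="\t", index=False)


def read_truth(directory: str | Path) -> TruthSet:
    directory = Path(directory)

    def load(name: str, **kw) -> pd.DataFrame:
        df = pd.read_csv(directory / name, sep="\t", **kw)
        return df

    comp = {
        cond: load(f"compartments_{cond}.bed") for cond in CONDITIONS
    }
    loops = load("loops.tsv")
    if len(loops):
        loops["in_CK"] = loops["in_CK"].astype(bool)
        loops["in_PD"] = loops["in_PD"].astype(bool)
    genes = load("genes.bed")
    de = load("de_genes.tsv")
    return TruthSet(
        comp,
        load("switch_regions.bed"),
        load("tad_boundaries.tsv"),
        loops,
        genes=genes,
        de_genes=de,
        mark_enriched=load("mark_enriched.bed"),
    )
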