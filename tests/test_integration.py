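"""Cross-omics integration operations."""

import numpy as np
import pandas as pd
import pytest

from chromoswitch.compartments import CompartmentTrack
from chromoswitch.integration import (
    ab_gene_stats,
    ab_peak_stats,
    anchor_mark_fraction,
    de_by_peak_group,
    de_flag,
    expression_prep,
    go_hypergeometric,
    region_de_overlap,
    specific_peaks,
)
from chromoswitch.io import BinTable
from chromoswitch.sim import (
    make_genome,
    plan_truth,
    simulate_genes_expression,
    simulate_peaks,
)

from conftest import compartment_config


def test_fpkm_arithmetic_and_length_filter():
    counts = pd.DataFrame({"gene_id": ["g1", "g2"], "s1": [100, 10]})
    lengths = pd.Series({"g1": 1000.0})
    libs = pd.Series({"s1": 1e7})
    de = pd.DataFrame({"gene_id": ["g1"], "log2fc": [1.0], "padj": [0.049]})
    with pytest.warns(UserWarning, match="without length"):
        out = expression_prep(counts, lengths, libs, de)
    assert len(out) == 1
    assert out["fpkm_s1"].iloc[0] == pytest.approx(10.0)
    assert out["de"].iloc[0] and out["de_direction"].iloc[0] == "up"


def test_de_cutoff_is_strict():
    table = pd.DataFrame(
        {
            "gene_id": ["a", "b", "c", "d"],
            "log2fc": [1.0, 0.99, -1.2, 1.5],
            "padj": [0.049, 0.001, 0.05, 0.04],
        }
    )
    out = de_flag(table).set_index("gene_id")
    assert out.loc["a", "de"]                     # exactly at |FC| 1, p < 0.05
    assert not out.loc["b", "de"]                 # |FC| below 1
    assert not out.loc["c", "de"]                 # p not strictly < 0.05
    assert out.loc["d", "de_direction"] == "up"


def _track(bins, labels):
    labels = np.asarray(labels, dtype="<U1")
    pc1 = np.where(labels == "A", 1.0, -1.0)
    return CompartmentTrack(bins, pc1, labels)


def test_gene_midpoint_assignment_is_deterministic():
    bins = BinTable.from_chrom_sizes({"chr1": 80_000}, 20_000)
    track = _track(bins, ["A", "B", "B", "B"])
    # gene straddles bins 0/1; midpoint 21000 -> bin 1 (B)
    genes = pd.DataFrame(
        {"chrom": ["chr1"], "start": [18_000], "end": [24_000], "name": ["g1"]}
    )
    expr = pd.DataFrame({"gene_id": ["g1"], "fpkm_CK_1": [5.0]})
    out = ab_gene_stats(track, genes, expr, "CK")
    assert out["n_genes"] == {"A": 0, "B": 1}


def test_ab_gene_stats_detects_planted_shift():
    config = compartment_config(seed=71)
    truth = plan_truth(config)
    bins, genes = make_genome(config, truth)
    expr, _ = simulate_genes_expression(config, truth, effect=1.0)
    track = _track(bins, truth.labels("CK", bins))
    out = ab_gene_stats(track, genes, expr, "CK")
    assert out["mean_fpkm"]["A"] > out["mean_fpkm"]["B"]
    assert out["expression_wilcoxon_p"] < 1e-3
    assert out["gene_density_per_mb"]["A"] > out["gene_density_per_mb"]["B"]
    assert out["density_wilcoxon_p"] < 1e-3


def test_ab_peak_stats_extreme_and_conservation():
    bins = BinTable.from_chrom_sizes({"chr1": 2_000_000}, 20_000)
    labels = np.array(["A"] * 50 + ["B"] * 50)
    track = _track(bins, labels)
    rng = np.random.default_rng(0)
    starts = rng.choice(np.arange(50) * 20_000, size=40, replace=False)
    peaks = pd.DataFrame(
        {"chrom": "chr1", "start": starts + 2_000, "end": starts + 6_000}
    )
    out = ab_peak_stats(track, peaks)
    assert out["total_coverage_bp"]["B"] == 0.0
    assert out["wilcoxon_p"] < 1e-3
    total = out["total_coverage_bp"]["A"] + out["total_coverage_bp"]["B"]
    assert total == (peaks["end"] - peaks["start"]).sum()


def test_region_de_overlap_by_construction():
    genes = pd.DataFrame(
        {
            "chrom": ["chr1"] * 3,
            "start": [100, 300, 500],
            "end": [200, 400, 600],
            "name": ["u1", "u2", "d1"],
        }
    )
    expr = pd.DataFrame(
        {
            "gene_id": ["u1", "u2", "d1"],
            "log2fc": [2.0, 1.5, -2.0],
            "padj": [0.001, 0.001, 0.001],
        }
    )
    regions = pd.DataFrame(
        {"chrom": ["chr1"], "start": [0], "end": [650], "direction": ["B2A"]}
    )
    up = region_de_overlap(regions, genes, expr, direction_filter="up")
    assert sorted(up["gene_id"]) == ["u1", "u2"]
    empty = region_de_overlap(regions.iloc[:0], genes, expr)
    assert empty.empty


def test_switch_de_recovery_in_correct_direction(std_truth_and_tracks):
    """>= 90% of planted switch-DE genes recovered in the right class."""
    config, truth, bins, genes, tracks = std_truth_and_tracks
    from chromoswitch.compartments import compartment_switches
    from chromoswitch.sim import simulate_genes_expression as sim_expr

    expr, de = sim_expr(config, truth)
    table = de_flag(expr.merge(de, on="gene_id"))
    regions, _ = compartment_switches(tracks["CK"], tracks["PD"])
    overlap = region_de_overlap(regions, genes, table)
    want = {"B2A": "up", "A2B": "down"}
    # planted: genes inside switch regions with the matching direction
    from chromoswitch.intervals import overlaps_any

    gene_iv = genes.rename(columns={"name": "gene_id"})[
        ["chrom", "start", "end", "gene_id"]
    ]
    n_planted = n_found = 0
    for dirn, de_dir in want.items():
        reg = truth.switch_regions[truth.switch_regions["direction"] == dirn]
        planted_ids = set(gene_iv[overlaps_any(gene_iv, reg)]["gene_id"])
        found = set(
            overlap[
                (overlap["region_class"] == dirn)
                & (overlap["de_direction"] == de_dir)
            ]["gene_id"]
        )
        n_planted += len(planted_ids)
        n_found += len(planted_ids & found)
    assert n_planted > 0
    assert n_found / n_planted >= 0.9


def test_specific_peaks_partition_and_symmetry():
    ck = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [100, 500], "end": [200, 600]}
    )
    pdp = pd.DataFrame({"chrom": ["chr1"], "start": [199], "end": [300]})
    part = specific_peaks(ck, pdp)
    assert len(part["common_CK"]) == 1          # 1 bp overlap at [199,200)
    assert len(part["CK_specific"]) == 1
    assert len(part["PD_specific"]) == 0
    # identical sets: all common; disjoint: all specific
    same = specific_peaks(ck, ck)
    assert len(same["CK_specific"]) == len(same["PD_specific"]) == 0
    swapped = specific_peaks(pdp, ck)
    pd.testing.assert_frame_equal(
        part["CK_specific"].reset_index(drop=True),
        swapped["PD_specific"].reset_index(drop=True),
    )


def test_de_by_peak_group_counts_dual_membership():
    genes = pd.DataFrame(
        {"chrom": ["chr1"], "start": [100], "end": [200], "name": ["g1"]}
    )
    expr = pd.DataFrame({"gene_id": ["g1"], "log2fc": [2.0], "padj": [0.001]})
    part = {
        "PD_specific": pd.DataFrame(
            {"chrom": ["chr1"], "start": [150], "end": [160]}
        ),
        "CK_specific": pd.DataFrame(
            {"chrom": ["chr1"], "start": [120], "end": [130]}
        ),
    }
    out = de_by_peak_group(expr, part, genes)
    assert out["PD_specific"]["n"] == 1 and out["CK_specific"]["n"] == 1


def test_de_by_peak_group_recovers_planted_ordering():
    """Switch-coupled planting: PD-specific-peak genes have higher log2FC."""
    config = compartment_config(seed=81, n_extra_de=0)
    truth = plan_truth(config)
    bins, genes = make_genome(config, truth)
    expr, de = simulate_genes_expression(config, truth)
    table = de_flag(expr.merge(de, on="gene_id"))
    peaks = simulate_peaks(config, truth)
    part = specific_peaks(peaks["H3K4me3"]["CK"], peaks["H3K4me3"]["PD"])
    out = de_by_peak_group(table, part, genes)
    assert out["PD_specific"]["mean_log2fc"] > out["CK_specific"]["mean_log2fc"]


def test_anchor_mark_fraction_trivial_and_planted():
    loops = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start1": [100_000, 300_000], "end1": [105_000, 305_000],
            "start2": [200_000, 400_000], "end2": [205_000, 405_000],
        }
    )
    cover_all = pd.DataFrame(
        {"chrom": ["chr1"], "start": [0], "end": [1_000_000]}
    )
    out = anchor_mark_fraction(loops, {"m1": cover_all, "m2": cover_all})
    assert out["either_fraction"] == 1.0
    assert out["both_of_either_fraction"] == 1.0
    empty = pd.DataFrame({"chrom": [], "start": [], "end": []})
    out0 = anchor_mark_fraction(loops, {"m1": empty, "m2": empty})
    assert out0["either_fraction"] == 0.0
    assert np.isnan(out0["both_of_either_fraction"])


def test_anchor_mark_fraction_recovers_planted_probability():
    """Simulator anchor-mark probability 0.63 recovered within 0.05."""
    config = compartment_config(seed=91, peak_prob_b=0.0)
    truth = plan_truth(config)
    make_genome(config, truth)
    rng = np.random.default_rng(5)
    rows = []
    for chrom in ("chr1", "chr2"):
        pos = np.sort(rng.choice(np.arange(10, 240), size=120, replace=False))
        for k in range(0, 118, 2):
            rows.append(
                (chrom, int(pos[k]) * 20_000, int(pos[k + 1]) * 20_000)
            )
    truth.loops = pd.DataFrame(
        rows, columns=["chrom", "anchor1", "anchor2"]
    ).assign(in_CK=True, in_PD=True)
    peaks = simulate_peaks(config, truth)
    bins = config.bins()
    lb = truth.loop_bins("CK", bins)
    loops = pd.DataFrame(
        {
            "chrom": lb["chrom"],
            "start1": truth.loops["anchor1"],
            "end1": truth.loops["anchor1"] + 20_000,
            "start2": truth.loops["anchor2"],
            "end2": truth.loops["anchor2"] + 20_000,
        }
    )
    out = anchor_mark_fraction(
        loops, {m: peaks[m]["CK"] for m in peaks}
    )
    assert out["either_fraction"] == pytest.approx(0.63, abs=0.05)
    assert out["both_of_either_fraction"] == pytest.approx(0.30, abs=0.08)


def test_go_enrichment_oracle_cases():
    universe = [f"g{i}" for i in range(20)]
    term_map = pd.DataFrame(
        {"gene_id": universe[:5] + universe[5:10], "term_id": ["T1"] * 5 + ["T2"] * 5}
    )
    out = go_hypergeometric(universe[:4] + [universe[10]], universe, term_map)
    rec = out.set_index("term_id")
    import math

    expect = sum(
        math.comb(5, x) * math.comb(15, 5 - x) / math.comb(20, 5)
        for x in range(4, 6)
    )
    assert rec.loc["T1", "p"] == pytest.approx(expect)
    assert rec.loc["T2", "k"] == 0 and rec.loc["T2", "p"] == 1.0
    # query = universe: k = K for every term, p = 1
    full = go_hypergeometric(universe, universe, term_map)
    assert (full["k"] == full["K"]).all()
    assert np.allclose(full["p"], 1.0)
    with pytest.raises(ValueError):
        go_hypergeometric(["missing"], universe, term_map)
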