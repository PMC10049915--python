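"""Simulator tests: planted structure is present, recoverable and reproducible."""

import numpy as np
import pandas as pd
import pytest

from chromoswitch.io import cis_trans_fractions, distance_decay
from chromoswitch.sim import (
    SimConfig,
    make_genome,
    plan_truth,
    read_truth,
    simulate_contacts,
    simulate_genes_expression,
    simulate_peaks,
    write_truth,
)
from chromoswitch.stats import wilcoxon_rank_sum

from conftest import compartment_config, loop_config


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="does not divide"):
        SimConfig(chrom_length_bp=1_000_000, bin_size_bp=3_000)
    with pytest.raises(ValueError):
        SimConfig(decay_exponent=0.0)
    with pytest.raises(ValueError):
        SimConfig(compartment_factor=-1.0)
    with pytest.raises(ValueError):
        SimConfig(loop_max_dist_bp=3_000_000)


def test_genome_bins_and_gene_density_ratio():
    config = compartment_config(seed=2)
    truth = plan_truth(config)
    bins, genes = make_genome(config, truth)
    assert bins.n_bins == 500 and list(bins.n_bins_per_chrom) == [250, 250]
    # realized A:B gene-density ratio within 20% of the configured 2:1
    labels = truth.labels("CK", bins)
    mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
    gene_bin = [bins.bin_of(c, int(p)) for c, p in zip(genes["chrom"], mid)]
    per_bin = np.zeros(bins.n_bins)
    np.add.at(per_bin, gene_bin, 1)
    assert len(genes) >= 200
    ratio = per_bin[labels == "A"].mean() / per_bin[labels == "B"].mean()
    assert ratio == pytest.approx(2.0, rel=0.2)


@pytest.mark.parametrize("seed", [3, 4])
def test_matrix_symmetric_integer_nonnegative(seed):
    config = compartment_config(seed=seed)
    truth = plan_truth(config)
    m = simulate_contacts(config, truth, "CK")
    sym = m.symmetric()
    assert (sym != sym.T).nnz == 0
    assert (sym.data >= 0).all()
    assert np.allclose(sym.data, np.round(sym.data))


@pytest.mark.parametrize("alpha", [0.8, 1.0, 1.5])
def test_decay_exponent_recovered(alpha):
    config = loop_config(
        seed=int(alpha * 10),
        decay_exponent=alpha,
        depth=50.0,
        loop_factor=1.0,
        n_loops_common=0,
        n_loops_ck_only=0,
        n_loops_pd_only=0,
        trans_rate=0.0,
    )
    truth = plan_truth(config)
    m = simulate_contacts(config, truth, "CK")
    dd = distance_decay(m)
    assert dd["exponent"] == pytest.approx(-alpha, abs=0.1)


def test_depth_zero_gives_empty_matrix():
    config = loop_config(seed=1, depth=0.0, trans_rate=0.0)
    truth = plan_truth(config)
    m = simulate_contacts(config, truth, "CK")
    assert m.total == 0


def test_trans_rate_zero_gives_pure_cis():
    config = compartment_config(seed=5, trans_rate=0.0)
    truth = plan_truth(config)
    m = simulate_contacts(config, truth, "CK")
    assert cis_trans_fractions(m)["cis_fraction"] == 1.0


def test_loop_pixel_exceeds_distance_stratum():
    """A factor-10 planted anchor pixel beats its stratum mean in >=95/100 seeds."""
    wins = 0
    for seed in range(100):
        config = loop_config(
            seed=seed,
            loop_factor=10.0,
            n_loops_common=1,
            n_loops_ck_only=0,
            n_loops_pd_only=0,
            depth=10.0,
        )
        truth = plan_truth(config)
        m = simulate_contacts(config, truth, "CK")
        lb = truth.loop_bins("CK", config.bins())
        b1, b2 = int(lb["bin1"].iloc[0]), int(lb["bin2"].iloc[0])
        d = b2 - b1
        dense = m.dense_chrom("chr1")
        stratum = np.diagonal(dense, offset=d)
        if dense[b1, b2] > stratum.mean():
            wins += 1
    assert wins >= 95


def test_contacts_reproducible_and_condition_streams_differ():
    config = compartment_config(seed=9)
    truth = plan_truth(config)
    a = simulate_contacts(config, truth, "CK")
    b = simulate_contacts(config, truth, "CK")
    assert (a.upper != b.upper).nnz == 0
    c = simulate_contacts(config, truth, "PD")
    assert (a.upper != c.upper).nnz > 0


def test_expression_null_rejection_rate_is_nominal():
    """effect=0: A-vs-B Wilcoxon rejects at ~5% over 200 seeds."""
    rejections = 0
    n_seeds = 200
    for seed in range(n_seeds):
        config = compartment_config(seed=seed, n_extra_de=0)
        truth = plan_truth(config)
        bins, genes = make_genome(config, truth)
        expr, _ = simulate_genes_expression(config, truth, effect=0.0)
        labels = truth.labels("CK", bins)
        mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
        gb = np.array([bins.bin_of(c, int(p)) for c, p in zip(genes["chrom"], mid)])
        fpkm = expr[[c for c in expr.columns if c.startswith("fpkm_CK")]].mean(axis=1)
        a = fpkm[labels[gb] == "A"]
        b = fpkm[labels[gb] == "B"]
        if wilcoxon_rank_sum(a, b) < 0.05:
            rejections += 1
    assert rejections / n_seeds == pytest.approx(0.05, abs=0.03)


def test_expression_effect_one_is_detected():
    """effect=1 log2 unit with >=300 genes/group: p < 0.001 in >=95% of seeds."""
    hits = 0
    for seed in range(20):
        config = compartment_config(
            seed=seed, gene_prob_a=1.0, gene_prob_b=1.0, n_extra_de=0,
            n_chromosomes=3,
        )
        truth = plan_truth(config)
        bins, genes = make_genome(config, truth)
        expr, _ = simulate_genes_expression(config, truth, effect=1.0)
        labels = truth.labels("CK", bins)
        mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
        gb = np.array([bins.bin_of(c, int(p)) for c, p in zip(genes["chrom"], mid)])
        fpkm = expr[[c for c in expr.columns if c.startswith("fpkm_CK")]].mean(axis=1)
        a, b = fpkm[labels[gb] == "A"], fpkm[labels[gb] == "B"]
        assert min(len(a), len(b)) >= 300
        if wilcoxon_rank_sum(a, b) < 1e-3:
            hits += 1
    assert hits >= 19


def test_planted_de_genes_pass_the_cutoff():
    config = compartment_config(seed=21)
    truth = plan_truth(config)
    make_genome(config, truth)
    _, de = simulate_genes_expression(config, truth)
    de = de.set_index("gene_id")
    for row in truth.de_genes.itertuples():
        rec = de.loc[row.gene_id]
        assert abs(rec["log2fc"]) >= 1.0 and rec["padj"] < 0.05
        assert (rec["log2fc"] > 0) == (row.direction == "up")
    others = de.drop(truth.de_genes["gene_id"])
    assert not ((others["log2fc"].abs() >= 1.0) & (others["padj"] < 0.05)).any()


def test_peak_enrichment_ratio_realized():
    config = compartment_config(
        seed=31, peak_prob_b=0.3, peak_enrichment=3.0, anchor_peak_prob=0.0
    )
    truth = plan_truth(config)
    bins, _ = make_genome(config, truth)
    peaks = simulate_peaks(config, truth)
    labels = truth.labels("CK", bins)
    df = bins.to_dataframe()
    allp = pd.concat([peaks[m]["CK"] for m in peaks], ignore_index=True)
    assert len(allp) >= 500
    per_bin = np.zeros(bins.n_bins)
    for r in allp.itertuples():
        per_bin[bins.bin_of(r.chrom, (r.start + r.end) // 2)] += 1
    ratio = per_bin[labels == "A"].mean() / per_bin[labels == "B"].mean()
    assert ratio == pytest.approx(3.0, rel=0.3)


def test_anchor_peak_probability_realized():
    """P(anchor has either mark) ~ 0.63 over many anchors."""
    config = compartment_config(seed=41)
    truth = plan_truth(config)
    make_genome(config, truth)
    # many synthetic anchors for a tight binomial check; background peaks off
    rng = np.random.default_rng(0)
    pos = np.sort(rng.choice(np.arange(10, 230), size=80, replace=False))[:80]
    rows = []
    for k in range(0, len(pos) - 1, 2):
        rows.append(("chr1", int(pos[k]) * 20_000, int(pos[k + 1]) * 20_000))
        rows.append(("chr2", int(pos[k]) * 20_000, int(pos[k + 1]) * 20_000))
    truth.loops = pd.DataFrame(rows, columns=["chrom", "anchor1", "anchor2"]).assign(
        in_CK=True, in_PD=True
    )
    config2 = compartment_config(seed=41, peak_prob_b=0.0)
    peaks = simulate_peaks(config2, truth)
    bins = config.bins()
    anchors = truth.loop_bins("CK", bins)
    anchor_bins = np.unique(np.concatenate([anchors["bin1"], anchors["bin2"]]))
    covered = np.zeros(len(anchor_bins), dtype=bool)
    df = bins.to_dataframe()
    for m in peaks:
        starts = set(zip(peaks[m]["CK"]["chrom"], peaks[m]["CK"]["start"]))
        for k, b in enumerate(anchor_bins):
            key = (df["chrom"].iloc[b], int(df["start"].iloc[b]))
            if key in starts:
                covered[k] = True
    assert covered.mean() == pytest.approx(0.63, abs=0.08)


def test_null_peak_enrichment_is_nonsignificant():
    """enrichment=1 and no anchor coupling: A-vs-B Wilcoxon ns in >=90% of seeds."""
    from chromoswitch.intervals import coverage_per_bin

    ns = 0
    for seed in range(20):
        config = compartment_config(seed=seed, anchor_peak_prob=0.0)
        truth = plan_truth(config)
        bins, _ = make_genome(config, truth)
        peaks = simulate_peaks(config, truth, enrichment=1.0)
        cov = coverage_per_bin(bins, peaks["H3K4me3"]["CK"])
        labels = truth.labels("CK", bins)
        p = wilcoxon_rank_sum(cov[labels == "A"], cov[labels == "B"])
        if p >= 0.05:
            ns += 1
    assert ns >= 18


def test_truth_roundtrip(tmp_path):
    config = compartment_config(seed=51)
    truth = plan_truth(config)
    make_genome(config, truth)
    simulate_genes_expression(config, truth)
    write_truth(truth, tmp_path)
    back = read_truth(tmp_path)
    for cond in ("CK", "PD"):
        pd.testing.assert_frame_equal(truth.compartments[cond], back.compartments[cond])
    pd.testing.assert_frame_equal(truth.switch_regions, back.switch_regions)
    pd.testing.assert_frame_equal(truth.tad_boundaries, back.tad_boundaries)
    pd.testing.assert_frame_equal(truth.loops, back.loops)
    pd.testing.assert_frame_equal(truth.genes, back.genes)
    pd.testing.assert_frame_equal(truth.de_genes, back.de_genes)
    # switch BED carries the direction column with A2B/B2A values
    text = (tmp_path / "switch_regions.bed").read_text().splitlines()
    assert text[0].split("\t") == ["chrom", "start", "end", "direction"]
    assert all(line.split("\t")[3] in ("A2B", "B2A") for line in text[1:])


def test_empty_loop_truth_file_has_header(tmp_path):
    config = compartment_config(
        seed=52, n_loops_common=0, n_loops_ck_only=0, n_loops_pd_only=0
    )
    truth = plan_truth(config)
    make_genome(config, truth)
    simulate_genes_expression(config, truth)
    write_truth(truth, tmp_path)
    lines = (tmp_path / "loops.tsv").read_text().splitlines()
    assert lines[0].startswith("chrom") and len(lines) == 1
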