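"""Shared fixtures: standard desk-scale simulations, reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from chromoswitch.balance import expected_cis, ice_balance, oe_log2
from chromoswitch.sim import SimConfig, make_genome, plan_truth, simulate_contacts


def compartment_config(seed: int, **overrides) -> SimConfig:
    """The standard compartment-study genome: 2 chroms x 5 Mb at 20 kb."""
    kw = dict(seed=seed)
    kw.update(overrides)
    return SimConfig(**kw)


def loop_config(seed: int, **overrides) -> SimConfig:
    """Loop-study genome: one 2.5 Mb chromosome at 5 kb, decay-only background."""
    kw = dict(
        seed=seed,
        n_chromosomes=1,
        chrom_length_bp=2_500_000,
        bin_size_bp=5_000,
        depth=30.0,
        compartment_factor=1.0,
        tad_factor=1.0,
        n_switch_regions=0,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def tad_config(seed: int, **overrides) -> SimConfig:
    """TAD-study genome: 2 chroms x 5 Mb at 10 kb, domains every 300 kb."""
    kw = dict(
        seed=seed,
        bin_size_bp=10_000,
        compartment_factor=1.0,
        n_switch_regions=0,
        loop_factor=1.0,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def balanced_oe(config: SimConfig, condition: str = "CK", bin_size_bp=None):
    truth = plan_truth(config)
    m = simulate_contacts(config, truth, condition, bin_size_bp=bin_size_bp)
    bal = ice_balance(m)
    exp = expected_cis(bal)
    return truth, bal, exp, oe_log2(bal, exp)


@pytest.fixture(scope="session")
def std_truth_and_tracks():
    """One full compartment call for both conditions on the standard genome."""
    import chromoswitch.balance as bal_mod
    from chromoswitch.compartments import call_pc1_compartments

    config = compartment_config(seed=11)
    truth = plan_truth(config)
    bins, genes = make_genome(config, truth)
    gd = np.zeros(bins.n_bins)
    mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
    for c, p in zip(genes["chrom"], mid):
        gd[bins.bin_of(c, int(p))] += 1
    tracks = {}
    for cond in ("CK", "PD"):
        m = simulate_contacts(config, truth, cond)
        bal = ice_balance(m)
        oe = oe_log2(bal, expected_cis(bal))
        corr = {c: bal_mod.correlation_map(oe, c) for c in bins.chroms}
        tracks[cond] = call_pc1_compartments(corr, bins, gd, cond)
    return config, truth, bins, genes, tracks


@pytest.fixture(scope="session")
def sim_workspace(tmp_path_factory):
    """A simulated two-condition workspace plus one completed pipeline run."""
    from chromoswitch.pipeline import PipelineConfig, run_pipeline
    from chromoswitch.sim import write_simulated_workspace

    root = tmp_path_factory.mktemp("workspace")
    cfg_path = write_simulated_workspace(SimConfig(seed=17), root)
    report = run_pipeline(PipelineConfig.from_yaml(cfg_path))
    return root, cfg_path, report
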