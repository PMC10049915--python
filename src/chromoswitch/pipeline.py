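"""Two-condition analysis pipeline: stats -> balance -> expected/OE ->
compartments -> switches -> insulation/boundaries -> loops -> differential
loops/anchors -> integration, from a single declarative YAML config.

Every stage persists its outputs under the configured output directory
(atomic writes), and the run report collects every headline count so that
each number is reproducible from the persisted files.  Reports contain no
timestamps: a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import balance as bal_mod
from . import compartments as comp_mod
from . import insulation as ins_mod
from . import integration as int_mod
from . import loops as loop_mod
from .io import (
    cis_trans_fractions,
    distance_decay,
    interchrom_counts,
    read_hicpro,
    write_bedgraph,
)
from .util import atomic_write

logger = logging.getLogger("chromoswitch")

CONDITIONS = ("CK", "PD")
RESOLUTIONS = {"compartments": 20_000, "insulation": 10_000, "loops": 5_000}


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage '{stage}': {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration (usually loaded from YAML)."""

    output_dir: Path
    matrices: dict[str, dict[int, tuple[Path, Path]]]  # cond -> res -> (matrix, bed)
    genes_bed: Path | None = None
    expression_tsv: Path | None = None
    peaks: dict[str, dict[str, Path]] = field(default_factory=dict)
    go_map_tsv: Path | None = None
    seed: int = 0
    resolutions: dict[str, int] = field(default_factory=lambda: dict(RESOLUTIONS))
    parameters: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        r = self.resolutions
        if not (r["loops"] <= r["insulation"] <= r["compartments"]):
            raise ValueError(
                "resolutions must satisfy loops <= insulation <= compartments"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        def p(x):
            q = Path(x)
            return q if q.is_absolute() else base / q
        matrices: dict[str, dict[int, tuple[Path, Path]]] = {}
        for cond, entries in raw["matrices"].items():
            matrices[cond] = {
                int(res): (p(v["matrix"]), p(v["bed"]))
                for res, v in entries.items()
            }
        peaks = {
            mark: {cond: p(path) for cond, path in conds.items()}
            for mark, conds in raw.get("peaks", {}).items()
        }
        return cls(
            output_dir=p(raw["output_dir"]),
            matrices=matrices,
            genes_bed=p(raw["genes_bed"]) if raw.get("genes_bed") else None,
            expression_tsv=p(raw["expression_tsv"]) if raw.get("expression_tsv") else None,
            peaks=peaks,
            go_map_tsv=p(raw["go_map_tsv"]) if raw.get("go_map_tsv") else None,
            seed=int(raw.get("seed", 0)),
            resolutions={**RESOLUTIONS, **{
                k: int(v) for k, v in raw.get("resolutions", {}).items()
            }},
            parameters=raw.get("parameters", {}),
        )

    def validate_inputs(self) -> None:
        missing = []
        for cond, entries in self.matrices.items():
            for res, (mp, bp) in entries.items():
                for q in (mp, bp):
                    if not Path(q).exists():
                        missing.append(str(q))
        for q in (self.genes_bed, self.expression_tsv, self.go_map_tsv):
            if q is not None and not Path(q).exists():
                missing.append(str(q))
        for conds in self.peaks.values():
            for q in conds.values():
                if not Path(q).exists():
                    missing.append(str(q))
        if missing:
            raise FileNotFoundError("missing input files: " + ", ".join(missing))


def _load_genes(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "name" not in df.columns:       # headerless BED6
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run report (also written to disk)."""
    from . import __version__

    config.validate_inputs()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "tool": "chromoswitch",
        "version": __version__,
        "seed": config.seed,
        "resolutions": dict(config.resolutions),
        "parameters": config.parameters,
        "stages": {},
    }

    genes = _load_genes(config.genes_bed) if config.genes_bed else None
    expr = (
        int_mod.de_flag(pd.read_csv(config.expression_tsv, sep="\t"))
        if config.expression_tsv
        else None
    )
    peaks = {
        mark: {cond: pd.read_csv(path, sep="\t") for cond, path in conds.items()}
        for mark, conds in config.peaks.items()
    }

    def timed(stage):
        def deco(fn):
            def wrapper(*a, **kw):
                t0 = time.perf_counter()
                try:
                    res = fn(*a, **kw)
                except PipelineError:
                    raise
                except Exception as exc:
                    raise PipelineError(stage, str(exc)) from exc
                logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)
                return res
            return wrapper
        return deco

    # ---- stats ------------------------------------------------------------
    @timed("stats")
    def stage_stats():
        res = config.resolutions["compartments"]
        block = {}
        for cond in CONDITIONS:
            mp, bp = config.matrices[cond][res]
            m = read_hicpro(mp, bp, condition=cond)
            ct = cis_trans_fractions(m)
            dd = distance_decay(m)
            ic = interchrom_counts(m) if len(m.bins.chroms) > 1 else None
            with atomic_write(out / f"stats_{cond}.tsv") as fh:
                pd.DataFrame(
                    {
                        "metric": ["cis_fraction", "decay_exponent"],
                        "value": [ct["cis_fraction"], dd["exponent"]],
                    }
                ).to_csv(fh, sep="\t", index=False)
            if ic is not None:
                with atomic_write(out / f"interchrom_{cond}.tsv") as fh:
                    ic.to_csv(fh, sep="\t")
            block[cond] = {
                "cis_fraction": ct["cis_fraction"],
                "decay_exponent": dd["exponent"],
            }
        return block

    report["stages"]["stats"] = stage_stats()

    # ---- balance / expected / OE at each resolution -----------------------
    bal_params = config.parameters.get("balance", {})
    exp_params = config.parameters.get("expected", {})

    @timed("balance")
    def stage_balance():
        cache: dict[tuple[str, int], tuple] = {}
        for cond in CONDITIONS:
            for res in sorted(set(config.resolutions.values())):
                mp, bp = config.matrices[cond][res]
                m = read_hicpro(mp, bp, condition=cond)
                b = bal_mod.ice_balance(m, **bal_params)
                e = bal_mod.expected_cis(b, **exp_params)
                o = bal_mod.oe_log2(b, e)
                cache[(cond, res)] = (b, e, o)
                wdf = pd.DataFrame(
                    {
                        "bin": np.arange(m.bins.n_bins),
                        "weight": b.balance.weights,
                        "masked": b.balance.mask.astype(int),
                    }
                )
                with atomic_write(out / f"weights_{cond}_{res}.tsv") as fh:
                    wdf.to_csv(fh, sep="\t", index=False)
        return cache

    cache = stage_balance()

    # ---- compartments + switches ------------------------------------------
    comp_res = config.resolutions["compartments"]

    @timed("compartments")
    def stage_compartments():
        tracks = {}
        for cond in CONDITIONS:
            b, e, o = cache[(cond, comp_res)]
            bins = b.bins
            corr = {c: bal_mod.correlation_map(o, c) for c in bins.chroms}
            if genes is not None:
                gd = np.zeros(bins.n_bins)
                mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
                for c, p_ in zip(genes["chrom"], mid):
                    gd[bins.bin_of(c, int(p_))] += 1
            else:
                gd = np.zeros(bins.n_bins)
            track = comp_mod.call_pc1_compartments(corr, bins, gd, cond)
            write_bedgraph(bins, track.pc1, out / f"pc1_{cond}.bedgraph")
            tracks[cond] = track
        regions, counts = comp_mod.compartment_switches(tracks["CK"], tracks["PD"])
        with atomic_write(out / "switch_regions.bed") as fh:
            regions.to_csv(fh, sep="\t", index=False)
        summary = {cond: comp_mod.compartment_summary(tracks[cond]) for cond in CONDITIONS}
        return tracks, regions, counts, summary

    tracks, switch_regions, switch_counts, comp_summary = stage_compartments()
    report["stages"]["compartments"] = {
        "A_fraction": {c: comp_summary[c]["A_fraction"] for c in CONDITIONS},
        "switch_counts": switch_counts,
        "n_switch_regions": int(len(switch_regions)),
    }

    # ---- insulation / boundaries ------------------------------------------
    ins_res = config.resolutions["insulation"]
    ins_params = config.parameters.get("insulation", {})

    @timed("insulation")
    def stage_insulation():
        result = {}
        for cond in CONDITIONS:
            b, _, _ = cache[(cond, ins_res)]
            track = ins_mod.insulation_track(
                b, window_bp=ins_params.get("window_bp", 200_000), condition=cond
            )
            bd, tads = ins_mod.call_boundaries(
                track,
                delta_window_bp=ins_params.get("delta_window_bp", 100_000),
                min_strength=ins_params.get("min_strength", 0.1),
            )
            write_bedgraph(track.bins, track.score, out / f"insulation_{cond}.bedgraph")
            with atomic_write(out / f"boundaries_{cond}.bed") as fh:
                pd.DataFrame(
                    [(x.chrom, x.start, x.end, f"{x.strength:.4f}") for x in bd],
                    columns=["chrom", "start", "end", "strength"],
                ).to_csv(fh, sep="\t", index=False)
            with atomic_write(out / f"tads_{cond}.bed") as fh:
                tads.to_csv(fh, sep="\t", index=False)
            result[cond] = (bd, tads)
        return result

    ins_result = stage_insulation()
    report["stages"]["insulation"] = {
        "n_boundaries": {c: len(ins_result[c][0]) for c in CONDITIONS},
        "n_tads": {c: int(len(ins_result[c][1])) for c in CONDITIONS},
    }

    # ---- loops + differential ---------------------------------------------
    loop_res = config.resolutions["loops"]
    loop_params = loop_mod.LoopCallParams(**config.parameters.get("loops", {}))

    @timed("loops")
    def stage_loops():
        calls = {}
        oes = {}
        for cond in CONDITIONS:
            b, e, o = cache[(cond, loop_res)]
            # local Poisson backgrounds need the unbiased per-distance mean;
            # the lowess-smoothed profile misfits structured decay (TAD kink)
            # and miscalibrates lambda
            e_raw = bal_mod.expected_cis(b, span=0.0)
            calls[cond] = loop_mod.call_loops(b, e_raw, loop_params, condition=cond)
            oes[cond] = o
            with atomic_write(out / f"loops_{cond}.bedpe") as fh:
                calls[cond].to_csv(fh, sep="\t", index=False)
        merged = loop_mod.merge_and_score(
            calls["CK"], calls["PD"], oes["CK"], oes["PD"],
            cutoff=config.parameters.get("diffloops", {}).get("cutoff", 1.0),
        )
        if genes is not None:
            merged = loop_mod.classify_anchors(merged, genes)
        with atomic_write(out / "loops_merged.bedpe") as fh:
            merged.to_csv(fh, sep="\t", index=False)
        lengths = loop_mod.loop_length_summary(merged)
        with atomic_write(out / "loop_lengths.tsv") as fh:
            lengths.to_csv(fh, sep="\t", index=False)
        return calls, merged, lengths

    loop_calls, merged_loops, loop_lengths = stage_loops()
    block = {
        "n_called": {c: int(len(loop_calls[c])) for c in CONDITIONS},
        "n_merged": int(len(merged_loops)),
        "classes": merged_loops["class"].value_counts().to_dict()
        if len(merged_loops) else {},
        "origins": merged_loops["origin"].value_counts().to_dict()
        if len(merged_loops) else {},
    }
    if "style" in merged_loops.columns and len(merged_loops):
        block["styles"] = merged_loops["style"].value_counts().to_dict()
    report["stages"]["loops"] = block

    # ---- integration -------------------------------------------------------
    @timed("integration")
    def stage_integration():
        result: dict[str, Any] = {}
        if genes is not None and expr is not None:
            for cond in CONDITIONS:
                result[f"ab_genes_{cond}"] = int_mod.ab_gene_stats(
                    tracks[cond], genes, expr, cond
                )
            ov = int_mod.region_de_overlap(switch_regions, genes, expr)
            with atomic_write(out / "switch_de_genes.tsv") as fh:
                ov.to_csv(fh, sep="\t", index=False)
            result["switch_de_counts"] = {
                f"{cls}_{d}": int(n)
                for (cls, d), n in ov.groupby(
                    ["region_class", "de_direction"]
                ).size().items()
            }
        for mark, conds in peaks.items():
            for cond in CONDITIONS:
                if cond in conds and genes is not None:
                    result[f"ab_peaks_{mark}_{cond}"] = int_mod.ab_peak_stats(
                        tracks[cond], conds[cond]
                    )
            if set(CONDITIONS) <= set(conds):
                part = int_mod.specific_peaks(conds["CK"], conds["PD"])
                result[f"specific_peaks_{mark}"] = {
                    k: int(len(v)) for k, v in part.items()
                }
                if expr is not None and genes is not None:
                    result[f"de_by_peak_group_{mark}"] = int_mod.de_by_peak_group(
                        expr, part, genes
                    )
        if peaks and len(merged_loops):
            by_mark = {m: peaks[m]["CK"] for m in peaks if "CK" in peaks[m]}
            if by_mark:
                result["anchor_marks"] = int_mod.anchor_mark_fraction(
                    merged_loops, by_mark
                )
        if config.go_map_tsv is not None and expr is not None:
            term_map = pd.read_csv(config.go_map_tsv, sep="\t")
            de_ids = set(expr.loc[expr["de"], "gene_id"])
            go = int_mod.go_hypergeometric(
                de_ids, set(expr["gene_id"]), term_map
            )
            with atomic_write(out / "go_enrichment.tsv") as fh:
                go.to_csv(fh, sep="\t", index=False)
            result["go_significant_terms"] = int(go["significant"].sum()) if len(go) else 0
        return result

    report["stages"]["integration"] = stage_integration()
    write_report(report, out / "report.json")
    return report


def _sanitize(obj):
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Schema-stable JSON report; round-trips through parse/serialize."""
    with atomic_write(path) as fh:
        json.dump(_sanitize(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def summarize_report(report: dict) -> str:
    """Human-readable one-screen summary of the headline statistics."""
    lines = [f"chromoswitch {report.get('version', '?')} run (seed {report.get('seed')})"]
    st = report.get("stages", {})
    if "stats" in st:
        for cond, v in st["stats"].items():
            lines.append(
                f"  [{cond}] cis fraction {v['cis_fraction']:.3f}, "
                f"decay exponent {v['decay_exponent']:.2f}   (stats_{cond}.tsv)"
            )
    if "compartments" in st:
        c = st["compartments"]
        lines.append(
            f"  A fraction CK {c['A_fraction']['CK']:.3f} / PD {c['A_fraction']['PD']:.3f}; "
            f"switches A2B {c['switch_counts']['A2B']} B2A {c['switch_counts']['B2A']}"
            "   (switch_regions.bed)"
        )
    if "insulation" in st:
        i = st["insulation"]
        lines.append(
            f"  boundaries CK {i['n_boundaries']['CK']} / PD {i['n_boundaries']['PD']}"
            "   (boundaries_*.bed)"
        )
    if "loops" in st:
        l = st["loops"]
        lines.append(
            f"  loops CK {l['n_called']['CK']} / PD {l['n_called']['PD']}, "
            f"merged {l['n_merged']} {l.get('classes', {})}   (loops_merged.bedpe)"
        )
    return "\n".join(lines)
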