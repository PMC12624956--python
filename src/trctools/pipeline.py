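"""Configuration-driven orchestration: simulate -> tracks -> metrics -> report.

A run is described by a YAML/dict configuration naming genotypes (one of
which is the reference), per-assay simulation parameters per genotype, and
analysis parameters. Everything is funnelled through seeded generators, so
a run is deterministic: the same config + seed produce a byte-identical
report JSON.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import coverage as cv
from . import forks as fk
from . import pausing as ps
from . import rfd as rf
from . import simulate as sim
from .genome import read_annotations, read_chrom_sizes, read_origins
from .genome import write_annotations, write_chrom_sizes, write_origins

log = logging.getLogger("trctools")

_GENOTYPE_KEYS = {
    "pause_ratio",
    "strand_noise",
    "fork_speed_mean",
    "fork_speed_sd",
    "headon_multiplier",
    "chip_enrichment",
    "proseq_reads",  # optional path: skip simulation for this assay
    "gloe_events",
    "brdu_signal",
}


def demo_config() -> dict:
    """Two-genotype simulated study, desk-scale."""
    return {
        "seed": 0,
        "reference": "WT",
        "genotypes": {
            "WT": {"pause_ratio": 6.0, "strand_noise": 0.05, "fork_speed_mean": 1.8,
                   "headon_multiplier": 1.0},
            "mutant": {"pause_ratio": 2.0, "strand_noise": 0.15, "fork_speed_mean": 1.6,
                       "headon_multiplier": 0.8},
        },
        "sim": {
            "n_reads_proseq": 50_000,
            "n_reads_gloeseq": 50_000,
            "n_brdu_reads": 60,
        },
        "pause": {"pause_width": 100, "term_width": 200, "min_body_events": 10},
        "rfd": {"bin_size": 1000, "flank": 10_000, "min_delta": 0.5, "smooth_bins": 5},
        "fork": {"bin_size": 100, "min_amplitude": 0.3},
        "paths": {},
    }


def validate(config: Mapping[str, Any]) -> list[str]:
    """Return a list of problems; empty iff a run would start."""
    problems: list[str] = []
    genotypes = config.get("genotypes")
    if not isinstance(genotypes, Mapping) or not genotypes:
        problems.append("genotypes: must be a non-empty mapping")
        genotypes = {}
    ref = config.get("reference")
    if not ref:
        problems.append("reference: missing")
    elif genotypes and ref not in genotypes:
        problems.append(f"reference: genotype {ref!r} not among genotypes")
    for label, block in genotypes.items():
        if not isinstance(block, Mapping):
            problems.append(f"genotypes.{label}: must be a mapping")
            continue
        for key in block:
            if key not in _GENOTYPE_KEYS:
                problems.append(f"genotypes.{label}.{key}: unknown parameter")
    for section, key, cond, msg in [
        ("rfd", "bin_size", lambda v: v >= 1, "must be >= 1"),
        ("rfd", "flank", lambda v: v >= 1, "must be >= 1"),
        ("rfd", "smooth_bins", lambda v: v >= 1, "must be >= 1"),
        ("pause", "pause_width", lambda v: v >= 1, "must be >= 1"),
        ("pause", "term_width", lambda v: v >= 1, "must be >= 1"),
        ("fork", "bin_size", lambda v: v >= 1, "must be >= 1"),
    ]:
        v = config.get(section, {}).get(key)
        if v is not None and not cond(v):
            problems.append(f"{section}.{key}: {msg} (got {v})")
    for cmp_label in config.get("comparisons", []):
        if cmp_label not in genotypes:
            problems.append(f"comparisons: unknown genotype {cmp_label!r}")
    paths = config.get("paths", {}) or {}
    for key, p in paths.items():
        if p and not Path(p).exists():
            problems.append(f"paths.{key}: file not found: {p}")
    return problems


def _child_seed(master: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def run(config: Mapping[str, Any], outdir: str | Path, seed: int | None = None) -> dict:
    """Execute the full pipeline and return the run report (also written to
    ``<outdir>/report.json`` with every figure-level table alongside)."""
    problems = validate(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0) if seed is None else seed)
    t0 = time.time()

    paths = config.get("paths", {}) or {}
    if paths.get("chrom_sizes"):
        layout = read_chrom_sizes(paths["chrom_sizes"])
        genes = read_annotations(paths["genes"], layout)
        origins = read_origins(paths["origins"], layout)
    else:
        layout, genes, origins = sim.toy_genome(master_seed)
    write_chrom_sizes(layout, outdir / "genome.chrom.sizes")
    write_annotations(genes, outdir / "genes.bed")
    write_origins(origins, outdir / "origins.bed")

    sim_block = dict(config.get("sim", {}))
    pause_cfg = ps.PauseConfig(**config.get("pause", {}))
    rfd_block = dict(config.get("rfd", {}))
    fork_block = dict(config.get("fork", {}))

    report: dict[str, Any] = {
        "config": _jsonable(config),
        "seed": master_seed,
        "genotypes": {},
        "comparisons": {},
    }
    metrics_by_genotype: dict[str, Any] = {}
    reference = config["reference"]

    for gi, (label, block) in enumerate(config["genotypes"].items()):
        log.info("genotype %s: simulating and analysing", label)
        gdir = outdir / label
        gdir.mkdir(exist_ok=True)
        sub_seed = _child_seed(master_seed, gi)
        scfg = sim.SimConfig(
            seed=sub_seed,
            layout=layout,
            genes=list(genes),
            origins=list(origins),
            **sim_block,
            **{k: v for k, v in block.items() if not k.endswith(("_reads", "_events", "_signal"))},
        )
        entry: dict[str, Any] = {}

        # --- nascent transcription: 5' events -> PI/TI
        if block.get("proseq_reads"):
            reads = cv.read_bed_reads(block["proseq_reads"])
        else:
            reads, _ = sim.simulate_proseq(scfg)
        cov5 = cv.reads_to_5prime_events(reads, layout)
        cov5_rpm = cv.rpm_normalize(cov5)
        cv.write_bedgraph(cov5_rpm, gdir / "proseq_5prime_rpm")
        metrics = ps.compute_gene_metrics(cov5_rpm, genes, pause_cfg)
        metrics.to_csv(gdir / "gene_metrics.tsv", sep="\t", float_format="%.6g")
        metrics_by_genotype[label] = metrics
        entry["pi_median"] = _round(metrics["pi"].median())
        entry["ti_median"] = _round(metrics["ti"].median())
        entry["n_genes_pi_defined"] = int(metrics["pi"].notna().sum())
        entry["n_genes_ti_defined"] = int(metrics["ti"].notna().sum())

        # --- replication end capture: RFD profile and origins
        if block.get("gloe_events"):
            ev_reads = cv.read_bed_reads(block["gloe_events"])
            events = [
                sim.StrandedEvent(r.chrom, r.start, r.strand) for r in ev_reads
            ]
        else:
            events, _ = sim.simulate_gloeseq(scfg)
        cov3 = sim.events_to_coverage(events, layout)
        profile = rf.rfd_profile(cov3, bin_size=rfd_block.get("bin_size", 1000))
        profile.to_tsv(gdir / "rfd_profile.tsv")
        profile.to_bedgraph(gdir / "rfd.bedgraph")
        delta_table, delta_summary = rf.delta_rfd_at_origins(
            profile,
            origins,
            flank=rfd_block.get("flank", 10_000),
            chrom_lengths=layout.chrom_lengths,
        )
        delta_table.to_csv(gdir / "origin_delta_rfd.tsv", sep="\t", index=False, float_format="%.6g")
        asc, desc = rf.detect_origins(
            profile,
            min_delta=rfd_block.get("min_delta", 0.5),
            smooth_bins=rfd_block.get("smooth_bins", 5),
        )
        rf.write_origin_calls_bed(asc, gdir / "origin_calls.bed")
        entry["rfd_origin_delta"] = {k: _round(v) for k, v in delta_summary.items()}
        entry["n_origin_calls"] = len(asc)
        entry["n_termination_calls"] = len(desc)

        # --- single-molecule fork speeds
        if block.get("brdu_signal"):
            brdu_reads = fk.read_brdu_tsv(block["brdu_signal"])
        else:
            brdu_reads, _ = sim.simulate_brdu_reads(scfg)
        fcfg = fk.ForkConfig(
            bin_size=fork_block.get("bin_size", 100),
            t_pulse=scfg.t_pulse,
            t_fall=scfg.t_fall,
            rise_width=scfg.rise_width,
            min_amplitude=fork_block.get("min_amplitude", 0.3),
        )
        calls = [c for r in brdu_reads for c in fk.detect_forks(r, fcfg)]
        fk.write_fork_calls_tsv(calls, gdir / "fork_calls.tsv")
        usable = [c for c in calls if c.speed is not None]
        if usable:
            summ = fk.speed_summary(usable, ["all"] * len(usable))["all"]
            entry["fork_speed"] = {k: _round(v) for k, v in summ.items()}
        relation_speeds: dict[str, dict[str, list[float]]] = {"head_on": {}, "co_directional": {}}
        for c in usable:
            if c.direction is None:
                continue
            for a in fk.classify_fork(c, genes):
                if a.primary:
                    relation_speeds[a.relation].setdefault(a.gene_id, []).append(c.speed)
        by_rel = {
            rel: [s for per_gene in d.values() for s in per_gene]
            for rel, d in relation_speeds.items()
        }
        entry["fork_speed_by_relation"] = {
            rel: {"median": _round(float(np.median(v))), "n": len(v)} if v else {"median": None, "n": 0}
            for rel, v in by_rel.items()
        }
        head_med = {g: float(np.median(v)) for g, v in relation_speeds["head_on"].items()}
        co_med = {g: float(np.median(v)) for g, v in relation_speeds["co_directional"].items()}
        # pairing unit is the gene; fall back to an unpaired comparison when
        # too few genes carry forks of both relations
        paired_keys = set(head_med) & set(co_med)
        if len(paired_keys) >= 5:
            res = fk.compare_groups((head_med, co_med), design="paired_by_gene")
            entry["headon_vs_co_test"] = _jsonable(res.to_dict())
        elif len(by_rel["head_on"]) >= 2 and len(by_rel["co_directional"]) >= 2:
            res = fk.compare_groups(
                [by_rel["head_on"], by_rel["co_directional"]], design="unpaired"
            )
            entry["headon_vs_co_test"] = _jsonable(res.to_dict())
        else:
            entry["headon_vs_co_test"] = None

        report["genotypes"][label] = entry

    # --- comparisons to the reference genotype
    ref_metrics = metrics_by_genotype[reference]
    for label, metrics in metrics_by_genotype.items():
        if label == reference:
            continue
        cmp_entry: dict[str, Any] = {}
        for metric in ("pi", "ti"):
            try:
                ratios, median, n_excl = ps.normalize_to_reference(metrics, ref_metrics, metric)
            except Exception:
                cmp_entry[metric] = None
                continue
            cmp_entry[metric] = {
                "median_log2_ratio": _round(median),
                "fraction_decreased": _round(ps.fraction_decreased(ratios)),
                "n_genes": int(len(ratios)),
                "n_excluded": int(n_excl),
            }
            ratios.to_csv(outdir / f"{label}_vs_{reference}_{metric}_log2.tsv", sep="\t")
        report["comparisons"][f"{label}_vs_{reference}"] = cmp_entry

    report["runtime_s"] = None  # excluded from the byte-identity contract
    text = json.dumps(report, sort_keys=True, indent=2)
    (outdir / "report.json").write_text(text)
    log.info("run finished in %.1f s", time.time() - t0)
    return report


def _round(v, nd: int = 6):
    if v is None:
        return None
    try:
        f = float(v)
    except (TypeError, ValueError):
        return v
    if not np.isfinite(f):
        return None
    return round(f, nd)


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else _round(f)
    return obj


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
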