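"""Full-analysis orchestration: simulate/ingest -> annotate -> diversity ->
sweep scans -> LD -> tree/PCA, with publication-style table outputs.

One scan is run per (wild, cultivated) contrast, each with its own pair of
right-tail thresholds, mirroring the per-contrast design of multi-group
domestication studies.  All randomness flows from a single top-level seed;
per-stage seeds are derived deterministically, so identical configurations
produce byte-identical output bundles (wall-clock timings are written to a
separate ``timings.json`` which is the only non-deterministic artifact).
"""
from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation as ann_mod
from . import diversity as div_mod
from . import ld as ld_mod
from . import structure_phylo as sp_mod
from . import sweep_scan as scan_mod
from ._utils import derive_seed
from .errors import PipelineError, ValidationError
from .variant_io import (
    GenotypeMatrix,
    filter_sites,
    read_fasta,
    read_gff,
    read_grouping,
    read_vcf,
)

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    vcf: str
    gff: str
    fasta: str
    groups_file: str
    out_dir: str
    wild_group: str = "wild"
    cultivated_groups: list | None = None  # default: every other group with >= 2 samples
    min_qual: float = 20.0
    min_maf: float = 0.1
    max_missing: float = 1.0
    scan: scan_mod.ScanConfig = field(default_factory=scan_mod.ScanConfig)
    ld_max_dist: int = 50_000
    ld_bin_width: int = 100
    ld_max_pairs: int = 1_000_000
    bootstrap: int = 100
    pca_components: int = 10
    seed: int = 0


class _Run:
    """Bookkeeping for one pipeline execution (created files, timings)."""

    def __init__(self, out_dir):
        self.out_dir = out_dir
        self.created: list = []
        self.timings: dict = {}
        self.log: dict = {"stages": []}

    def path(self, name: str) -> str:
        p = os.path.join(self.out_dir, name)
        self.created.append(p)
        return p

    def cleanup(self):
        for p in self.created:
            if os.path.exists(p):
                os.remove(p)


def _write_tsv(df: pd.DataFrame, path: str):
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def format_table1(summaries: dict) -> pd.DataFrame:
    """Fixed-column per-group SNP summary table.

    Columns: group, n, total, private, theta_pi_e3, utr3, utr5, utr5_utr3,
    intergenic, intronic, cds_total, nonsynonymous, stopgain, stoploss,
    synonymous, unknown, nonsyn_syn_ratio, total_genes — independent of the
    insertion order of ``summaries``.
    """
    rows = []
    order = sorted((k for k in summaries if k != "total")) + (
        ["total"] if "total" in summaries else []
    )
    for key in order:
        s = summaries[key]
        rows.append(
            {
                "group": s.group,
                "n": s.n_samples,
                "total": s.total,
                "private": s.private,
                "theta_pi_e3": s.theta_pi_e3,
                "utr3": s.region_counts.get("utr3", 0),
                "utr5": s.region_counts.get("utr5", 0),
                "utr5_utr3": s.region_counts.get("utr5_utr3", 0),
                "intergenic": s.region_counts.get("intergenic", 0),
                "intronic": s.region_counts.get("intronic", 0),
                "cds_total": s.cds_total,
                "nonsynonymous": s.effect_counts.get("nonsynonymous", 0),
                "stopgain": s.effect_counts.get("stopgain", 0),
                "stoploss": s.effect_counts.get("stoploss", 0),
                "synonymous": s.effect_counts.get("synonymous", 0),
                "unknown": s.unknown,
                "nonsyn_syn_ratio": s.nonsyn_syn_ratio,
                "total_genes": s.genes_touched,
            }
        )
    cols = [
        "group", "n", "total", "private", "theta_pi_e3", "utr3", "utr5",
        "utr5_utr3", "intergenic", "intronic", "cds_total", "nonsynonymous",
        "stopgain", "stoploss", "synonymous", "unknown", "nonsyn_syn_ratio",
        "total_genes",
    ]
    return pd.DataFrame(rows, columns=cols)


def run_full(cfg: RunConfig) -> dict:
    """Run every stage and emit the report bundle into ``cfg.out_dir``.

    Returns a dict with the run log and output paths.  Any stage failure
    removes the partial outputs and raises :class:`PipelineError` naming
    the stage.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    run = _Run(cfg.out_dir)
    state: dict = {}
    try:
        _stage(run, "ingest", _ingest, cfg, state)
        _stage(run, "annotate", _annotate, cfg, state)
        _stage(run, "diversity", _diversity, cfg, state)
        _stage(run, "scan", _scan, cfg, state)
        _stage(run, "ld", _ld, cfg, state)
        _stage(run, "tree", _tree, cfg, state)
        _stage(run, "pca", _pca, cfg, state)
        _stage(run, "log", _finalize, cfg, state)
    except PipelineError:
        run.cleanup()
        raise
    except Exception as exc:  # noqa: BLE001
        run.cleanup()
        raise PipelineError(state.get("_stage", "?"), str(exc)) from exc
    return {"log": run.log, "paths": run.created, "state": state}


def _stage(run: _Run, name: str, fn, cfg, state):
    state["_stage"] = name
    state["_run"] = run
    t0 = time.perf_counter()
    fn(cfg, state)
    run.timings[name] = time.perf_counter() - t0
    run.log["stages"].append(name)


def _ingest(cfg: RunConfig, state):
    gm_raw = read_vcf(cfg.vcf, min_qual=cfg.min_qual)
    grouping = read_grouping(cfg.groups_file, gm_raw)
    reference = read_fasta(cfg.fasta)
    genes = read_gff(cfg.gff)
    chrom_lengths = {c: len(s) for c, s in reference.items()}

    wild = cfg.wild_group
    if wild not in grouping.labels:
        raise ValidationError(f"wild group '{wild}' not present in grouping")
    cultivated = cfg.cultivated_groups
    if cultivated is None:
        cultivated = [
            g
            for g in grouping.labels
            if g != wild and len(grouping.samples_in(g)) >= 2
        ]
    unknown = [g for g in cultivated if g not in grouping.labels]
    if unknown:
        raise ValidationError(f"unknown cultivated group(s): {', '.join(unknown)}")

    state.update(
        gm_raw=gm_raw,
        gm=filter_sites(gm_raw, min_maf=cfg.min_maf, max_missing=cfg.max_missing),
        grouping=grouping,
        reference=reference,
        genes=genes,
        chrom_lengths=chrom_lengths,
        contrasts=[(wild, c) for c in cultivated],
    )


def _annotate(cfg: RunConfig, state):
    run: _Run = state["_run"]
    annot = ann_mod.GenomeAnnotator(state["genes"], state["reference"])
    gm: GenotypeMatrix = state["gm"]
    ann = annot.annotate(gm)
    state["annotations"] = ann

    snp_idx = np.flatnonzero(gm.sites["vclass"].to_numpy() == "snp")
    gm_snp = gm.take_sites(snp_idx)
    ann_snp = ann.iloc[snp_idx].reset_index(drop=True)
    summaries = ann_mod.summarize(gm_snp, state["grouping"], ann_snp)
    state["summaries"] = summaries

    venn = ann_mod.venn_from_matrix(gm_snp, state["grouping"])
    venn_df = pd.DataFrame(
        sorted(
            ({"groups": ";".join(k), "n_groups": len(k), "count": v} for k, v in venn.items()),
            key=lambda r: (r["n_groups"], r["groups"]),
        )
    )
    _write_tsv(venn_df, run.path("venn_counts.tsv"))
    state["venn"] = venn


def _diversity(cfg: RunConfig, state):
    run: _Run = state["_run"]
    gm, grouping = state["gm"], state["grouping"]
    genome_length = sum(state["chrom_lengths"].values())

    rows = []
    for label in grouping.labels:
        if len(grouping.samples_in(label)) < 2:
            continue
        res = div_mod.group_theta_pi(gm, grouping, label, genome_length)
        rows.append(
            {
                "group": label,
                "theta_pi_per_bp": res.theta_pi_per_bp,
                "theta_pi_e3": res.theta_pi_e3,
                "n_snps_used": res.n_snps_used,
                "length": res.callable_length,
            }
        )
        if label in state["summaries"]:
            state["summaries"][label].theta_pi_e3 = res.theta_pi_e3
    _write_tsv(pd.DataFrame(rows), run.path("diversity_by_group.tsv"))
    _write_tsv(format_table1(state["summaries"]), run.path("annotation_summary.tsv"))

    het_rows = []
    for s in gm.samples:
        st = div_mod.heterozygosity_rate(state["gm_raw"], s, genome_length)
        het_rows.append(
            {
                "sample": s,
                "group": grouping.assignment[s],
                "het_snp_count": st.het_snp_count,
                "het_rate_pct": st.het_rate,
            }
        )
    _write_tsv(pd.DataFrame(het_rows), run.path("heterozygosity_by_sample.tsv"))


def _scan(cfg: RunConfig, state):
    run: _Run = state["_run"]
    gm, grouping = state["gm"], state["grouping"]
    thresholds, summary_rows = {}, []
    pi_frames = []
    for wild, cult in state["contrasts"]:
        stats = scan_mod.compute_window_stats(
            gm, grouping, wild, cult, state["chrom_lengths"], cfg.scan
        )
        stats, thr = scan_mod.flag_outliers(stats, cfg.scan)
        thresholds[cult] = thr
        regions = scan_mod.merge_regions(stats)
        regions = scan_mod.assign_genes(regions, state["genes"])
        state.setdefault("regions", {})[cult] = regions

        _write_tsv(stats, run.path(f"window_stats_{cult}.tsv"))
        with open(run.path(f"selected_regions_{cult}.bed"), "w") as fh:
            for r in regions:
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.n_windows_merged}"
                    f"\t{r.mean_fst:.6g}\t{r.mean_log2_ratio:.6g}"
                    f"\t{','.join(r.genes) if r.genes else '.'}\n"
                )
        with open(run.path(f"selected_genes_{cult}.txt"), "w") as fh:
            for gid in sorted({g for r in regions for g in r.genes}):
                fh.write(gid + "\n")

        summary_rows.append(
            scan_mod.region_summary(
                regions, gm, grouping, cult, state.get("annotations")
            )
        )
        pw = stats[["chrom", "start", "end", "pi_wild", "pi_cult", "n_snps"]].copy()
        pw.insert(3, "contrast", f"{wild}_vs_{cult}")
        pi_frames.append(pw)

    _write_tsv(pd.DataFrame(summary_rows), run.path("region_summary.tsv"))
    _write_tsv(pd.concat(pi_frames, ignore_index=True), run.path("windowed_pi.tsv"))
    with open(run.path("scan_thresholds.json"), "w") as fh:
        json.dump(thresholds, fh, indent=2, sort_keys=True)
    state["thresholds"] = thresholds


def _ld(cfg: RunConfig, state):
    run: _Run = state["_run"]
    gm, grouping = state["gm"], state["grouping"]
    decay_frames, summary_rows = [], []
    for label in grouping.labels:
        if len(grouping.samples_in(label)) < 4:
            continue
        curve = ld_mod.decay_curve(
            gm,
            grouping,
            label,
            max_dist=cfg.ld_max_dist,
            bin_width=cfg.ld_bin_width,
            max_pairs=cfg.ld_max_pairs,
            seed=derive_seed(cfg.seed, f"ld:{label}"),
        )
        curve = curve.copy()
        curve.insert(0, "group", label)
        decay_frames.append(curve)
        half = ld_mod.decay_distance(curve, fraction=0.5)
        summary_rows.append(
            {
                "group": label,
                "half_decay_bp": half if half is not None else "NA",
                "decay_to_r2_0.75_bp": _maybe(
                    ld_mod.decay_distance(curve, absolute=0.75)
                ),
            }
        )
    _write_tsv(pd.concat(decay_frames, ignore_index=True), run.path("ld_decay.tsv"))
    _write_tsv(pd.DataFrame(summary_rows), run.path("ld_summary.tsv"))


def _maybe(x):
    return x if x is not None else "NA"


def _tree(cfg: RunConfig, state):
    run: _Run = state["_run"]
    tree = sp_mod.bootstrap_support(
        state["gm"],
        n_replicates=cfg.bootstrap,
        seed=derive_seed(cfg.seed, "bootstrap"),
    )
    with open(run.path("tree.nwk"), "w") as fh:
        fh.write(sp_mod.write_newick(tree) + "\n")
    state["tree"] = tree


def _pca(cfg: RunConfig, state):
    run: _Run = state["_run"]
    coords, explained = sp_mod.pca(state["gm"], n_components=cfg.pca_components)
    out = coords.copy()
    out.insert(0, "sample", coords.index)
    out.insert(1, "group", [state["grouping"].assignment[s] for s in coords.index])
    _write_tsv(out.reset_index(drop=True), run.path("pca_coords.tsv"))
    _write_tsv(
        pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(explained))],
                "explained_fraction": explained,
            }
        ),
        run.path("pca_eigenvalues.tsv"),
    )


def _finalize(cfg: RunConfig, state):
    run: _Run = state["_run"]
    log = {
        "seed": cfg.seed,
        "min_qual": cfg.min_qual,
        "min_maf": cfg.min_maf,
        "max_missing": cfg.max_missing,
        "window_size": cfg.scan.window_size,
        "step": cfg.scan.step,
        "tail_quantile": cfg.scan.tail_quantile,
        "min_snps_per_window": cfg.scan.min_snps_per_window,
        "bootstrap": cfg.bootstrap,
        "contrasts": [list(c) for c in state["contrasts"]],
        "thresholds": state["thresholds"],
        "n_sites_after_filters": int(state["gm"].n_sites),
        "n_samples": int(state["gm"].n_samples),
    }
    run.log.update(log)
    with open(run.path("run_log.json"), "w") as fh:
        json.dump(run.log, fh, indent=2, sort_keys=True)
    # wall-clock timings are inherently non-deterministic; kept apart so the
    # rest of the bundle is byte-identical across same-seed runs
    with open(os.path.join(cfg.out_dir, "timings.json"), "w") as fh:
        json.dump(run.timings, fh, indent=2, sort_keys=True)
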