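"""Selective-sweep scan: sliding windows, log2 pi-ratio + Z(FST) joint
right-tail outlier flagging, region merging and gene assignment.

The scan contrasts a wild reference group against one cultivated group.
Each 10 kb window (5 kb step by default) carries the two groups' diversity,
their Weir-Cockerham FST, the genome-wide Z-score of FST, and
``log2(pi_wild / pi_cultivated)`` — oriented so that diversity *loss* in
the cultivated group lands in the right tail.  Windows strictly above the
empirical (1 - q) quantiles of *both* statistics are flagged; overlapping
or book-ended flagged windows merge into candidate selected regions, which
are then annotated with every gene model they overlap by at least 1 bp.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import ratio_2dp, round2_half_up
from .differentiation import fst_components_table, windowed_fst, z_transform
from .diversity import site_pi_array, windowed_pi
from .errors import ValidationError
from .variant_io import GenotypeMatrix, PopulationGrouping


@dataclass
class ScanConfig:
    window_size: int = 10_000
    step: int = 5_000
    tail_quantile: float = 0.05
    min_snps_per_window: int = 10
    clamp_negative_fst: bool = True

    def __post_init__(self):
        if self.step > self.window_size:
            raise ValidationError("step must be <= window_size")
        if not 0 < self.tail_quantile < 0.5:
            raise ValidationError("tail_quantile must be in (0, 0.5)")


@dataclass
class SelectedRegion:
    chrom: str
    start: int
    end: int
    n_windows_merged: int
    mean_fst: float
    mean_log2_ratio: float
    genes: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def make_windows(chrom_lengths: dict, cfg: ScanConfig) -> list:
    """Sliding windows tiling each chromosome, 0-based half-open.

    Starts advance by ``cfg.step``; the final partial window is kept only
    when it is strictly longer than one step (a shorter remainder is
    already covered by the previous window), except that a chromosome
    shorter than one window yields its single truncated window.
    """
    windows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValidationError(f"chromosome {chrom} has non-positive length")
        start = 0
        while start < length:
            end = min(start + cfg.window_size, length)
            if start == 0 or end - start > cfg.step or end - start == cfg.window_size:
                windows.append((chrom, start, end))
            start += cfg.step
    return windows


def log2_pi_ratio(pi_wild: float, pi_cult: float) -> float:
    """log2(pi_wild / pi_cultivated) with documented zero rules.

    Zero cultivated diversity with positive wild diversity maps to +inf
    (ranks above every finite window); the reverse maps to -inf; both zero
    is undefined (NaN, window unusable).
    """
    if pi_wild == 0 and pi_cult == 0:
        return float("nan")
    if pi_cult == 0:
        return float("inf")
    if pi_wild == 0:
        return float("-inf")
    return float(np.log2(pi_wild / pi_cult))


def compute_window_stats(
    gm: GenotypeMatrix,
    grouping: PopulationGrouping,
    wild: str,
    cultivated: str,
    chrom_lengths: dict,
    cfg: ScanConfig | None = None,
) -> pd.DataFrame:
    """Assemble the per-window scan table for one wild/cultivated contrast.

    Columns: chrom, start, end, n_snps, pi_wild, pi_cult, fst, z_fst,
    log2_pi_ratio, usable, flagged (flagged filled by
    :func:`flag_outliers`).
    """
    cfg = cfg or ScanConfig()
    windows = make_windows(chrom_lengths, cfg)
    pi = windowed_pi(
        gm, grouping, windows, groups=[wild, cultivated], min_snps=cfg.min_snps_per_window
    )
    pi_w = pi[pi["group"] == wild].reset_index(drop=True)
    pi_c = pi[pi["group"] == cultivated].reset_index(drop=True)
    comp = fst_components_table(gm, grouping, wild, cultivated)
    fst = windowed_fst(
        comp,
        windows,
        min_snps=cfg.min_snps_per_window,
        clamp_negative=cfg.clamp_negative_fst,
    )

    ratio = np.array(
        [log2_pi_ratio(w, c) for w, c in zip(pi_w["pi"], pi_c["pi"])], dtype=float
    )
    usable = (
        pi_w["usable"].to_numpy()
        & pi_c["usable"].to_numpy()
        & fst["usable"].to_numpy()
        & ~np.isnan(ratio)
    )
    stats = pd.DataFrame(
        {
            "chrom": [w[0] for w in windows],
            "start": [w[1] for w in windows],
            "end": [w[2] for w in windows],
            "n_snps": fst["n_snps"],
            "pi_wild": pi_w["pi"],
            "pi_cult": pi_c["pi"],
            "fst": fst["fst"],
            "log2_pi_ratio": ratio,
            "usable": usable,
        }
    )
    z = np.full(len(stats), np.nan)
    if usable.sum() >= 2:
        z[usable] = z_transform(stats.loc[usable, "fst"].to_numpy())
    stats["z_fst"] = z
    stats["flagged"] = False
    return stats


def _tail_quantile(values: np.ndarray, q: float) -> float:
    """Empirical (1-q) quantile, type-7, with infinities given finite ranks
    just outside the observed finite range so interpolation stays defined."""
    v = np.array(values, dtype=float)
    finite = v[np.isfinite(v)]
    if len(finite) == 0:
        raise ValidationError("no finite values for quantile computation")
    hi = finite.max() + 1.0
    lo = finite.min() - 1.0
    v[np.isposinf(v)] = hi
    v[np.isneginf(v)] = lo
    return float(np.quantile(v, 1.0 - q))


def flag_outliers(stats: pd.DataFrame, cfg: ScanConfig | None = None):
    """Flag windows strictly above the right-tail thresholds of both
    statistics.

    Thresholds are empirical (1 - tail_quantile) quantiles over usable
    windows only.  Ties at a threshold are not flagged.  Returns the table
    with the ``flagged`` column filled plus the threshold dict (reported in
    the run log).
    """
    cfg = cfg or ScanConfig()
    usable = stats["usable"].to_numpy()
    if usable.sum() < 20:
        raise ValidationError(
            f"only {int(usable.sum())} usable windows; need >= 20 for tail quantiles"
        )
    ratio_thr = _tail_quantile(
        stats.loc[usable, "log2_pi_ratio"].to_numpy(), cfg.tail_quantile
    )
    z_thr = _tail_quantile(stats.loc[usable, "z_fst"].to_numpy(), cfg.tail_quantile)
    out = stats.copy()
    out["flagged"] = (
        usable
        & (out["log2_pi_ratio"].to_numpy() > ratio_thr)
        & (out["z_fst"].to_numpy() > z_thr)
    )
    thresholds = {
        "log2_pi_ratio_threshold": ratio_thr,
        "z_fst_threshold": z_thr,
        "tail_quantile": cfg.tail_quantile,
        "n_usable_windows": int(usable.sum()),
        "n_flagged_windows": int(out["flagged"].sum()),
    }
    return out, thresholds


def merge_regions(stats: pd.DataFrame) -> list:
    """Merge flagged windows into non-overlapping selected regions.

    Overlapping or book-ended windows on the same chromosome merge; any
    gap of >= 1 bp splits.  Region FST and log2 ratio are SNP-weighted
    means over member windows.
    """
    flagged = stats[stats["flagged"]].sort_values(["chrom", "start"])
    regions: list[SelectedRegion] = []
    cur = None
    members: list = []

    def _close(cur, members):
        w = np.maximum(np.array([m["n_snps"] for m in members], dtype=float), 1.0)
        fst = np.array([m["fst"] for m in members], dtype=float)
        ratio = np.array([m["log2_pi_ratio"] for m in members], dtype=float)
        return SelectedRegion(
            chrom=cur[0],
            start=int(cur[1]),
            end=int(cur[2]),
            n_windows_merged=len(members),
            mean_fst=float((w * fst).sum() / w.sum()),
            mean_log2_ratio=float((w * ratio).sum() / w.sum()),
        )

    for _, row in flagged.iterrows():
        if cur is not None and row["chrom"] == cur[0] and row["start"] <= cur[2]:
            cur = (cur[0], cur[1], max(cur[2], int(row["end"])))
            members.append(row)
        else:
            if cur is not None:
                regions.append(_close(cur, members))
            cur = (row["chrom"], int(row["start"]), int(row["end"]))
            members = [row]
    if cur is not None:
        regions.append(_close(cur, members))
    return regions


def assign_genes(regions, genes) -> list:
    """Attach every gene whose span overlaps a region by >= 1 bp.

    Genes are counted once per region; returns new region objects with the
    ``genes`` list filled (sorted gene ids).
    """
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for r in regions:
        hits = [
            g.gene_id
            for g in by_chrom.get(r.chrom, [])
            if g.span[0] < r.end and g.span[1] > r.start
        ]
        out.append(replace(r, genes=sorted(set(hits))))
    return out


def mean_genes_per_region(regions) -> float | None:
    """Average gene-in-region assignments per region, 2-decimal half-up."""
    if not regions:
        return None
    total = sum(len(r.genes) for r in regions)
    return ratio_2dp(total, len(regions))


def region_summary(
    regions,
    gm: GenotypeMatrix,
    grouping: PopulationGrouping,
    group: str,
    annotations: pd.DataFrame | None = None,
) -> dict:
    """Selected-region statistics for one cultivated group.

    SNP count and diversity are computed over the group's segregating SNP
    sites falling inside the merged regions; nonsynonymous/synonymous
    counts (and their 2-decimal ratio) come from the site annotations.
    """
    snps = gm.snps()
    idx = grouping.indices(snps.samples, group)
    alt, tot = snps.allele_counts(idx)
    pi = site_pi_array(alt, tot)
    present = (snps.dosages[idx] > 0).any(axis=0)

    chroms = snps.sites["chrom"].to_numpy()
    pos0 = snps.pos0
    in_region = np.zeros(snps.n_sites, dtype=bool)
    for r in regions:
        in_region |= (chroms == r.chrom) & (pos0 >= r.start) & (pos0 < r.end)

    total_len = sum(r.length for r in regions)
    sel = in_region & present
    n_snp = int(sel.sum())
    theta = float(pi[in_region].sum()) / total_len if total_len else 0.0

    nonsyn = syn = 0
    if annotations is not None:
        snp_mask = gm.sites["vclass"].to_numpy() == "snp"
        eff = annotations.loc[snp_mask, "effect_class"].to_numpy()
        nonsyn = int((sel & (eff == "nonsynonymous")).sum())
        syn = int((sel & (eff == "synonymous")).sum())

    genes = sorted({gid for r in regions for gid in r.genes})
    return {
        "group": group,
        "n_snps_in_regions": n_snp,
        "theta_pi_in_regions": theta,
        "nonsynonymous": nonsyn,
        "synonymous": syn,
        "nonsyn_syn_ratio": ratio_2dp(nonsyn, syn),
        "n_regions": len(regions),
        "n_flagged_windows": int(sum(r.n_windows_merged for r in regions)),
        "n_genes": len(genes),
        "mean_genes_per_region": mean_genes_per_region(regions),
        "mean_fst": round2_half_up(
            float(np.mean([r.mean_fst for r in regions]))
        )
        if regions
        else None,
    }


def evaluate_scan(regions, true_intervals) -> dict:
    """Sensitivity/precision of merged regions against known sweep intervals.

    Sensitivity: fraction of true intervals overlapped by >= 1 region.
    Precision: fraction of regions overlapping >= 1 true interval.
    """
    def _overlaps(a_chrom, a_lo, a_hi, b):
        return any(
            c == a_chrom and lo < a_hi and hi > a_lo for c, lo, hi in b
        )

    truths = [(c, int(lo), int(hi)) for c, lo, hi in true_intervals]
    found = sum(
        1
        for c, lo, hi in truths
        if any(r.chrom == c and r.start < hi and r.end > lo for r in regions)
    )
    good = sum(1 for r in regions if _overlaps(r.chrom, r.start, r.end, truths))
    return {
        "sensitivity": found / len(truths) if truths else float("nan"),
        "precision": good / len(regions) if regions else float("nan"),
        "n_regions": len(regions),
        "n_true_intervals": len(truths),
    }
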