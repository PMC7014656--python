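"""Linkage disequilibrium: composite genotype r², distance-binned decay
curves, and decay-distance summaries.

Real inputs are unphased, so r² is the squared Pearson correlation of
diploid dosage vectors (the "composite" LD measure), computed
pairwise-complete over samples with both genotypes called.  The simulator
provides phased haplotypes so tests can check the genotype measure against
the classical haplotype formula D²/(pA qA pB qB).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .variant_io import GenotypeMatrix, PopulationGrouping

_VAR_TOL = 1e-12


@dataclass
class LDBin:
    distance_lo: int
    distance_hi: int
    mean_r2: float
    n_pairs: int

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.distance_lo + self.distance_hi)


def pair_r2(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing entries (< 0) are dropped pairwise.  Returns NaN when fewer
    than 2 complete samples remain or either site is monomorphic among
    them (zero variance).
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    m = (a >= 0) & (b >= 0)
    if m.sum() < 2:
        return float("nan")
    a, b = a[m], b[m]
    va, vb = a.var(), b.var()
    if va <= _VAR_TOL or vb <= _VAR_TOL:
        return float("nan")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def _enumerate_pairs(pos: np.ndarray, max_dist: int):
    """Index pairs (i, j>i) on one chromosome with pos[j]-pos[i] < max_dist."""
    hi = np.searchsorted(pos, pos + max_dist, side="left")
    counts = hi - np.arange(len(pos)) - 1
    counts = np.maximum(counts, 0)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, int), np.empty(0, int)
    ii = np.repeat(np.arange(len(pos)), counts)
    # offsets 1..counts[i] within each i block
    block_start = np.concatenate(([0], np.cumsum(counts)))[:-1]
    offs = np.arange(total) - np.repeat(block_start, counts) + 1
    jj = ii + offs
    return ii, jj


def _bulk_r2(dos: np.ndarray, ii: np.ndarray, jj: np.ndarray, chunk: int = 100_000):
    """Pairwise-complete r² for many site pairs of a (samples x sites) block."""
    out = np.empty(len(ii), dtype=float)
    for s in range(0, len(ii), chunk):
        e = min(s + chunk, len(ii))
        X = dos[:, ii[s:e]].astype(float)
        Y = dos[:, jj[s:e]].astype(float)
        M = (X >= 0) & (Y >= 0)
        n = M.sum(axis=0).astype(float)
        Xm = np.where(M, X, 0.0)
        Ym = np.where(M, Y, 0.0)
        sx, sy = Xm.sum(0), Ym.sum(0)
        sxx = (Xm * Xm).sum(0)
        syy = (Ym * Ym).sum(0)
        sxy = (Xm * Ym).sum(0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cov = sxy - sx * sy / n
            vx = sxx - sx * sx / n
            vy = syy - sy * sy / n
            r2 = cov * cov / (vx * vy)
        bad = (n < 2) | (vx <= _VAR_TOL * n) | (vy <= _VAR_TOL * n)
        r2[bad] = np.nan
        out[s:e] = r2
    return out


def decay_curve(
    gm: GenotypeMatrix,
    grouping: PopulationGrouping,
    group: str,
    max_dist: int = 50_000,
    bin_width: int = 100,
    max_pairs: int = 1_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean r² per distance bin for intra-chromosome SNP pairs of a group.

    Deterministic for a given matrix; when the number of qualifying pairs
    exceeds ``max_pairs`` a seeded uniform subsample is scored instead.
    Returns a DataFrame with columns ``bin_lo, bin_hi, mean_r2, n_pairs``
    tiling [0, max_dist).
    """
    idx = grouping.indices(gm.samples, group)
    if len(idx) < 4:
        raise ValidationError(f"group '{group}' has < 4 samples; LD needs >= 4")
    snps = gm.snps()
    dos = snps.dosages[idx]
    chroms = snps.sites["chrom"].to_numpy()
    pos0 = snps.pos0

    ii_all, jj_all, dist_all = [], [], []
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        pos = pos0[sel]
        ii, jj = _enumerate_pairs(pos, max_dist)
        ii_all.append(sel[ii])
        jj_all.append(sel[jj])
        dist_all.append(pos[jj] - pos[ii])
    ii = np.concatenate(ii_all) if ii_all else np.empty(0, int)
    jj = np.concatenate(jj_all) if jj_all else np.empty(0, int)
    dist = np.concatenate(dist_all) if dist_all else np.empty(0, int)

    if len(ii) > max_pairs:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(ii), size=max_pairs, replace=False)
        pick.sort()
        ii, jj, dist = ii[pick], jj[pick], dist[pick]

    r2 = _bulk_r2(dos, ii, jj)
    ok = np.isfinite(r2)
    bins = np.arange(0, max_dist + bin_width, bin_width)
    which = np.digitize(dist[ok], bins) - 1
    n_bins = len(bins) - 1
    n_pairs = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=r2[ok], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(n_pairs > 0, sums / np.maximum(n_pairs, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_lo": bins[:-1],
            "bin_hi": bins[1:],
            "mean_r2": mean_r2,
            "n_pairs": n_pairs,
        }
    )


def decay_distance(curve: pd.DataFrame, fraction: float = 0.5, absolute: float | None = None):
    """Distance at which the decay curve first drops to a threshold.

    The threshold is ``fraction * max(mean_r2)`` (half-maximum by default)
    or, when ``absolute`` is given, that absolute r² level.  The crossing
    point is linearly interpolated between adjacent occupied bin midpoints.
    Returns ``None`` when the curve never reaches the threshold within the
    binned range.
    """
    occ = curve[(curve["n_pairs"] > 0) & np.isfinite(curve["mean_r2"])]
    if len(occ) == 0:
        raise ValidationError("decay curve has no occupied bins")
    mids = (0.5 * (occ["bin_lo"] + occ["bin_hi"])).to_numpy(dtype=float)
    vals = occ["mean_r2"].to_numpy(dtype=float)
    if absolute is not None:
        threshold = float(absolute)
    else:
        if not 0 < fraction < 1:
            raise ValidationError("fraction must be in (0, 1)")
        threshold = fraction * float(vals.max())
    below = np.flatnonzero(vals <= threshold)
    if len(below) == 0:
        return None
    k = below[0]
    if k == 0:
        return float(mids[0])
    x0, x1 = mids[k - 1], mids[k]
    v0, v1 = vals[k - 1], vals[k]
    if v0 == v1:
        return float(x1)
    return float(x0 + (x1 - x0) * (v0 - threshold) / (v0 - v1))


def fit_decay_length(curve: pd.DataFrame) -> float:
    """Least-squares fit of ``A * exp(-d / L) + c`` to the decay curve;
    returns the decay length L in bp.

    The additive baseline absorbs the sampling floor of r2 (about 1/n for
    unlinked sites), which would otherwise bias the fitted length.
    """
    from scipy.optimize import curve_fit

    occ = curve[(curve["n_pairs"] > 0) & np.isfinite(curve["mean_r2"])]
    mids = (0.5 * (occ["bin_lo"] + occ["bin_hi"])).to_numpy(dtype=float)
    vals = occ["mean_r2"].to_numpy(dtype=float)
    if len(mids) < 4:
        raise ValidationError("need >= 4 occupied bins to fit a decay length")
    p0 = (max(vals.max(), 1e-3), max(mids.mean(), 1.0), 0.01)
    popt, _ = curve_fit(
        lambda d, amp, L, c: amp * np.exp(-d / L) + c,
        mids,
        vals,
        p0=p0,
        bounds=([0.0, 1.0, 0.0], [1.0, np.inf, 1.0]),
        maxfev=20_000,
    )
    return float(popt[1])
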