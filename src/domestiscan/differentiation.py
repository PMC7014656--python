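"""Two-population FST: per-site Weir & Cockerham variance components,
ratio-of-averages window aggregation, and genome-wide Z-scoring.

The estimator is the Weir & Cockerham (1984) method-of-moments theta
computed from sample allele counts.  Because the inputs are allele counts
rather than genotypes, the within-individual component is not separable
and the allele-based (haploid-sample) form of the estimator is used: the
units of sampling are the ``n`` non-missing alleles of each group.  For
Balding-Nichols-diverged populations its expectation is the divergence
parameter F, which is what the simulator-recovery checks exercise.

Windowed FST is the "ratio of averages": sum of numerator components over
usable sites divided by the sum of total components, the standard way to
aggregate W&C over a region.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import window_reduce
from .errors import ValidationError


@dataclass
class FstComponents:
    """Per-site variance components; FST = a / a_plus_b_plus_c."""

    a: float
    a_plus_b_plus_c: float
    usable: bool

    @property
    def fst(self) -> float:
        if not self.usable:
            return float("nan")
        return self.a / self.a_plus_b_plus_c


def site_fst_components(alt1: int, n1: int, alt2: int, n2: int) -> FstComponents:
    """W&C components for one biallelic site from two groups' allele counts.

    ``alt_i`` alt alleles out of ``n_i`` non-missing alleles.  Sites with
    fewer than 2 alleles in either group, or monomorphic across both
    groups, are unusable.
    """
    a, d, usable = _components_arrays(
        np.array([alt1]), np.array([n1]), np.array([alt2]), np.array([n2])
    )
    return FstComponents(float(a[0]), float(d[0]), bool(usable[0]))


def _components_arrays(alt1, n1, alt2, n2):
    """Vectorized W&C (1984) two-population components (allele-based).

    Returns ``(a, a+b, usable)`` arrays.  With r=2 populations of allele
    sample sizes n1, n2:

        n_bar = (n1+n2)/2
        n_c   = n1+n2 - (n1^2+n2^2)/(n1+n2)
        p_bar = (n1 p1 + n2 p2) / (n1+n2)
        s^2   = [n1 (p1-p_bar)^2 + n2 (p2-p_bar)^2] / n_bar
        a     = (n_bar/n_c) * [s^2 - (p_bar q_bar - s^2/2)/(n_bar-1)]
        b     = n_bar/(n_bar-1) * (p_bar q_bar - s^2/2)
    """
    alt1 = np.asarray(alt1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    alt2 = np.asarray(alt2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    ok = (n1 >= 2) & (n2 >= 2)
    n1s = np.where(ok, n1, 2.0)
    n2s = np.where(ok, n2, 2.0)
    p1 = np.where(ok, alt1 / n1s, 0.0)
    p2 = np.where(ok, alt2 / n2s, 0.0)
    ntot = n1s + n2s
    n_bar = ntot / 2.0
    n_c = ntot - (n1s**2 + n2s**2) / ntot
    p_bar = (n1s * p1 + n2s * p2) / ntot
    s2 = (n1s * (p1 - p_bar) ** 2 + n2s * (p2 - p_bar) ** 2) / n_bar
    pq = p_bar * (1.0 - p_bar)
    inner = pq - s2 / 2.0
    a = (n_bar / n_c) * (s2 - inner / (n_bar - 1.0))
    b = n_bar / (n_bar - 1.0) * inner
    denom = a + b
    usable = ok & (denom > 0)
    return a, denom, usable


def fst_components_table(gm, grouping, group1: str, group2: str) -> pd.DataFrame:
    """Per-SNP-site components between two groups of a genotype matrix."""
    snps = gm.snps()
    idx1 = grouping.indices(snps.samples, group1)
    idx2 = grouping.indices(snps.samples, group2)
    alt1, n1 = snps.allele_counts(idx1)
    alt2, n2 = snps.allele_counts(idx2)
    a, denom, usable = _components_arrays(alt1, n1, alt2, n2)
    return pd.DataFrame(
        {
            "chrom": snps.sites["chrom"].to_numpy(),
            "pos0": snps.pos0,
            "a": a,
            "denom": denom,
            "usable": usable,
        }
    )


def windowed_fst(
    components: pd.DataFrame,
    windows,
    min_snps: int = 10,
    clamp_negative: bool = True,
) -> pd.DataFrame:
    """Ratio-of-averages window FST from per-site components.

    A window is unusable when it holds fewer than ``min_snps`` usable sites
    or its summed denominator is not positive.  Negative estimates are
    clamped to 0 by default (standard practice before right-tail Z-scoring).
    """
    usable = components[components["usable"]]
    counts, sums = window_reduce(
        usable["chrom"].to_numpy(),
        usable["pos0"].to_numpy(),
        windows,
        {"a": usable["a"].to_numpy(), "denom": usable["denom"].to_numpy()},
    )
    ok = (counts >= min_snps) & (sums["denom"] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(ok, sums["a"] / np.where(ok, sums["denom"], 1.0), np.nan)
    if clamp_negative:
        fst = np.where(ok, np.maximum(fst, 0.0), np.nan)
    return pd.DataFrame(
        {
            "chrom": [w[0] for w in windows],
            "start": [w[1] for w in windows],
            "end": [w[2] for w in windows],
            "fst": fst,
            "n_snps": counts,
            "usable": ok,
        }
    )


def z_transform(values) -> np.ndarray:
    """Standard z-scores with the sample (n-1) standard deviation.

    Degenerate inputs (fewer than 2 finite values, or zero spread) raise:
    a flat genome-wide scan has no meaningful right tail.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValidationError("z_transform needs >= 2 finite values")
    mean = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if sd == 0:
        raise ValidationError("z_transform: zero standard deviation (degenerate scan)")
    return (x - mean) / sd
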