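"""Nucleotide diversity (pairwise theta-pi) and per-sample heterozygosity.

The per-site estimator is the unbiased pairwise heterozygosity
``2*p*(1-p) * n/(n-1)`` with ``p`` the alt-allele frequency among the
``n`` non-missing alleles of a group — equal to the mean number of
pairwise differences among the group's sequences at that site.  Summing
over sites and dividing by the analyzed sequence length (not the number
of variant sites) gives diversity per base pair, reported on the
conventional 1e-3 scale.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import window_reduce
from .errors import ValidationError
from .variant_io import GenotypeMatrix, PopulationGrouping


@dataclass
class DiversityResult:
    group: str
    theta_pi_per_bp: float
    callable_length: int
    n_snps_used: int

    @property
    def theta_pi_e3(self) -> float:
        return 1e3 * self.theta_pi_per_bp


@dataclass
class SampleStats:
    sample: str
    het_snp_count: int
    genome_length: int
    het_rate: float  # percent


def site_pi(alt_count: int, allele_total: int) -> float:
    """Unbiased per-site pairwise diversity; 0 for monomorphic sites.

    Sites with fewer than 2 non-missing alleles are undefined and
    contribute 0 (callers also drop them from the usable-site count).
    """
    if not 0 <= alt_count <= allele_total:
        raise ValidationError("alt_count must be in [0, allele_total]")
    if allele_total < 2:
        return 0.0
    p = alt_count / allele_total
    return 2.0 * p * (1.0 - p) * allele_total / (allele_total - 1.0)


def site_pi_array(alt_counts: np.ndarray, allele_totals: np.ndarray) -> np.ndarray:
    """Vectorized :func:`site_pi`; entries with < 2 alleles give 0."""
    alt = np.asarray(alt_counts, dtype=float)
    tot = np.asarray(allele_totals, dtype=float)
    ok = tot >= 2
    p = np.divide(alt, tot, out=np.zeros_like(alt), where=ok)
    pi = np.zeros_like(p)
    pi[ok] = 2.0 * p[ok] * (1.0 - p[ok]) * tot[ok] / (tot[ok] - 1.0)
    return pi


def _group_pi_values(gm: GenotypeMatrix, grouping: PopulationGrouping, group: str):
    idx = grouping.indices(gm.samples, group)
    if len(idx) < 2:
        raise ValidationError(
            f"group '{group}' has {len(idx)} sample(s); diversity needs >= 2"
        )
    alt, tot = gm.allele_counts(idx)
    return site_pi_array(alt, tot), tot


def group_theta_pi(
    gm: GenotypeMatrix,
    grouping: PopulationGrouping,
    group: str,
    length: int,
) -> DiversityResult:
    """Group diversity per bp over an analyzed sequence of ``length`` bases.

    Uses SNP sites only; monomorphic and all-missing sites contribute 0.
    """
    if length <= 0:
        raise ValidationError("length must be positive")
    snps = gm.snps()
    pi, tot = _group_pi_values(snps, grouping, group)
    used = int(((pi > 0) & (tot >= 2)).sum())
    return DiversityResult(
        group=group,
        theta_pi_per_bp=float(pi.sum()) / length,
        callable_length=int(length),
        n_snps_used=used,
    )


def heterozygosity_rate(
    gm: GenotypeMatrix, sample: str, genome_length: int
) -> SampleStats:
    """Percent heterozygosity: heterozygous SNP count over total length."""
    if genome_length <= 0:
        raise ValidationError("genome_length must be positive")
    i = gm.sample_index(sample)
    snps = gm.snps()
    het = int((snps.dosages[i] == 1).sum())
    return SampleStats(
        sample=sample,
        het_snp_count=het,
        genome_length=int(genome_length),
        het_rate=100.0 * het / genome_length,
    )


def windowed_pi(
    gm: GenotypeMatrix,
    grouping: PopulationGrouping,
    windows,
    groups=None,
    min_snps: int = 10,
) -> pd.DataFrame:
    """Per-window diversity for each group.

    ``windows`` is a list of ``(chrom, start, end)`` 0-based half-open
    intervals (typically from :func:`domestiscan.sweep_scan.make_windows`).
    Window diversity is the sum of per-site pi over the window divided by
    the window length.  ``n_snps`` counts the group's callable variant
    sites in the window (>= 2 non-missing alleles; monomorphic sites count
    but contribute 0), and windows with fewer than ``min_snps`` of them
    are flagged unusable while still being reported.
    """
    snps = gm.snps()
    groups = list(groups) if groups is not None else grouping.labels
    frames = []
    chroms = snps.sites["chrom"].to_numpy()
    pos0 = snps.pos0
    for label in groups:
        pi, tot = _group_pi_values(snps, grouping, label)
        callable_ = tot >= 2
        counts, sums = window_reduce(
            chroms[callable_], pos0[callable_], windows, {"pi": pi[callable_]}
        )
        lengths = np.array([e - s for _, s, e in windows], dtype=float)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": [w[0] for w in windows],
                    "start": [w[1] for w in windows],
                    "end": [w[2] for w in windows],
                    "group": label,
                    "pi": sums["pi"] / lengths,
                    "n_snps": counts,
                    "usable": counts >= min_snps,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
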