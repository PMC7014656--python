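"""Functional classification of variants and per-group summary tables.

Every variant gets a genomic-region class (CDS / UTR / intron / intergenic)
and, where applicable, a coding-effect class.  Region precedence when a site
overlaps several features or genes is "most genic first":
CDS > UTR > intron > intergenic; a site sitting in a 5'UTR of one gene and a
3'UTR of an overlapping gene gets the combined class ``utr5_utr3``.

Coding effects for SNPs are called on the codon rebuilt from the CDS in
translation order (reverse-complemented on the minus strand) with the
standard genetic code.  CDS indels are frameshift when the length change is
not a multiple of 3.  SNPs falling in a CDS whose model is unusable
(length not divisible by 3, or the reference base disagrees with the FASTA)
are assigned the residual class ``unknown``.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._utils import ratio_2dp, revcomp
from .errors import DataIntegrityError, ValidationError
from .variant_io import GeneModel, GenotypeMatrix, PopulationGrouping, SNP, INDEL

# region classes
INTERGENIC = "intergenic"
INTRONIC = "intronic"
UTR5 = "utr5"
UTR3 = "utr3"
UTR5_UTR3 = "utr5_utr3"
CDS = "cds"
REGION_CLASSES = (UTR3, UTR5, UTR5_UTR3, INTERGENIC, INTRONIC, CDS)

# effect classes
SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
STOPGAIN = "stopgain"
STOPLOSS = "stoploss"
FRAMESHIFT = "frameshift"
NONFRAMESHIFT = "nonframeshift"
UNKNOWN = "unknown"
NONE = "none"

_CODON_TABLE = None


def _translate(codon: str) -> str:
    global _CODON_TABLE
    if _CODON_TABLE is None:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    try:
        return _CODON_TABLE[codon.upper()]
    except KeyError:
        raise DataIntegrityError(f"untranslatable codon '{codon}'") from None


def _pos_in(intervals, pos0: int) -> bool:
    return any(s <= pos0 < e for s, e in intervals)


def _class_within_gene(gene: GeneModel, pos0: int) -> str:
    if _pos_in(gene.cds_intervals, pos0):
        return CDS
    if _pos_in(gene.utr5_intervals, pos0):
        return UTR5
    if _pos_in(gene.utr3_intervals, pos0):
        return UTR3
    return INTRONIC


def classify_region(chrom: str, pos0: int, genes) -> tuple:
    """Region class and overlapping gene ids for a single position.

    ``genes`` may be a plain list of :class:`GeneModel` or a prebuilt
    :class:`GenomeAnnotator` index.  Total function: positions outside any
    gene span are ``intergenic``.
    """
    overlapping = [g for g in genes if g.chrom == chrom and g.contains(pos0)]
    return _combine_classes(overlapping, pos0), [g.gene_id for g in overlapping]


def _combine_classes(overlapping, pos0: int) -> str:
    if not overlapping:
        return INTERGENIC
    classes = {g.gene_id: _class_within_gene(g, pos0) for g in overlapping}
    vals = set(classes.values())
    if CDS in vals:
        return CDS
    if UTR5 in vals and UTR3 in vals:
        return UTR5_UTR3
    if UTR5 in vals:
        return UTR5
    if UTR3 in vals:
        return UTR3
    return INTRONIC


def coding_effect(site, gene: GeneModel, reference: dict) -> str:
    """Effect of a CDS SNP: synonymous / nonsynonymous / stopgain / stoploss.

    The codon containing the site is assembled from the gene's CDS intervals
    in translation order, honoring strand and the phase of the first CDS
    segment, and translated with the standard genetic code.  The reference
    base at the site must match the record's ref allele.
    """
    if site.variant_class != SNP:
        raise ValidationError("coding_effect requires a SNP")
    if not gene.cds_valid:
        raise ValidationError(f"gene {gene.gene_id} has an invalid CDS")
    seq = reference[gene.chrom]
    pos0 = site.pos - 1
    if seq[pos0] != site.ref:
        raise DataIntegrityError(
            f"reference mismatch at {site.chrom}:{site.pos}: "
            f"FASTA has {seq[pos0]}, VCF ref is {site.ref}"
        )

    cds = sorted(gene.cds_intervals)
    genomic_cs = "".join(seq[s:e] for s, e in cds)
    # genomic offset of the site within the concatenated CDS
    offset = 0
    for s, e in cds:
        if s <= pos0 < e:
            offset += pos0 - s
            break
        offset += e - s
    else:
        raise ValidationError(f"site {site.chrom}:{site.pos} not in CDS of {gene.gene_id}")

    if gene.strand == "-":
        coding = revcomp(genomic_cs)
        idx = len(coding) - 1 - offset
        ref_b, alt_b = revcomp(site.ref), revcomp(site.alt)
    else:
        coding = genomic_cs
        idx = offset
        ref_b, alt_b = site.ref, site.alt

    idx -= gene.cds_phase_first
    if idx < 0:
        return UNKNOWN  # upstream of the declared reading frame
    codon_start = 3 * (idx // 3)
    codon = coding[gene.cds_phase_first:][codon_start : codon_start + 3]
    if len(codon) < 3:
        return UNKNOWN
    within = idx % 3
    if codon[within] != ref_b:  # defensive; implies inconsistent gene model
        raise DataIntegrityError(
            f"CDS/reference inconsistency for {gene.gene_id} at {site.chrom}:{site.pos}"
        )
    alt_codon = codon[:within] + alt_b + codon[within + 1 :]
    aa_ref, aa_alt = _translate(codon), _translate(alt_codon)
    if aa_ref == aa_alt:
        return SYNONYMOUS
    if aa_alt == "*":
        return STOPGAIN
    if aa_ref == "*":
        return STOPLOSS
    return NONSYNONYMOUS


def indel_effect(site, gene: GeneModel) -> str:
    """Frameshift (length change % 3 != 0) vs in-frame for a CDS indel."""
    if site.variant_class != INDEL:
        raise ValidationError("indel_effect requires an indel")
    diff = abs(len(site.ref) - len(site.alt))
    return FRAMESHIFT if diff % 3 else NONFRAMESHIFT


class GenomeAnnotator:
    """Interval-indexed annotator for bulk variant classification."""

    def __init__(self, genes, reference: dict | None = None):
        self.genes = list(genes)
        self.reference = reference
        self._trees: dict = defaultdict(IntervalTree)
        for g in self.genes:
            s, e = g.span
            if e > s:
                self._trees[g.chrom].addi(s, e, g)

    def overlapping(self, chrom: str, pos0: int):
        return sorted(
            (iv.data for iv in self._trees[chrom].at(pos0)),
            key=lambda g: g.gene_id,
        )

    def annotate(self, gm: GenotypeMatrix) -> pd.DataFrame:
        """Region and effect class per site of the matrix.

        Returns a DataFrame aligned with ``gm.sites`` with columns
        ``region_class``, ``effect_class`` and ``gene_ids`` (list).
        SNP effects fall back to ``unknown`` for unusable gene models or
        reference mismatches, which feed the residual column of the summary
        table.
        """
        regions, effects, gene_ids = [], [], []
        for rec in gm.site_records():
            pos0 = rec.pos - 1
            if rec.variant_class == INDEL:
                # an indel is "in" a feature when any deleted/anchored base is
                span = range(pos0, pos0 + max(len(rec.ref), 1))
                hits = {
                    g.gene_id: g
                    for p in span
                    for g in self.overlapping(rec.chrom, p)
                }
                overl = sorted(hits.values(), key=lambda g: g.gene_id)
                in_cds = any(
                    _pos_in(g.cds_intervals, p) for g in overl for p in span
                )
                region = (
                    CDS if in_cds else _combine_classes(overl, pos0)
                )
                eff = indel_effect(rec, overl[0]) if in_cds else NONE
            else:
                overl = self.overlapping(rec.chrom, pos0)
                region = _combine_classes(overl, pos0)
                eff = NONE
                if region == CDS and rec.variant_class == SNP:
                    cds_genes = [
                        g for g in overl if _pos_in(g.cds_intervals, pos0)
                    ]
                    valid = [g for g in cds_genes if g.cds_valid]
                    if not valid or self.reference is None:
                        eff = UNKNOWN
                    else:
                        try:
                            eff = coding_effect(rec, valid[0], self.reference)
                        except DataIntegrityError:
                            eff = UNKNOWN
                elif region == CDS:
                    eff = UNKNOWN  # equal-length multi-base substitution in CDS
            regions.append(region)
            effects.append(eff)
            gene_ids.append([g.gene_id for g in overl])
        return pd.DataFrame(
            {"region_class": regions, "effect_class": effects, "gene_ids": gene_ids}
        )


# ---------------------------------------------------------------------------
# Group-level accounting
# ---------------------------------------------------------------------------


def group_presence(gm: GenotypeMatrix, grouping: PopulationGrouping) -> pd.DataFrame:
    """Boolean site-by-group presence: a group carries a site when at least
    one member has a non-missing genotype with >= 1 alt allele."""
    cols = {}
    for label in grouping.labels:
        idx = grouping.indices(gm.samples, label)
        cols[label] = (gm.dosages[idx] > 0).any(axis=0)
    return pd.DataFrame(cols, index=gm.sites.index)


def venn_partition(site_sets: dict) -> dict:
    """Counts of every non-empty intersection class over group site-sets.

    Keys of the result are tuples of group labels (sorted) naming the exact
    set of groups carrying those sites; e.g. ``("A",)`` counts sites private
    to A, and the tuple of all labels counts sites shared by every group.
    """
    labels = sorted(site_sets)
    counts: Counter = Counter()
    universe = set().union(*site_sets.values()) if site_sets else set()
    for key in universe:
        sig = tuple(l for l in labels if key in site_sets[l])
        counts[sig] += 1
    return dict(counts)


def venn_from_matrix(gm: GenotypeMatrix, grouping: PopulationGrouping) -> dict:
    """Vectorized venn partition over presence signatures of the matrix."""
    presence = group_presence(gm, grouping)
    labels = list(presence.columns)
    bits = presence.to_numpy(dtype=bool)
    keep = bits.any(axis=1)
    bits = bits[keep]
    weights = (1 << np.arange(len(labels)))[::-1]
    codes = bits @ weights
    out = {}
    for code, n in zip(*np.unique(codes, return_counts=True)):
        sig = tuple(l for i, l in enumerate(labels) if code & weights[i])
        out[sig] = int(n)
    return out


@dataclass
class AnnotationSummary:
    """Per-group functional accounting (one row of the Table-1-style output)."""

    group: str
    n_samples: int
    total: int
    private: int
    region_counts: dict = field(default_factory=dict)
    effect_counts: dict = field(default_factory=dict)
    unknown: int = 0
    nonsyn_syn_ratio: float | None = None
    genes_touched: int = 0
    theta_pi_e3: float | None = None  # filled by the reporting layer

    @property
    def cds_total(self) -> int:
        """All CDS SNPs: effect classes plus the residual 'unknown' class."""
        return (
            sum(self.effect_counts.get(k, 0) for k in (NONSYNONYMOUS, STOPGAIN, STOPLOSS, SYNONYMOUS))
            + self.unknown
        )


def summarize(
    gm: GenotypeMatrix,
    grouping: PopulationGrouping,
    annotations: pd.DataFrame,
    include_total: bool = True,
) -> dict:
    """Per-group region/effect counts, private counts and nonsyn/syn ratios.

    Operates on whatever variant classes the matrix contains; pass
    ``gm.snps()`` (with matching annotations) for a SNP table.  Ratios are
    rounded half-up to 2 decimals; a zero synonymous count yields ``None``
    rather than a division error.
    """
    if len(annotations) != gm.n_sites:
        raise ValidationError("annotations not aligned with matrix sites")
    presence = group_presence(gm, grouping)
    region = annotations["region_class"].to_numpy()
    effect = annotations["effect_class"].to_numpy()
    gene_lists = annotations["gene_ids"].tolist()
    n_groups_carrying = presence.to_numpy(dtype=int).sum(axis=1)

    def _row(label: str, mask: np.ndarray, n_samples: int, private: int):
        reg = Counter(region[mask])
        eff = Counter(effect[mask])
        cds_mask = mask & (region == CDS)
        genes = set()
        for i in np.flatnonzero(cds_mask):
            genes.update(gene_lists[i])
        ns, sy = eff.get(NONSYNONYMOUS, 0), eff.get(SYNONYMOUS, 0)
        return AnnotationSummary(
            group=label,
            n_samples=n_samples,
            total=int(mask.sum()),
            private=private,
            region_counts={k: int(reg.get(k, 0)) for k in REGION_CLASSES},
            effect_counts={
                k: int(eff.get(k, 0))
                for k in (NONSYNONYMOUS, STOPGAIN, STOPLOSS, SYNONYMOUS, FRAMESHIFT, NONFRAMESHIFT)
            },
            unknown=int(eff.get(UNKNOWN, 0)),
            nonsyn_syn_ratio=ratio_2dp(ns, sy),
            genes_touched=len(genes),
        )

    out = {}
    for label in grouping.labels:
        mask = presence[label].to_numpy()
        private = int((mask & (n_groups_carrying == 1)).sum())
        out[label] = _row(label, mask, len(grouping.samples_in(label)), private)
    if include_total:
        all_mask = np.ones(gm.n_sites, dtype=bool)
        out["total"] = _row("total", all_mask, gm.n_samples, 0)
    return out
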