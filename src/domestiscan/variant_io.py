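"""Input layer: VCF / GFF3 / FASTA / group-assignment readers and site filters.

Coordinate convention: files keep their native 1-based inclusive coordinates
at the boundary; everything internal (gene intervals, windows) is 0-based
half-open.  The :class:`GenotypeMatrix` stores diploid alt-allele dosages
(0/1/2, ``-1`` for missing) for biallelic records, sorted by
(chrom, pos, ref, alt).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError, VcfParseError

MISSING = -1

#: variant size classes: single-base substitutions, short length variants
#: (1-5 bp difference) and larger structural variants (> 5 bp difference).
SNP, INDEL, SV = "snp", "indel", "sv"


def classify_variant(ref: str, alt: str) -> str:
    """Size-class of a ref/alt pair.

    0 bp length difference with single-base alleles is a SNP; 1-5 bp
    difference is an indel; more than 5 bp is a structural variant.
    Equal-length multi-base substitutions are rare and binned with SVs so
    that the SNP class keeps strict single-nucleotide semantics.
    """
    diff = abs(len(ref) - len(alt))
    if diff == 0:
        return SNP if len(ref) == 1 else SV
    return INDEL if diff <= 5 else SV


@dataclass(frozen=True)
class SiteRecord:
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    variant_class: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt at {self.chrom}:{self.pos}")


class GenotypeMatrix:
    """Samples x biallelic sites with diploid dosage coding.

    Attributes
    ----------
    samples : list of str
    sites : pandas.DataFrame
        Columns ``chrom, pos, ref, alt, vclass``; ``pos`` is 1-based.
    dosages : int8 ndarray, shape (n_samples, n_sites)
        Count of alt alleles per sample; ``-1`` marks a missing genotype.
    """

    def __init__(self, samples, sites: pd.DataFrame, dosages: np.ndarray):
        self.samples = list(samples)
        self.sites = sites.reset_index(drop=True)
        self.dosages = np.asarray(dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.sites)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} != "
                f"({len(self.samples)}, {len(self.sites)})"
            )
        bad = (self.dosages > 2) | (self.dosages < MISSING)
        if bad.any():
            raise ValidationError("dosages must be in {0,1,2} or -1 (missing)")

    # -- basic views ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def pos0(self) -> np.ndarray:
        """0-based site positions."""
        return self.sites["pos"].to_numpy() - 1

    def site_records(self):
        return [
            SiteRecord(r.chrom, int(r.pos), r.ref, r.alt, r.vclass)
            for r in self.sites.itertuples()
        ]

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise ValidationError(f"unknown sample '{sample}'") from None

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.samples, self.sites.iloc[idx], self.dosages[:, idx]
        )

    def snps(self) -> "GenotypeMatrix":
        """Subset to single-nucleotide sites (diversity/FST/LD substrate)."""
        return self.take_sites(np.flatnonzero(self.sites["vclass"].to_numpy() == SNP))

    def sorted(self) -> "GenotypeMatrix":
        order = np.lexsort(
            (
                self.sites["alt"].to_numpy(),
                self.sites["ref"].to_numpy(),
                self.sites["pos"].to_numpy(),
                self.sites["chrom"].to_numpy(),
            )
        )
        return self.take_sites(order)

    # -- allele accounting ---------------------------------------------
    def allele_counts(self, sample_idx=None):
        """(alt_alleles, total_non_missing_alleles) per site.

        ``sample_idx`` restricts to a subset of rows (e.g. one population
        group); default is the whole cohort.
        """
        d = self.dosages if sample_idx is None else self.dosages[np.asarray(sample_idx)]
        called = d >= 0
        alt = np.where(called, d, 0).sum(axis=0)
        total = 2 * called.sum(axis=0)
        return alt.astype(np.int64), total.astype(np.int64)

    def missing_fraction(self) -> np.ndarray:
        return (self.dosages < 0).mean(axis=0)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.sites[["chrom", "pos", "ref", "alt"]].equals(
                other.sites[["chrom", "pos", "ref", "alt"]]
            )
            and np.array_equal(self.dosages, other.dosages)
        )


@dataclass
class PopulationGrouping:
    """Sample -> group-label assignment (e.g. wild / seed / rhizome)."""

    assignment: dict

    @property
    def labels(self):
        """Group labels in deterministic (sorted) order."""
        return sorted(set(self.assignment.values()))

    def samples_in(self, label: str):
        return [s for s, g in self.assignment.items() if g == label]

    def indices(self, samples, label: str) -> np.ndarray:
        """Row indices of a group within an ordered sample list."""
        members = set(self.samples_in(label))
        idx = np.array([i for i, s in enumerate(samples) if s in members], dtype=int)
        if len(idx) == 0:
            raise ValidationError(f"group '{label}' has no samples in the matrix")
        return idx

    def sizes(self):
        return {g: len(self.samples_in(g)) for g in self.labels}


@dataclass
class GeneModel:
    """One gene with 0-based half-open feature intervals in genomic order."""

    gene_id: str
    chrom: str
    strand: str
    span: tuple
    cds_intervals: list = field(default_factory=list)
    utr5_intervals: list = field(default_factory=list)
    utr3_intervals: list = field(default_factory=list)
    exon_intervals: list = field(default_factory=list)
    cds_phase_first: int = 0  # phase of the first CDS segment in translation order

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def cds_valid(self) -> bool:
        """CDS usable for codon-level effect calls (non-empty, length % 3 == 0)."""
        return self.cds_length > 0 and self.cds_length % 3 == 0

    @property
    def intron_intervals(self):
        """Gaps between consecutive exons."""
        exons = sorted(self.exon_intervals)
        return [
            (exons[i][1], exons[i + 1][0])
            for i in range(len(exons) - 1)
            if exons[i + 1][0] > exons[i][1]
        ]

    def contains(self, pos0: int) -> bool:
        return self.span[0] <= pos0 < self.span[1]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_TYPE_TO_DOSAGE = np.array([0, 1, MISSING, 2], dtype=np.int8)  # cyvcf2 gt_types


def _prevalidate_vcf(path) -> None:
    """Structural check of a plain-text VCF; names the offending line.

    htslib downgrades many record-level problems to warnings, so the
    reader's error contract (parse error naming the line) needs an explicit
    pass.  Compressed inputs are left to htslib.
    """
    if str(path).endswith((".gz", ".bgz")):
        return
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise VcfParseError(
                    f"malformed VCF record at {path} line {lineno}: "
                    f"expected >= 8 columns, found {len(parts)}"
                )
            if not parts[1].isdigit():
                raise VcfParseError(
                    f"malformed VCF record at {path} line {lineno}: "
                    f"POS '{parts[1]}' is not an integer"
                )


def read_vcf(path, min_qual: float = 20.0, multiallelic: str = "drop") -> GenotypeMatrix:
    """Read a VCF v4.x into a :class:`GenotypeMatrix`.

    Records with QUAL below ``min_qual`` are dropped (a missing QUAL
    passes).  Multiallelic records are dropped by default, or split into
    one biallelic pseudo-record per alt allele with ``multiallelic="split"``.
    Sites come out sorted by (chrom, pos, ref, alt).
    """
    from cyvcf2 import VCF

    if multiallelic not in ("drop", "split"):
        raise ValidationError("multiallelic must be 'drop' or 'split'")

    _prevalidate_vcf(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n_header = vcf.raw_header.count("\n")

    chroms, poss, refs, alts, rows = [], [], [], [], []
    i = -1
    try:
        for i, v in enumerate(vcf):
            if v.QUAL is not None and v.QUAL < min_qual:
                continue
            alt_alleles = v.ALT
            if len(alt_alleles) == 0:
                continue
            if len(alt_alleles) > 1:
                if multiallelic == "drop":
                    continue
                gts = np.array([g[:2] for g in v.genotypes], dtype=np.int16)
                for k, alt in enumerate(alt_alleles, start=1):
                    miss = (gts < 0).any(axis=1)
                    dos = (gts == k).sum(axis=1).astype(np.int8)
                    dos[miss] = MISSING
                    chroms.append(v.CHROM)
                    poss.append(v.POS)
                    refs.append(v.REF)
                    alts.append(alt)
                    rows.append(dos)
                continue
            dos = _GT_TYPE_TO_DOSAGE[v.gt_types]
            chroms.append(v.CHROM)
            poss.append(v.POS)
            refs.append(v.REF)
            alts.append(alt_alleles[0])
            rows.append(dos)
    except Exception as exc:  # noqa: BLE001 - re-raise with file location
        raise VcfParseError(
            f"malformed VCF record at {path} line {n_header + i + 2}: {exc}"
        ) from exc

    if rows:
        dosages = np.vstack(rows)  # (n_sites, n_samples)
    else:
        dosages = np.zeros((0, len(samples)), dtype=np.int8)
    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(poss, dtype=np.int64),
            "ref": refs,
            "alt": alts,
        }
    )
    sites["vclass"] = [classify_variant(r, a) for r, a in zip(refs, alts)]
    return GenotypeMatrix(samples, sites, dosages.T).sorted()


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path, contig_lengths: dict | None = None) -> None:
    """Write the matrix as an uncompressed VCF v4.2 (GT only, QUAL '.')."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=domestiscan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + gm.samples) + "\n")
        sites = gm.sites
        for j in range(gm.n_sites):
            gts = "\t".join(_DOSAGE_TO_GT[int(d)] for d in gm.dosages[:, j])
            fh.write(
                f"{sites.chrom.iat[j]}\t{sites.pos.iat[j]}\t.\t{sites.ref.iat[j]}"
                f"\t{sites.alt.iat[j]}\t.\t.\t.\tGT\t{gts}\n"
            )


def filter_sites(
    gm: GenotypeMatrix, min_maf: float = 0.1, max_missing: float = 1.0
) -> GenotypeMatrix:
    """Keep sites with MAF >= ``min_maf`` (on non-missing alleles) and a
    missing-genotype fraction <= ``max_missing``.

    Idempotent; the sample set is unchanged.  Removing every site is
    legal and produces an (empty) matrix with a warning.
    """
    if not 0 <= min_maf <= 0.5:
        raise ValidationError("min_maf must be in [0, 0.5]")
    if not 0 <= max_missing <= 1:
        raise ValidationError("max_missing must be in [0, 1]")
    alt, total = gm.allele_counts()
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    keep = (maf >= min_maf) & (gm.missing_fraction() <= max_missing)
    if not keep.any() and gm.n_sites:
        warnings.warn("all sites removed by filter_sites", stacklevel=2)
    return gm.take_sites(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# GFF3 / FASTA / grouping
# ---------------------------------------------------------------------------


def read_gff(path) -> list:
    """Parse GFF3 gene models (gene/mRNA/exon/CDS/UTR features).

    Returns one :class:`GeneModel` per gene; introns are derived from exon
    gaps.  Genes whose CDS length is not a multiple of 3 are still returned
    (region classification uses them) but carry ``cds_valid == False`` so
    codon-level effect calls skip them.
    """
    import gffutils

    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []  # header-only file: no gene models
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        def _ivals(ftype):
            return [
                (f.start - 1, f.end)
                for f in db.children(g, featuretype=ftype, order_by="start")
            ]

        cds_feats = list(db.children(g, featuretype="CDS", order_by="start"))
        cds = [(f.start - 1, f.end) for f in cds_feats]
        phase = 0
        if cds_feats:
            first = cds_feats[0] if g.strand != "-" else cds_feats[-1]
            if first.frame not in (None, ".", ""):
                phase = int(first.frame)
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand if g.strand in "+-" else "+",
                span=(g.start - 1, g.end),
                cds_intervals=cds,
                utr5_intervals=_ivals("five_prime_UTR"),
                utr3_intervals=_ivals("three_prime_UTR"),
                exon_intervals=_ivals("exon"),
                cds_phase_first=phase,
            )
        )
    return genes


def read_fasta(path) -> dict:
    """Chrom -> uppercase sequence string."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_grouping(path, gm: GenotypeMatrix) -> PopulationGrouping:
    """Read a two-column ``sample<TAB>group`` table and validate it covers
    every sample of the matrix.  Duplicate rows with conflicting labels and
    matrix samples absent from the table are errors.
    """
    assignment: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path} line {lineno}: expected 2 tab-separated columns"
                )
            sample, group = parts
            if sample in assignment and assignment[sample] != group:
                raise ValidationError(
                    f"{path} line {lineno}: sample '{sample}' assigned to both "
                    f"'{assignment[sample]}' and '{group}'"
                )
            assignment[sample] = group
    missing = [s for s in gm.samples if s not in assignment]
    if missing:
        raise ValidationError(
            "samples present in VCF but absent from grouping table: "
            + ", ".join(missing)
        )
    return PopulationGrouping({s: assignment[s] for s in gm.samples})
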