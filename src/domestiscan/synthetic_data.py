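"""Synthetic cohort generator: diverged populations, implanted sweeps,
genic reference architecture, and distance-decaying LD.

The generator emulates a multi-group resequencing study design at desk
scale.  Allele frequencies follow the Balding-Nichols model: an ancestral
frequency drawn from a Beta distribution, and each group's frequency drawn
from Beta(p(1-F)/F, (1-p)(1-F)/F) with group-specific divergence F, so the
expected Weir-Cockerham FST between two groups with divergence F is F —
a closed-form oracle used throughout the tests.  Selective sweeps are
implanted by pushing the target group's frequencies toward the nearer
boundary within declared intervals (p -> p^gamma for p <= 1/2, else
1 - (1-p)^gamma), which depresses expected heterozygosity for gamma > 1.
Linkage disequilibrium is generated by a site-ordered Markov copying
process on haplotypes: adjacent sites at distance d share their latent
uniform draw with probability exp(-d / (2 L_c)), else the draw is
refreshed.  Sharing the latent draw preserves every site's marginal
frequency exactly; because the pairwise correlation r is proportional to
the sharing probability and r2 is its square, the half-rate makes the
*measured* mean-r2 curve decay exponentially at scale L_c, so the
correlation length is a directly testable input parameter.
Hitchhiking LD around sweeps is deliberately not emulated.

Default group sizes follow the emulated study cohort: 22 wild, 21 seed,
13 rhizome, 11 flower and 2 outgroup ("american") accessions.  Group
divergence values are chosen to spread per-group diversity over roughly
the 1.9-4.2 (x1e-3) range seen in such data, since under Balding-Nichols
E[2 p_g (1-p_g)] = (1-F) E[2p(1-p)].
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, ValidationError
from .variant_io import (
    GeneModel,
    GenotypeMatrix,
    MISSING,
    PopulationGrouping,
    classify_variant,
    write_vcf,
)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = sorted(
    "".join(c) for c in __import__("itertools").product("ACGT", repeat=3)
    if "".join(c) not in _STOPS
)


@dataclass
class GroupSpec:
    label: str
    n_diploids: int
    divergence: float  # Balding-Nichols F in [0, 1)

    def __post_init__(self):
        if not 0 <= self.divergence < 1:
            raise ValidationError("divergence F must be in [0, 1)")
        if self.n_diploids < 1:
            raise ValidationError("n_diploids must be >= 1")


@dataclass
class SweepSpec:
    chrom: str
    start: int  # 0-based half-open
    end: int
    group: str
    gamma: float = 8.0  # 1 -> no sweep

    def __post_init__(self):
        if self.gamma < 1:
            raise ValidationError("sweep intensity gamma must be >= 1")
        if self.end <= self.start:
            raise ValidationError("sweep interval must be non-empty")


@dataclass
class SimConfig:
    """All parameters of the synthetic cohort."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_sites: int = 20_000  # SNP density 0.01/bp at the defaults
    ancestral_beta: tuple = (0.8, 0.8)
    groups: list = field(
        default_factory=lambda: [
            GroupSpec("wild", 22, 0.05),
            GroupSpec("flower", 11, 0.10),
            GroupSpec("seed", 21, 0.25),
            GroupSpec("rhizome", 13, 0.40),
            GroupSpec("american", 2, 0.60),
        ]
    )
    sweep_intervals: list = field(
        default_factory=lambda: [
            SweepSpec("chr1", 200_000, 250_000, "seed", 8.0),
            SweepSpec("chr1", 600_000, 650_000, "rhizome", 8.0),
            SweepSpec("chr2", 300_000, 350_000, "seed", 8.0),
            SweepSpec("chr2", 700_000, 750_000, "flower", 8.0),
        ]
    )
    ld_correlation_length: float | None = 500.0  # bp; None -> no LD
    missing_rate: float = 0.02
    n_genes: int = 100
    gene_length: int = 3_000
    cds_fraction: float = 0.5
    n_indels: int = 60

    def __post_init__(self):
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate group labels")
        for s in self.sweep_intervals:
            if s.group not in labels:
                raise ValidationError(f"sweep targets unknown group '{s.group}'")
            if s.chrom not in self.chrom_names or s.end > self.chrom_length:
                raise ValidationError("sweep interval out of chromosome bounds")
        if self.n_sites + self.n_indels > self.n_chroms * self.chrom_length // 20:
            raise ValidationError("too many sites for the genome size")

    @property
    def chrom_names(self):
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def chrom_lengths(self) -> dict:
        return {c: self.chrom_length for c in self.chrom_names}

    @property
    def genome_length(self) -> int:
        return self.n_chroms * self.chrom_length


def standard_sweep_scenario(seed: int = 1) -> SimConfig:
    """The two-group sweep-recovery scenario used for end-to-end checks.

    20 Mb over 4 chromosomes, 10 implanted 50 kb sweeps (gamma = 8) in the
    cultivated group, divergence F = 0.05 for both groups, 22 wild + 20
    cultivated diploids, and the SNP density typical of deep plant
    resequencing cohorts (27,422 SNPs/Mb).  LD is off: sweeps and LD are
    independent axes of the generator, and leaving LD off keeps genotypes
    exchangeable across sites, which the analytic sweep check assumes.
    """
    n_chroms, length = 4, 5_000_000
    sweeps = []
    starts = [400_000, 1_900_000, 3_400_000]  # 3 per chrom, well separated
    k = 0
    for c in range(n_chroms):
        for s in starts:
            if k >= 10:
                break
            sweeps.append(SweepSpec(f"chr{c + 1}", s, s + 50_000, "cultivated", 8.0))
            k += 1
    return SimConfig(
        seed=seed,
        n_chroms=n_chroms,
        chrom_length=length,
        n_sites=548_440,  # 27,422 SNPs/Mb x 20 Mb
        groups=[GroupSpec("wild", 22, 0.05), GroupSpec("cultivated", 20, 0.05)],
        sweep_intervals=sweeps,
        ld_correlation_length=None,
        missing_rate=0.02,
        n_genes=200,
        n_indels=0,
    )


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------


def simulate_positions(cfg: SimConfig, rng: np.random.Generator):
    """Distinct, sorted 0-based SNP positions per chromosome (roughly even
    split of cfg.n_sites across chromosomes)."""
    per = np.full(cfg.n_chroms, cfg.n_sites // cfg.n_chroms)
    per[: cfg.n_sites % cfg.n_chroms] += 1
    out = {}
    for chrom, n in zip(cfg.chrom_names, per):
        pos = rng.choice(cfg.chrom_length, size=n, replace=False)
        pos.sort()
        out[chrom] = pos
    return out


def simulate_frequencies(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Ancestral and per-group allele frequencies (Balding-Nichols).

    Returns ``(positions, ancestral, freqs)`` where ``freqs`` maps group
    label to a dict chrom -> frequency array aligned with ``positions``.
    Groups with F = 0 copy the ancestral frequencies exactly.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    positions = simulate_positions(cfg, rng)
    a, b = cfg.ancestral_beta
    ancestral = {c: rng.beta(a, b, size=len(p)) for c, p in positions.items()}
    freqs = {}
    for g in cfg.groups:
        freqs[g.label] = {}
        for chrom, anc in ancestral.items():
            if g.divergence == 0:
                freqs[g.label][chrom] = anc.copy()
            else:
                F = g.divergence
                alpha = anc * (1 - F) / F
                beta = (1 - anc) * (1 - F) / F
                # guard against zero shape parameters at boundary frequencies
                alpha = np.maximum(alpha, 1e-9)
                beta = np.maximum(beta, 1e-9)
                freqs[g.label][chrom] = rng.beta(alpha, beta)
    return positions, ancestral, freqs


def sweep_transform(p: np.ndarray, gamma: float) -> np.ndarray:
    """Push frequencies toward the nearer boundary; identity at gamma = 1."""
    p = np.asarray(p, dtype=float)
    return np.where(p <= 0.5, p**gamma, 1.0 - (1.0 - p) ** gamma)


def implant_sweeps(positions, freqs, cfg: SimConfig):
    """Apply every configured sweep to its target group's frequencies."""
    out = {g: {c: f.copy() for c, f in per.items()} for g, per in freqs.items()}
    for sw in cfg.sweep_intervals:
        pos = positions[sw.chrom]
        mask = (pos >= sw.start) & (pos < sw.end)
        arr = out[sw.group][sw.chrom]
        arr[mask] = sweep_transform(arr[mask], sw.gamma)
    return out


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def _haplotypes_for_group(
    pos: np.ndarray, p: np.ndarray, n_hap: int, lc: float | None, rng
) -> np.ndarray:
    """(n_hap, n_sites) binary haplotypes with exponential-decay LD.

    Latent-uniform copying: haplotype h keeps its uniform u across adjacent
    sites with probability exp(-d / (2 lc)); allele = (u < p_site).
    Marginals stay Bernoulli(p_site) exactly, and mean r2 decays with
    distance at scale lc (r is linear in the sharing probability, r2
    quadratic, hence the factor 2).
    """
    n = len(pos)
    if n == 0:
        return np.zeros((n_hap, 0), dtype=np.int8)
    if lc is None or lc <= 0:
        return (rng.random((n_hap, n)) < p[None, :]).astype(np.int8)
    u = np.empty((n_hap, n))
    u[:, 0] = rng.random(n_hap)
    keep_p = np.exp(-np.diff(pos) / (2.0 * lc))
    fresh = rng.random((n_hap, n - 1))
    keep = rng.random((n_hap, n - 1)) < keep_p[None, :]
    for k in range(1, n):
        u[:, k] = np.where(keep[:, k - 1], u[:, k - 1], fresh[:, k - 1])
    return (u < p[None, :]).astype(np.int8)


def simulate_genotypes(positions, freqs, cfg: SimConfig, rng=None, return_haplotypes=False):
    """Diploid dosages for every group; optionally the phased haplotypes.

    Returns ``(samples, grouping, dosage_by_chrom)`` where
    ``dosage_by_chrom`` maps chrom -> (n_samples, n_sites) int8 array, or a
    4-tuple additionally carrying the haplotype arrays when
    ``return_haplotypes`` is set.  Missing genotypes are masked in at rate
    ``cfg.missing_rate``.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    samples, assignment = [], {}
    for g in cfg.groups:
        width = max(2, len(str(g.n_diploids)))
        for i in range(g.n_diploids):
            name = f"{g.label}_{i + 1:0{width}d}"
            samples.append(name)
            assignment[name] = g.label
    grouping = PopulationGrouping(assignment)

    dosage_by_chrom, hap_by_chrom = {}, {}
    for chrom in cfg.chrom_names:
        pos = positions[chrom]
        blocks, hap_blocks = [], []
        for g in cfg.groups:
            p = freqs[g.label][chrom]
            haps = _haplotypes_for_group(
                pos, p, 2 * g.n_diploids, cfg.ld_correlation_length, rng
            )
            hap_blocks.append(haps)
            blocks.append((haps[0::2] + haps[1::2]).astype(np.int8))
        dos = np.vstack(blocks)
        if cfg.missing_rate > 0:
            mask = rng.random(dos.shape) < cfg.missing_rate
            dos[mask] = MISSING
        dosage_by_chrom[chrom] = dos
        hap_by_chrom[chrom] = np.vstack(hap_blocks)
    if return_haplotypes:
        return samples, grouping, dosage_by_chrom, hap_by_chrom
    return samples, grouping, dosage_by_chrom


def simulate_cohort(cfg: SimConfig):
    """End-to-end in-memory simulation: GenotypeMatrix + grouping + truth.

    Convenience wrapper chaining frequencies -> sweeps -> genotypes; SNPs
    only (file emission adds indels and the reference).  Returns
    ``(gm, grouping, truth)`` where truth carries positions, frequencies
    and sweep intervals for oracle checks.
    """
    rng = np.random.default_rng(cfg.seed)
    positions, ancestral, base = simulate_frequencies(cfg, rng)
    freqs = implant_sweeps(positions, base, cfg)
    samples, grouping, dosage_by_chrom = simulate_genotypes(positions, freqs, cfg, rng)
    sites, dos_cols = [], []
    ref_alt = ("A", "C")  # placeholder alleles for in-memory matrices
    for chrom in cfg.chrom_names:
        pos = positions[chrom]
        sites.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos + 1,
                    "ref": ref_alt[0],
                    "alt": ref_alt[1],
                    "vclass": "snp",
                }
            )
        )
        dos_cols.append(dosage_by_chrom[chrom])
    gm = GenotypeMatrix(samples, pd.concat(sites, ignore_index=True), np.hstack(dos_cols))
    truth = {
        "positions": positions,
        "ancestral": ancestral,
        "frequencies": freqs,
        "base_frequencies": base,
        "sweeps": [(s.chrom, s.start, s.end) for s in cfg.sweep_intervals],
    }
    return gm, grouping, truth


# ---------------------------------------------------------------------------
# Reference + gene architecture
# ---------------------------------------------------------------------------


def _build_gene(chrom, start, cfg, rng) -> tuple:
    """One two-exon gene model plus its CDS sequence (translation order)."""
    utr = 150
    intron = 200
    cds_len = max(3 * int(cfg.gene_length * cfg.cds_fraction // 3), 6)
    half = 3 * (cds_len // 6)
    exon1_cds, exon2_cds = half, cds_len - half
    strand = "+" if rng.random() < 0.5 else "-"

    s = start
    utr5 = (s, s + utr)
    cds1 = (utr5[1], utr5[1] + exon1_cds)
    cds2 = (cds1[1] + intron, cds1[1] + intron + exon2_cds)
    utr3 = (cds2[1], cds2[1] + utr)
    span = (s, utr3[1])
    if strand == "-":  # mirror the 5'->3' feature order
        utr5_iv, utr3_iv = utr3, utr5
    else:
        utr5_iv, utr3_iv = utr5, utr3
    gene = GeneModel(
        gene_id=f"gene_{chrom}_{start}",
        chrom=chrom,
        strand=strand,
        span=span,
        cds_intervals=[cds1, cds2],
        utr5_intervals=[utr5_iv],
        utr3_intervals=[utr3_iv],
        exon_intervals=[(utr5[0], cds1[1]), (cds2[0], utr3[1])],
    )
    n_codons = cds_len // 3
    body = rng.choice(_NONSTOP_CODONS, size=n_codons - 2)
    coding = "ATG" + "".join(body) + "TAA"  # start, internal-stop-free, stop
    return gene, coding


def build_reference(cfg: SimConfig, rng: np.random.Generator):
    """Random genome with tiled gene models; CDS frames are start/stop
    consistent.  Returns ``(sequences, genes)``."""
    seqs = {
        c: rng.choice(_BASES, size=cfg.chrom_length)
        for c in cfg.chrom_names
    }
    genes = []
    if cfg.n_genes > 0:
        per = np.full(cfg.n_chroms, cfg.n_genes // cfg.n_chroms)
        per[: cfg.n_genes % cfg.n_chroms] += 1
        for chrom, n in zip(cfg.chrom_names, per):
            if n == 0:
                continue
            spacing = cfg.chrom_length // (n + 1)
            if spacing <= cfg.gene_length:
                raise ValidationError("genome too small for requested gene count")
            for i in range(n):
                gene, coding = _build_gene(chrom, (i + 1) * spacing, cfg, rng)
                from ._utils import revcomp

                placed = coding if gene.strand == "+" else revcomp(coding)
                off = 0
                for s, e in gene.cds_intervals:
                    seqs[chrom][s:e] = list(placed[off : off + (e - s)])
                    off += e - s
                genes.append(gene)
    return {c: "".join(s) for c, s in seqs.items()}, genes


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


def _write_fasta(seqs: dict, path, width: int = 70):
    with open(path, "w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _cds_phases(gene: GeneModel):
    """GFF3 phase per CDS interval (genomic order)."""
    order = sorted(gene.cds_intervals)
    if gene.strand == "-":
        order = order[::-1]
    phases, done = {}, 0
    for s, e in order:
        phases[(s, e)] = (3 - done % 3) % 3
        done += e - s
    return phases


def _write_gff(genes, path):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            base = f"{g.chrom}\tsim\t"
            tail = f"\t.\t{g.strand}\t"
            fh.write(f"{base}gene\t{s + 1}\t{e}{tail}.\tID={g.gene_id}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(f"{base}mRNA\t{s + 1}\t{e}{tail}.\tID={mrna};Parent={g.gene_id}\n")
            for i, (xs, xe) in enumerate(sorted(g.exon_intervals), 1):
                fh.write(
                    f"{base}exon\t{xs + 1}\t{xe}{tail}.\tID={mrna}.exon{i};Parent={mrna}\n"
                )
            phases = _cds_phases(g)
            for i, (cs, ce) in enumerate(sorted(g.cds_intervals), 1):
                fh.write(
                    f"{base}CDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t{phases[(cs, ce)]}"
                    f"\tID={mrna}.cds{i};Parent={mrna}\n"
                )
            for i, (us, ue) in enumerate(sorted(g.utr5_intervals), 1):
                fh.write(
                    f"{base}five_prime_UTR\t{us + 1}\t{ue}{tail}.\t"
                    f"ID={mrna}.utr5.{i};Parent={mrna}\n"
                )
            for i, (us, ue) in enumerate(sorted(g.utr3_intervals), 1):
                fh.write(
                    f"{base}three_prime_UTR\t{us + 1}\t{ue}{tail}.\t"
                    f"ID={mrna}.utr3.{i};Parent={mrna}\n"
                )


def _guaranteed_cds_positions(genes) -> list:
    """Nine CDS positions of the first valid gene covering all three codon
    positions across three codons (keeps every annotation path exercised)."""
    for g in genes:
        if g.cds_valid:
            s, e = sorted(g.cds_intervals)[0]
            if e - s >= 12:
                return [(g.chrom, s + 3 + k) for k in range(9)]
    return []


def emit_dataset(cfg: SimConfig, outdir) -> dict:
    """Write a complete consistent dataset: FASTA, GFF3, VCF, groups TSV.

    The VCF holds every SNP (ref allele taken from the FASTA) plus
    ``cfg.n_indels`` short length variants for annotation tests.  A
    self-check verifies VCF-vs-FASTA consistency before returning.  Output
    is byte-identical for identical configs.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    seqs, genes = build_reference(cfg, rng)

    positions, _, base = simulate_frequencies(cfg, rng)
    # force a few CDS SNPs at every codon position
    for chrom, pos0 in _guaranteed_cds_positions(genes):
        pos = positions[chrom]
        if pos0 not in pos:
            j = int(np.searchsorted(pos, pos0))
            positions[chrom] = np.insert(pos, j, pos0)
            anc = float(rng.beta(*cfg.ancestral_beta))
            for g in cfg.groups:
                per = base[g.label][chrom]
                F = g.divergence
                val = anc if F == 0 else float(
                    rng.beta(max(anc * (1 - F) / F, 1e-9), max((1 - anc) * (1 - F) / F, 1e-9))
                )
                base[g.label][chrom] = np.insert(per, j, val)
    freqs = implant_sweeps(positions, base, cfg)
    samples, grouping, dosage_by_chrom = simulate_genotypes(positions, freqs, cfg, rng)

    # assemble site table: SNPs from the reference, plus indels
    frames, dosage_cols = [], []
    for chrom in cfg.chrom_names:
        pos = positions[chrom]
        seq = seqs[chrom]
        refs = np.array([seq[p] for p in pos])
        shift = rng.integers(1, 4, size=len(pos))
        alts = _BASES[(np.searchsorted(_BASES, refs) + shift) % 4]
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos + 1, "ref": refs, "alt": alts, "vclass": "snp"}
            )
        )
        dosage_cols.append(dosage_by_chrom[chrom])

    if cfg.n_indels > 0:
        per = np.full(cfg.n_chroms, cfg.n_indels // cfg.n_chroms)
        per[: cfg.n_indels % cfg.n_chroms] += 1
        n_samples = sum(g.n_diploids for g in cfg.groups)
        for chrom, n in zip(cfg.chrom_names, per):
            taken = set(positions[chrom].tolist())
            seq = seqs[chrom]
            pos_list, refs, alts = [], [], []
            while len(pos_list) < n:
                p = int(rng.integers(0, cfg.chrom_length - 10))
                if any(q in taken for q in range(p, p + 8)):
                    continue
                taken.update(range(p, p + 8))
                length = int(rng.integers(1, 6))
                if rng.random() < 0.5:  # deletion
                    ref, alt = seq[p : p + 1 + length], seq[p]
                else:  # insertion
                    ins = "".join(rng.choice(_BASES, size=length))
                    ref, alt = seq[p], seq[p] + ins
                pos_list.append(p + 1)
                refs.append(ref)
                alts.append(alt)
            p_ind = rng.uniform(0.1, 0.5, size=n)
            dos = rng.binomial(2, p_ind[None, :], size=(n_samples, n)).astype(np.int8)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos_list,
                        "ref": refs,
                        "alt": alts,
                        "vclass": [classify_variant(r, a) for r, a in zip(refs, alts)],
                    }
                )
            )
            dosage_cols.append(dos)

    sites = pd.concat(frames, ignore_index=True)
    gm = GenotypeMatrix(samples, sites, np.hstack(dosage_cols)).sorted()

    # self-check: every ref allele must match the reference sequence
    for rec in gm.sites.sample(n=min(200, gm.n_sites), random_state=0).itertuples():
        expect = seqs[rec.chrom][rec.pos - 1 : rec.pos - 1 + len(rec.ref)]
        if expect != rec.ref:
            raise DataIntegrityError(
                f"emitted VCF ref disagrees with FASTA at {rec.chrom}:{rec.pos}"
            )

    paths = {
        "fasta": os.path.join(outdir, "reference.fa"),
        "gff": os.path.join(outdir, "genes.gff3"),
        "vcf": os.path.join(outdir, "variants.vcf"),
        "groups": os.path.join(outdir, "groups.tsv"),
    }
    _write_fasta(seqs, paths["fasta"])
    _write_gff(genes, paths["gff"])
    write_vcf(gm, paths["vcf"], contig_lengths=cfg.chrom_lengths)
    with open(paths["groups"], "w") as fh:
        for s in samples:
            fh.write(f"{s}\t{grouping.assignment[s]}\n")
    return paths
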