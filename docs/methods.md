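# Methods

This note records the models, estimators, numerical conventions and design
choices behind the package, and what the synthetic-data checks do and do
not demonstrate about real data.

## Data model and coordinates

Files keep their native conventions at the boundary (VCF/GFF3 1-based
inclusive); all internal interval arithmetic — gene features, scan windows,
selected regions — is 0-based half-open, converted exactly once at I/O.
This removes the usual off-by-one hazards in window tiling and overlap
tests. Genotypes are stored as diploid alt-allele dosages {0,1,2} with −1
for missing; only biallelic records enter the matrix (multiallelic records
are dropped by default or optionally split into per-alt pseudo-records).
Variant size classes: SNP (single-base substitution), indel (1–5 bp length
difference), SV (> 5 bp). SVs are counted and classified but excluded from
diversity/F<sub>ST</sub>/LD, which are SNP statistics.

Site filters mirror common resequencing practice: a QUAL threshold at
ingest (default 20; records without a QUAL pass) and a minor-allele-
frequency filter (default 0.1, computed on non-missing alleles) with an
optional missing-fraction cap. `filter_sites` is idempotent and never
imputes; PCA is the only consumer that mean-imputes, locally.

## Diversity

Per-site diversity is the unbiased pairwise estimator
2p̂(1−p̂)·n/(n−1) on the n non-missing alleles of a group, identical to the
mean pairwise difference among the group's sequences at that site. Group
and window values divide the summed per-site diversity by *sequence
length* (chromosome or window), not by the number of variant sites, which
reproduces the per-bp ×10⁻³ scale of published tables; no callability mask
is applied, and that choice is deliberate and documented (denominators on
real data are therefore slight underestimates wherever assembly gaps
exist). Heterozygosity is 100 × (heterozygous SNP calls)/(total length),
computed on the unfiltered call set.

A window's `n_snps` counts the group's *callable* variant sites (≥ 2
non-missing alleles), not its segregating sites; windows below
`min_snps_per_window` (default 10) are unusable. Counting segregating
sites instead would disqualify precisely the windows a sweep has driven
toward monomorphism — the signal the scan exists to find.

## Differentiation

Per-site Weir & Cockerham (1984) two-population variance components are
computed from allele counts. Because the inputs are allele counts rather
than genotypes, the within-individual component is not estimable and the
allele-based (haploid-sample) form is used: units of sampling are the
non-missing alleles, and the reported total component is a+b. Under the
Balding–Nichols model with both groups at divergence F, the expectation of
the windowed estimator is F — the recovery tests exploit this closed form.
Window F<sub>ST</sub> is the ratio of averages Σa/Σ(a+b) over usable sites
(monomorphic-in-both and under-sampled sites are unusable); negative
window estimates are clamped to 0 before Z-scoring (configurable, default
on), and Z uses the genome-wide mean and n−1 standard deviation over
usable windows only.

## Sweep scan

Windows are `window_size` = 10 kb sliding by `step` = 5 kb; a trailing
partial window is kept only when longer than one step (a shorter remainder
is already covered by the previous window), except that a chromosome
shorter than one window yields its single truncated window. The scan
statistic pair per window is log₂(π_wild/π_cultivated) and Z(F<sub>ST</sub>).
The ratio is oriented wild-over-cultivated so that diversity loss in the
cultivated group is a *large positive* value; zero rules: cultivated π = 0
with wild π > 0 maps to +∞ (ranks above all finite windows), the reverse
to −∞, both zero marks the window unusable.

Thresholds are empirical (1 − q) quantiles (type-7, linear interpolation)
with q = 0.05, computed per contrast over usable windows; infinities are
given finite ranks just outside the observed range before quantile
interpolation. A window is flagged iff **strictly** above both thresholds
(ties are not flagged); fewer than 20 usable windows is an error.
Overlapping or book-ended flagged windows merge into regions (any ≥ 1 bp
gap splits); region F<sub>ST</sub> and ratio are SNP-weighted means of member
windows. Genes attach on ≥ 1 bp span overlap, counted once per region;
the mean genes/region and nonsyn/syn ratios are reported with 2-decimal
half-up rounding. Each (wild, cultivated) contrast is scanned
independently with its own thresholds.

Known property of the joint-tail design: with ~4,000 windows and 5%
marginal tails, neutral windows inevitably occupy the tail slots not taken
by true sweeps, and their joint exceedance (≈ independence product, ~2–3
windows per genome scan) appears as singleton false regions. With ten
implanted 50 kb sweeps this puts expected precision at roughly 0.8 — the
irreducible noise floor of the quantile-based joint scan at that sweep
fraction; sensitivity is far more robust (every strongly swept window is
orders of magnitude beyond both thresholds).

## Linkage disequilibrium

r² is the squared Pearson correlation of diploid dosage vectors
(composite LD), pairwise-complete over samples, requiring ≥ 2 complete
samples and nonzero variance at both sites; real input is unphased so no
haplotype measure is attempted (the simulator's phased haplotypes back an
oracle test of the genotype measure against D²/(p_A q_A p_B q_B)).
Intra-chromosome pairs closer than `max_dist` (default 50 kb) are binned
(default 100 bp); beyond `max_pairs` = 10⁶ a seeded uniform subsample is
scored. The decay-distance summary finds the first crossing of
fraction × max(mean r²) — half-maximum by default — with linear
interpolation between bin midpoints, or of an absolute r² level; a curve
already below the threshold at its closest bin returns that bin's
midpoint, and a curve never reaching it returns the "not reached"
sentinel (None). `fit_decay_length` fits A·e^(−d/L) + c; the additive
baseline absorbs the ~1/n sampling floor of r² that would otherwise bias
L upward.

## Population structure

Distance is allele-sharing: mean |dosage_i − dosage_j|/2 over sites called
in both samples (0 for identical samples, 1 for opposite homozygotes
everywhere); a pair with no shared called site is an error. The published
pipelines this mirrors do not state their distance formula, so topology —
not branch lengths — is the comparable output. Neighbor joining follows
Saitou–Nei with the Q-criterion; ties break to the smallest index pair, so
output is deterministic; negative branch lengths clamp to 0; the unrooted
tree keeps a top-level trifurcation. Bootstrap resamples sites (columns)
with replacement; edge support is the fraction of replicate trees
containing the edge's bipartition. Newick output writes supports as
internal labels and quotes labels containing metacharacters.

PCA drops monomorphic sites, mean-imputes missing dosages per site,
centers by 2p̂ and scales by √(2p̂(1−p̂)) (Patterson normalization), then
eigendecomposes the sample covariance; coordinates are eigenvectors scaled
by √eigenvalue with a deterministic sign (largest-magnitude coordinate
positive), and explained fractions are over the positive spectrum.

## Synthetic cohort generator

The generator emulates a five-group domestication cohort at desk scale.
Defaults: 69 diploids (wild 22, seed 21, rhizome 13, flower 11, outgroup
2 — the emulated study design), 2 chromosomes × 1 Mb, 20,000 SNPs (0.01/bp),
ancestral frequencies Beta(0.8, 0.8), group divergences F = 0.05/0.10/
0.25/0.40/0.60 (wild/flower/seed/rhizome/outgroup), four 50 kb sweeps at
γ = 8 targeting cultivated groups, LD correlation length 500 bp, 2%
missing genotypes, 100 two-exon genes of 3 kb with half their span coding.
Under Balding–Nichols, E[2p_g q_g] = (1−F)·E[2pq], so the divergence
spread produces per-group diversities spanning roughly 1–3 ×10⁻³ with the
cultivated ordering flower > seed > rhizome; the wild group is kept at low
F because it doubles as the sweep-scan reference, so its diversity *rank*
(lowest in the emulated cohort) is not reproduced.

Frequencies: ancestral p ~ Beta; group frequency ~ Beta(p(1−F)/F,
(1−p)(1−F)/F) (exactly p at F = 0). Sweeps: within each interval the
target group's frequency moves to p^γ (p ≤ ½) or 1−(1−p)^γ, strictly
reducing expected heterozygosity for γ > 1; the transform acts on
frequencies, so hitchhiking LD around sweeps is *not* emulated. LD: each
haplotype carries a latent uniform that survives from one site to the next
with probability e^(−d/2L_c), and the allele is 1[u < p_site]; marginals
are exactly Bernoulli(p_site), r is linear in the survival probability and
r² quadratic, so mean r² decays at scale L_c — making L_c the directly
measurable input. Genotypes are independent haplotype pairs; binomial
sampling replaces the chain when LD is off.

Emission writes a consistent FASTA (genes carry start/internal-stop-free
CDS frames, reverse-complemented on minus strands), GFF3 (gene/mRNA/exon/
CDS/UTR with correct phases), VCF (ref alleles taken from the FASTA; a few
short indels included for the annotation paths; nine CDS SNPs are forced
to cover all three codon positions) and the groups TSV, with a
ref-vs-FASTA self-check before returning. Identical configs emit
byte-identical files.

The standard sweep-recovery scenario is 20 Mb over 4 chromosomes, ten
50 kb sweeps at γ = 8, both groups at F = 0.05, 22 + 20 diploids, and the
SNP density typical of deep plant resequencing (27,422 SNPs/Mb); LD is off
there since sweep detection and LD are independent generator axes.

What passing these checks shows — and does not. The generator validates
estimator algebra, window mechanics, threshold logic and end-to-end
plumbing against closed-form truths. It does not contain linked selection,
demographic history, mutation-rate heterogeneity, call-rate structure or
reference bias, so recovery rates measured here do not predict error rates
on real cohorts.

## Reproducibility and orchestration

`report.run_full` chains ingest → annotate → diversity → per-contrast
scans → LD → tree → PCA; any stage failure removes partial outputs and
raises an error naming the stage. All randomness flows from one seed;
per-stage seeds derive via SHA-256, so a given configuration yields a
byte-identical bundle (wall-clock timings live in a separate
`timings.json`, the single non-deterministic artifact). Floats in tables
are written at 6 significant digits. The command-line layer exposes
`simulate` and `run-all`; the individual stages are the library functions
themselves, which is the intended API for anything beyond the end-to-end
run. `run_full` defaults to 100 bootstrap replicates (a tractable default;
raise to 1000 for publication-grade support values).

## Known limitations

* Region classes take gene-level precedence; transcript-level effects
  (alternative splicing, multiple mRNAs per gene) are out of scope, and
  the first valid gene model wins when CDS of overlapping genes disagree.
* CDS SNPs in genes with invalid models (length not divisible by 3,
  reference mismatch) fall into a residual "unknown" class rather than
  being guessed.
* The θπ denominator uses full sequence length (no callability mask).
* The allele-count F<sub>ST</sub> form cannot separate the within-individual
  component; inbreeding-sensitive applications need genotype-level
  estimators.
* Joint 5%-tail sweep scans carry an irreducible false-region floor
  (see above); interpret isolated single-window regions with caution.
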