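"""annotation: region precedence, codon effects, venn partitions, summaries."""
import itertools

import numpy as np
import pandas as pd
import pytest

from domestiscan import annotation as ann
from domestiscan import synthetic_data as sd
from domestiscan import variant_io as vio
from domestiscan.errors import DataIntegrityError
from domestiscan.variant_io import GeneModel, SiteRecord

from conftest import make_gm


def gene(gene_id="g1", chrom="chr1", strand="+", span=(100, 400), cds=None,
         utr5=None, utr3=None, exons=None):
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, span=span,
        cds_intervals=cds or [], utr5_intervals=utr5 or [],
        utr3_intervals=utr3 or [], exon_intervals=exons or [],
    )


class TestClassifyRegion:
    def test_precedence_and_intergenic(self):
        g = gene(cds=[(150, 350)], utr5=[(100, 150)], utr3=[(350, 400)],
                 exons=[(100, 400)])
        assert ann.classify_region("chr1", 200, [g])[0] == ann.CDS
        assert ann.classify_region("chr1", 120, [g])[0] == ann.UTR5
        assert ann.classify_region("chr1", 360, [g])[0] == ann.UTR3
        assert ann.classify_region("chr1", 50, [g])[0] == ann.INTERGENIC
        assert ann.classify_region("chr2", 200, [g])[0] == ann.INTERGENIC

    def test_intronic_between_exons(self):
        g = gene(span=(0, 900), cds=[(0, 300), (500, 900)], exons=[(0, 300), (500, 900)])
        assert ann.classify_region("chr1", 400, [g])[0] == ann.INTRONIC

    def test_utr5_utr3_overlap_of_two_genes(self):
        a = gene("gA", span=(0, 200), utr5=[(150, 200)], exons=[(0, 200)])
        b = gene("gB", span=(150, 400), utr3=[(150, 220)], exons=[(150, 400)])
        cls, ids = ann.classify_region("chr1", 170, [a, b])
        assert cls == ann.UTR5_UTR3
        assert ids == ["gA", "gB"]

    def test_cds_beats_utr_across_genes(self):
        a = gene("gA", span=(0, 200), utr5=[(150, 200)], exons=[(0, 200)])
        b = gene("gB", span=(100, 400), cds=[(150, 300)], exons=[(100, 400)])
        assert ann.classify_region("chr1", 170, [a, b])[0] == ann.CDS


def snp(chrom, pos1, ref, alt):
    return SiteRecord(chrom, pos1, ref, alt, "snp")


class TestCodingEffect:
    # CDS at 0-based [0, 9): ATG GAA TAA  (Met, Glu, stop)
    REF = {"chr1": "ATGGAATAACCCCCC"}
    G = gene(span=(0, 9), cds=[(0, 9)], exons=[(0, 9)])

    def test_synonymous_third_position(self):
        # GAA -> GAG, both Glu
        assert ann.coding_effect(snp("chr1", 6, "A", "G"), self.G, self.REF) == ann.SYNONYMOUS

    def test_nonsynonymous(self):
        # GAA -> GCA, Glu -> Ala
        assert ann.coding_effect(snp("chr1", 5, "A", "C"), self.G, self.REF) == ann.NONSYNONYMOUS

    def test_stopgain(self):
        # GAA -> TAA
        assert ann.coding_effect(snp("chr1", 4, "G", "T"), self.G, self.REF) == ann.STOPGAIN

    def test_stoploss(self):
        # TAA -> CAA (Gln)
        assert ann.coding_effect(snp("chr1", 7, "T", "C"), self.G, self.REF) == ann.STOPLOSS

    def test_reference_mismatch_is_error(self):
        with pytest.raises(DataIntegrityError, match="mismatch"):
            ann.coding_effect(snp("chr1", 6, "T", "G"), self.G, self.REF)

    def test_agrees_with_full_cds_retranslation_oracle(self):
        """Effects on a random toy genome match a brute-force translator that
        rebuilds the whole CDS with and without the variant (both strands)."""
        from Bio.Seq import Seq

        cfg = sd.SimConfig(seed=11, n_chroms=2, chrom_length=60_000, n_sites=200,
                           n_genes=20, n_indels=0, sweep_intervals=[])
        rng = np.random.default_rng(11)
        seqs, genes = sd.build_reference(cfg, rng)
        checked = 0
        for _ in range(1000):
            g = genes[rng.integers(len(genes))]
            cds = sorted(g.cds_intervals)
            s, e = cds[rng.integers(len(cds))]
            pos0 = int(rng.integers(s, e))
            ref = seqs[g.chrom][pos0]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            got = ann.coding_effect(snp(g.chrom, pos0 + 1, ref, alt), g, seqs)

            # oracle: rebuild and translate the full CDS
            genomic = "".join(seqs[g.chrom][a:b] for a, b in cds)
            mutated_chrom = seqs[g.chrom][:pos0] + alt + seqs[g.chrom][pos0 + 1:]
            genomic_mut = "".join(mutated_chrom[a:b] for a, b in cds)
            if g.strand == "-":
                genomic = str(Seq(genomic).reverse_complement())
                genomic_mut = str(Seq(genomic_mut).reverse_complement())
            p_ref = str(Seq(genomic).translate())
            p_alt = str(Seq(genomic_mut).translate())
            (i,) = [i for i in range(len(p_ref)) if p_ref[i] != p_alt[i]] or [None]
            if i is None:
                expect = ann.SYNONYMOUS
            elif p_alt[i] == "*":
                expect = ann.STOPGAIN
            elif p_ref[i] == "*":
                expect = ann.STOPLOSS
            else:
                expect = ann.NONSYNONYMOUS
            assert got == expect, (g.gene_id, g.strand, pos0, ref, alt)
            checked += 1
        assert checked == 1000


class TestIndelEffect:
    def test_frameshift_and_inframe(self):
        g = gene(cds=[(150, 350)])
        two_del = SiteRecord("chr1", 200, "ATT", "A", "indel")
        three_ins = SiteRecord("chr1", 200, "A", "ACCC", "indel")
        assert ann.indel_effect(two_del, g) == ann.FRAMESHIFT
        assert ann.indel_effect(three_ins, g) == ann.NONFRAMESHIFT

    def test_intronic_indel_has_no_effect(self):
        g = gene(span=(0, 900), cds=[(0, 300), (500, 900)], exons=[(0, 300), (500, 900)])
        annot = ann.GenomeAnnotator([g])
        gm = make_gm([[1], [1]], start_pos=401)
        gm.sites.loc[0, ["ref", "alt", "vclass"]] = ["AT", "A", "indel"]
        table = annot.annotate(gm)
        assert table.loc[0, "region_class"] == ann.INTRONIC
        assert table.loc[0, "effect_class"] == ann.NONE


class TestVenn:
    def test_simple_partition(self):
        counts = ann.venn_partition({"A": {1, 2, 3}, "B": {2, 3, 4}})
        assert counts == {("A",): 1, ("B",): 1, ("A", "B"): 2}

    def test_disjoint_groups_share_nothing(self):
        counts = ann.venn_partition({"A": {1}, "B": {2}, "C": {3}})
        assert ("A", "B", "C") not in counts
        assert sum(counts.values()) == 3

    def test_single_group_degenerate(self):
        assert ann.venn_partition({"A": {1, 2}}) == {("A",): 2}

    def test_matches_exhaustive_enumeration(self):
        """5 random key sets: counts equal brute force over all 31 classes."""
        rng = np.random.default_rng(5)
        labels = list("ABCDE")
        sets = {l: set(map(int, rng.choice(2000, size=600))) for l in labels}
        got = ann.venn_partition(sets)
        universe = set().union(*sets.values())
        brute = {}
        for r in range(1, 6):
            for combo in itertools.combinations(labels, r):
                inside = set(universe)
                for l in combo:
                    inside &= sets[l]
                for l in labels:
                    if l not in combo:
                        inside -= sets[l]
                if inside:
                    brute[tuple(combo)] = len(inside)
        assert got == brute
        assert sum(got.values()) == len(universe)

    def test_matrix_venn_matches_set_venn(self, ingested):
        gm = ingested["gm"].snps()
        grouping = ingested["grouping"]
        presence = ann.group_presence(gm, grouping)
        sets = {
            g: set(np.flatnonzero(presence[g].to_numpy()).tolist())
            for g in grouping.labels
        }
        assert ann.venn_from_matrix(gm, grouping) == ann.venn_partition(sets)


class TestSummarize:
    def test_single_site_counts(self):
        gm = make_gm([[1], [0]])
        grouping = vio.PopulationGrouping({"s1": "a", "s2": "b"})
        annots = pd.DataFrame(
            {"region_class": [ann.CDS], "effect_class": [ann.SYNONYMOUS],
             "gene_ids": [["g1"]]}
        )
        out = ann.summarize(gm, grouping, annots)
        assert out["a"].total == 1 and out["a"].private == 1
        assert out["a"].region_counts[ann.CDS] == 1
        assert sum(out["a"].region_counts.values()) == out["a"].total
        assert out["b"].total == 0
        assert out["a"].effect_counts[ann.SYNONYMOUS] == 1
        assert out["a"].nonsyn_syn_ratio == 0.0  # 0 nonsyn over 1 syn

    def test_region_counts_conserved_per_group(self, ingested):
        gm = ingested["gm"].snps()
        annot = ann.GenomeAnnotator(ingested["genes"], ingested["reference"])
        table = annot.annotate(gm)
        out = ann.summarize(gm, ingested["grouping"], table)
        for s in out.values():
            assert sum(s.region_counts.values()) == s.total

    def test_zero_synonymous_gives_none_marker(self):
        gm = make_gm([[1], [1]])
        grouping = vio.PopulationGrouping({"s1": "a", "s2": "a"})
        annots = pd.DataFrame(
            {"region_class": [ann.CDS], "effect_class": [ann.NONSYNONYMOUS],
             "gene_ids": [["g1"]]}
        )
        out = ann.summarize(gm, grouping, annots)
        assert out["a"].nonsyn_syn_ratio is None
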