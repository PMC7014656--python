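"""sweep_scan: window tiling, joint-tail flagging, region merging, genes."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from domestiscan import sweep_scan as ss
from domestiscan.errors import ValidationError
from domestiscan.variant_io import GeneModel


class TestMakeWindows:
    def test_example_tiling(self):
        w = ss.make_windows({"c": 25_000}, ss.ScanConfig())
        assert [x[1] for x in w] == [0, 5_000, 10_000, 15_000]
        assert w[-1] == ("c", 15_000, 25_000)

    def test_short_chromosome_single_window(self):
        assert ss.make_windows({"c": 8_000}, ss.ScanConfig()) == [("c", 0, 8_000)]

    def test_full_coverage_by_bp_scan(self):
        L = 100_000
        covered = np.zeros(L, dtype=bool)
        for _, s, e in ss.make_windows({"c": L}, ss.ScanConfig()):
            covered[s:e] = True
        assert covered.all()

    @pytest.mark.parametrize("L", [9_999, 10_000, 12_345, 14_999, 15_001, 23_000])
    def test_coverage_various_lengths(self, L):
        covered = np.zeros(L, dtype=bool)
        for _, s, e in ss.make_windows({"c": L}, ss.ScanConfig()):
            covered[s:e] = True
        assert covered.all()

    def test_bad_config_rejected(self):
        with pytest.raises(ValidationError):
            ss.ScanConfig(window_size=100, step=200)
        with pytest.raises(ValidationError):
            ss.ScanConfig(tail_quantile=0.6)


class TestLog2PiRatio:
    def test_values(self):
        assert ss.log2_pi_ratio(4e-3, 1e-3) == pytest.approx(2.0)
        assert ss.log2_pi_ratio(2e-3, 2e-3) == 0.0

    def test_zero_rules(self):
        assert ss.log2_pi_ratio(1e-3, 0.0) == np.inf
        assert ss.log2_pi_ratio(0.0, 1e-3) == -np.inf
        assert np.isnan(ss.log2_pi_ratio(0.0, 0.0))


def _stats(ratios, zs, usable=None, chrom="c", start0=0):
    n = len(ratios)
    usable = [True] * n if usable is None else usable
    starts = start0 + 10_000 * np.arange(n)  # non-adjacent windows
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + 5_000,
            "n_snps": 50,
            "pi_wild": 1e-3,
            "pi_cult": 1e-3,
            "fst": 0.05,
            "log2_pi_ratio": np.asarray(ratios, dtype=float),
            "z_fst": np.asarray(zs, dtype=float),
            "usable": usable,
            "flagged": False,
        }
    )


class TestFlagOutliers:
    def test_perfectly_correlated_scores_flag_five_percent(self):
        scores = np.arange(1.0, 101.0)
        out, thr = ss.flag_outliers(_stats(scores, scores))
        assert out.flagged.sum() == 5
        assert set(out[out.flagged].log2_pi_ratio) == {96.0, 97.0, 98.0, 99.0, 100.0}

    def test_anti_correlated_scores_flag_nothing(self):
        scores = np.arange(1.0, 101.0)
        out, _ = ss.flag_outliers(_stats(scores, scores[::-1]))
        assert out.flagged.sum() == 0

    def test_identical_windows_flag_nothing(self):
        out, _ = ss.flag_outliers(_stats([1.0] * 50, [2.0] * 50))
        assert out.flagged.sum() == 0

    def test_single_joint_maximum_flagged(self):
        rng = np.random.default_rng(0)
        ratios = rng.normal(size=1000)
        zs = rng.normal(size=1000)
        ratios[123] = ratios.max() + 5
        zs[123] = zs.max() + 5
        out, _ = ss.flag_outliers(_stats(ratios, zs))
        assert out.flagged[123]

    def test_infinite_ratio_sorts_above_everything(self):
        ratios = np.concatenate([np.zeros(99), [np.inf]])
        zs = np.arange(100.0)
        out, _ = ss.flag_outliers(_stats(ratios, zs))
        assert out.flagged[99]

    def test_marginal_tail_bound(self):
        """Joint flags are a subset of each marginal 5% tail."""
        rng = np.random.default_rng(8)
        out, _ = ss.flag_outliers(_stats(rng.normal(size=400), rng.normal(size=400)))
        assert out.flagged.sum() <= 0.05 * 400

    def test_too_few_usable_windows_raise(self):
        with pytest.raises(ValidationError, match="usable"):
            ss.flag_outliers(_stats([1.0] * 10, [1.0] * 10))

    def test_unusable_windows_never_flagged(self):
        scores = np.arange(1.0, 101.0)
        usable = [True] * 99 + [False]
        out, _ = ss.flag_outliers(_stats(scores, scores, usable=usable))
        assert not out.flagged.iloc[99]


def _flagged_stats(intervals, chrom="c"):
    rows = []
    for s, e in intervals:
        rows.append(
            {"chrom": chrom, "start": s, "end": e, "n_snps": 10, "fst": 0.5,
             "log2_pi_ratio": 1.0, "usable": True, "flagged": True,
             "pi_wild": 1e-3, "pi_cult": 1e-4, "z_fst": 3.0}
        )
    return pd.DataFrame(rows)


class TestMergeRegions:
    def test_overlap_merges(self):
        regions = ss.merge_regions(_flagged_stats([(0, 10_000), (5_000, 15_000)]))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 15_000)
        assert regions[0].n_windows_merged == 2

    def test_gap_splits(self):
        regions = ss.merge_regions(_flagged_stats([(0, 10_000), (20_000, 30_000)]))
        assert len(regions) == 2

    def test_bookended_merge(self):
        regions = ss.merge_regions(_flagged_stats([(0, 10_000), (10_000, 20_000)]))
        assert len(regions) == 1

    def test_chromosomes_never_merge(self):
        a = _flagged_stats([(0, 10_000)], chrom="c1")
        b = _flagged_stats([(0, 10_000)], chrom="c2")
        regions = ss.merge_regions(pd.concat([a, b], ignore_index=True))
        assert len(regions) == 2

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 30), min_size=1, max_size=12, unique=True))
    def test_matches_interval_union_oracle(self, starts):
        intervals = [(5_000 * s, 5_000 * s + 10_000) for s in sorted(starts)]
        regions = ss.merge_regions(_flagged_stats(intervals))
        # brute-force union on a bp grid
        line = np.zeros(200_000, dtype=bool)
        for s, e in intervals:
            line[s:e] = True
        padded = np.concatenate(([False], line, [False]))
        n_components = int((padded[1:] & ~padded[:-1]).sum())
        assert len(regions) == n_components
        assert sum(r.length for r in regions) == int(line.sum())


def _gene(gid, chrom, lo, hi):
    return GeneModel(gene_id=gid, chrom=chrom, strand="+", span=(lo, hi))


class TestAssignGenes:
    def test_overlap_by_one_bp_counts(self):
        regions = ss.merge_regions(_flagged_stats([(1_000, 11_000)]))
        genes = [
            _gene("gA", "c", 0, 1_001),      # 1 bp overlap
            _gene("gB", "c", 10_999, 20_000),  # 1 bp overlap
            _gene("gC", "c", 11_000, 20_000),  # book-ended, no overlap
            _gene("gD", "other", 1_000, 11_000),
        ]
        (r,) = ss.assign_genes(regions, genes)
        assert r.genes == ["gA", "gB"]

    def test_intergenic_desert(self):
        regions = ss.merge_regions(_flagged_stats([(0, 10_000)]))
        (r,) = ss.assign_genes(regions, [_gene("g", "c", 50_000, 60_000)])
        assert r.genes == []

    def test_mean_genes_per_region_rounding(self):
        # 37 regions carrying 24 gene assignments -> 0.65
        regions = ss.merge_regions(
            _flagged_stats([(i * 20_000, i * 20_000 + 10_000) for i in range(37)])
        )
        genes = [_gene(f"g{i}", "c", i * 20_000 + 100, i * 20_000 + 200) for i in range(24)]
        regions = ss.assign_genes(regions, genes)
        assert sum(len(r.genes) for r in regions) == 24
        assert ss.mean_genes_per_region(regions) == 0.65


class TestScanInvariants:
    def test_chromosome_order_invariance(self, ingested):
        from domestiscan.variant_io import filter_sites

        gm = filter_sites(ingested["gm"], 0.1, 1.0)
        grouping = ingested["grouping"]
        L = ingested["cfg"].chrom_length
        cfg = ss.ScanConfig(min_snps_per_window=2)
        s1 = ss.compute_window_stats(gm, grouping, "wild", "seed",
                                     {"chr1": L, "chr2": L}, cfg)
        s2 = ss.compute_window_stats(gm, grouping, "wild", "seed",
                                     {"chr2": L, "chr1": L}, cfg)
        m1 = s1.sort_values(["chrom", "start"]).reset_index(drop=True)
        m2 = s2.sort_values(["chrom", "start"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(m1, m2)
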