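"""Joint-outlier scan, region handling, rank-sum test and enrichment."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from statsmodels.stats.multitest import multipletests

from yakpop.sweep_scan import (
    ScanConfig,
    SweepRegion,
    annotate_genes,
    bh_fdr,
    category_enrichment,
    chi2_2x2,
    joint_outlier_scan,
    merge_regions,
    robustness_check,
    validate_sweeps,
    wilcoxon_rank_sum,
)
from yakpop.synthetic_data import generate_null_window_stats


def null_stats(n, seed=0, rho=0.0):
    return generate_null_window_stats(n, correlation=rho, seed=seed)


class TestJointOutlierScan:
    def test_window_at_genome_mean_not_flagged(self):
        df = null_stats(500, seed=1)
        df.loc[0, ["fst", "log_ratio"]] = [df["fst"].mean(), df["log_ratio"].mean()]
        scan, _ = joint_outlier_scan(df, p=0.005)
        assert not scan["flagged"].iloc[0]

    def test_flag_count_monotone_in_p(self):
        df = null_stats(5000, seed=2)
        counts = [joint_outlier_scan(df, p=p)[0]["flagged"].sum() for p in (0.001, 0.01, 0.05, 0.2)]
        assert counts == sorted(counts)

    def test_zero_sd_errors(self):
        df = null_stats(200, seed=3)
        df["fst"] = 0.1
        with pytest.raises(ValueError, match="zero variance"):
            joint_outlier_scan(df)

    def test_fixed_cutoffs_respected(self):
        df = null_stats(1000, seed=4)
        config = ScanConfig(p=0.005, fixed_log_ratio_cutoff=0.65, fixed_fst_cutoff=0.17)
        scan, cutoffs = joint_outlier_scan(df, config=config)
        assert cutoffs["log_ratio_cutoff"] == 0.65
        assert cutoffs["fst_cutoff"] == 0.17
        expected = (df["log_ratio"] > 0.65) & (df["fst"] > 0.17)
        assert (scan["flagged"] == expected).all()

    def test_nan_windows_never_flagged(self):
        df = null_stats(300, seed=5)
        df.loc[5, "log_ratio"] = np.nan
        scan, _ = joint_outlier_scan(df, p=0.5)
        assert not scan["flagged"].iloc[5]


def scan_frame(rows):
    """rows: (chrom, start, end, flagged, fst, log_ratio)"""
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "flagged", "fst", "log_ratio"]
    )


class TestMergeRegions:
    def test_single_window_region(self):
        df = scan_frame([("chr1", 0, 50_000, True, 0.2, 1.0)])
        (r,) = merge_regions(df)
        assert (r.start, r.end, r.n_windows) == (0, 50_000, 1)

    def test_bookended_windows_merge_to_union(self):
        df = scan_frame(
            [
                ("chr1", 0, 50_000, True, 0.2, 1.0),
                ("chr1", 10_000, 60_000, True, 0.3, 0.9),
                ("chr1", 20_000, 70_000, True, 0.25, 1.2),
            ]
        )
        (r,) = merge_regions(df)
        assert (r.start, r.end) == (0, 70_000)
        assert r.n_windows == 3
        assert r.peak_fst == 0.3 and r.peak_log_ratio == 1.2

    def test_distant_windows_stay_separate(self):
        df = scan_frame(
            [
                ("chr1", 0, 50_000, True, 0.2, 1.0),
                ("chr1", 150_000, 200_000, True, 0.2, 1.0),
                ("chr2", 0, 50_000, True, 0.2, 1.0),
            ]
        )
        regions = merge_regions(df)
        assert len(regions) == 3

    def test_every_flagged_window_in_exactly_one_region(self, rng):
        starts = np.sort(rng.choice(np.arange(0, 500) * 10_000, size=60, replace=False))
        df = scan_frame([("chr1", s, s + 50_000, True, 0.1, 0.5) for s in starts])
        regions = merge_regions(df)
        for s in starts:
            hits = [r for r in regions if r.start <= s and s + 50_000 <= r.end]
            assert len(hits) == 1


class TestAnnotateGenes:
    def test_containment_and_halfopen_boundary(self):
        regions = [SweepRegion("chr1", 100, 200, 1, 0.2, 1.0)]
        genes = pd.DataFrame(
            [
                ("chr1", 120, 150, "inside"),
                ("chr1", 200, 260, "abutting"),  # touches end, half-open: no overlap
                ("chr1", 50, 101, "one_bp"),
                ("chr2", 100, 200, "other_chrom"),
            ],
            columns=["chrom", "start", "end", "gene"],
        )
        (r,) = annotate_genes(regions, genes)
        assert sorted(r.genes) == ["inside", "one_bp"]

    def test_matches_all_pairs_brute_force(self, rng):
        regions = [
            SweepRegion("chr1", int(s), int(s) + 30_000, 1, 0.1, 0.5)
            for s in rng.choice(np.arange(100) * 50_000, size=10, replace=False)
        ]
        genes = pd.DataFrame(
            [
                ("chr1", int(s), int(s) + int(rng.integers(1_000, 40_000)), f"g{k}")
                for k, s in enumerate(rng.integers(0, 5_000_000, size=200))
            ],
            columns=["chrom", "start", "end", "gene"],
        )
        annotated = annotate_genes(regions, genes)
        for r in annotated:
            expected = {
                row.gene
                for row in genes.itertuples()
                if row.start < r.end and row.end > r.start
            }
            assert set(r.genes) == expected


class TestWilcoxon:
    def test_exact_no_overlap_example(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_values_give_p_one(self):
        _, p = wilcoxon_rank_sum([5, 5, 5], [5, 5, 5, 5])
        assert p == 1.0

    def test_exact_matches_scipy(self, rng):
        for _ in range(60):
            a = rng.random(int(rng.integers(3, 8)))
            b = rng.random(int(rng.integers(3, 8)))
            u, p = wilcoxon_rank_sum(a, b)
            ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_normal_approximation_matches_scipy_with_ties(self, rng):
        for _ in range(60):
            a = rng.integers(0, 6, int(rng.integers(12, 30))).astype(float)
            b = rng.integers(0, 6, int(rng.integers(12, 30))).astype(float)
            if np.all(np.concatenate([a, b]) == a[0]):
                continue
            u, p = wilcoxon_rank_sum(a, b)
            ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            assert u == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_one_sided_large_shift(self, rng):
        a = rng.normal(0, 1, 60)
        b = rng.normal(3, 1, 60)
        _, p = wilcoxon_rank_sum(a, b, alternative="less")
        assert p < 1e-6
        _, p_wrong_side = wilcoxon_rank_sum(a, b, alternative="greater")
        assert p_wrong_side > 0.999

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestValidateSweeps:
    @staticmethod
    def frame_with_tajd(n, rng, sweep_idx=(), shift=0.0):
        df = generate_null_window_stats(n, seed=int(rng.integers(1 << 30)))
        df["tajd_d"] = rng.normal(0, 1, n)
        df.loc[list(sweep_idx), "tajd_d"] += shift
        df["flagged"] = False
        df.loc[list(sweep_idx), "flagged"] = True
        return df

    def test_shifted_sweep_windows_detected(self, rng):
        df = self.frame_with_tajd(400, rng, sweep_idx=range(20), shift=-2.0)
        regions = merge_regions(df)
        report = validate_sweeps(df, regions)
        assert report["tajima_d"]["p_one_sided"] < 1e-4
        assert report["tajima_d"]["median_sweep"] < report["tajima_d"]["median_background"]

    def test_random_regions_not_significant(self, rng):
        df = self.frame_with_tajd(400, rng, sweep_idx=range(100, 120), shift=0.0)
        report = validate_sweeps(df, merge_regions(df))
        assert report["tajima_d"]["p_one_sided"] > 0.001

    def test_r2_contrast_reported(self, rng):
        df = self.frame_with_tajd(200, rng, sweep_idx=range(10), shift=-1.0)
        r2 = rng.random(200)
        r2[:10] += 1.0
        report = validate_sweeps(df, merge_regions(df), r2_by_window=r2)
        assert report["r2"]["p_one_sided"] < 1e-3

    def test_empty_regions_error(self, rng):
        df = self.frame_with_tajd(50, rng)
        with pytest.raises(ValueError, match="no sweep regions"):
            validate_sweeps(df, [])


class TestRobustness:
    @staticmethod
    def scans_with_flags(flags1, flags2):
        n = len(flags1)
        base = dict(chrom="chr1", fst=0.1, log_ratio=0.5)
        rows1, rows2 = [], []
        for i in range(n):
            w = dict(start=i * 100_000, end=i * 100_000 + 50_000, **base)
            rows1.append({**w, "flagged": flags1[i]})
            rows2.append({**w, "flagged": flags2[i]})
        return pd.DataFrame(rows1), pd.DataFrame(rows2)

    def test_toy_nine_of_ten_shared(self):
        # 10 genes, one inside each window; subscan 2 misses gene 9
        flags1 = [True] * 10
        flags2 = [True] * 9 + [False]
        s1, s2 = self.scans_with_flags(flags1, flags2)
        genes = pd.DataFrame(
            [("chr1", i * 100_000 + 10_000, i * 100_000 + 20_000, f"g{i}") for i in range(10)],
            columns=["chrom", "start", "end", "gene"],
        )
        report = robustness_check(s1, s2, [f"g{i}" for i in range(10)], genes)
        assert report["fraction_both"] == pytest.approx(0.9)

    def test_identical_and_disjoint_scans(self):
        s1, s2 = self.scans_with_flags([True, True, False], [True, True, False])
        genes = pd.DataFrame(
            [("chr1", i * 100_000, i * 100_000 + 10_000, f"g{i}") for i in range(3)],
            columns=["chrom", "start", "end", "gene"],
        )
        assert robustness_check(s1, s2, ["g0", "g1"], genes)["fraction_both"] == 1.0
        s1, s2 = self.scans_with_flags([True, False, False], [False, True, False])
        assert robustness_check(s1, s2, ["g0", "g1"], genes)["fraction_both"] == 0.0

    def test_window_mismatch_errors(self):
        s1, s2 = self.scans_with_flags([True], [True])
        s2["start"] += 1
        with pytest.raises(ValueError, match="identical windows"):
            robustness_check(s1, s2, ["g0"], pd.DataFrame(columns=["chrom", "start", "end", "gene"]))


class TestEnrichment:
    def test_chi2_hand_value_and_scipy(self):
        chi2, p = chi2_2x2(20, 80, 10, 890)
        ref = scipy.stats.chi2_contingency([[20, 80], [10, 890]], correction=False)
        assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_chi2_random_tables_match_scipy(self, rng):
        for _ in range(100):
            t = rng.integers(1, 200, size=4)
            chi2, p = chi2_2x2(*t)
            ref = scipy.stats.chi2_contingency(t.reshape(2, 2), correction=False)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_bh_stepup_by_hand(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_bh_matches_statsmodels(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_fdr(p), ref, atol=1e-12)

    def test_balanced_category_not_flagged(self):
        universe = [f"g{i}" for i in range(100)]
        selected = universe[:20]
        # category holds 50% of selected and 50% of background
        cat = universe[:10] + universe[20:60]
        df = category_enrichment(selected, universe, {"cat": cat})
        assert df["chi2"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert not df["significant"].iloc[0]

    def test_enriched_category_flagged(self):
        universe = [f"g{i}" for i in range(1000)]
        selected = universe[:30]
        cat = universe[:25] + universe[500:510]
        df = category_enrichment(selected, universe, {"cat": cat, "null": universe[600:700]})
        row = df.set_index("category").loc["cat"]
        assert row["significant"] and row["q"] < 0.05

    def test_input_validation(self):
        with pytest.raises(ValueError, match="empty"):
            category_enrichment([], [], {})
        with pytest.raises(ValueError, match="subset"):
            category_enrichment(["x"], ["y"], {})
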