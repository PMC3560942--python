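"""Tests for support classification, the novel-SNP hard-filter cascade and
the window scans."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pssmap as pm
from pssmap.poolscan import (AMBIGUOUS, NOT_COVERED, NOT_SUPPORTED, SUPPORTED,
                             RepeatMask, _cluster_flags, classify_support,
                             classify_support_table, novel_snp_filter,
                             snp_density_profile, support_summary, top_window,
                             window_allele_scan, window_fraction_ci)
from pssmap.sim import PileupSummary, VariantSite


def make_pileup(a_ref=0, a_alt=0, b_ref=0, b_alt=0, qual=50.0, mq=50.0,
                chrom="chr1", pos=100):
    return PileupSummary(chrom=chrom, pos=pos, ref_allele="G", alt_allele="A",
                         a_ref=a_ref, a_alt=a_alt, b_ref=b_ref, b_alt=b_alt,
                         site_quality=qual, mapping_quality=mq)


# ---------------------------------------------------------------------------
# Support classification
# ---------------------------------------------------------------------------


class TestClassifySupport:
    @pytest.mark.parametrize("pileup, call", [
        (make_pileup(a_alt=2, b_ref=3), SUPPORTED),       # consensus alleles differ
        (make_pileup(b_ref=5), NOT_COVERED),              # pool A has no reads
        (make_pileup(a_ref=1, a_alt=1, b_ref=2), AMBIGUOUS),  # non-homozygous pool
        (make_pileup(a_ref=1, b_ref=2), NOT_SUPPORTED),   # consensus alleles agree
        (make_pileup(a_alt=1, b_ref=1), SUPPORTED),       # singletons are consensus
        (make_pileup(a_alt=2, b_ref=1, b_alt=1), AMBIGUOUS),
    ])
    def test_rule_application(self, pileup, call):
        assert classify_support(pileup).call == call

    def test_every_pileup_gets_exactly_one_call(self, rng):
        counts = rng.integers(0, 4, size=(500, 4))
        pileups = [make_pileup(*row) for row in counts]
        calls = [classify_support(p).call for p in pileups]
        assert all(c in (SUPPORTED, NOT_SUPPORTED, NOT_COVERED, AMBIGUOUS) for c in calls)

    def test_table_classifier_agrees_with_scalar(self, rng):
        counts = rng.integers(0, 4, size=(500, 4))
        df = pd.DataFrame(counts, columns=["a_ref", "a_alt", "b_ref", "b_alt"])
        df["chrom"] = "chr1"
        df["pos"] = np.arange(1, 501)
        table_calls = classify_support_table(df)["call"].tolist()
        scalar_calls = [classify_support(make_pileup(*row)).call for row in counts]
        assert table_calls == scalar_calls


class TestSupportSummary:
    def test_all_supported_confirmation_rate_one(self):
        calls = [classify_support(make_pileup(a_alt=2, b_ref=2)) for _ in range(10)]
        s = support_summary(calls)
        assert s.confirmation_rate == 1.0 and s.covered_fraction == 1.0

    def test_planted_depth_zero_sites_set_covered_fraction_exactly(self):
        covered = [make_pileup(a_alt=1, b_ref=1) for _ in range(60)]
        uncovered = [make_pileup() for _ in range(40)]
        s = support_summary([classify_support(p) for p in covered + uncovered])
        assert s.covered_fraction == pytest.approx(0.6)
        assert s.n_covered == 60

    def test_simulated_truth_recovered_with_no_error(self):
        """True strain SNPs classify supported, planted non-SNPs not_supported."""
        rng = pm.substream(3, "support")
        n_true, n_false = 1000, 100
        truth = np.array([1.0] * n_true + [0.0] * n_false)  # pool A alt frequency
        a_ref, a_alt = pm.simulate_pool_counts(truth, 2.5, 0.0, rng)
        b_ref, b_alt = pm.simulate_pool_counts(np.zeros(n_true + n_false), 2.5, 0.0, rng)
        df = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, n_true + n_false + 1),
                           "a_ref": a_ref, "a_alt": a_alt, "b_ref": b_ref, "b_alt": b_alt})
        calls = classify_support_table(df)
        covered = (df.a_ref + df.a_alt > 0) & (df.b_ref + df.b_alt > 0)
        is_true = np.arange(n_true + n_false) < n_true
        assert (calls.loc[covered & is_true, "call"] == SUPPORTED).all()
        assert (calls.loc[covered & ~is_true, "call"] == NOT_SUPPORTED).all()
        s = support_summary(calls)
        assert s.confirmation_rate == pytest.approx(
            (covered & is_true).sum() / covered.sum())

    def test_confirmation_rate_approaches_one_with_depth(self):
        rng = pm.substream(4, "depth")
        for depth, floor in ((1.0, 0.0), (30.0, 0.999)):
            a_ref, a_alt = pm.simulate_pool_counts(np.ones(2000), depth, 0.0, rng)
            b_ref, b_alt = pm.simulate_pool_counts(np.zeros(2000), depth, 0.0, rng)
            df = pd.DataFrame({"chrom": "c", "pos": np.arange(1, 2001),
                               "a_ref": a_ref, "a_alt": a_alt,
                               "b_ref": b_ref, "b_alt": b_alt})
            s = support_summary(classify_support_table(df))
            assert s.confirmation_rate is None or s.confirmation_rate >= floor

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError):
            support_summary([])


# ---------------------------------------------------------------------------
# Novel-SNP filter cascade
# ---------------------------------------------------------------------------


def _candidate(pos, chrom="chr1", in_repeat=False, **pileup_kw):
    site = VariantSite(chrom=chrom, pos=pos, ref_allele="G", alt_allele="A",
                       in_repeat=in_repeat)
    kw = dict(a_ref=0, a_alt=3, b_ref=4, b_alt=0, qual=50.0, mq=50.0)
    kw.update(pileup_kw)
    return site, make_pileup(chrom=chrom, pos=pos, **kw)


class TestNovelSnpFilter:
    def test_clean_candidate_passes(self):
        [v] = novel_snp_filter([_candidate(100)])
        assert v.passed and v.failed_filters == ()

    @pytest.mark.parametrize("kw, code, should_fail", [
        (dict(a_alt=1, b_alt=0, b_ref=6), "min_alt_reads", True),
        (dict(a_alt=1, b_alt=1, b_ref=5), "min_alt_reads", False),
        (dict(qual=30.0), "site_quality", True),
        (dict(qual=30.01), "site_quality", False),
        (dict(mq=40.0), "mapping_quality", True),
        (dict(mq=40.01), "mapping_quality", False),
        (dict(a_ref=0, a_alt=2, b_ref=2, b_alt=0), "depth_range", True),   # depth 4
        (dict(a_ref=0, a_alt=2, b_ref=3, b_alt=0), "depth_range", False),  # depth 5
        (dict(a_ref=0, a_alt=39, b_ref=40, b_alt=0), "depth_range", False),  # 79
        (dict(a_ref=0, a_alt=40, b_ref=40, b_alt=0), "depth_range", True),   # 80
    ])
    def test_threshold_boundaries_are_strict(self, kw, code, should_fail):
        [v] = novel_snp_filter([_candidate(100, **kw)])
        assert (code in v.failed_filters) == should_fail

    def test_repeat_mask_membership_uses_bed_half_open_convention(self):
        mask = RepeatMask({"chr1": [(99, 150)]})  # 0-based half-open [99, 150)
        inside = novel_snp_filter([_candidate(100)], mask)[0]   # 1-based 100 -> 0-based 99
        assert "repeat_mask" in inside.failed_filters
        edge = novel_snp_filter([_candidate(151)], mask)[0]     # 0-based 150, excluded
        assert "repeat_mask" not in edge.failed_filters
        flagged = novel_snp_filter([_candidate(500, in_repeat=True)])[0]
        assert "repeat_mask" in flagged.failed_filters

    def test_cluster_of_four_in_ten_bp_removes_all_four(self):
        cands = [_candidate(p) for p in (100, 102, 105, 109)]
        verdicts = novel_snp_filter(cands)
        assert all("snp_cluster" in v.failed_filters for v in verdicts)

    def test_three_in_ten_bp_is_tolerated(self):
        cands = [_candidate(p) for p in (100, 104, 109)]
        verdicts = novel_snp_filter(cands)
        assert all("snp_cluster" not in v.failed_filters for v in verdicts)

    def test_cluster_window_slides_over_positions(self):
        # 4 sites span exactly 10 bp (101..110): within one 10-bp window
        verdicts = novel_snp_filter([_candidate(p) for p in (101, 104, 107, 110)])
        assert all("snp_cluster" in v.failed_filters for v in verdicts)
        # span of 11 bp (101..111): never 4 inside any 10-bp window
        verdicts = novel_snp_filter([_candidate(p) for p in (101, 104, 107, 111)])
        assert all("snp_cluster" not in v.failed_filters for v in verdicts)

    def test_all_filters_evaluated_no_short_circuit(self):
        [v] = novel_snp_filter([_candidate(100, a_ref=0, a_alt=1, b_ref=1, b_alt=0,
                                           qual=10.0, mq=10.0)])
        assert set(v.failed_filters) == {"min_alt_reads", "site_quality",
                                         "mapping_quality", "depth_range"}
        # reason codes keep cascade order
        assert list(v.failed_filters) == [c for c in pm.FILTER_CODES
                                          if c in v.failed_filters]

    def test_unsorted_candidates_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            novel_snp_filter([_candidate(200), _candidate(100)])

    def test_filter_is_idempotent_and_cluster_is_position_pure(self, rng):
        pos = np.unique(rng.integers(1, 5000, size=300))
        cands = [_candidate(int(p)) for p in pos]
        v1 = novel_snp_filter(cands)
        v2 = novel_snp_filter(cands)
        assert v1 == v2
        np.testing.assert_array_equal(
            _cluster_flags(pos), [("snp_cluster" in v.failed_filters) for v in v1])


# ---------------------------------------------------------------------------
# Window scans
# ---------------------------------------------------------------------------


def brute_force_windows(counts: pd.DataFrame, lengths, window_bp, step_bp):
    rows = []
    for chrom, clen in lengths.items():
        sub = counts[counts["chrom"] == chrom]
        for start in range(0, clen, step_bp):
            end = min(start + window_bp, clen)
            inside = sub[(sub["pos"] - 1 >= start) & (sub["pos"] - 1 < end)]
            rows.append((chrom, start, end, len(inside),
                         int(inside["a_reads"].sum()), int(inside["b_reads"].sum())))
    return rows


class TestWindowAlleleScan:
    def test_pure_strain_a_window_has_fraction_one(self):
        counts = pd.DataFrame({"chrom": ["c"] * 3, "pos": [10, 20, 30],
                               "a_reads": [4, 2, 1], "b_reads": [0, 0, 0]})
        w = window_allele_scan(counts, {"c": 100}, window_bp=100, step_bp=100)
        assert w["strainA_fraction"].iloc[0] == 1.0

    def test_fraction_is_read_weighted(self):
        counts = pd.DataFrame({"chrom": ["c"] * 2, "pos": [10, 20],
                               "a_reads": [30, 0], "b_reads": [0, 10]})
        w = window_allele_scan(counts, {"c": 100}, window_bp=100, step_bp=100)
        assert w["strainA_fraction"].iloc[0] == pytest.approx(0.75)

    def test_empty_window_fraction_is_missing_not_zero(self):
        counts = pd.DataFrame({"chrom": ["c"], "pos": [10],
                               "a_reads": [1], "b_reads": [1]})
        w = window_allele_scan(counts, {"c": 300}, window_bp=100, step_bp=100)
        assert np.isnan(w["strainA_fraction"].iloc[2])
        assert w["low_density"].iloc[2]

    @pytest.mark.parametrize("seed", range(5))
    def test_window_sums_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lengths = {"c1": 5_000, "c2": 3_000}
        n = 1_200
        chrom = np.where(rng.uniform(size=n) < 0.6, "c1", "c2")
        pos = rng.integers(1, 5_000, size=n)
        pos[chrom == "c2"] = rng.integers(1, 3_000, size=(chrom == "c2").sum())
        counts = pd.DataFrame({"chrom": chrom, "pos": pos,
                               "a_reads": rng.poisson(2, n), "b_reads": rng.poisson(2, n)})
        w = window_allele_scan(counts, lengths, window_bp=1_000, step_bp=400)
        oracle = brute_force_windows(counts, lengths, 1_000, 400)
        got = list(zip(w["chrom"], w["start"], w["end"], w["n_snps"],
                       w["strainA_reads"], w["strainB_reads"]))
        assert got == oracle

    def test_non_overlapping_tiling_conserves_reads_and_sites(self, rng):
        lengths = {"c1": 10_000}
        counts = pd.DataFrame({"chrom": "c1", "pos": rng.integers(1, 10_001, 500),
                               "a_reads": rng.poisson(2, 500), "b_reads": rng.poisson(2, 500)})
        w = window_allele_scan(counts, lengths, window_bp=1_000, step_bp=1_000)
        assert w["n_snps"].sum() == 500
        assert w["strainA_reads"].sum() == counts["a_reads"].sum()
        assert w["strainB_reads"].sum() == counts["b_reads"].sum()

    def test_last_window_truncates_at_chromosome_end(self):
        counts = pd.DataFrame({"chrom": ["c"], "pos": [1], "a_reads": [1], "b_reads": [0]})
        w = window_allele_scan(counts, {"c": 2_500}, window_bp=1_000, step_bp=1_000)
        assert w["end"].iloc[-1] == 2_500

    def test_confidence_intervals_bracket_fraction(self):
        counts = pd.DataFrame({"chrom": ["c"], "pos": [10],
                               "a_reads": [30], "b_reads": [10]})
        w = window_fraction_ci(window_allele_scan(counts, {"c": 100},
                                                  window_bp=100, step_bp=100))
        row = w.iloc[0]
        assert row["ci_low"] < row["strainA_fraction"] < row["ci_high"]

    def test_planted_enrichment_region_tops_the_scan(self):
        """A region with strain-A frequency 0.9 against a 0.5 background is the
        genome-wide maximum-fraction window."""
        rng = pm.substream(5, "plant")
        lengths = {"c1": 100_000_000, "c2": 100_000_000}
        n = 5_000
        chrom = np.where(rng.uniform(size=n) < 0.5, "c1", "c2")
        pos = rng.integers(1, 100_000_000, size=n)
        planted = (chrom == "c2") & (pos - 1 >= 40_000_000) & (pos - 1 < 50_000_000)
        freq = np.where(planted, 0.9, 0.5)
        ref, alt = pm.simulate_pool_counts(freq, 3.0, 0.0, rng)
        counts = pd.DataFrame({"chrom": chrom, "pos": pos, "a_reads": alt, "b_reads": ref})
        best = top_window(window_allele_scan(counts, lengths))
        assert best["chrom"] == "c2"
        assert best["start"] < 50_000_000 and best["end"] > 40_000_000


class TestSnpDensityProfile:
    def test_one_site_per_window(self):
        sites = [VariantSite("c", p, "G", "A") for p in (100, 300, 500)]
        prof = snp_density_profile(sites, {"c": 600}, window_bp=200)
        assert prof["n_snps"].tolist() == [1, 1, 1]
        assert prof["has_snp"].all()

    def test_empty_chromosome_all_zero(self):
        prof = snp_density_profile([], {"c": 1_000}, window_bp=200)
        assert (prof["n_snps"] == 0).all() and not prof["has_snp"].any()

    def test_counts_conserve_total_sites(self, rng):
        pos = rng.integers(1, 50_001, size=800)
        sites = pd.DataFrame({"chrom": "c", "pos": pos})
        prof = snp_density_profile(sites, {"c": 50_000}, window_bp=1_000)
        assert prof["n_snps"].sum() == 800
        # brute-force recount of a few windows
        for _, row in prof.head(10).iterrows():
            n = ((pos - 1 >= row["start"]) & (pos - 1 < row["end"])).sum()
            assert n == row["n_snps"]

    def test_low_density_fraction_over_10mb_tiles(self):
        # 2 sites on a 20-Mb chromosome: both 10-Mb tiles have <= 4 SNPs
        sites = [VariantSite("c", 5, "G", "A"), VariantSite("c", 15_000_000, "G", "A")]
        prof = snp_density_profile(sites, {"c": 20_000_000})
        assert prof.attrs["low_density_fraction_10mb"] == 1.0
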