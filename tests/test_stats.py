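import numpy as np
import pandas as pd
import pytest
import scipy.stats

from igaseq.core import FractionPair, compute_iga_index_table
from igaseq.io import AbundanceTable, MetadataTable, SampleMetadata, ValidationError
from igaseq.stats import (
    benjamini_hochberg,
    compare_groups,
    mann_whitney_u,
    summarize_enrichment,
    wilcoxon_signed_rank,
)

from .conftest import make_metadata
from .oracles import mwu_exact_bruteforce, wilcoxon_exact_bruteforce


class TestMannWhitney:
    def test_fully_separated_groups(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.u_statistic == 0
        assert res.p_two_sided == pytest.approx(0.1)  # 2 of 20 labelings

    def test_single_observations(self):
        res = mann_whitney_u([1.0], [2.0], mode="exact")
        assert res.p_two_sided == 1.0

    def test_symmetry_in_arguments(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 7))
            y = rng.normal(size=rng.integers(2, 7))
            a = mann_whitney_u(x, y, mode="exact")
            b = mann_whitney_u(y, x, mode="exact")
            assert a.p_two_sided == pytest.approx(b.p_two_sided)
            assert a.u_statistic == pytest.approx(b.u_statistic)

    def test_all_identical_values_convention(self):
        res = mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_two_sided == 1.0

    def test_empty_group_is_error(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])

    def test_matches_bruteforce_with_and_without_ties(self, rng):
        for trial in range(60):
            n1 = int(rng.integers(1, 5))
            n2 = int(rng.integers(1, 9 - n1))
            if trial % 2:  # force ties via a coarse grid
                x = rng.integers(0, 4, size=n1).astype(float)
                y = rng.integers(0, 4, size=n2).astype(float)
            else:
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
            if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
                continue
            res = mann_whitney_u(x, y, mode="exact")
            assert res.p_two_sided == pytest.approx(float(mwu_exact_bruteforce(x, y)), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        # scipy's exact distribution is the independent reference when the
        # data are tie-free
        for _ in range(25):
            x = rng.normal(size=int(rng.integers(3, 8)))
            y = rng.normal(size=int(rng.integers(3, 8)))
            ours = mann_whitney_u(x, y, mode="exact")
            ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_auto_mode_switches_at_25(self, rng):
        small = mann_whitney_u(rng.normal(size=12), rng.normal(size=13))
        big = mann_whitney_u(rng.normal(size=13), rng.normal(size=13))
        assert small.mode_used == "exact"
        assert big.mode_used == "normal-approx"

    def test_exact_request_above_cap_falls_back(self, rng):
        res = mann_whitney_u(rng.normal(size=20), rng.normal(size=20), mode="exact")
        assert res.mode_used == "normal-approx"

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=5)
        a = mann_whitney_u(x, y, mode="exact")
        b = mann_whitney_u(np.exp(x), np.exp(y), mode="exact")
        assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_type_one_error_under_null(self, rng):
        # exact test at n=4 vs 4: rejection rate at alpha=0.05 stays at or
        # below 0.05 up to Monte-Carlo error (>= 2000 replicates)
        reps = 2000
        rejections = 0
        for _ in range(reps):
            x = rng.normal(size=4)
            y = rng.normal(size=4)
            if mann_whitney_u(x, y, mode="exact").p_two_sided < 0.05:
                rejections += 1
        mc_se = np.sqrt(0.05 * 0.95 / reps)
        assert rejections / reps <= 0.05 + 3 * mc_se


class TestWilcoxon:
    def test_all_positive_distinct_differences(self):
        a = [5.0, 6.0, 7.0, 8.0, 9.0]
        b = [1.0, 2.0, 3.0, 4.0, 4.5]
        res = wilcoxon_signed_rank(a, b, mode="exact")
        assert res.w_statistic == 0
        assert res.p_two_sided == pytest.approx(2 / 32)

    def test_symmetry_on_swap(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        assert wilcoxon_signed_rank(a, b, mode="exact").p_two_sided == pytest.approx(
            wilcoxon_signed_rank(b, a, mode="exact").p_two_sided
        )

    def test_all_zero_differences_convention(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.p_two_sided == 1.0
        assert np.isnan(res.w_statistic)
        assert res.n_zero_dropped == 2

    def test_zero_differences_dropped_and_counted(self):
        res = wilcoxon_signed_rank([1.0, 5.0, 7.0], [1.0, 2.0, 3.0], mode="exact")
        assert res.n_zero_dropped == 1

    def test_matches_bruteforce_with_and_without_ties(self, rng):
        for trial in range(60):
            n = int(rng.integers(1, 9))
            if trial % 2:
                d = rng.integers(-3, 4, size=n).astype(float)
            else:
                d = rng.normal(size=n)
            a = rng.normal(size=n)
            res = wilcoxon_signed_rank(a + d, a, mode="exact")
            assert res.p_two_sided == pytest.approx(
                float(wilcoxon_exact_bruteforce(a + d, a)), abs=1e-12
            )

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 10))
            d = rng.normal(size=n)
            a = rng.normal(size=n)
            ours = wilcoxon_signed_rank(a + d, a, mode="exact")
            ref = scipy.stats.wilcoxon(d, method="exact")
            assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_auto_mode_exact_at_study_scale(self, rng):
        res = wilcoxon_signed_rank(rng.normal(size=20), rng.normal(size=20))
        assert res.mode_used == "exact"
        res = wilcoxon_signed_rank(rng.normal(size=21), rng.normal(size=21))
        assert res.mode_used == "normal-approx"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank([1.0], [1.0, 2.0])


class TestCompareGroups:
    def test_separated_groups_significant(self):
        metadata = make_metadata(20)
        values = pd.Series(
            {s.sample_id: (1.0 if s.group == "adult" else 2.0) + 0.001 * i
             for i, s in enumerate(metadata)}
        )
        res = compare_groups(values, metadata, statistic_name="abundance", taxon_id="T")
        assert res.group_medians["elderly"] > res.group_medians["adult"]
        assert res.significant and res.highly_significant

    def test_identical_distribution_p_one(self):
        metadata = make_metadata(3)
        values = pd.Series({s.sample_id: 1.0 for s in metadata})
        res = compare_groups(values, metadata)
        assert res.p_two_sided == 1.0
        assert not res.significant

    def test_one_group_all_missing_untestable(self):
        metadata = make_metadata(3)
        values = pd.Series(
            {s.sample_id: (np.nan if s.group == "adult" else 1.0 + hash(s.sample_id) % 5)
             for s in metadata}
        )
        res = compare_groups(values, metadata)
        assert res.untestable
        assert np.isnan(res.p_two_sided)

    def test_three_groups_rejected(self):
        metadata = MetadataTable(
            [SampleMetadata(f"S{i}", g, 10.0) for i, g in enumerate("abc")]
        )
        with pytest.raises(ValidationError, match="exactly 2"):
            compare_groups(pd.Series({f"S{i}": float(i) for i in range(3)}), metadata)


class TestEnrichment:
    def _pair_and_index(self, pos_df, neg_df):
        pos = AbundanceTable(pos_df, "iga_pos")
        neg = AbundanceTable(neg_df, "iga_neg")
        pair = FractionPair(pos, neg)
        return pair, compute_iga_index_table(pair)

    def test_doubled_abundance_is_pos_enriched(self, rng):
        metadata = make_metadata(20)
        idx = pd.Index(metadata.sample_ids, name="sample_id")
        base = rng.uniform(0.05, 0.2, size=(40, 1))
        pos_df = pd.DataFrame(2 * base, index=idx, columns=["T"])
        neg_df = pd.DataFrame(base, index=idx, columns=["T"])
        pair, index_table = self._pair_and_index(pos_df, neg_df)
        results = summarize_enrichment(pair, index_table, metadata, mode="exact")
        assert len(results) == 2  # one per group
        for r in results:
            assert r.direction == "iga_pos_enriched"
            assert r.p_two_sided == pytest.approx(2 / 2**20)
            assert not r.low_power

    def test_equal_fractions_not_significant(self):
        metadata = make_metadata(6)
        idx = pd.Index(metadata.sample_ids, name="sample_id")
        df = pd.DataFrame(np.full((12, 1), 0.2), index=idx, columns=["T"])
        pair, index_table = self._pair_and_index(df, df.copy())
        for r in summarize_enrichment(pair, index_table, metadata):
            assert r.direction == "not_significant"
            assert r.p_two_sided == 1.0
            assert r.mean_iga_index == pytest.approx(0.0)

    def test_mean_index_is_arithmetic_mean(self):
        metadata = MetadataTable(
            [SampleMetadata("S1", "g1", 10.0), SampleMetadata("S2", "g1", 10.0),
             SampleMetadata("S3", "g2", 10.0), SampleMetadata("S4", "g2", 10.0)]
        )
        idx = pd.Index(metadata.sample_ids, name="sample_id")
        # choose abundances whose indices in g1 are 0.2 and 0.4
        pos = pd.DataFrame([[0.01], [0.01], [0.01], [0.01]], index=idx, columns=["T"])
        neg = pd.DataFrame([[0.1], [0.1], [0.1], [0.1]], index=idx, columns=["T"])
        pair, _ = self._pair_and_index(pos, neg)
        values = pd.DataFrame([[0.2], [0.4], [0.1], [0.3]], index=idx, columns=["T"])
        from igaseq.core import IgAIndexTable

        table = IgAIndexTable(values, "pseudocount", 1e-5)
        res = {r.group: r for r in summarize_enrichment(pair, table, metadata)}
        assert res["g1"].mean_iga_index == pytest.approx(0.3)
        assert res["g2"].mean_iga_index == pytest.approx(0.2)
        assert all(r.low_power for r in res.values())  # fewer than 5 pairs


def test_benjamini_hochberg_matches_statsmodels_and_keeps_nan():
    p = np.array([0.01, 0.02, np.nan, 0.5])
    adj = benjamini_hochberg(p)
    assert np.isnan(adj[2])
    from statsmodels.stats.multitest import multipletests

    expected = multipletests(np.array([0.01, 0.02, 0.5]), method="fdr_bh")[1]
    np.testing.assert_allclose(adj[[0, 1, 3]], expected)
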