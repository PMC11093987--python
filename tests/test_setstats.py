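"""Rank scores, permutation tests, and the classical test wrappers."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nlrkit.setstats import (
    bh_adjust,
    fisher_exact_2x2,
    kruskal_wallis,
    matched_perm_diff_test,
    perm_diff_test,
    perm_pvalue_set_score,
    rank_set_score,
    significance_tier,
    tail_count_test,
    wilcoxon_rank_sum,
)


def _values(n, rng=None, index_prefix="g"):
    rng = rng or np.random.default_rng(0)
    return pd.Series(rng.normal(size=n), index=[f"{index_prefix}{i}" for i in range(n)])


class TestRankScore:
    def test_top_set_scores_one(self):
        v = pd.Series([1.0, 2.0, 3.0, 9.0, 10.0], index=list("abcde"))
        assert rank_set_score(v, ["d", "e"]).normalized_score == pytest.approx(1.0)

    def test_bottom_set_scores_zero(self):
        v = pd.Series([1.0, 2.0, 3.0, 9.0, 10.0], index=list("abcde"))
        assert rank_set_score(v, ["a", "b"]).normalized_score == pytest.approx(0.0)

    def test_formula_n10_m2(self):
        # members at ranks 3 and 7: mean 5, attainable extremes 1.5 and 9.5
        v = pd.Series(np.arange(1.0, 11.0), index=[f"g{i}" for i in range(10)])
        score = rank_set_score(v, ["g2", "g6"])
        assert score.normalized_score == pytest.approx((5 - 1.5) / (9.5 - 1.5))

    def test_monotone_transform_invariance(self, rng):
        v = _values(50, rng)
        s1 = rank_set_score(v, ["g3", "g7", "g11"]).normalized_score
        s2 = rank_set_score(np.exp(v), ["g3", "g7", "g11"]).normalized_score
        assert s1 == pytest.approx(s2)

    def test_missing_gene_listed(self):
        v = _values(10)
        with pytest.raises(KeyError, match="zz"):
            rank_set_score(v, ["g1", "zz"])


class TestSetScorePermutation:
    def test_top_set_minimal_p(self):
        v = pd.Series(np.arange(100.0), index=[f"g{i}" for i in range(100)])
        res = perm_pvalue_set_score(v, ["g97", "g98", "g99"], R=999, seed=1)
        assert res.p_addone == pytest.approx(1 / 1000)

    def test_seed_reproducibility(self, rng):
        v = _values(200, rng)
        a = perm_pvalue_set_score(v, [f"g{i}" for i in range(10)], R=500, seed=9)
        b = perm_pvalue_set_score(v, [f"g{i}" for i in range(10)], R=500, seed=9)
        assert a == b

    def test_null_sets_give_uniform_p(self, rng):
        # random sets from the background: empirical rejection near alpha
        hits = 0
        n_rerun = 200
        for k in range(n_rerun):
            v = _values(150, rng)
            members = list(rng.choice(v.index, size=12, replace=False))
            res = perm_pvalue_set_score(v, members, R=400, seed=k)
            hits += res.p_addone <= 0.05
        assert 0.03 <= hits / n_rerun <= 0.07


class TestPermDiff:
    def test_constant_feature_never_rejects(self):
        v = pd.Series(5.0, index=[f"g{i}" for i in range(50)])
        res = perm_diff_test(v, [f"g{i}" for i in range(10)],
                             [f"g{i}" for i in range(10, 50)], R=500, seed=0)
        assert res.observed == 0.0 and res.p_raw == pytest.approx(1.0)

    def test_shifted_set_has_tiny_p(self, rng):
        bg = _values(300, rng)
        shifted = pd.Series(rng.normal(3.0, 1.0, size=30),
                            index=[f"s{i}" for i in range(30)])
        v = pd.concat([bg, shifted])
        res = perm_diff_test(v, list(shifted.index), list(bg.index),
                             R=10_000, seed=4, direction="greater")
        assert res.p_addone <= 0.001

    def test_small_set_rejected(self):
        v = _values(20)
        with pytest.raises(ValueError, match=">= 3"):
            perm_diff_test(v, ["g0", "g1"], [f"g{i}" for i in range(2, 20)])

    def test_overlapping_groups_rejected(self):
        v = _values(20)
        with pytest.raises(ValueError, match="overlap"):
            perm_diff_test(v, ["g0", "g1", "g2"], [f"g{i}" for i in range(20)])

    def test_median_statistic_supported(self, rng):
        v = _values(60, rng)
        res = perm_diff_test(v, [f"g{i}" for i in range(8)],
                             [f"g{i}" for i in range(8, 60)],
                             stat="median", R=300, seed=2)
        assert 0.0 <= res.p_addone <= 1.0

    def test_addone_floor(self, rng):
        v = _values(60, rng)
        res = perm_diff_test(v, [f"g{i}" for i in range(8)],
                             [f"g{i}" for i in range(8, 60)], R=200, seed=0)
        assert res.p_addone >= 1 / 201


class TestMatchedPermDiff:
    def test_one_bin_reduces_to_plain_test_exactly(self, rng):
        v = _values(120, rng)
        cov = _values(120, np.random.default_rng(5))
        set_ids = [f"g{i}" for i in range(15)]
        bg_ids = [f"g{i}" for i in range(15, 120)]
        a = perm_diff_test(v, set_ids, bg_ids, R=400, seed=11)
        b = matched_perm_diff_test(v, set_ids, bg_ids, cov, n_bins=1, R=400, seed=11)
        assert a.p_raw == b.p_raw and a.null_mean == b.null_mean

    def test_single_bin_stratification_contract(self):
        # set entirely in the high-covariate bin: null draws must come from
        # that bin, whose members all carry value 100
        genes = [f"g{i}" for i in range(40)]
        # background: 18 low-covariate (value 0) + 18 high-covariate (value 100)
        cov = pd.Series([0.0] * 18 + [1.0] * 22, index=genes)
        val = pd.Series([0.0] * 18 + [100.0] * 22, index=genes)
        set_ids = genes[36:]
        bg_ids = genes[:36]
        res = matched_perm_diff_test(val, set_ids, bg_ids, cov, n_bins=2,
                                     R=200, seed=0)
        # every null pseudo-set is drawn from the value-100 bin, so the null
        # difference always equals the observed difference
        assert res.p_raw == 1.0

    def test_empty_bin_named_in_error(self):
        # background covariates only at 0 and 1: the interpolated median edge
        # (0.5) opens a middle bin with no background candidates, and the set
        # genes (covariate 0.6) land exactly there
        genes = [f"g{i}" for i in range(30)]
        cov = pd.Series(np.r_[np.zeros(13), np.ones(13), np.full(4, 0.6)],
                        index=genes)
        val = pd.Series(np.arange(30.0), index=genes)
        with pytest.raises(ValueError, match="bin"):
            matched_perm_diff_test(val, genes[26:], genes[:26], cov, n_bins=4,
                                   R=100, seed=0)

    def test_confounded_feature_calibrated_only_when_matched(self, rng):
        # feature is a deterministic function of the covariate; the set has
        # systematically higher covariates
        naive_p, matched_p = [], []
        for k in range(20):
            bg_cov = rng.uniform(0, 1, 200)
            set_cov = rng.uniform(0.5, 1, 30)
            genes = [f"b{i}" for i in range(200)] + [f"s{i}" for i in range(30)]
            cov = pd.Series(np.r_[bg_cov, set_cov], index=genes)
            feat = 10 * cov
            set_ids = [f"s{i}" for i in range(30)]
            bg_ids = [f"b{i}" for i in range(200)]
            naive_p.append(perm_diff_test(feat, set_ids, bg_ids, R=500, seed=k,
                                          direction="greater").p_addone)
            matched_p.append(matched_perm_diff_test(feat, set_ids, bg_ids, cov,
                                                    n_bins=10, R=500, seed=k,
                                                    direction="greater").p_addone)
        assert max(naive_p) < 0.01  # the naive test always rejects
        assert np.mean(np.array(matched_p) <= 0.05) <= 0.15  # matched does not


class TestTailCount:
    def test_observed_matches_brute_force(self, rng):
        bg = np.arange(1, 1001, dtype=float)
        genes = [f"g{i}" for i in range(20)]
        vals = pd.Series(rng.uniform(0, 1100, size=20), index=genes)
        res = tail_count_test(vals, genes, bg, tail="top5", R=200, seed=0)
        thr = np.quantile(bg, 0.95)
        assert res.observed == sum(v > thr for v in vals)

    def test_all_in_tail_minimal_p(self):
        bg = np.arange(1, 1001, dtype=float)
        genes = [f"g{i}" for i in range(10)]
        vals = pd.Series(2000.0, index=genes)
        res = tail_count_test(vals, genes, bg, tail="top5", R=999, seed=1)
        assert res.p_addone == pytest.approx(1 / 1000)

    def test_null_mean_matches_expectation(self):
        bg = np.arange(1, 2001, dtype=float)
        genes = [f"g{i}" for i in range(20)]
        vals = pd.Series(np.linspace(100, 1900, 20), index=genes)
        res = tail_count_test(vals, genes, bg, tail="top5", R=4000, seed=3)
        assert res.null_mean == pytest.approx(20 * 0.05, abs=0.15)

    def test_bottom_tail(self):
        bg = np.arange(1, 1001, dtype=float)
        vals = pd.Series([0.0, 0.0, 0.0, 500.0], index=list("abcd"))
        res = tail_count_test(vals, list("abcd"), bg, tail="bottom5", R=200, seed=0)
        assert res.observed == 3.0


class TestWilcoxon:
    def test_exact_two_sided_small_sample(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_multisets(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_exact_against_enumeration_oracle(self):
        # brute force: all C(9,4) assignments of ranks to group x
        x = [1.3, 2.1, 5.7, 9.9]
        y = [0.4, 3.3, 4.8, 7.2, 8.8]
        pooled = sorted(x + y)
        ranks = {v: i + 1 for i, v in enumerate(pooled)}
        obs = sum(ranks[v] for v in x)
        n = len(pooled)
        count = total = 0
        for combo in itertools.combinations(range(1, n + 1), len(x)):
            total += 1
            s = sum(combo)
            mu = len(x) * (n + 1) / 2
            if abs(s - mu) >= abs(obs - mu) - 1e-12:
                count += 1
        assert wilcoxon_rank_sum(x, y) == pytest.approx(count / total, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            wilcoxon_rank_sum([], [1.0])

    def test_large_sample_uses_tie_corrected_approximation(self, rng):
        x = rng.normal(0, 1, 40).round(1)  # rounding induces ties
        y = rng.normal(0.8, 1, 40).round(1)
        p = wilcoxon_rank_sum(x, y, alternative="less")
        assert 0 < p < 0.05


class TestKruskal:
    def test_identical_groups(self):
        assert kruskal_wallis([[1, 2, 3], [1, 2, 3]]) == pytest.approx(1.0)

    def test_hand_computed_three_groups(self):
        # ranks: g1 {1,2,3}, g2 {4,5,6}, g3 {7,8,9}; no ties
        groups = [[1, 2, 3], [11, 12, 13], [21, 22, 23]]
        H = 12 / (9 * 10) * (3 * (2**2 + 5**2 + 8**2)) - 3 * 10
        from scipy.stats import chi2

        assert kruskal_wallis(groups) == pytest.approx(chi2.sf(H, df=2), abs=1e-9)

    def test_direction_consistent_with_wilcoxon(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(2, 1, 30)
        assert kruskal_wallis([a, b]) < 0.01
        assert wilcoxon_rank_sum(a, b) < 0.01

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            kruskal_wallis([[1, 2], [5]])


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact_2x2([[2, 2], [2, 2]]) == pytest.approx(1.0)

    def test_diagonal_table_hand_enumeration(self):
        # P(X=5) + P(X=0) at margins (5,5)/(5,5): 2/C(10,5) = 2/252
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252, abs=1e-6)

    def test_transpose_invariance(self, rng):
        t = rng.integers(0, 20, size=(2, 2))
        assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(t.T))

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            fisher_exact_2x2([[1, -1], [2, 3]])


class TestBH:
    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_dominates_raw(self, rng):
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_series_index_preserved(self):
        s = pd.Series([0.01, 0.5], index=["a", "b"])
        q = bh_adjust(s)
        assert list(q.index) == ["a", "b"]


def test_significance_tiers():
    assert [significance_tier(p) for p in (0.5, 0.04, 0.004, 0.0004)] == [
        "ns", "*", "**", "***",
    ]
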