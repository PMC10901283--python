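import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from disulfiscore import (
    bh_adjust,
    differential_expression,
    fold_change,
    hallmark_correlation_profile,
    kruskal_test,
    rank_sum_test,
    spearman_assoc,
)
from oracles import bh_stepup_bruteforce, kruskal_h, ranksum_exact_p


class TestFoldChange:
    def test_ratio_of_means(self):
        assert fold_change([4, 4], [2, 2]) == (2.0, False)

    def test_identical_groups(self):
        assert fold_change([1, 2, 3], [1, 2, 3]) == (1.0, False)

    def test_zero_normal_mean_flagged(self):
        with pytest.warns(UserWarning, match="zero"):
            fc, flagged = fold_change([3, 3], [0, 0])
        assert flagged and np.isinf(fc)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            fold_change([], [1])


class TestRankSumTest:
    def test_separated_pairs_exact_third(self):
        res = rank_sum_test([1, 2], [3, 4])
        assert res["exact"]
        assert res["p"] == pytest.approx(1 / 3)

    def test_identical_multisets_p_one(self):
        res = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert res["p"] == pytest.approx(1.0)

    def test_group_swap_symmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=5)
        assert rank_sum_test(a, b)["p"] == pytest.approx(
            rank_sum_test(b, a)["p"])

    def test_exact_branch_matches_enumeration_all_small_sizes(self, rng):
        for n_a, n_b in itertools.product(range(2, 9), repeat=2):
            if n_a + n_b > 10:
                continue
            vals = rng.permutation(np.arange(1.0, n_a + n_b + 1))
            a, b = vals[:n_a], vals[n_a:]
            res = rank_sum_test(a, b, exact_threshold=10)
            assert res["exact"]
            assert res["p"] == pytest.approx(ranksum_exact_p(a, b), abs=1e-12)

    def test_ties_fall_back_to_asymptotic(self):
        res = rank_sum_test([1, 1, 2], [2, 3, 3])
        assert not res["exact"]

    def test_small_group_is_error(self):
        with pytest.raises(ValueError):
            rank_sum_test([1], [2, 3])


class TestKruskalTest:
    def test_three_identical_groups_h_zero(self):
        res = kruskal_test([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res["H"] == pytest.approx(0.0)

    def test_ordered_disjoint_groups_match_rank_formula(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        res = kruskal_test(groups)
        assert res["H"] == pytest.approx(kruskal_h(groups), abs=1e-12)

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError, match="rank_sum"):
            kruskal_test([[1, 2], [3, 4]])

    def test_all_values_identical_gives_h_zero(self):
        res = kruskal_test([[5, 5], [5, 5], [5, 5]])
        assert res["H"] == 0.0 and res["p"] == 1.0


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman_assoc(x, np.exp(x))["rho"] == pytest.approx(1.0)
        assert spearman_assoc(x, -(x**3))["rho"] == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        res = spearman_assoc([1, 2, 3], [2, 1, 3])
        assert res["rho"] == pytest.approx(0.5)

    def test_symmetry_and_monotone_invariance(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        r1 = spearman_assoc(x, y)["rho"]
        assert spearman_assoc(y, x)["rho"] == pytest.approx(r1)
        assert spearman_assoc(np.exp(x), y)["rho"] == pytest.approx(r1)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spearman_assoc([1, 1, 1], [1, 2, 3])


class TestBhAdjust:
    def test_three_equal_spaced(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]).tolist() == [0.2]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=200))
    def test_matches_stepup_bruteforce(self, pvals):
        got = bh_adjust(pvals)
        want = bh_stepup_bruteforce(pvals)
        np.testing.assert_allclose(got, want, atol=1e-12)
        assert (got >= np.asarray(pvals) - 1e-15).all()

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=500)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)


class TestHallmarkCorrelationProfile:
    def _scores(self, activity):
        return pd.DataFrame(
            {"activity_score": activity},
            index=[f"s{i}" for i in range(len(activity))],
        )

    def test_self_correlation_is_top_hit(self, rng):
        activity = rng.normal(size=30)
        scores = self._scores(activity)
        pathways = pd.DataFrame(
            np.vstack([activity, rng.normal(size=(3, 30))]),
            index=["self", "n1", "n2", "n3"], columns=scores.index,
        )
        out = hallmark_correlation_profile(scores, pathways)
        assert out.iloc[0]["feature_id"] == "self"
        assert out.iloc[0]["rho"] == pytest.approx(1.0)

    def test_negated_activity_rho_minus_one(self, rng):
        activity = rng.normal(size=20)
        scores = self._scores(activity)
        pathways = pd.DataFrame([-activity, rng.normal(size=20)],
                                index=["neg", "null"], columns=scores.index)
        out = hallmark_correlation_profile(scores, pathways)
        assert out.set_index("feature_id").loc["neg", "rho"] == pytest.approx(-1)

    def test_fdr_is_bh_over_profile(self, rng):
        activity = rng.normal(size=25)
        scores = self._scores(activity)
        pathways = pd.DataFrame(rng.normal(size=(6, 25)),
                                index=[f"p{i}" for i in range(6)],
                                columns=scores.index)
        out = hallmark_correlation_profile(scores, pathways)
        np.testing.assert_allclose(
            np.sort(out["fdr"]), np.sort(bh_adjust(out["p"].to_numpy())))
        assert (out["fdr"] >= out["p"] - 1e-15).all()

    def test_too_few_shared_samples_is_error(self, rng):
        scores = self._scores(rng.normal(size=2))
        pathways = pd.DataFrame(rng.normal(size=(2, 2)), index=["a", "b"],
                                columns=scores.index)
        with pytest.raises(ValueError, match="shared"):
            hallmark_correlation_profile(scores, pathways)

    def test_null_fdr_discovery_rate_controlled(self):
        hits = 0
        n_rep, n_feat = 200, 40
        for seed in range(n_rep):
            rng = np.random.default_rng(10_000 + seed)
            activity = rng.normal(size=30)
            pathways = pd.DataFrame(
                rng.normal(size=(n_feat, 30)),
                index=[f"p{i}" for i in range(n_feat)],
                columns=[f"s{i}" for i in range(30)],
            )
            out = hallmark_correlation_profile(self._scores(activity), pathways)
            hits += (out["fdr"] < 0.05).sum()
        assert hits / (n_rep * n_feat) <= 0.05


class TestDifferentialExpression:
    def test_fold_change_and_fdr_columns(self, rng):
        genes = [f"g{i}" for i in range(5)]
        tumor = pd.DataFrame(rng.lognormal(1, 0.3, (5, 6)), index=genes)
        normal = pd.DataFrame(rng.lognormal(0, 0.3, (5, 6)), index=genes)
        out = differential_expression(tumor, normal)
        assert set(out.columns) == {"gene_id", "fold_change", "p", "fdr",
                                    "flagged"}
        assert (out["fold_change"] > 0).all()

    def test_log2_input_unlogged_for_fc(self):
        tumor = pd.DataFrame([[3.0, 3.0], [1.0, 1.0]], index=["g", "h"])
        normal = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=["g", "h"])
        out = differential_expression(tumor, normal, log2=True).set_index(
            "gene_id")
        assert out.loc["g", "fold_change"] == pytest.approx(4.0)
        assert out.loc["h", "fold_change"] == pytest.approx(1.0)
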