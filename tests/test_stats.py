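"""Group statistics: hand-computed examples, identities, calibration."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from _oracles import brute_bh_fdr
from fcnetopo import stats as fstats
from fcnetopo.cohort import load_reference_demographics


class TestNormalityCheck:
    def test_level_on_gaussian_samples(self):
        rng = np.random.default_rng(0)
        keep = sum(
            fstats.normality_check(rng.standard_normal(100))[0] for _ in range(100)
        )
        assert keep >= 90

    def test_power_on_exponential_samples(self):
        rng = np.random.default_rng(1)
        reject = sum(
            not fstats.normality_check(rng.exponential(size=100))[0] for _ in range(100)
        )
        assert reject >= 80

    def test_deterministic_and_constant_rejected(self):
        x = np.random.default_rng(2).standard_normal(50)
        assert fstats.normality_check(x) == fstats.normality_check(x)
        ok, stat, p = fstats.normality_check(np.full(10, 3.0))
        assert not ok and p == 0.0


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        res = fstats.kruskal_wallis([(1, 2, 3), (4, 5, 6), (7, 8, 9)])
        assert res.statistic == pytest.approx(7.2)
        assert res.df == 2

    def test_identical_groups_h_zero(self):
        res = fstats.kruskal_wallis([(2.0, 2.0), (2.0, 2.0), (2.0, 2.0)])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_group_order_invariance(self):
        groups = [(1, 5, 3), (2, 8, 4), (9, 7, 6)]
        a = fstats.kruskal_wallis(groups)
        b = fstats.kruskal_wallis(groups[::-1])
        assert a.statistic == pytest.approx(b.statistic)


class TestMannWhitney:
    def test_exact_enumeration_example(self):
        res = fstats.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1)  # 2/20 arrangements as extreme
        assert res.extra["method"] == "exact"

    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = fstats.mann_whitney(x, x)
        assert res.p == pytest.approx(1.0)
        assert res.extra["method"] == "asymptotic"

    def test_u_sum_identity(self, rng):
        x, y = rng.standard_normal(12), rng.standard_normal(9)
        ux = fstats.mann_whitney(x, y).statistic
        uy = fstats.mann_whitney(y, x).statistic
        assert ux + uy == pytest.approx(len(x) * len(y))


class TestAncova:
    def test_exact_two_group_fit(self, rng):
        group = np.array(["A"] * 6 + ["B"] * 6)
        ages = rng.uniform(20, 60, 12)
        metric = 2.0 + (group == "B").astype(float)
        res = fstats.ancova(metric, group, ages[None, :], ["age"])
        assert res.statistic_name == "t"
        assert res.extra["coef"] == pytest.approx(1.0, abs=1e-10)
        assert res.extra["residual_ss"] == pytest.approx(0.0, abs=1e-16)

    def test_age_only_signal_gives_null_group_effect(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(100):
            group = np.array(["A"] * 15 + ["B"] * 15)
            age = rng.uniform(20, 60, 30)
            metric = 0.5 * age + rng.standard_normal(30)
            ps.append(fstats.ancova(metric, group, age[None, :], ["age"]).p)
        assert np.mean(ps) > 0.35  # p uniform under the null

    def test_three_group_type_i_calibration(self):
        rng = np.random.default_rng(4)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            group = np.repeat(["A", "B", "C"], 12)
            age = rng.uniform(20, 60, 36)
            metric = 0.3 * age + rng.standard_normal(36)
            if fstats.ancova(metric, group, age[None, :], ["age"]).p < 0.05:
                rejections += 1
        lo, hi = sps.binom.interval(0.95, n_sims, 0.05)
        assert lo <= rejections <= hi

    def test_two_group_t_squared_equals_f_without_covariates(self, rng):
        group = np.array(["A"] * 10 + ["B"] * 10)
        metric = rng.standard_normal(20)
        t_res = fstats.ancova(metric, group)
        f_oneway = sps.f_oneway(metric[:10], metric[10:])
        assert t_res.statistic**2 == pytest.approx(f_oneway.statistic, abs=1e-9)
        assert t_res.p == pytest.approx(f_oneway.pvalue, abs=1e-9)


class TestCorrections:
    def test_bonferroni(self):
        assert fstats.bonferroni(0.008, 6) == pytest.approx(0.048)
        assert fstats.bonferroni(0.5, 6) == 1.0
        assert fstats.bonferroni(0.03, 1) == 0.03

    def test_bh_fdr_step_up_example(self):
        reject, p_adj = fstats.bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.1)
        assert reject.all()
        assert np.all(p_adj >= [0.01, 0.02, 0.03, 0.04])

    def test_all_ones_rejects_nothing(self):
        reject, _ = fstats.bh_fdr(np.ones(10), q=0.1)
        assert not reject.any()

    def test_order_invariance(self, rng):
        p = rng.uniform(size=20)
        perm = rng.permutation(20)
        r1, _ = fstats.bh_fdr(p, 0.1)
        r2, _ = fstats.bh_fdr(p[perm], 0.1)
        assert np.array_equal(r1[perm], r2)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_step_up(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(5, 60))
        for q in (0.05, 0.1, 0.25):
            reject, _ = fstats.bh_fdr(p, q)
            assert np.array_equal(reject, brute_bh_fdr(p, q))


class TestNodalComparison:
    def _table(self, rng, shift_nodes=(), shift=0.0, n_nodes=50):
        g1 = rng.standard_normal((33, n_nodes))
        g2 = rng.standard_normal((34, n_nodes))
        for node in shift_nodes:
            g1[:, node] += shift
        table = pd.DataFrame(np.vstack([g1, g2]), columns=range(n_nodes))
        groups = ["IGE"] * 33 + ["CTRL"] * 34
        return table, groups

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(5)
        table, groups = self._table(rng, n_nodes=200)
        res = fstats.nodal_comparison(table, groups)
        hits = int(res["significant_uncorrected"].sum())
        lo, hi = sps.binom.interval(0.95, 200, 0.05)
        assert lo <= hits <= hi
        assert not res["significant_fdr"].any()

    def test_planted_effect_recall(self):
        rng = np.random.default_rng(6)
        planted = list(range(20))
        table, groups = self._table(rng, shift_nodes=planted, shift=2.0)
        res = fstats.nodal_comparison(table, groups)
        hit_nodes = set(res.loc[res["significant_uncorrected"], "node"])
        recall = len(hit_nodes & set(planted)) / len(planted)
        assert recall >= 0.8

    def test_fdr_set_nested_in_uncorrected(self, rng):
        table, groups = self._table(rng, shift_nodes=range(10), shift=1.0)
        res = fstats.nodal_comparison(table, groups)
        assert (res["significant_fdr"] <= res["significant_uncorrected"]).all()


class TestHubFrequency:
    def test_identical_hub_sets(self):
        hubs = {f"s{i}": {1, 2, 3} for i in range(9)}
        groups = {f"s{i}": ["WC", "DR", "CTRL"][i % 3] for i in range(9)}
        out = fstats.hub_frequency(hubs, groups, n_nodes=5)
        assert (out["counts"].loc[1] == 3).all()
        assert out["three_group_test"].p == 1.0
        assert out["two_group_test"].p == 1.0

    def test_empty_hub_sets_zero_counts(self):
        hubs = {"a": set(), "b": set()}
        groups = {"a": "WC", "b": "CTRL"}
        out = fstats.hub_frequency(hubs, groups, n_nodes=4)
        assert (out["counts"].to_numpy() == 0).all()

    def test_median_cardinality_hand_count(self):
        hubs = {"a": {0}, "b": {0, 1}, "c": {0, 1, 2}, "d": set(), "e": {0, 1, 2, 3}}
        groups = {"a": "WC", "b": "WC", "c": "DR", "d": "DR", "e": "CTRL"}
        out = fstats.hub_frequency(hubs, groups, n_nodes=5)
        assert out["medians"] == {"CTRL": 4.0, "DR": 1.5, "WC": 1.5}


class TestCohortDescriptives:
    def test_reference_cohort_worked_examples(self):
        desc = fstats.cohort_descriptives(load_reference_demographics())
        assert desc["summary"]["WC"]["median_age"] == pytest.approx(22.5)
        assert desc["summary"]["DR"]["median_age"] == pytest.approx(31.0)
        assert desc["summary"]["WC"]["median_duration"] == pytest.approx(6.5)
        assert desc["summary"]["DR"]["mean_n_aeds"] == pytest.approx(1.9, abs=0.05)
        assert desc["summary"]["DR"]["aed_range"] == (1, 4)

    def test_tests_present_for_multi_group_manifest(self):
        desc = fstats.cohort_descriptives(load_reference_demographics())
        assert desc["tests"]["age_kruskal"].statistic_name == "H"
        assert desc["tests"]["sex_chi2"].statistic_name == "chi2"


class TestMetricCovariateCorrelation:
    def test_perfect_and_hand_computed(self):
        res = fstats.metric_covariate_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(1.0)
        res2 = fstats.metric_covariate_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert res2.statistic == pytest.approx(0.98198, abs=1e-5)

    def test_orthogonal_vectors_r_zero(self):
        res = fstats.metric_covariate_correlation([1.0, -1.0, 1.0, -1.0],
                                                  [1.0, 1.0, -1.0, -1.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fstats.metric_covariate_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
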