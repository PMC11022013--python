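from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from osteomap import (permanova, permutation_test_pc_scores,
                      regress_bm_on_size)


def exhaustive_oracle(values, na):
    """Brute-force enumeration of all group-a choices for a two-group
    mean-difference permutation test in 1-D."""
    values = np.asarray(values, dtype=float)
    obs = abs(values[:na].mean() - values[na:].mean())
    hits = total = 0
    for chosen in combinations(range(len(values)), na):
        rest = [i for i in range(len(values)) if i not in chosen]
        stat = abs(values[list(chosen)].mean() - values[rest].mean())
        total += 1
        if stat >= obs - 1e-12:
            hits += 1
    return hits / total


class TestPermutationTest:
    def test_exhaustive_three_vs_three_enumeration(self):
        scores = np.array([1.0, 2, 3, 4, 5, 6])[:, None]
        labels = ["a"] * 3 + ["b"] * 3
        res = permutation_test_pc_scores(scores, labels, k_components=1,
                                         method="exhaustive")
        assert res[0].p_raw == pytest.approx(2 / 20)
        assert res[0].p_raw == pytest.approx(
            exhaustive_oracle(scores[:, 0], 3))

    def test_identical_groups_statistic_zero(self):
        scores = np.tile([[1.0, 2.0]], (8, 1))
        res = permutation_test_pc_scores(scores, ["a"] * 4 + ["b"] * 4,
                                         k_components=2, n_perm=99, seed=0)
        assert res[0].statistic == 0.0
        assert res[0].p_raw == 1.0

    def test_bonferroni_multiplies_by_pair_count(self, rng):
        scores = rng.normal(size=(40, 3))
        labels = np.repeat(list("abcde"), 8)
        res = permutation_test_pc_scores(scores, labels, k_components=3,
                                         n_perm=199, seed=3)
        assert len(res) == 10
        for r in res:
            assert r.p_adjusted == pytest.approx(min(1.0, 10 * r.p_raw))
            assert r.p_raw >= 1 / 200

    def test_deterministic_under_seed(self, rng):
        scores = rng.normal(size=(20, 2))
        labels = ["a"] * 10 + ["b"] * 10
        r1 = permutation_test_pc_scores(scores, labels, 2, n_perm=99, seed=5)
        r2 = permutation_test_pc_scores(scores, labels, 2, n_perm=99, seed=5)
        assert r1[0].p_raw == r2[0].p_raw

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            permutation_test_pc_scores(np.zeros((3, 1)), ["a", "a", "b"],
                                       k_components=1)


class TestPermanova:
    def test_separated_groups_hit_minimum_p(self):
        data = np.array([0.0, 0, 0, 1, 1, 1])[:, None]
        labels = ["a"] * 3 + ["b"] * 3
        res = permanova(data, labels, n_perm=199, seed=0)
        assert res.ss_within == pytest.approx(0.0, abs=1e-12)
        assert res.ss_between == pytest.approx(1.5)   # analytic: 2*3*(0.5^2)/2
        # exhaustive truth: only the 2 perfectly separating assignments of
        # C(6,3)=20 reach the observed (infinite) pseudo-F, so p -> 2/20
        assert res.p == pytest.approx(2 / 20, abs=0.05)
        assert res.p >= 1 / 200

    def test_one_dimensional_equivalence_with_anova(self, rng):
        groups = [rng.normal(loc=m, size=7) for m in (0.0, 0.5, 1.0)]
        data = np.concatenate(groups)[:, None]
        labels = np.repeat(["a", "b", "c"], 7)
        res = permanova(data, labels, n_perm=49, seed=0)
        f_oracle = sps.f_oneway(*groups).statistic
        assert res.pseudo_F == pytest.approx(f_oracle, rel=1e-9)

    def test_ss_decomposition_exact(self, rng):
        data = rng.normal(size=(24, 10))
        labels = np.repeat(["a", "b", "c"], 8)
        res = permanova(data, labels, n_perm=49, seed=1)
        assert (res.ss_between + res.ss_within) == pytest.approx(
            res.ss_total, rel=1e-9)
        assert 0.0 <= res.R2 <= 1.0

    def test_pairwise_bonferroni(self, rng):
        data = rng.normal(size=(30, 5))
        labels = np.repeat(["a", "b", "c"], 10)
        res = permanova(data, labels, n_perm=99, seed=2, pairwise=True)
        assert len(res.pairwise) == 3
        for r in res.pairwise:
            assert r.p_adjusted == pytest.approx(min(1.0, 3 * r.p_raw))

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(np.zeros((3, 2)), ["a", "a", "b"], n_perm=9)


class TestSizeRegression:
    def test_exactly_linear_data_r2_one(self, rng):
        cs = rng.uniform(50, 400, size=12)
        slopes = rng.normal(size=5)
        bm = np.outer(np.log(cs), slopes) + rng.normal(size=5)
        res = regress_bm_on_size(bm, cs, n_perm=49, seed=0)
        assert res.R2_multivariate == pytest.approx(1.0, abs=1e-10)
        assert res.p_perm <= 0.05

    def test_single_column_slope_closed_form(self, rng):
        cs = rng.uniform(10, 100, size=15)
        y = rng.normal(size=15)
        res = regress_bm_on_size(y, cs, n_perm=9, seed=0)
        x = np.log(cs)
        slope_oracle = (np.sum((x - x.mean()) * (y - y.mean()))
                        / np.sum((x - x.mean()) ** 2))
        assert res.coefficients[0] == pytest.approx(slope_oracle, rel=1e-10)

    def test_null_size_rarely_significant(self, rng):
        rejections = 0
        n_sims = 60
        for i in range(n_sims):
            bm = rng.normal(size=(20, 6))
            cs = rng.uniform(50, 300, size=20)
            res = regress_bm_on_size(bm, cs, n_perm=99, seed=i)
            rejections += res.p_perm <= 0.05
        assert rejections / n_sims <= 0.15

    def test_constant_size_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regress_bm_on_size(np.random.default_rng(0).normal(size=(8, 2)),
                               np.full(8, 100.0), n_perm=9)
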