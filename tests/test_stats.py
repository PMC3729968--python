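from math import comb

import numpy as np
import pytest

from megconn.stats import (discard_outliers, effect_modification_regression,
                           ks_normality, mann_whitney, permutation_roi_test,
                           spearman)


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic_u == 0.0
        assert res.direction == "lower_in_x"

    def test_identical_multisets_give_half_u(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(x, x)
        assert res.statistic_u == len(x) ** 2 / 2
        assert res.p_value == 1.0

    def test_swap_complement_identity(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=7)
        a = mann_whitney(x, y)
        b = mann_whitney(y, x)
        assert np.isclose(a.statistic_u + b.statistic_u, 9 * 7)
        assert np.isclose(a.p_value, b.p_value)

    def test_constant_data_gives_p_one(self):
        res = mann_whitney([2.0] * 5, [2.0] * 4)
        assert res.p_value == 1.0 and res.direction == "equal"

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1, 2], [3, 4, 5])


class TestPermutation:
    def test_exhaustive_minimum_p_for_separated_groups(self):
        values = np.array([[1.0], [2.0], [3.0], [10.0], [11.0], [12.0]])
        labels = np.array(list("aaabbb"))
        res = permutation_roi_test(values, labels, n_perm=5000, seed=0)
        # both tails of the exhaustive null reach the observed |t|
        assert res.n_permutations == comb(6, 3)
        assert np.isclose(res.per_roi_p[0], 2.0 / comb(6, 3))

    def test_label_swap_leaves_p_unchanged(self, rng):
        values = rng.normal(size=(12, 4))
        labels = np.array(["g1"] * 5 + ["g2"] * 7)
        flipped = np.where(labels == "g1", "g2", "g1")
        a = permutation_roi_test(values, labels, n_perm=2000, seed=3)
        b = permutation_roi_test(values, flipped, n_perm=2000, seed=3)
        assert np.allclose(a.per_roi_p, b.per_roi_p)

    def test_degenerate_roi_flagged_with_p_one(self, rng):
        values = np.column_stack([rng.normal(size=10),
                                  np.full(10, 3.14)])
        labels = np.array(["a"] * 5 + ["b"] * 5)
        res = permutation_roi_test(values, labels, n_perm=2000, seed=1)
        assert res.degenerate[1] and res.per_roi_p[1] == 1.0
        assert not res.degenerate[0]

    def test_monte_carlo_p_floor_and_determinism(self, rng):
        values = rng.normal(size=(20, 3))
        values[:10] += 5.0
        labels = np.array(["a"] * 10 + ["b"] * 10)
        a = permutation_roi_test(values, labels, n_perm=1000, seed=8)
        b = permutation_roi_test(values, labels, n_perm=1000, seed=8)
        assert np.array_equal(a.per_roi_p, b.per_roi_p)
        assert np.all(a.per_roi_p >= 1.0 / (comb(20, 10) if comb(20, 10)
                                            <= 1000 else 1001))

    def test_maxstat_correction_is_conservative(self, rng):
        values = rng.normal(size=(16, 6))
        labels = np.array(["a"] * 8 + ["b"] * 8)
        plain = permutation_roi_test(values, labels, n_perm=2000, seed=5)
        corr = permutation_roi_test(values, labels, n_perm=2000, seed=5,
                                    correction="maxstat")
        assert np.all(corr.per_roi_p >= plain.per_roi_p - 1e-12)


class TestSpearman:
    def test_strict_monotone_gives_unit_rho(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 11.0])
        rho_up, _ = spearman(x, np.exp(x))
        rho_dn, _ = spearman(x, -(x ** 3))
        assert np.isclose(rho_up, 1.0) and np.isclose(rho_dn, -1.0)

    def test_hand_computed_example(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert np.isclose(rho, 0.8)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spearman([1, 2, 3, 4, 5], [2, 2, 2, 2, 2])


class TestEffectModification:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(0)
        vol = np.concatenate([rng.uniform(1, 2, 12),
                              rng.uniform(1, 2, 12)])
        grp = np.array(["c"] * 12 + ["p"] * 12)
        y = np.where(grp == "c", 0.3 + 2.0 * vol, 0.1 - 1.5 * vol)
        res = effect_modification_regression(y, vol, grp)
        assert np.isclose(res.slope_group1, 2.0, atol=1e-10)
        assert np.isclose(res.slope_group2, -1.5, atol=1e-10)

    def test_opposite_slopes_detected(self):
        rng = np.random.default_rng(1)
        vol = np.concatenate([rng.uniform(0, 1, 30),
                              rng.uniform(0, 1, 30)])
        grp = np.array(["c"] * 30 + ["p"] * 30)
        y = np.where(grp == "c", 1.0 * vol, -1.0 * vol) \
            + 0.05 * rng.normal(size=60)
        res = effect_modification_regression(y, vol, grp)
        assert res.slope_group1 > 0 > res.slope_group2
        assert res.interaction_p < 0.01

    def test_equal_slopes_give_small_interaction(self):
        rng = np.random.default_rng(2)
        slopes = []
        for k in range(10):
            vol = rng.uniform(0, 1, 60)
            grp = np.array(["c"] * 30 + ["p"] * 30)
            y = 0.7 * vol + 0.1 * rng.normal(size=60)
            res = effect_modification_regression(y, vol, grp)
            slopes.append((res.slope_group1, res.slope_group2,
                           res.interaction_p))
        # interaction rarely significant; per-group slopes near truth
        assert np.mean([p < 0.05 for *_, p in slopes]) <= 0.2
        assert abs(np.mean([s1 for s1, *_ in slopes]) - 0.7) < 0.1

    def test_constant_volume_in_group_rejected(self):
        vol = np.array([1.0] * 6 + [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        grp = np.array(["c"] * 6 + ["p"] * 6)
        with pytest.raises(ValueError, match="collinear"):
            effect_modification_regression(np.arange(12.0), vol, grp)


class TestKsNormality:
    def test_skewed_sample_strongly_rejected(self):
        rng = np.random.default_rng(3)
        rejections = [ks_normality(rng.exponential(size=200))[1] < 0.05
                      for _ in range(30)]
        assert np.mean(rejections) >= 0.9

    def test_statistic_bounded(self, rng):
        stat, _ = ks_normality(rng.normal(size=50))
        assert 0.0 <= stat <= 1.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ks_normality(np.ones(20))


def test_outlier_rule_drops_gross_outlier(rng):
    x = np.linspace(0, 1, 20)
    y = 2.0 * x + 0.01 * rng.normal(size=20)
    y[7] += 5.0
    xk, yk, dropped = discard_outliers(x, y)
    assert dropped == 1 and len(xk) == 19
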