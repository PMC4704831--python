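"""The statistical procedures against independent oracles.

Implementations here are hand-written formulas; the oracles are scipy's test
functions, statsmodels OLS, and exhaustive permutation — independent code
paths for the same mathematics.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as ss

from methylfunnel import (
    ancova_group_age,
    chi_square_independence,
    one_way_anova,
    pearson,
    spearman,
    t_test_unpaired,
)

class TestTTest:
    def test_identical_samples_give_t0_p1(self):
        res = t_test_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_pure_shift_recovers_difference(self):
        res = t_test_unpaired([1, 2, 3], [11, 12, 13])
        assert res.estimate == pytest.approx(-10.0)
        assert res.p_value < 0.001

    @pytest.mark.parametrize("equal_variance", [True, False])
    def test_matches_scipy_on_random_samples(self, rng, equal_variance):
        for _ in range(300):
            x = rng.normal(0, 1 + rng.random(), rng.integers(2, 10))
            y = rng.normal(rng.normal(), 1 + rng.random(), rng.integers(2, 10))
            mine = t_test_unpaired(x, y, equal_variance=equal_variance)
            ref = ss.ttest_ind(x, y, equal_var=equal_variance)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            t_test_unpaired([1.0], [1.0, 2.0])


class TestAnova:
    def test_all_constant_uses_f0_p1_convention(self):
        res = one_way_anova([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_two_groups_equal_t_squared(self, rng):
        x, y = rng.normal(0, 1, 6), rng.normal(0.5, 1, 8)
        f = one_way_anova([x, y])
        t = t_test_unpaired(x, y, equal_variance=True)
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-12)
        assert f.p_value == pytest.approx(t.p_value, rel=1e-12)

    def test_matches_scipy_on_random_groups(self, rng):
        for _ in range(300):
            groups = [rng.normal(rng.normal(), 1, rng.integers(2, 8))
                      for _ in range(rng.integers(2, 5))]
            mine = one_way_anova(groups)
            ref = ss.f_oneway(*groups)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def _statsmodels_ancova(values, groups, ages, order):
    """Independent oracle: statsmodels OLS with treatment coding."""
    import pandas as pd
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": values, "g": pd.Categorical(groups, categories=order),
                       "age": ages})
    full = smf.ols("y ~ C(g) + age", data=df).fit()
    reduced = smf.ols("y ~ age", data=df).fit()
    F, p, _ = full.compare_f_test(reduced)
    grand = np.mean(ages)
    adjusted = {
        g: float(full.predict(pd.DataFrame(
            {"g": pd.Categorical([g], categories=order), "age": [grand]})).iloc[0])
        for g in order
    }
    return F, p, float(full.params["age"]), adjusted, full


class TestAncova:
    def test_pure_covariate_signal(self, rng):
        ages = rng.uniform(60, 85, 30)
        groups = rng.choice(["NC", "aMCI", "AD"], 30).tolist()
        while min(groups.count(g) for g in ("NC", "aMCI", "AD")) < 3:
            groups = rng.choice(["NC", "aMCI", "AD"], 30).tolist()
        res = ancova_group_age(2.0 * ages, groups, ages)
        assert res.covariate_slope == pytest.approx(2.0, abs=1e-9)
        assert res.group_p > 0.99

    def test_matches_statsmodels_oracle(self, rng):
        order = ["NC", "aMCI", "AD"]
        for _ in range(100):
            n = int(rng.integers(15, 40))
            groups = rng.choice(order, n).tolist()
            while min(groups.count(g) for g in order) < 3:
                groups = rng.choice(order, n).tolist()
            ages = rng.uniform(55, 90, n)
            effects = dict(zip(order, rng.normal(0, 0.3, 3)))
            values = (np.array([effects[g] for g in groups])
                      - 0.002 * ages + rng.normal(0, 0.1, n))
            mine = ancova_group_age(values, groups, ages, group_order=order)
            F, p, slope, adjusted, full = _statsmodels_ancova(values, groups, ages, order)
            assert mine.group_F == pytest.approx(F, abs=1e-8)
            assert mine.group_p == pytest.approx(p, abs=1e-8)
            assert mine.covariate_slope == pytest.approx(slope, abs=1e-8)
            for g in order:
                assert mine.adjusted_group_means[g] == pytest.approx(adjusted[g], abs=1e-8)
            # pairwise contrast oracle: t-test on the dummy-coefficient contrast
            cmp_t = full.t_test("C(g)[T.aMCI] - C(g)[T.AD] = 0")
            d, t, pv = mine.contrasts[("aMCI", "AD")]
            assert t == pytest.approx(float(np.squeeze(cmp_t.tvalue)), abs=1e-8)
            assert pv == pytest.approx(float(np.squeeze(cmp_t.pvalue)), abs=1e-8)

    def test_recovers_known_effects_within_3se(self, rng):
        order = ["NC", "aMCI", "AD"]
        truth = {"NC": 0.0, "aMCI": -0.2, "AD": -0.18}
        misses = 0
        for _ in range(200):
            groups = (["NC"] * 12 + ["aMCI"] * 12 + ["AD"] * 12)
            ages = rng.uniform(55, 90, 36)
            values = (np.array([truth[g] for g in groups])
                      - 0.002 * ages + rng.normal(0, 0.05, 36))
            res = ancova_group_age(values, groups, ages, group_order=order)
            d, t, _ = res.contrasts[("NC", "aMCI")]
            se = d / t
            misses += abs(d - 0.2) > 3 * se
        assert misses / 200 < 0.05  # 3 SE covers ~99.7% under normality

    def test_constant_covariate_is_singular(self):
        with pytest.raises(ValueError, match="age"):
            ancova_group_age([1.0, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3, [70.0] * 6)

    def test_group_f_close_to_anova_when_age_uninformative(self, rng):
        groups = ["NC"] * 10 + ["aMCI"] * 10 + ["AD"] * 10
        values = np.r_[rng.normal(0, 1, 10), rng.normal(1, 1, 10), rng.normal(2, 1, 10)]
        ages = rng.uniform(55, 90, 30)  # independent of values
        anc = ancova_group_age(values, groups, ages)
        anova = one_way_anova([values[:10], values[10:20], values[20:]])
        assert anc.group_F == pytest.approx(anova.statistic, rel=0.25)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(8.0)
        assert spearman(x, np.exp(x)).statistic == pytest.approx(1.0)
        assert spearman(x, -(x**3)).statistic == pytest.approx(-1.0)

    def test_matches_scipy_t_approximation(self, rng):
        for _ in range(300):
            n = int(rng.integers(5, 20))
            x = rng.normal(0, 1, n)
            y = 0.5 * x + rng.normal(0, 1, n)
            mine = spearman(x, y)
            ref = ss.spearmanr(x, y)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exact_permutation_matches_enumeration_with_ties(self):
        # n=8 with one tied pair, as in the discovery-stage MMSE column
        x = np.array([28.0, 27, 27, 25, 20, 19, 15, 12])
        y = np.array([0.71, 0.69, 0.72, 0.60, 0.55, 0.58, 0.49, 0.46])
        mine = spearman(x, y, exact=True)

        def midranks(v):
            order = np.argsort(v)
            r = np.empty(len(v))
            sv = np.sort(v)
            for i, vi in enumerate(v):
                eq = sv == vi
                r[i] = np.mean(np.nonzero(eq)[0]) + 1
            return r

        rx, ry = midranks(x), midranks(y)
        rho_oracle = np.corrcoef(rx, ry)[0, 1]
        assert mine.statistic == pytest.approx(rho_oracle, abs=1e-12)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        assert mine.p_value == pytest.approx(count / total, abs=1e-12)

    @given(st.lists(st.integers(-1000, 1000), min_size=3, max_size=12))
    def test_invariant_under_monotone_transform(self, xs):
        xs = np.asarray(xs, dtype=float)
        ys = np.arange(len(xs), dtype=float) + 0.5
        if len(np.unique(xs)) < 2:
            return
        base = spearman(xs, ys).statistic
        transformed = spearman(np.exp(xs / 50.0), ys).statistic
        assert transformed == pytest.approx(base, abs=1e-12)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(6.0)
        assert pearson(x, 3 * x + 1).statistic == pytest.approx(1.0)
        assert pearson(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_scipy(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 15))
            x = rng.normal(0, 1, n)
            y = rng.normal(0, 1, n)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            mine = pearson(x, y)
            ref = ss.pearsonr(x, y)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestChiSquare:
    def test_uniform_table_gives_zero(self):
        res = chi_square_independence([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_computed_2x2(self):
        # E = 15 in every cell; chi2 = 4 * 25/15 = 20/3
        res = chi_square_independence([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(20.0 / 3.0, abs=1e-12)
        assert res.df == 1

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(300):
            table = rng.integers(1, 40, size=(2, 3))
            mine = chi_square_independence(table)
            ref = ss.chi2_contingency(table, correction=False)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_independence([[0, 0], [5, 3]])


class TestSharedProperties:
    def test_reordering_samples_leaves_statistics_unchanged(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        perm = rng.permutation(10)
        assert t_test_unpaired(x, y).statistic == pytest.approx(
            t_test_unpaired(x[perm], y[perm]).statistic, abs=1e-12)
        paired_perm = rng.permutation(10)
        assert spearman(x, y).statistic == pytest.approx(
            spearman(x[paired_perm], y[paired_perm]).statistic, abs=1e-12)

    def test_null_rejection_rate_is_calibrated(self, rng):
        # pooled over 4000 replicates per test at alpha=0.05
        alpha, n_rep = 0.05, 4000
        rej_t = rej_r = 0
        for _ in range(n_rep):
            x, y = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
            rej_t += t_test_unpaired(x, y).p_value < alpha
            rej_r += pearson(x, y).p_value < alpha
        bound = 2.58 * math.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rej_t / n_rep - alpha) < bound
        assert abs(rej_r / n_rep - alpha) < bound
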