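"""Correlation, FDR, ANOVA and group-comparison wrappers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from telovita import benjamini_hochberg, spearman, t_test, tukey_hsd, two_way_anova
from telovita.errors import TelovitaError


class TestSpearman:
    def test_perfect_monotone_is_plus_minus_one(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)
        assert spearman(x, -(x**3)).rho == pytest.approx(-1.0)

    def test_rank_formula_worked_example(self):
        # d^2 = (1,1,1,1,0): rho = 1 - 6*4/(5*24) = 0.8
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rho == pytest.approx(0.8)

    @given(st.lists(st.integers(-1000, 1000), min_size=5, max_size=30,
                    unique=True))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_strictly_monotone_transforms(self, xs):
        x = np.array(xs, dtype=float) / 7.3
        rng = np.random.default_rng(0)
        y = rng.permutation(x)
        base = spearman(x, y).rho
        assert spearman(np.exp(x / 200.0), y).rho == pytest.approx(base, abs=1e-9)
        assert spearman(x, 3.0 * y + 11.0).rho == pytest.approx(base, abs=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(TelovitaError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestBenjaminiHochberg:
    def test_worked_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.04, 0.05]),
            [0.04, 0.04, 0.05, 0.05])

    def test_single_and_equal_values(self):
        assert benjamini_hochberg([0.03]) == pytest.approx([0.03])
        np.testing.assert_allclose(benjamini_hochberg([0.2, 0.2, 0.2]),
                                   [0.2, 0.2, 0.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_dominating(self, ps):
        p = np.array(ps)
        q = benjamini_hochberg(p)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)
        # same raw ordering -> same adjusted ordering
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(TelovitaError):
            benjamini_hochberg([0.5, 1.5])


class TestTwoWayAnova:
    @staticmethod
    def toy_2x2(reps=3):
        rng = np.random.default_rng(3)
        rows = []
        effects = {("M", 4): 1.0, ("M", 8): 2.0, ("F", 4): 2.5, ("F", 8): 5.0}
        for (sex, age), mu in effects.items():
            for _ in range(reps):
                rows.append((mu + rng.normal(0, 0.3), sex, age))
        vals, sexes, ages = zip(*rows)
        return np.array(vals), list(sexes), list(ages)

    def test_sums_of_squares_match_hand_decomposition(self):
        vals, sexes, ages = self.toy_2x2()
        table = two_way_anova(vals, sexes, ages).table
        v = np.asarray(vals)
        s = np.array([x == "M" for x in sexes])
        a = np.array([x == 4 for x in ages])
        grand = v.mean()
        ss_sex = sum(v[m].size * (v[m].mean() - grand) ** 2 for m in (s, ~s))
        ss_age = sum(v[m].size * (v[m].mean() - grand) ** 2 for m in (a, ~a))
        cell_means = {k: v[m].mean() for k, m in
                      {(1, 1): s & a, (1, 0): s & ~a,
                       (0, 1): ~s & a, (0, 0): ~s & ~a}.items()}
        ss_cells = sum(np.sum((v[m] - cell_means[k]) ** 2) for k, m in
                       {(1, 1): s & a, (1, 0): s & ~a,
                        (0, 1): ~s & a, (0, 0): ~s & ~a}.items())
        ss_total = np.sum((v - grand) ** 2)
        ss_inter = ss_total - ss_sex - ss_age - ss_cells
        assert table.loc["C(sex)", "sum_sq"] == pytest.approx(ss_sex, abs=1e-10)
        assert table.loc["C(age)", "sum_sq"] == pytest.approx(ss_age, abs=1e-10)
        assert table.loc["C(sex):C(age)", "sum_sq"] == pytest.approx(
            ss_inter, abs=1e-10)
        assert table.loc["Residual", "sum_sq"] == pytest.approx(ss_cells, abs=1e-10)

    def test_additive_truth_gives_small_interaction_f(self):
        rng = np.random.default_rng(11)
        sexes, ages, vals = [], [], []
        for sex, s_eff in (("M", 0.0), ("F", 1.0)):
            for age, a_eff in ((4, 0.0), (8, 2.0), (12, 4.0)):
                for _ in range(200):
                    sexes.append(sex)
                    ages.append(age)
                    vals.append(s_eff + a_eff + rng.normal(0, 1.0))
        table = two_way_anova(np.array(vals), sexes, ages).table
        f_inter = table.loc["C(sex):C(age)", "F"]
        f_main = table.loc["C(age)", "F"]
        assert f_inter < 5.0 < f_main

    def test_replicate_order_within_cells_irrelevant(self):
        vals, sexes, ages = self.toy_2x2()
        table1 = two_way_anova(vals, sexes, ages).table
        perm = np.r_[1, 0, 2, 4, 3, 5, 7, 6, 8, 10, 9, 11]  # within-cell swaps
        table2 = two_way_anova(vals[perm], [sexes[i] for i in perm],
                               [ages[i] for i in perm]).table
        np.testing.assert_allclose(table1["sum_sq"], table2["sum_sq"], atol=1e-10)

    def test_empty_cell_recommends_cell_means(self):
        with pytest.raises(TelovitaError, match="cell"):
            two_way_anova([1.0, 2.0, 3.0, 4.0, 1.5, 2.5],
                          ["M", "M", "F", "F", "M", "F"],
                          [4, 4, 8, 8, 4, 8])


class TestGroupComparisons:
    def test_identical_groups_t_zero_p_one(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        # pooled sd = 1, se = sqrt(2/3): t = -3 / 0.8165 ~ -3.674
        res = t_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-9)
        assert res.df == 4

    def test_degenerate_groups_rejected(self):
        with pytest.raises(TelovitaError):
            t_test([2.0, 2.0], [2.0, 2.0])

    def test_tukey_identical_groups_share_one_letter(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, 30)
        res = tukey_hsd(vals, ["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        assert set(res.letters.values()) == {"a"}

    def test_tukey_separated_group_gets_own_letter(self):
        rng = np.random.default_rng(5)
        vals = np.r_[rng.normal(0, 0.5, 10), rng.normal(8, 0.5, 10),
                     rng.normal(8.1, 0.5, 10)]
        res = tukey_hsd(vals, ["lo"] * 10 + ["hi1"] * 10 + ["hi2"] * 10)
        assert res.letters["hi1"] == res.letters["hi2"]
        assert res.letters["lo"] != res.letters["hi1"]
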