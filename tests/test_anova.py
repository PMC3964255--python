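"""Two-way ANOVA, observed power and the Newman-Keuls ranking."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from maekin.anova import (anova_from_ss, observed_power, snk_test,
                          two_way_anova)


def brute_force_ss(grid):
    """Definitional double sums for the balanced no-replication layout."""
    a, b = grid.shape
    grand = sum(grid[i][j] for i in range(a) for j in range(b)) / (a * b)
    row = [sum(grid[i][j] for j in range(b)) / b for i in range(a)]
    col = [sum(grid[i][j] for i in range(a)) / a for j in range(b)]
    ss_a = b * sum((r - grand) ** 2 for r in row)
    ss_b = a * sum((c - grand) ** 2 for c in col)
    ss_tot = sum((grid[i][j] - grand) ** 2
                 for i in range(a) for j in range(b))
    return ss_a, ss_b, ss_tot - ss_a - ss_b


class TestTwoWayAnova:
    def test_matches_brute_force_double_sums(self, rng):
        grid = rng.normal(1.0, 0.3, size=(3, 4))
        table = two_way_anova(grid)
        ss_a, ss_b, ss_err = brute_force_ss(grid)
        assert table.rows[0].ss == pytest.approx(ss_a, rel=1e-9)
        assert table.rows[1].ss == pytest.approx(ss_b, rel=1e-9)
        assert table.row("error").ss == pytest.approx(ss_err, rel=1e-9)
        assert table.rows[0].df == 2 and table.rows[1].df == 3
        assert table.row("error").df == 6

    def test_matches_statsmodels_ols(self, rng):
        import pandas as pd
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        grid = rng.normal(0.5, 0.2, size=(4, 5))
        a, b = np.indices(grid.shape)
        df = pd.DataFrame({"y": grid.ravel(), "a": a.ravel(), "b": b.ravel()})
        lm = smf.ols("y ~ C(a) + C(b)", data=df).fit()
        sm_tab = anova_lm(lm, typ=2)
        table = two_way_anova(grid)
        assert table.rows[0].ss == pytest.approx(sm_tab.loc["C(a)", "sum_sq"])
        assert table.rows[1].ss == pytest.approx(sm_tab.loc["C(b)", "sum_sq"])
        assert table.row("error").ss == pytest.approx(
            sm_tab.loc["Residual", "sum_sq"])
        assert table.rows[0].f == pytest.approx(sm_tab.loc["C(a)", "F"])
        assert table.rows[0].p == pytest.approx(sm_tab.loc["C(a)", "PR(>F)"])

    def test_additive_grid_has_zero_error(self, rng):
        a_eff = rng.normal(0, 1, 5)
        b_eff = rng.normal(0, 1, 7)
        grid = a_eff[:, None] + b_eff[None, :]
        table = two_way_anova(grid)
        assert table.row("error").ss == pytest.approx(0.0, abs=1e-12)

    def test_constant_grid_flagged_zero_variance(self):
        table = two_way_anova(np.full((3, 4), 2.5))
        assert table.zero_variance
        assert np.isnan(table.rows[0].f)
        assert table.rows[0].ss == pytest.approx(0.0, abs=1e-15)

    def test_unbalanced_grid_rejected(self):
        with pytest.raises(ValueError, match="unbalanced|2-D"):
            two_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0]])
        grid = np.ones((3, 4))
        grid[1, 2] = np.nan
        with pytest.raises(ValueError, match="unbalanced"):
            two_way_anova(grid)

    @given(arrays(float, (4, 5), elements=st.floats(-10, 10)))
    def test_ss_decomposition(self, grid):
        """ss_A + ss_B + ss_error = ss_total on every balanced grid."""
        table = two_way_anova(grid)
        total = float(np.sum((grid - grid.mean()) ** 2))
        parts = (table.rows[0].ss + table.rows[1].ss + table.row("error").ss)
        assert parts == pytest.approx(total, rel=1e-9, abs=1e-9)


class TestAnovaFromSS:
    def test_unit_f_ratio(self):
        table = anova_from_ss(1.0, 1, 1.0, 1, 1.0, 1)
        assert table.rows[0].f == pytest.approx(1.0)

    def test_zero_error_df_rejected(self):
        with pytest.raises(ValueError):
            anova_from_ss(1.0, 1, 1.0, 1, 1.0, 0)

    def test_noncentrality_identity_df_times_f(self):
        table = anova_from_ss(10.067, 5, 1.464, 24, 0.762, 120)
        row = table.rows[0]
        assert row.noncent == pytest.approx(row.df * row.f, rel=1e-12)


class TestObservedPower:
    def test_central_case_equals_alpha(self):
        assert observed_power(0.0, 5, 120, alpha=0.05) == pytest.approx(0.05)

    def test_monotone_in_noncentrality(self):
        lams = np.linspace(0, 40, 30)
        powers = [observed_power(l, 2, 10) for l in lams]
        assert np.all(np.diff(powers) > 0)

    def test_published_saturated_power(self):
        # df*F = 5 * 316.937 for the strongest published main effect
        assert observed_power(1584.685, 5, 120) == pytest.approx(1.0,
                                                                 abs=5e-4)

    def test_negative_noncentrality_rejected(self):
        with pytest.raises(ValueError):
            observed_power(-1.0, 2, 10)


from functools import lru_cache


@lru_cache(maxsize=None)
def _q(alpha, r, df):
    from scipy.stats import studentized_range
    return float(studentized_range.isf(alpha, r, df))


def snk_brute_force(means, n, ms_error, df_error, alpha):
    """Independent all-pairs studentized-range step-down for small k."""
    k = len(means)
    order = sorted(range(k), key=lambda i: -means[i])
    m = [means[i] for i in order]
    spans = [(i, j) for i in range(k) for j in range(i + 1, k)]
    spans.sort(key=lambda ij: ij[0] - ij[1])  # big spans first
    accepted = []
    for i, j in spans:
        if any(ai <= i and j <= aj for ai, aj in accepted):
            continue
        r = j - i + 1
        crit = _q(alpha, r, df_error) * (ms_error / n) ** 0.5
        if not (m[i] - m[j] > crit):
            accepted.append((i, j))
    covered = {x for ai, aj in accepted for x in range(ai, aj + 1)}
    spans_out = sorted(accepted) + [(i, i) for i in range(k)
                                    if i not in covered]
    return [tuple(order[i:j + 1]) for i, j in sorted(spans_out)]


class TestSNK:
    def test_all_equal_means_one_subset(self):
        res = snk_test([0.5, 0.5, 0.5], 10, 0.01, 20)
        assert len(res.subsets) == 1
        assert set(res.subsets[0]) == {0, 1, 2}

    def test_overwhelming_separation_two_singletons(self):
        ms, n = 0.01, 10
        gap = 100 * (ms / n) ** 0.5
        res = snk_test([1.0, 1.0 + gap], n, ms, 20)
        assert len(res.subsets) == 2
        assert all(len(s) == 1 for s in res.subsets)

    def test_four_mean_case_matches_brute_force(self):
        means = [1.0, 0.99, 0.5, 0.1]
        res = snk_test(means, 25, 6.353e-03, 120, alpha=0.05,
                       labels=list(range(4)))
        expected = snk_brute_force(means, 25, 6.353e-03, 120, 0.05)
        assert [tuple(s) for s in res.subsets] == expected
        # sanity: the two top means are homogeneous at this error scale
        assert set(res.subsets[0]) == {0, 1}

    @given(st.lists(st.floats(0, 5), min_size=3, max_size=6), st.floats(0, 3))
    def test_shift_invariance(self, means, shift):
        base = snk_test(means, 10, 0.02, 30)
        shifted = snk_test([m + shift for m in means], 10, 0.02, 30)
        assert base.subsets == shifted.subsets

    def test_random_cases_match_brute_force(self, rng):
        for _ in range(25):
            k = int(rng.integers(3, 6))
            means = rng.normal(1.0, 0.2, k).tolist()
            res = snk_test(means, 12, 0.015, 33)
            assert [tuple(s) for s in res.subsets] == \
                snk_brute_force(means, 12, 0.015, 33, 0.05)

    def test_zero_error_groups_exact_ties(self):
        res = snk_test([0.3, 0.5, 0.5, 0.1], 5, 0.0, 10)
        assert [tuple(s) for s in res.subsets] == [(1, 2), (0,), (3,)]

    def test_subsets_are_contiguous_runs(self, rng):
        means = rng.normal(1.0, 0.5, 6)
        res = snk_test(means, 8, 0.05, 40)
        ordered = list(res.labels)
        for sub in res.subsets:
            idx = [ordered.index(l) for l in sub]
            assert idx == list(range(min(idx), max(idx) + 1))
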