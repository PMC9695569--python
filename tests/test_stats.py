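"""Box-Cox, balanced two-way ANOVA, Tukey HSD, compact letter display."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pspwedge import (BoxCoxSpec, TukeyComparison, boxcox, letter_display,
                      tukey_hsd, two_way_anova)
from pspwedge.errors import LayoutError

RNG = np.random.default_rng(8627)


class TestBoxCox:
    def test_fixed_point_at_one(self):
        for lam in (0.35, 0.5, 1.0, 2.0):
            assert boxcox(1.0, BoxCoxSpec(lam=lam)) == pytest.approx(0.0)

    def test_half_power_example(self):
        assert boxcox(9.0, BoxCoxSpec(lam=0.5)) == pytest.approx(4.0)

    def test_lambda_zero_limit_is_log(self):
        assert boxcox(5.0, BoxCoxSpec(lam=1e-8)) == pytest.approx(
            math.log(5.0), abs=1e-6)
        assert boxcox(5.0, BoxCoxSpec(lam=0.0)) == pytest.approx(math.log(5.0))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            boxcox(0.0, BoxCoxSpec(lam=0.5))
        with pytest.raises(ValueError):
            boxcox(-2.0, BoxCoxSpec(lam=0.5, shift=1.0))

    def test_shift_and_monotonicity(self):
        spec = BoxCoxSpec(lam=0.35, shift=1.0)
        xs = np.linspace(0.0, 10.0, 50)
        ys = boxcox(xs, spec)
        assert np.all(np.diff(ys) > 0)


def _layout(levels_a, levels_b, reps, values):
    rows = []
    it = iter(values)
    for a in levels_a:
        for b in levels_b:
            for _ in range(reps):
                rows.append({"A": a, "B": b, "y": next(it)})
    return pd.DataFrame(rows)


def _anova_oracle(df):
    """Brute-force mean decomposition for a balanced two-way layout."""
    grand = df["y"].mean()
    n = len(df)
    a_means = df.groupby("A")["y"].mean()
    b_means = df.groupby("B")["y"].mean()
    cell_means = df.groupby(["A", "B"])["y"].mean()
    n_a, n_b = len(a_means), len(b_means)
    reps = n // (n_a * n_b)
    ss_a = reps * n_b * sum((m - grand) ** 2 for m in a_means)
    ss_b = reps * n_a * sum((m - grand) ** 2 for m in b_means)
    ss_ab = reps * sum(
        (cell_means[(a, b)] - a_means[a] - b_means[b] + grand) ** 2
        for a in a_means.index for b in b_means.index)
    ss_res = sum(
        (row.y - cell_means[(row.A, row.B)]) ** 2
        for row in df.itertuples())
    return ss_a, ss_b, ss_ab, ss_res


class TestTwoWayAnova:
    def test_all_equal_observations(self):
        df = _layout([1, 2], [1, 2], 3, itertools.repeat(7.0))
        table = two_way_anova(df, "y", "A", "B")
        assert table.loc["A", "sum_sq"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["B", "sum_sq"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["A:B", "sum_sq"] == pytest.approx(0.0, abs=1e-12)

    def test_two_by_two_hand_oracle(self):
        # B flips the response by 2, A and the interaction do nothing
        df = _layout([1, 2], [1, 2], 2, iter([0, 0, 2, 2, 0, 0, 2, 2]))
        table = two_way_anova(df, "y", "A", "B")
        assert table.loc["B", "sum_sq"] == pytest.approx(8.0)
        assert table.loc["A", "sum_sq"] == pytest.approx(0.0, abs=1e-10)
        assert table.loc["A:B", "sum_sq"] == pytest.approx(0.0, abs=1e-10)
        assert table.loc["residual", "sum_sq"] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("n_a,n_b,reps", [(2, 2, 2), (3, 2, 4), (5, 6, 10)])
    def test_random_balanced_vs_oracle(self, n_a, n_b, reps):
        values = RNG.normal(10, 3, n_a * n_b * reps)
        df = _layout(range(n_a), range(n_b), reps, iter(values))
        table = two_way_anova(df, "y", "A", "B")
        ss_a, ss_b, ss_ab, ss_res = _anova_oracle(df)
        assert table.loc["A", "sum_sq"] == pytest.approx(ss_a, abs=1e-9)
        assert table.loc["B", "sum_sq"] == pytest.approx(ss_b, abs=1e-9)
        assert table.loc["A:B", "sum_sq"] == pytest.approx(ss_ab, abs=1e-9)
        assert table.loc["residual", "sum_sq"] == pytest.approx(ss_res, abs=1e-9)
        # df identity and F/p construction
        assert table["df"].sum() == len(df) - 1
        f = table.loc["A", "F"]
        p = sps.f.sf(f, table.loc["A", "df"], table.loc["residual", "df"])
        assert table.loc["A", "p"] == pytest.approx(p, rel=1e-9)

    def test_unbalanced_rejected(self):
        df = _layout([1, 2], [1, 2], 2, iter(RNG.normal(size=8)))
        with pytest.raises(LayoutError):
            two_way_anova(df.iloc[:-1], "y", "A", "B")

    def test_single_replicate_rejected(self):
        df = _layout([1, 2], [1, 2], 1, iter(RNG.normal(size=4)))
        with pytest.raises(LayoutError):
            two_way_anova(df, "y", "A", "B")


class TestTukeyHsd:
    def test_two_groups_equal_pooled_t_test(self):
        """With k = 2 the studentized range collapses to sqrt(2)|t| and
        the Tukey p equals the two-sided pooled t-test p."""
        for _ in range(20):
            g1 = RNG.normal(0, 1, 8)
            g2 = RNG.normal(0.8, 1, 8)
            ms = (g1.var(ddof=1) + g2.var(ddof=1)) / 2
            comps = tukey_hsd({"a": g1.mean(), "b": g2.mean()},
                              ms_residual=ms, df_residual=14, n_per_group=8)
            t, p_t = sps.ttest_ind(g1, g2, equal_var=True)
            assert comps[0].q == pytest.approx(math.sqrt(2) * abs(t), rel=1e-9)
            assert comps[0].p == pytest.approx(p_t, abs=1e-6)

    def test_matches_scipy_one_way_tukey(self):
        groups = [RNG.normal(m, 1.0, 6) for m in (0.0, 0.5, 2.0, 2.1)]
        ms = np.mean([g.var(ddof=1) for g in groups])
        df_res = 4 * (6 - 1)
        means = {i: g.mean() for i, g in enumerate(groups)}
        comps = tukey_hsd(means, ms, df_res, 6)
        ref = sps.tukey_hsd(*groups)
        for c in comps:
            assert c.p == pytest.approx(ref.pvalue[c.level_a, c.level_b],
                                        abs=1e-8)

    def test_identical_means_not_significant(self):
        comps = tukey_hsd({1: 5.0, 2: 5.0, 3: 5.0}, ms_residual=2.0,
                          df_residual=27, n_per_group=10)
        assert all(c.p == pytest.approx(1.0) for c in comps)
        assert not any(c.significant for c in comps)

    def test_separated_means_all_significant(self):
        comps = tukey_hsd({1: 0.0, 2: 50.0, 3: 100.0}, ms_residual=1e-6,
                          df_residual=27, n_per_group=10)
        assert all(c.significant for c in comps)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd({1: 0.0, 2: 1.0}, 1.0, 0, 5)


def _fake_comparisons(levels, sig_pairs):
    comps = []
    for a, b in itertools.combinations(levels, 2):
        sig = frozenset((a, b)) in sig_pairs
        comps.append(TukeyComparison(level_a=a, level_b=b, mean_diff=0.0,
                                     q=0.0, p=0.01 if sig else 0.5,
                                     significant=sig))
    return comps


def _check_cld(display, comps):
    for c in comps:
        shared = set(display[c.level_a]) & set(display[c.level_b])
        assert bool(shared) == (not c.significant), (
            f"{c.level_a} vs {c.level_b}: letters {display}")


class TestLetterDisplay:
    def test_all_pairs_significant(self):
        levels = [1, 2, 3]
        means = {1: 1.0, 2: 2.0, 3: 3.0}
        comps = _fake_comparisons(
            levels, {frozenset(p) for p in itertools.combinations(levels, 2)})
        display = letter_display(comps, means)
        assert [display[l] for l in levels] == ["A", "B", "C"]

    def test_no_pair_significant(self):
        levels = [1, 2, 3]
        comps = _fake_comparisons(levels, set())
        display = letter_display(comps, {1: 1.0, 2: 2.0, 3: 3.0})
        assert [display[l] for l in levels] == ["A", "A", "A"]

    def test_chain_pattern(self):
        # only the extremes differ: A / AB / B
        levels = [1, 2, 3]
        comps = _fake_comparisons(levels, {frozenset((1, 3))})
        display = letter_display(comps, {1: 1.0, 2: 2.0, 3: 3.0})
        assert [display[l] for l in levels] == ["A", "AB", "B"]

    def test_letters_follow_ascending_means(self):
        levels = ["x", "y", "z"]
        means = {"x": 9.0, "y": 1.0, "z": 5.0}
        comps = _fake_comparisons(
            levels, {frozenset(p) for p in itertools.combinations(levels, 2)})
        display = letter_display(comps, means)
        assert display == {"y": "A", "z": "B", "x": "C"}

    def test_share_letter_iff_not_significant_random_patterns(self):
        """CLD invariant on arbitrary significance patterns."""
        for trial in range(60):
            k = int(RNG.integers(2, 8))
            levels = list(range(k))
            means = {l: float(RNG.normal()) for l in levels}
            pairs = list(itertools.combinations(levels, 2))
            mask = RNG.random(len(pairs)) < 0.4
            sig = {frozenset(p) for p, m in zip(pairs, mask) if m}
            comps = _fake_comparisons(levels, sig)
            display = letter_display(comps, means)
            _check_cld(display, comps)

    def test_incomplete_comparisons_rejected(self):
        comps = _fake_comparisons([1, 2], set())
        with pytest.raises(ValueError):
            letter_display(comps, {1: 0.0, 2: 1.0, 3: 2.0})


class TestFormatP:
    def test_footnote_convention(self):
        from pspwedge.stats import format_p
        assert format_p(3e-7) == "<0.0001"
        assert format_p(0.0432) == "0.0432"
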