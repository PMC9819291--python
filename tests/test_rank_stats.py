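"""Rank statistics against closed forms and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from facit_mcid.rank_stats import (
    DegenerateDataError,
    chi_square,
    compare_groups,
    mann_whitney_u,
    spearman_rho,
    wilcoxon_signed_rank,
)


class TestSpearman:
    @pytest.mark.parametrize("x,y,rho", [
        ((1, 2, 3), (3, 2, 1), -1.0),
        ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),   # 1 - 6*2/(4*15)
        ((5, 1, 9, 2), (5, 1, 9, 2), 1.0),
    ])
    def test_known_rank_correlations(self, x, y, rho):
        assert spearman_rho(x, y).statistic == pytest.approx(rho)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    def test_exact_permutation_p_matches_enumeration(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = spearman_rho(x, y, p_mode="exact")
        # independent oracle: enumerate rho over all permutations of y
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        obs = np.corrcoef(rx, ry)[0, 1]
        count = sum(
            abs(np.corrcoef(rx, np.array(p))[0, 1]) >= abs(obs) - 1e-12
            for p in itertools.permutations(ry))
        assert res.p_value == pytest.approx(count / 720)

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_strictly_monotone_transforms(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=12)
        y = r.normal(size=12)
        base = spearman_rho(x, y)
        warped = spearman_rho(np.exp(x), 3.0 * y + 7.0)
        assert warped.statistic == pytest.approx(base.statistic)
        assert warped.p_value == pytest.approx(base.p_value)


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        assert mann_whitney_u([1, 2], [3, 4]).statistic == 0.0

    def test_identical_samples_sit_at_the_null_mean(self):
        a = [1.0, 2.0, 3.0]
        res = mann_whitney_u(a, a)
        assert res.statistic == pytest.approx(len(a) ** 2 / 2)

    def test_u_equals_bruteforce_pair_counting(self, rng):
        for _ in range(25):
            a = rng.integers(0, 8, size=rng.integers(2, 7)).astype(float)
            b = rng.integers(0, 8, size=rng.integers(2, 7)).astype(float)
            brute = sum((ai > bi) + 0.5 * (ai == bi) for ai in a for bi in b)
            assert mann_whitney_u(a, b).statistic == pytest.approx(brute)
        assert mann_whitney_u([1, 3], [2, 4]).statistic == 1.0

    def test_exact_and_normal_p_converge_without_ties(self, rng):
        # the discrete exact null makes the gap sizeable at tiny n; it
        # must shrink monotonically and be small by n = 12 per group
        medians = {}
        for n in (6, 9, 12):
            diffs = []
            for _ in range(120):
                a = rng.normal(size=n)
                b = rng.normal(size=n)
                pe = mann_whitney_u(a, b, method="exact").p_value
                pa = mann_whitney_u(a, b, method="asymptotic").p_value
                diffs.append(abs(pe - pa))
            medians[n] = np.median(diffs)
        assert medians[6] > medians[9] > medians[12]
        assert medians[12] < 0.03

    def test_null_rejection_rate_near_nominal_alpha(self):
        r = np.random.default_rng(7)
        rejections = sum(
            mann_whitney_u(r.normal(size=30), r.normal(size=30)).p_value < 0.05
            for _ in range(10_000))
        assert rejections / 10_000 == pytest.approx(0.05, abs=0.01)


class TestWilcoxonSignedRank:
    def test_statistic_is_positive_rank_sum(self):
        before = np.zeros(5)
        after = np.array([1.0, -2.0, 3.0, -4.0, 5.0])
        res = wilcoxon_signed_rank(before, after)
        assert res.statistic == 9.0          # ranks 1+3+5

    def test_all_positive_shifts_are_maximally_onesided(self):
        before = np.arange(8, dtype=float)
        after = before + np.arange(1.0, 9.0)       # distinct positive shifts
        res = wilcoxon_signed_rank(before, after, method="exact")
        # all signs positive: the two-sided exact p is 2/2^8
        assert res.p_value == pytest.approx(2 / 2 ** 8)

    def test_no_change_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_pratt_keeps_zeros_in_the_ranking(self):
        before = np.array([0.0, 0.0, 0.0, 0.0])
        after = np.array([0.0, 1.0, 2.0, 3.0])
        drop = wilcoxon_signed_rank(before, after, zero_method="wilcox")
        keep = wilcoxon_signed_rank(before, after, zero_method="pratt")
        assert drop.statistic == 6.0         # ranks 1+2+3 among nonzeros
        assert keep.statistic == 9.0         # ranks 2+3+4 with zero ranked 1


class TestChiSquare:
    def test_independent_table_scores_zero(self):
        assert chi_square([[10, 10], [10, 10]]).statistic == 0.0

    def test_perfect_association_equals_n(self):
        res = chi_square([[20, 0], [0, 20]])
        assert res.statistic == pytest.approx(40.0)

    def test_matches_closed_form_2x2(self):
        a, b, c, d = 44, 100, 35, 109
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi_square([[a, b], [c, d]]).statistic == pytest.approx(expected)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [5, 5]])


def test_compare_groups_emits_one_row_per_variable(default_cohort):
    table = compare_groups(default_cohort, "ild",
                           ["facit_fs_base", "chfs_base", "sex_female"])
    assert list(table["variable"]) == ["facit_fs_base", "chfs_base", "sex_female"]
    assert table["p_value"].between(0, 1).all()
    assert set(table["method"]).issuperset({"mwu-normal"})
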