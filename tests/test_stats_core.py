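"""From-scratch statistical kernels against brute force and independent
reference implementations."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from vocscreen.exceptions import ConstantInputError, InsufficientDataError, SingularFitError
from vocscreen.stats_core import (
    boxs_m,
    evans_strength,
    exact_u_null,
    mann_whitney,
    pearson,
    polyfit_f,
    spearman,
)


def brute_force_mw_p(x, y):
    """Independent oracle: enumerate all group assignments of the pooled
    sample and count arrangements at least as extreme as the observed U."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    u_obs = sum(a > b for a in x for b in y) + 0.5 * sum(a == b for a in x for b in y)
    us = []
    for comb in itertools.combinations(range(n), n1):
        xs = pooled[list(comb)]
        ys = pooled[[i for i in range(n) if i not in comb]]
        us.append(
            sum(a > b for a in xs for b in ys)
            + 0.5 * sum(a == b for a in xs for b in ys)
        )
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestExactNull:
    def test_single_observation_each(self):
        counts = exact_u_null(1, 1)
        assert list(counts) == [1, 1]

    def test_three_vs_three_lowest_arrangement(self):
        counts = exact_u_null(3, 3)
        assert counts.sum() == 20
        assert counts[0] == 1  # P(U=0) = 1/20

    def test_nine_vs_nine_total_mass(self):
        counts = exact_u_null(9, 9)
        assert counts.sum() == math.comb(18, 9) == 48_620

    def test_null_is_symmetric(self):
        counts = exact_u_null(4, 6)
        assert list(counts) == list(counts[::-1])

    def test_size_limit_refused_with_guidance(self):
        with pytest.raises(InsufficientDataError, match="normal approximation"):
            exact_u_null(13, 13)


class TestMannWhitney:
    def test_complete_separation_nine_vs_nine(self):
        res = mann_whitney(np.arange(9.0), np.arange(9.0) + 100.0)
        assert res.u_statistic == 0
        assert res.method == "exact"
        assert res.p_two_tailed == pytest.approx(2 / 48_620)
        assert res.p_one_tailed == pytest.approx(1 / 48_620)

    def test_identical_samples_are_null(self):
        x = np.arange(9.0)
        res = mann_whitney(x, x)
        assert res.u_statistic == 40.5  # n1*n2/2
        assert res.p_two_tailed == pytest.approx(1.0, abs=1e-6)

    def test_one_tailed_is_half_of_two_tailed_without_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(0.8, size=9)
            res = mann_whitney(x, y)
            assert res.p_two_tailed == pytest.approx(
                min(1.0, 2 * res.p_one_tailed)
            )

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 4), (5, 5), (6, 7), (7, 7)])
    def test_exact_p_equals_brute_force_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            x = rng.normal(size=n1)
            y = rng.normal(0.5, size=n2)
            res = mann_whitney(x, y)
            assert res.method == "exact"
            assert res.p_two_tailed == pytest.approx(brute_force_mw_p(x, y), abs=1e-12)

    def test_agrees_with_scipy_exact(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=9), rng.normal(0.7, size=9)
        res = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approx_with_ties_tracks_scipy(self):
        rng = np.random.default_rng(13)
        x = rng.integers(0, 4, size=15).astype(float)
        y = rng.integers(1, 5, size=18).astype(float)
        res = mann_whitney(x, y)
        assert res.method == "normal_approx"
        assert res.tie_correction_applied
        ref = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert res.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_pooled_sample_is_degenerate(self):
        res = mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.degenerate
        assert res.p_two_tailed == 1.0

    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=8),
        st.lists(st.floats(-100, 100), min_size=2, max_size=8),
    )
    @settings(max_examples=60, deadline=None)
    def test_u_complement_identity(self, xs, ys):
        x, y = np.array(xs), np.array(ys)
        u_xy = mann_whitney(x, y).u_statistic
        u_yx = mann_whitney(y, x).u_statistic
        assert u_xy + u_yx == pytest.approx(len(xs) * len(ys))


class TestCorrelation:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.strength == "very_strong"
        assert res.p_value < 1e-10

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=25), rng.normal(size=25)
        res = pearson(x, y)
        ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)
        rs = spearman(x, y)
        ref_s = sps.spearmanr(x, y)
        assert rs.r == pytest.approx(ref_s.statistic, rel=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=15), rng.normal(size=15)
        r0 = pearson(x, y).r
        assert pearson(3.2 * x + 7, 0.5 * y - 2).r == pytest.approx(r0, rel=1e-12)

    def test_large_sample_null_correlation_is_small(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        assert abs(pearson(x, y).r) < 0.05

    @pytest.mark.parametrize(
        "r,label",
        [
            (0.10, "very_weak"),
            (0.20, "weak"),
            (-0.45, "moderate"),
            (0.637, "strong"),
            (0.799, "strong"),
            (0.80, "very_strong"),
            (-0.945, "very_strong"),
        ],
    )
    def test_evans_bins_closed_on_the_left(self, r, label):
        assert evans_strength(r) == label

    def test_constant_input_rejected(self):
        with pytest.raises(ConstantInputError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPolyFit:
    def test_noiseless_quadratic_recovery(self):
        x = np.linspace(-2, 3, 12)
        y = 1.5 - 0.7 * x + 2.25 * x**2
        res = polyfit_f(x, y, degree=2)
        assert res.coefficients == pytest.approx((1.5, -0.7, 2.25), abs=1e-8)
        assert res.r == pytest.approx(1.0)

    def test_coefficients_equal_normal_equations_solution(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=14)
        y = rng.normal(size=14)
        for degree in (2, 3):
            res = polyfit_f(x, y, degree)
            design = np.vander(x, degree + 1, increasing=True)
            beta = np.linalg.solve(design.T @ design, design.T @ y)
            assert res.coefficients == pytest.approx(tuple(beta), rel=1e-8)

    def test_f_statistic_definition(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=18)
        y = 1 + x + 0.5 * x**2 + rng.normal(size=18)
        res = polyfit_f(x, y, degree=2)
        k, df2 = res.df
        assert (k, df2) == (2, 15)
        expected_f = (res.r_squared / k) / ((1 - res.r_squared) / df2)
        assert res.f_statistic == pytest.approx(expected_f)

    def test_saturated_cubic_interpolates(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        y = np.array([1.0, -1.0, 3.0, 0.5])
        res = polyfit_f(x, y, degree=3)
        assert res.r_squared == pytest.approx(1.0)

    def test_quadratic_r_dominates_pearson_r(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            x = rng.normal(size=18)
            y = rng.normal(size=18)
            assert polyfit_f(x, y, 2).r >= abs(pearson(x, y).r) - 1e-12

    def test_too_few_distinct_x_raises(self):
        with pytest.raises(SingularFitError):
            polyfit_f([1.0, 1.0, 2.0, 2.0, 1.0], [1.0, 2.0, 3.0, 4.0, 5.0], 2)


class TestBoxsM:
    def test_identical_groups_give_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 3))
        res = boxs_m([x, x.copy()])
        assert res.m_statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_two_variable_instance(self):
        # tiny instance evaluated by direct formula as an oracle
        a = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 5.0], [5.0, 4.0], [4.0, 1.0]])
        b = np.array([[0.0, 1.0], [1.0, 3.0], [4.0, 2.0], [6.0, 7.0], [3.0, 0.0]])
        s1, s2 = np.cov(a, rowvar=False), np.cov(b, rowvar=False)
        pooled = (4 * s1 + 4 * s2) / 8
        m_hand = 8 * np.log(np.linalg.det(pooled)) - 4 * (
            np.log(np.linalg.det(s1)) + np.log(np.linalg.det(s2))
        )
        res = boxs_m([a, b])
        assert res.m_statistic == pytest.approx(m_hand, rel=1e-10)
        assert res.df == 3

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(1)
        a = rng.normal(size=(20, 3))
        b = rng.normal(scale=1.6, size=(25, 3))
        res = boxs_m([a, b])
        df = pd.DataFrame(np.vstack([a, b]), columns=list("xyz"))
        df["g"] = ["a"] * 20 + ["b"] * 25
        ref = pg.box_m(df, dvs=list("xyz"), group="g")
        assert res.chi2_approx == pytest.approx(float(ref["Chi2"].iloc[0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)

    def test_invariant_under_common_linear_transform(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(15, 3))
        b = rng.normal(scale=2.0, size=(14, 3))
        t = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        res0 = boxs_m([a, b])
        res1 = boxs_m([a @ t, b @ t])
        assert res1.m_statistic == pytest.approx(res0.m_statistic, rel=1e-8)

    def test_group_smaller_than_dimension_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(InsufficientDataError):
            boxs_m([rng.normal(size=(3, 3)), rng.normal(size=(10, 3))])
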