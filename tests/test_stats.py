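"""Two-sample test machinery.

Frozen expected values were computed with scipy.stats (ttest_ind with and
without equal_var) before the implementation was written; the exact
Mann–Whitney path is checked against literal enumeration of every group
assignment, which is a different algorithm from the count recurrence the
implementation uses.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from cladediv import (
    DegenerateSampleError,
    SampleSizeError,
    mann_whitney_u,
    run_all_tests,
    student_t_test,
    welch_t_test,
)


def brute_force_u_pvalue(x, y):
    """Two-sided exact Mann–Whitney p by enumerating all C(n1+n2, n1)
    assignments of the pooled tie-free values to the first group."""
    pooled = list(x) + list(y)
    n1 = len(x)
    idx = range(len(pooled))
    u_obs = sum(1 for a in x for b in y if a > b)
    center2 = n1 * (len(pooled) - n1)
    obs_dev = abs(2 * u_obs - center2)
    hits = total = 0
    for combo in itertools.combinations(idx, n1):
        chosen = set(combo)
        u = sum(
            1
            for i in combo
            for j in idx
            if j not in chosen and pooled[i] > pooled[j]
        )
        total += 1
        if abs(2 * u - center2) >= obs_dev:
            hits += 1
    return hits / total


class TestStudent:
    def test_identical_samples(self):
        r = student_t_test([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "x,y,t,df,p",
        [
            ([1, 2, 3, 4], [2, 3, 4, 5], -1.0954451150103321, 6.0,
             0.3153335962012299),
            ([0.1, 0.2], [0.4, 0.6], -3.130495168499706, 2.0,
             0.08867762313423291),
        ],
    )
    def test_frozen_worked_examples(self, x, y, t, df, p):
        r = student_t_test(x, y)
        assert r.statistic == pytest.approx(t, abs=1e-10)
        assert r.df == df
        assert r.p_value == pytest.approx(p, abs=1e-10)

    def test_zero_pooled_variance(self):
        with pytest.raises(DegenerateSampleError):
            student_t_test([1.0, 1.0], [1.0, 1.0])

    def test_sample_too_small(self):
        with pytest.raises(SampleSizeError):
            student_t_test([1.0], [1.0, 2.0])


class TestWelch:
    def test_reduces_to_student_for_equal_n_and_var(self):
        s = student_t_test([1, 2, 3, 4], [2, 3, 4, 5])
        w = welch_t_test([1, 2, 3, 4], [2, 3, 4, 5])
        assert w.statistic == pytest.approx(s.statistic, abs=1e-12)
        assert w.df == pytest.approx(s.df, abs=1e-12)

    def test_unequal_variances_shrink_df(self):
        s = student_t_test([0, 0, 0, 10], [2, 2, 2, 2.001])
        w = welch_t_test([0, 0, 0, 10], [2, 2, 2, 2.001])
        assert w.df < s.df

    def test_frozen_worked_example(self):
        r = welch_t_test([0.1, 0.2], [0.4, 0.6])
        assert r.statistic == pytest.approx(-3.130495168499706, abs=1e-10)
        assert r.df == pytest.approx(1.470588235294118, abs=1e-10)
        assert r.p_value == pytest.approx(0.1290478355482833, abs=1e-10)

    def test_identical_samples(self):
        r = welch_t_test([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0 and r.p_value == pytest.approx(1.0)

    def test_matches_scipy_on_random_samples(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            x = rng.exponential(0.1, rng.integers(3, 20))
            y = rng.exponential(0.2, rng.integers(3, 20))
            mine = welch_t_test(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert mine.statistic == pytest.approx(float(ref.statistic), abs=1e-10)
            assert mine.p_value == pytest.approx(float(ref.pvalue), abs=1e-10)


class TestMannWhitney:
    def test_exact_small_separated(self):
        r = mann_whitney_u([1, 2], [3, 4])
        assert r.statistic == 0.0
        assert r.method == "exact"
        assert r.p_value == pytest.approx(2 / 6, abs=1e-12)

    def test_exact_three_vs_three(self):
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.1, abs=1e-12)

    def test_ties_force_approximation(self):
        r = mann_whitney_u([1, 1, 2], [1, 2, 2])
        assert r.method == "normal_approx"
        assert 0 < r.p_value <= 1

    def test_identical_tied_samples_give_p_one(self):
        r = mann_whitney_u([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert r.p_value == 1.0

    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(99)
        for _ in range(60):
            n1 = int(rng.integers(2, 8))
            n2 = int(rng.integers(2, 8))
            pooled = rng.permutation(np.arange(1, n1 + n2 + 1)).astype(float)
            x, y = pooled[:n1], pooled[n1:]
            mine = mann_whitney_u(x, y)
            assert mine.method == "exact"
            assert mine.p_value == pytest.approx(
                brute_force_u_pvalue(x, y), abs=1e-12
            )

    def test_large_samples_use_approximation(self):
        rng = np.random.default_rng(4)
        r = mann_whitney_u(rng.normal(size=20), rng.normal(size=20))
        assert r.method == "normal_approx"

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = np.round(rng.exponential(1.0, 15), 1)
            y = np.round(rng.exponential(1.5, 18), 1)
            mine = mann_whitney_u(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic")
            assert mine.statistic == pytest.approx(float(ref.statistic))
            assert mine.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)


class TestPanelProperties:
    def test_antisymmetry(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            x = rng.exponential(0.1, int(rng.integers(3, 12)))
            y = rng.exponential(0.3, int(rng.integers(3, 12)))
            fwd = run_all_tests(x, y)
            rev = run_all_tests(y, x)
            for f, r in zip(fwd, rev):
                if f.name == "mann_whitney_u":
                    assert r.statistic == pytest.approx(
                        f.n1 * f.n2 - f.statistic, abs=1e-9
                    )
                else:
                    assert r.statistic == pytest.approx(-f.statistic, abs=1e-12)
                assert r.p_value == pytest.approx(f.p_value, abs=1e-12)

    def test_fixed_order_and_names(self):
        res = run_all_tests([1, 2, 3], [2, 3, 4])
        assert [r.name for r in res] == ["student_t", "welch_t", "mann_whitney_u"]

    def test_partial_degeneracy_keeps_u(self):
        res = run_all_tests([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert res[0].error is not None and res[1].error is not None
        assert res[2].error is None and res[2].p_value == 1.0

    def test_p_decreases_with_location_shift(self):
        rng = np.random.default_rng(21)
        base = rng.exponential(0.1, 20)
        prev = {name: 1.1 for name in ("student_t", "welch_t", "mann_whitney_u")}
        for shift in (0.01, 0.05, 0.1, 0.3, 0.6):
            for r in run_all_tests(base, base + shift):
                assert r.p_value <= prev[r.name] + 1e-9
                prev[r.name] = r.p_value

    def test_p_display_floor(self):
        r = student_t_test(np.arange(50.0), np.arange(100.0, 150.0))
        assert r.p_value < 1e-15
        assert r.p_display == "< 1e-15"
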