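import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import facefat as ff
from facefat import io as fio


class TestPearson:
    def test_perfect_line(self):
        r, r2 = ff.pearson([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_near_linear(self):
        r, r2 = ff.pearson([1, 2, 3], [2, 4, 7])
        assert r == pytest.approx(0.99340, abs=1e-5)
        # independent route: normalised covariance computed directly
        x, y = np.array([1, 2, 3.0]), np.array([2, 4, 7.0])
        direct = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert r == pytest.approx(direct, abs=1e-12)
        assert r2 == pytest.approx(r * r, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ff.pearson([1, 2, 3], [5, 5, 5])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ff.pearson([1, 2, 3], [1, 2])

    @settings(derandomize=True, max_examples=100)
    @given(
        data=st.lists(
            st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
            min_size=3, max_size=30,
        ),
        scale=st.floats(0.01, 50),
        shift=st.floats(-100, 100),
    )
    def test_symmetry_and_affine_invariance(self, data, scale, shift):
        x = np.array([p[0] for p in data])
        y = np.array([p[1] for p in data])
        if np.ptp(x) < 1e-6 or np.ptp(y) < 1e-6:
            return
        r_xy, _ = ff.pearson(x, y)
        r_yx, _ = ff.pearson(y, x)
        assert r_xy == pytest.approx(r_yx, abs=1e-9)
        r_aff, _ = ff.pearson(scale * x + shift, y)
        assert r_aff == pytest.approx(r_xy, abs=1e-6)
        r_neg, _ = ff.pearson(-x, y)
        assert r_neg == pytest.approx(-r_xy, abs=1e-9)

    def test_r2_equals_ols_coefficient_of_determination(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.uniform(-5, 5, 25)
            y = 2 * x + rng.normal(0, 3, 25)
            _, r2 = ff.pearson(x, y)
            slope, intercept, resid = ff.regress_line(x, y)
            ss_res = float(np.sum(resid**2))
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            assert r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-9)


class TestRegressLine:
    def test_exact_line(self):
        slope, intercept, resid = ff.regress_line([0, 1, 2], [1, 3, 5])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert np.allclose(resid, 0)

    def test_three_point_closed_form(self):
        slope, intercept, _ = ff.regress_line([0, 1, 2], [0, 0, 3])
        assert slope == pytest.approx(1.5)
        assert intercept == pytest.approx(-0.5)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 40)
        y = rng.uniform(0, 1, 40)
        _, _, resid = ff.regress_line(x, y)
        assert float(resid.sum()) == pytest.approx(0.0, abs=1e-9)


class TestSlopeTTest:
    def test_zero_correlation(self):
        t, p = ff.slope_t_test(0.0, 50)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_study_size_formula(self):
        # r² = 0.77 at n = 106 under t = r·sqrt(n−2)/sqrt(1−r²)
        t, p = ff.slope_t_test(np.sqrt(0.77), 106)
        assert t == pytest.approx(18.66, abs=0.01)
        assert p < 1e-6

    def test_three_point_tail(self):
        t, p = ff.slope_t_test(0.9934, 3)
        assert t == pytest.approx(8.66, abs=0.01)
        assert p == pytest.approx(0.0732, abs=5e-4)

    def test_perfect_correlation(self):
        t, p = ff.slope_t_test(1.0, 10)
        assert t == np.inf and p == 0.0
        t, p = ff.slope_t_test(-1.0, 10)
        assert t == -np.inf and p == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            ff.slope_t_test(0.5, 2)


def trim_oracle(x, y, k):
    """Enumerate all k-subsets; remove the one with the largest total
    |residual| from an independently computed OLS line; refit with polyfit."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    coeffs = np.polyfit(x, y, 1)
    resid = np.abs(y - np.polyval(coeffs, x))
    best = max(
        itertools.combinations(range(len(x)), k),
        key=lambda s: sum(resid[i] for i in s),
    )
    keep = [i for i in range(len(x)) if i not in best]
    return float(np.corrcoef(x[keep], y[keep])[0, 1] ** 2)


class TestTrimAndRefit:
    def test_zero_fraction_identity(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 30)
        y = x + rng.normal(0, 0.2, 30)
        res = ff.trim_and_refit(x, y, 0.0)
        assert res.n_removed == 0
        assert res.r2_after == res.r2_before

    def test_single_outlier_removal_saturates(self):
        x = np.arange(11.0)
        y = 2 * x + 1
        y[5] += 40.0  # gross outlier on an otherwise perfect line
        res = ff.trim_and_refit(x, y, 0.1)
        assert res.n_removed == 1
        assert res.r2_after == pytest.approx(1.0, abs=1e-12)
        assert res.r2_before < 0.9

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(8, 21))
            x = rng.uniform(0, 10, n)
            y = 1.5 * x + rng.normal(0, 2, n)
            frac = float(rng.uniform(0.05, 0.3))
            k = int(np.floor(frac * n))
            if n - k < 3 or k == 0:
                continue
            res = ff.trim_and_refit(x, y, frac)
            assert res.n_removed == k
            assert res.r2_after == pytest.approx(trim_oracle(x, y, k), abs=1e-9)

    def test_too_few_survivors(self):
        with pytest.raises(ValueError):
            ff.trim_and_refit([1, 2, 3], [1, 2, 4], 0.5)


class TestAssociateAll:
    def test_exact_linear_cohort(self, noise_free_run):
        cohort, contours = noise_free_run
        geometry = ff.characterize_cohort(contours)
        results = ff.associate_all(fio.cohort_frame(cohort), geometry)
        assert {r.parameter_name for r in results} == set(ff.PARAMETERS)
        for res in results:
            assert res.r2 == pytest.approx(1.0, abs=1e-9)
            assert res.significant

    def test_default_cohort_all_significant_negative(self, default_run):
        """Every parameter falls with a: negative slope, p << 0.001."""
        cohort, _, geometry = default_run
        results = ff.associate_all(
            fio.cohort_frame(cohort), geometry, trim_fractions=(0.10,)
        )
        for res in results:
            assert res.slope < 0
            assert np.sign(res.slope) == np.sign(res.r)
            assert res.p_value < 0.001
            assert res.n == 106
            assert res.trims[0].n_removed == 10

    def test_gate_filters_rows(self, default_run):
        cohort, _, geometry = default_run
        geometry = geometry.copy()
        geometry.loc[geometry.index[:50], "passes_gate"] = False
        results = ff.associate_all(fio.cohort_frame(cohort), geometry, gate=True)
        assert all(res.n == 56 for res in results)

    def test_empty_join_rejected(self, default_run):
        cohort, _, geometry = default_run
        geometry = geometry.copy()
        geometry["subject_id"] = "X" + geometry["subject_id"]
        with pytest.raises(ValueError):
            ff.associate_all(fio.cohort_frame(cohort), geometry)
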