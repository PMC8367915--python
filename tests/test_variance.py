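"""Variance engine: covariance construction, closed forms, brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crtmiss import (
    CorrelationStructure,
    build_cluster_covariance,
    decayed_correlation,
    information_matrix,
    make_design,
    variance_treatment_effect,
)
from crtmiss.design import DesignError
from crtmiss.variance import _cluster_information

from conftest import brute_force_variance


class TestDecayedCorrelation:
    @pytest.mark.parametrize(
        "rho, r, g, expected",
        [
            (0.05, 0.9, 1, 0.045),
            (0.05, 0.9, 2, 0.0405),
            (0.05, 0.9, 0, 0.05),
        ],
    )
    def test_worked_values(self, rho, r, g, expected):
        assert decayed_correlation(rho, r, g) == pytest.approx(expected, abs=1e-12)

    @given(
        rho=st.floats(0, 1),
        g=st.integers(0, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_compound_symmetry_ignores_lag(self, rho, g):
        assert decayed_correlation(rho, 1.0, g) == pytest.approx(rho)

    def test_negative_lag_rejected(self):
        with pytest.raises(DesignError):
            decayed_correlation(0.05, 0.9, -1)


class TestClusterCovariance:
    def test_two_consecutive_days_single_subject(self, corr_decay):
        design = make_design("Mo,Tu", 1, 5, 1)
        V = build_cluster_covariance(design, corr_decay)
        np.testing.assert_allclose(V, [[1.0, 0.045], [0.045, 1.0]], atol=1e-12)

    def test_single_period_compound_symmetry(self):
        design = make_design("Mo,Tu", 1, 5, 2)
        corr = CorrelationStructure(rho=0.3, r=1.0)
        V = build_cluster_covariance(design, corr, n_obs_periods=1)
        np.testing.assert_allclose(V, [[1.0, 0.3], [0.3, 1.0]], atol=1e-12)

    def test_cross_period_lag_is_calendar_days_not_period_index(self, corr_decay):
        # Tu and Th of scheme (Mo,Tu,Th) are adjacent periods but two days apart.
        design = make_design("Mo,Tu,Th", 1, 5, 1)
        V = build_cluster_covariance(design, corr_decay)
        assert V[1, 2] == pytest.approx(0.05 * 0.9**2, abs=1e-12)
        assert V[0, 2] == pytest.approx(0.05 * 0.9**3, abs=1e-12)

    def test_out_of_range_periods_rejected(self, corr_decay):
        design = make_design("Mo,Tu", 1, 5, 1)
        with pytest.raises(DesignError):
            build_cluster_covariance(design, corr_decay, n_obs_periods=3)


class TestInformationMatrix:
    def test_independence_gives_ols_counts(self):
        design = make_design("Mo,Tu,We,Th,Fr,Sa,Su", 1, 5, 4)
        corr = CorrelationStructure(rho=0.0)
        info = information_matrix(design, corr, arm=1)
        # OLS: period diagonal k*m, treatment diagonal k*m*T.
        np.testing.assert_allclose(np.diag(info)[:-1], 5 * 4, atol=1e-10)
        assert info[-1, -1] == pytest.approx(5 * 4 * 7, abs=1e-10)

    def test_truncation_to_first_period_only(self, example_corr):
        design = make_design("Mo,Tu,We", 1, 5, 2)
        weights = np.array([5.0, 0.0, 0.0])
        info = information_matrix(design, example_corr, 0, weights)
        assert info[0, 0] > 0
        assert np.all(info[1:, :] == 0) and np.all(info[:, 1:] == 0)

    def test_information_linear_in_fractional_weights(self, example_corr):
        design = make_design("Mo,We,Fr", 2, 4, 3)
        T = design.n_periods
        w1 = np.zeros(T); w1[-1] = 4.0
        w2 = np.zeros(T); w2[1] = 4.0
        mixed = 0.25 * w1 + 0.75 * w2
        expected = 0.25 * information_matrix(design, example_corr, 1, w1) \
            + 0.75 * information_matrix(design, example_corr, 1, w2)
        np.testing.assert_allclose(
            information_matrix(design, example_corr, 1, mixed), expected, atol=1e-10
        )

    def test_invalid_weights_rejected(self, example_corr):
        design = make_design("Mo,Tu", 1, 5, 2)
        with pytest.raises(DesignError, match="negative"):
            information_matrix(design, example_corr, 0, np.array([-1.0, 6.0]))
        with pytest.raises(DesignError, match="sum"):
            information_matrix(design, example_corr, 0, np.array([1.0, 1.0]))


class TestVarianceClosedForms:
    def test_independence_closed_form(self):
        design = make_design("Mo,Tu,We,Th,Fr,Sa,Su", 1, 5, 4)
        corr = CorrelationStructure(rho=0.0, r=0.5)
        var = variance_treatment_effect(design, corr)
        assert var == pytest.approx(2 / (5 * 4 * 7), abs=1e-10)

    def test_compound_symmetry_random_intercept_form(self):
        design = make_design("Mo,Tu,We,Th,Fr,Sa,Su", 1, 5, 2)
        corr = CorrelationStructure(rho=0.05, r=1.0)
        var = variance_treatment_effect(design, corr)
        expected = 2 * (0.05 + 0.95 / (2 * 7)) / 5
        assert var == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.0471429, abs=1e-7)

    def test_single_period_design_effect(self):
        # One measurement period: classical design-effect formula
        # 2(1+(m-1)rho)/(k m); exercised through the per-cluster information
        # reduction since public designs require two periods.
        k, m, rho = 5, 10, 0.05
        corr = CorrelationStructure(rho=rho)
        info = np.zeros((2, 2))
        for arm in (0, 1):
            info += k * _cluster_information(
                np.array([1.0]), np.array([0]), 1, m, corr, arm
            )
        var = np.linalg.inv(info)[-1, -1]
        assert var == pytest.approx(2 * (1 + (m - 1) * rho) / (k * m), abs=1e-10)
        assert var == pytest.approx(0.058, abs=1e-12)

    def test_unobserved_period_reported_singular(self, example_corr):
        design = make_design("Mo,Tu,We", 1, 5, 2)
        w = np.array([0.0, 5.0, 0.0])  # periods 3 never observed in either arm
        with pytest.raises(DesignError, match="period"):
            variance_treatment_effect(design, example_corr, (w, w))


class TestBruteForceOracle:
    """Period-level information reduction vs explicit full-stack GLS."""

    @pytest.mark.parametrize(
        "scheme, weeks, m",
        [
            ("Mo,Tu,We,Th,Fr,Sa,Su", 1, 4),
            ("Mo,Tu,We,Th,Fr", 2, 3),
            ("Mo,Tu,Th", 2, 5),
            ("Mo,Th", 4, 2),
        ],
    )
    def test_complete_data_matches_full_stack(self, scheme, weeks, m, example_corr):
        design = make_design(scheme, weeks, 3, m)
        assert design.subjects * design.n_periods <= 30
        var = variance_treatment_effect(design, example_corr)
        assert var == pytest.approx(
            brute_force_variance(design, example_corr), abs=1e-10
        )

    def test_dropout_truncation_matches_full_stack(self, example_corr):
        design = make_design("Mo,Tu,We,Th,Fr", 1, 3, 2)
        n_obs = ([5, 3, 1], [5, 5, 2])
        weights = []
        for arm_obs in n_obs:
            w = np.zeros(design.n_periods)
            for h in arm_obs:
                w[h - 1] += 1.0
            weights.append(w)
        var = variance_treatment_effect(design, example_corr, tuple(weights))
        assert var == pytest.approx(
            brute_force_variance(design, example_corr, n_obs), abs=1e-10
        )


class TestVarianceMonotonicity:
    def test_halved_by_doubling_clusters(self, example_corr):
        d1 = make_design("Mo,Tu,We,Th,Fr", 2, 5, 3)
        d2 = make_design("Mo,Tu,We,Th,Fr", 2, 10, 3)
        assert variance_treatment_effect(d2, example_corr) == pytest.approx(
            variance_treatment_effect(d1, example_corr) / 2, rel=1e-12
        )

    def test_nonincreasing_in_m_and_weeks(self, example_corr):
        base = [
            variance_treatment_effect(
                make_design("Mo,Tu,We,Th,Fr", 2, 5, m), example_corr
            )
            for m in (1, 2, 4, 8)
        ]
        assert all(a >= b for a, b in zip(base, base[1:]))
        by_weeks = [
            variance_treatment_effect(
                make_design("Mo,Tu,We,Th,Fr", R, 5, 2), example_corr
            )
            for R in (1, 2, 4, 8)
        ]
        assert all(a >= b for a, b in zip(by_weeks, by_weeks[1:]))

    def test_nondecreasing_in_rho_nonincreasing_in_decay(self):
        design = make_design("Mo,Tu,We,Th,Fr", 2, 5, 2)
        by_rho = [
            variance_treatment_effect(design, CorrelationStructure(rho, 0.95))
            for rho in (0.0, 0.025, 0.05, 0.1)
        ]
        assert all(a <= b for a, b in zip(by_rho, by_rho[1:]))
        # larger decay 1-r (smaller r) lowers between-period correlation and
        # with it the variance
        by_decay = [
            variance_treatment_effect(design, CorrelationStructure(0.05, r))
            for r in (1.0, 0.95, 0.9, 0.8)
        ]
        assert all(a >= b for a, b in zip(by_decay, by_decay[1:]))
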