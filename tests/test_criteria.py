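"""Unit and property tests for the evidence criteria."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ortho_group

from evidence_bench.criteria import (
    GaussianBelief,
    NotPositiveDefiniteError,
    accuracy,
    aic,
    aicc,
    bayes_factor,
    bic,
    complexity,
    laplace_free_energy,
)

LOG2PI = math.log(2 * math.pi)


class TestAccuracy:
    @pytest.mark.parametrize("e, C, expected", [
        ([0.0], [1.0], -0.5 * LOG2PI),
        ([1.0, 1.0], np.eye(2), -1.0 - LOG2PI),
    ])
    def test_hand_values(self, e, C, expected):
        assert accuracy(e, C) == pytest.approx(expected, abs=1e-12)

    def test_noise_scaling_shifts_by_half_logdet(self):
        """Scaling C_y by 4 with zero residual adds -0.5 log(4^n)."""
        e = np.zeros(5)
        C = np.diag(np.arange(1.0, 6.0))
        delta = accuracy(e, 4.0 * C) - accuracy(e, C)
        assert delta == pytest.approx(-0.5 * 5 * math.log(4.0), abs=1e-12)

    def test_singular_noise_rejected(self):
        with pytest.raises(NotPositiveDefiniteError):
            accuracy([1.0, 1.0], np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            accuracy([1.0, 2.0], np.eye(2), n=3)


class TestComplexity:
    def test_posterior_equal_prior_is_free(self):
        """No divergence from the prior means no complexity penalty."""
        C = np.array([[2.0, 0.3], [0.3, 1.0]])
        cp, ch = complexity(np.zeros(2), C, C)
        assert cp == pytest.approx(0.0, abs=1e-12)
        assert ch == 0.0

    def test_unit_deviation_hand_value(self):
        cp, _ = complexity([1.0], [1.0], [1.0])
        assert cp == pytest.approx(0.5, abs=1e-12)

    def test_shrinking_posterior_raises_occam_factor(self):
        """Halving every posterior eigenvalue strictly increases complexity."""
        rng = np.random.default_rng(7)
        A = rng.standard_normal((4, 4))
        S = A @ A.T + 4 * np.eye(4)
        C = np.eye(4) * 3.0
        e = rng.standard_normal(4)
        base, _ = complexity(e, C, S)
        shrunk, _ = complexity(e, C, 0.5 * S)
        assert shrunk > base

    def test_rotation_invariance(self):
        """Jointly rotating deviation and covariances leaves complexity fixed."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            d = int(rng.integers(2, 6))
            e = rng.standard_normal(d)
            A = rng.standard_normal((d, d))
            C = A @ A.T + d * np.eye(d)
            B = rng.standard_normal((d, d))
            S = B @ B.T + d * np.eye(d)
            R = ortho_group.rvs(d, random_state=int(rng.integers(2**31)))
            cp0, _ = complexity(e, C, S)
            cp1, _ = complexity(R @ e, R @ C @ R.T, R @ S @ R.T)
            assert cp1 == pytest.approx(cp0, rel=1e-9)

    @pytest.mark.parametrize("r, s1, s2", [
        (0.0, 1.0, 1.0), (0.5, 2.0, 0.3), (-0.9, 0.7, 1.4), (0.99, 3.0, 3.0),
    ])
    def test_correlated_pair_determinant(self, r, s1, s2):
        """|S| of a correlated 2x2 posterior is (1-r^2) s1^2 s2^2, so the
        Occam factor grows with posterior correlation."""
        S = np.array([[s1**2, r * s1 * s2], [r * s1 * s2, s2**2]])
        assert np.linalg.det(S) == pytest.approx((1 - r**2) * s1**2 * s2**2,
                                                 rel=1e-12)
        C = np.eye(2) * 4.0
        cp, _ = complexity(np.zeros(2), C, S)
        expected = 0.5 * (math.log(16.0) - math.log((1 - r**2) * s1**2 * s2**2))
        assert cp == pytest.approx(expected, rel=1e-9)

    def test_hyper_terms_zero_when_absent(self):
        cp, ch = complexity([1.0], [2.0], [1.0])
        assert ch == 0.0
        with pytest.raises(ValueError):
            complexity([1.0], [2.0], [1.0], C_lambda=[1.0])


class TestFreeEnergy:
    def test_no_fit_no_penalty(self):
        """Zero residuals with posterior = prior leaves only -n/2 log 2 pi."""
        n = 7
        bd = laplace_free_energy(np.zeros(n), np.ones(n), n,
                                 np.zeros(2), np.eye(2), np.eye(2))
        assert bd.f_l == pytest.approx(-0.5 * n * LOG2PI, abs=1e-12)

    def test_identity_is_exact(self):
        rng = np.random.default_rng(0)
        bd = laplace_free_energy(
            rng.standard_normal(6), np.full(6, 0.5), 6,
            rng.standard_normal(3), np.eye(3) * 2, np.eye(3) * 0.3,
            e_lambda=[0.2], C_lambda=[1.0], S_lambda=[0.4])
        assert bd.f_l == bd.accuracy - bd.complexity_params - bd.complexity_hypers

    def test_region_accuracies_sum_to_total(self):
        rng = np.random.default_rng(1)
        e = rng.standard_normal(10)
        C = rng.uniform(0.5, 2.0, 10)
        regions = {"a": np.arange(4), "b": np.arange(4, 10)}
        bd = laplace_free_energy(e, C, 10, np.zeros(2), np.eye(2), np.eye(2),
                                 region_index=regions)
        assert sum(bd.accuracy_by_region.values()) == pytest.approx(bd.accuracy,
                                                                    rel=1e-12)

    def test_set_complexities_exact_for_block_posteriors(self):
        """When the posterior has no cross-set correlation the per-set
        decomposition is exact."""
        rng = np.random.default_rng(2)
        e = rng.standard_normal(4)
        C = np.diag(rng.uniform(1, 3, 4))
        S = np.diag(rng.uniform(0.1, 1, 4))
        sets = {"u": np.arange(2), "v": np.arange(2, 4)}
        bd = laplace_free_energy(np.zeros(3), np.ones(3), 3, e, C, S,
                                 param_sets=sets)
        assert sum(bd.complexity_by_set.values()) == pytest.approx(
            bd.complexity_params, rel=1e-12)

    def test_non_partition_rejected(self):
        with pytest.raises(ValueError):
            laplace_free_energy(np.zeros(4), np.ones(4), 4,
                                np.zeros(1), [1.0], [1.0],
                                region_index={"a": [0, 1], "b": [1, 2, 3]})

    def test_serialises_flat(self):
        bd = laplace_free_energy(np.zeros(2), np.ones(2), 2,
                                 np.zeros(1), [1.0], [0.5],
                                 region_index={"r0": [0, 1]})
        rec = bd.to_record()
        assert {"f_l", "accuracy", "complexity_params",
                "complexity_hypers", "accuracy_region_r0"} <= rec.keys()
        assert rec["decomposition"] == "approximate"


class TestInformationCriteria:
    @pytest.mark.parametrize("acc, p, expected", [(-50.0, 0, -50.0),
                                                  (-50.0, 4, -54.0)])
    def test_aic(self, acc, p, expected):
        assert aic(acc, p) == expected

    def test_bic_hand_value(self):
        assert bic(-50.0, 4, 100) == pytest.approx(-50 - 2 * math.log(100))
        assert bic(-50.0, 0, 1000) == -50.0

    def test_bic_penalty_exceeds_aic_for_large_n(self):
        # log n > 2 once n > e^2 ~ 7.39
        for n in (8, 100, 10000):
            assert bic(0.0, 3, n) < aic(0.0, 3)

    def test_aicc_hand_value(self):
        assert aicc(-50.0, 4, 20) == pytest.approx(-54 - 20 / 15)
        assert aicc(-50.0, 0, 20) == aic(-50.0, 0)

    def test_aicc_approaches_aic(self):
        gaps = [aic(0.0, 4) - aicc(0.0, 4, n) for n in (10, 100, 10000)]
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] == pytest.approx(0.0, abs=1e-2)

    def test_aicc_invalid_regime_raises(self):
        with pytest.raises(ValueError):
            aicc(-50.0, 4, 5)

    def test_negative_p_rejected(self):
        for fn in (lambda: aic(0.0, -1), lambda: bic(0.0, -1, 10),
                   lambda: aicc(0.0, -1, 10), lambda: bic(0.0, 1, 0)):
            with pytest.raises(ValueError):
                fn()


class TestBayesFactor:
    def test_decision_threshold(self):
        res = bayes_factor(math.log(20.0), 0.0)
        assert res.bf == pytest.approx(20.0)
        assert res.posterior_prob_1 > 0.95
        assert round(res.log_bf) == 3

    def test_equal_evidence_is_even_odds(self):
        assert bayes_factor(-12.3, -12.3).posterior_prob_1 == pytest.approx(0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(-1e6, 1e6), b=st.floats(-1e6, 1e6))
    def test_antisymmetry(self, a, b):
        assert bayes_factor(a, b).log_bf == -bayes_factor(b, a).log_bf

    def test_extreme_evidence_does_not_overflow(self):
        res = bayes_factor(0.0, -5000.0)
        assert res.posterior_prob_1 == pytest.approx(1.0)
        assert np.isinf(res.bf)


class TestGaussianBelief:
    def test_validation(self):
        with pytest.raises(ValueError):
            GaussianBelief(np.zeros(2), np.array([[1.0, 0.5], [0.0, 1.0]]))
        with pytest.raises(NotPositiveDefiniteError):
            GaussianBelief(np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_zero_variance_encodes_fixed_parameter(self):
        b = GaussianBelief(np.array([1.0, 2.0]), np.diag([0.0, 1.0]))
        assert b.sd[0] == 0.0

    def test_credible_interval_covers_mean(self):
        b = GaussianBelief(np.array([3.0]), np.array([[4.0]]))
        lo, hi = b.credible_interval(0.95)
        assert lo[0] == pytest.approx(3 - 1.96 * 2, abs=1e-2)
        assert hi[0] == pytest.approx(3 + 1.96 * 2, abs=1e-2)
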