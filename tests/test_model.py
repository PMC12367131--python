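"""Generative-model layer: reparametrisations, simulation, containers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hmfc.model import (
    HyperParams,
    SubjectData,
    SubjectParams,
    derive_alpha,
    derive_intercept,
    draw_subject_params,
    sigmoid,
    simulate_ar1,
    simulate_hierarchical_dataset,
    simulate_subject,
    truncnorm_mean,
)


class TestSigmoid:
    def test_symmetry_point(self):
        assert sigmoid(0.0) == 0.5

    @given(st.floats(-600, 600))
    @settings(derandomize=True, deadline=None)
    def test_complementarity(self, z):
        assert sigmoid(z) + sigmoid(-z) == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_value(self):
        assert sigmoid(1.25) == pytest.approx(0.77730, abs=5e-6)

    def test_no_overflow_at_extreme_logodds(self):
        assert sigmoid(-700.0) >= 0.0
        assert sigmoid(700.0) <= 1.0

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            sigmoid(np.inf)


class TestReparametrisations:
    @pytest.mark.parametrize(
        "mu_x,a,expected",
        [(0.0, 0.37, 0.0), (0.5, 0.9, 0.05), (1.7, 1.0, 0.0)],
    )
    def test_intercept_formula(self, mu_x, a, expected):
        assert derive_intercept(mu_x, a) == pytest.approx(expected)

    def test_intercept_rejects_a_outside_unit_interval(self):
        with pytest.raises(ValueError):
            derive_intercept(0.5, 1.2)

    @pytest.mark.parametrize("beta,mu,expected", [(0.5, 0.2, 3.5), (1.0, 1.0, 2.0)])
    def test_alpha_formula(self, beta, mu, expected):
        assert derive_alpha(beta, mu) == pytest.approx(expected)

    def test_alpha_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            derive_alpha(-1.0, 0.2)

    def test_inverse_gamma_mean_round_trip(self, rng):
        # mean of IGa(alpha, beta) is beta/(alpha-1) = mu by construction
        beta, mu = 0.5, 0.2
        alpha = derive_alpha(beta, mu)
        draws = 1.0 / rng.gamma(alpha, 1.0 / beta, size=10**6)
        assert draws.mean() == pytest.approx(mu, rel=0.01)


class TestAR1Simulation:
    def test_noise_free_memory_free_is_constant(self, rng):
        p = SubjectParams(w=[0.0], a=0.0, sigma2=1e-30, mu_x=0.7)
        x = simulate_ar1(p, 50, rng).x
        assert np.allclose(x[1:], p.b, atol=1e-10)

    def test_stationary_variance_closed_form(self, rng):
        p = SubjectParams(w=[0.0], a=0.98, sigma2=0.2, mu_x=0.0)
        x = simulate_ar1(p, 10**5, rng, init_mode="stationary").x
        assert x.var() == pytest.approx(0.2 / (1 - 0.98**2), rel=0.05)

    def test_lag1_autocorrelation_matches_coefficient(self, rng):
        p = SubjectParams(w=[0.0], a=0.9, sigma2=0.3, mu_x=0.0)
        x = simulate_ar1(p, 200_000, rng).x
        c = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert c == pytest.approx(0.9, abs=0.02)

    def test_long_run_mean_converges_to_mux(self, rng):
        p = SubjectParams(w=[0.0], a=0.9, sigma2=0.3, mu_x=1.2)
        x = simulate_ar1(p, 10**5, rng).x
        # MC s.e. of the mean of an AR(1): sd * sqrt((1+a)/(1-a)/T)
        se = np.sqrt(0.3 / (1 - 0.81)) * np.sqrt((1.9 / 0.1) / 10**5)
        assert abs(x.mean() - 1.2) < 3 * se

    def test_random_walk_rejected_under_stationary_init(self, rng):
        p = SubjectParams(w=[0.0], a=1.0, sigma2=0.1, mu_x=0.0)
        with pytest.raises(ValueError):
            simulate_ar1(p, 10, rng, init_mode="stationary")

    def test_reproducible_given_seed(self):
        p = SubjectParams(w=[0.0], a=0.9, sigma2=0.3, mu_x=0.0)
        x1 = simulate_ar1(p, 100, np.random.default_rng(3)).x
        x2 = simulate_ar1(p, 100, np.random.default_rng(3)).x
        assert np.array_equal(x1, x2)


class TestSubjectSimulation:
    def test_fair_coin_when_no_signal(self, rng):
        p = SubjectParams(w=[0.0], a=0.0, sigma2=1e-30, mu_x=0.0)
        d, _ = simulate_subject(p, rng.standard_normal((10_000, 1)), rng)
        assert abs(d.responses.mean() - 0.5) < 3 * 0.005

    def test_choice_probability_matches_sigmoid(self, rng):
        p = SubjectParams(w=[1.25], a=0.0, sigma2=1e-30, mu_x=0.0)
        u = np.where(rng.random(20_000) < 0.5, 1.0, -1.0)[:, None]
        d, _ = simulate_subject(p, u, rng)
        rate = d.responses[u.ravel() > 0].mean()
        assert rate == pytest.approx(sigmoid(1.25), abs=0.015)

    def test_saturated_criterion_dominates(self, rng):
        p = SubjectParams(w=[0.5], a=0.0, sigma2=1e-30, mu_x=5.0)
        d, _ = simulate_subject(p, rng.standard_normal((2000, 1)), rng)
        assert d.responses.mean() > 0.95

    def test_dimension_mismatch_raises(self, rng):
        p = SubjectParams(w=[0.5, 0.2], a=0.5, sigma2=0.1, mu_x=0.0)
        with pytest.raises(ValueError):
            simulate_subject(p, rng.standard_normal((10, 1)), rng)


class TestHierarchicalSimulation:
    def test_reference_dataset_shape(self):
        eta = HyperParams.reference()
        data, params, trajs = simulate_hierarchical_dataset(eta, 5, 50, 0)
        assert len(data) == len(params) == len(trajs) == 5
        assert all(d.n_trials == 50 and d.n_covariates == 3 for d in data)
        assert eta.alpha_sigma2 == pytest.approx(3.5)

    def test_intercept_identity_holds_for_every_subject(self):
        eta = HyperParams.reference()
        _, params, _ = simulate_hierarchical_dataset(eta, 20, 10, 1)
        for p in params:
            assert p.b == pytest.approx(p.mu_x * (1 - p.a), abs=1e-14)

    def test_persistence_draws_match_truncnorm_mean(self, rng):
        eta = HyperParams.reference()
        draws = [draw_subject_params(eta, rng).a for _ in range(10_000)]
        expected = truncnorm_mean(0.98, 0.03, 0.0, 1.0)
        assert np.mean(draws) == pytest.approx(expected, abs=0.005)

    def test_degenerate_hierarchy_collapses(self):
        eta = HyperParams(
            mu_w=[0.4], sigma2_w=[1e-20], mu_a=0.9, sigma2_a=1e-4,
            mu_sigma2=0.1, beta_sigma2=0.2, sigma2_mux=1e-20,
        )
        _, params, _ = simulate_hierarchical_dataset(eta, 8, 10, 2)
        for p in params:
            assert p.w[0] == pytest.approx(0.4, abs=1e-8)
            assert p.mu_x == pytest.approx(0.0, abs=1e-8)

    def test_bit_reproducible_and_subject_streams_independent(self):
        eta = HyperParams.reference()
        d1, p1, t1 = simulate_hierarchical_dataset(eta, 4, 30, 9)
        d2, p2, t2 = simulate_hierarchical_dataset(eta, 4, 30, 9)
        assert all(np.array_equal(a.responses, b.responses) for a, b in zip(d1, d2))
        assert all(np.array_equal(a.x, b.x) for a, b in zip(t1, t2))
        # growing N leaves earlier subjects' draws untouched
        d3, p3, _ = simulate_hierarchical_dataset(eta, 6, 30, 9)
        assert np.array_equal(d1[0].responses, d3[0].responses)
        assert np.allclose(p1[2].w, p3[2].w)


class TestContainers:
    def test_non_binary_response_rejected(self):
        with pytest.raises(ValueError, match="responses must be 0/1"):
            SubjectData(0, [0, 1, 2], np.zeros((3, 1)))

    def test_row_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="covariate rows"):
            SubjectData(0, [0, 1], np.zeros((3, 1)))

    def test_params_domain_checks(self):
        with pytest.raises(ValueError):
            SubjectParams(w=[0.0], a=1.5, sigma2=0.1, mu_x=0.0)
        with pytest.raises(ValueError):
            SubjectParams(w=[0.0], a=0.5, sigma2=-1.0, mu_x=0.0)

    def test_hyperparams_positivity_checks(self):
        with pytest.raises(ValueError):
            HyperParams(mu_w=[0.0], sigma2_w=[1.0], mu_a=0.9, sigma2_a=0.0,
                        mu_sigma2=0.2, beta_sigma2=0.5, sigma2_mux=0.25)
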