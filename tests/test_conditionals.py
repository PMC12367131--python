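"""Per-subject and global conditional updates against grid oracles and
closed forms."""

import numpy as np
import pytest
from dataclasses import replace

from hmfc.conditionals import (
    HyperPriorConfig,
    update_a,
    update_global_mh,
    update_global_normals,
    update_mux,
    update_mux_fixed_criterion,
    update_sigma2,
    update_weights,
)
from hmfc.model import (
    HyperParams,
    LatentTrajectory,
    SubjectData,
    SubjectParams,
    sigmoid,
    simulate_ar1,
    truncnorm_rvs,
)

from _oracles import bernoulli_loglik_weight, ks_distance_to_grid


@pytest.fixture()
def ar_trajectory(rng):
    params = SubjectParams(w=[0.0], a=0.9, sigma2=0.3, mu_x=0.5)
    return params, simulate_ar1(params, 200, rng)


class TestWeightUpdate:
    def test_no_data_limit_returns_prior(self, rng):
        subject = SubjectData(0, np.empty(0, dtype=int), np.empty((0, 2)))
        traj = LatentTrajectory(np.empty(0))
        draws = np.array([
            update_weights(subject, traj, np.empty(0), np.array([0.5, -1.0]),
                           np.array([0.4, 0.9]), rng)
            for _ in range(20_000)
        ])
        assert np.allclose(draws.mean(0), [0.5, -1.0], atol=0.02)
        assert np.allclose(draws.var(0), [0.4, 0.9], rtol=0.05)

    def test_gibbs_marginal_matches_exact_bernoulli_posterior(self, rng):
        # alternate omega | w and w | omega on fixed (x, y); the stationary
        # marginal of w must equal the exact (unaugmented) posterior,
        # integrated on a dense grid
        from hmfc._pg import sample_pg1

        T, true_w = 200, 0.8
        u = rng.standard_normal(T)
        x = 0.3 * np.ones(T)  # fixed offset trajectory
        y = (rng.random(T) < sigmoid(true_w * u + x)).astype(int)
        subject = SubjectData(0, y, u[:, None])
        traj = LatentTrajectory(x)
        mu_w, s2_w = np.array([0.0]), np.array([1.0])

        w = 0.0
        draws = []
        for s in range(11_000):
            omega = sample_pg1(w * u + x, rng)
            w = float(update_weights(subject, traj, omega, mu_w, s2_w, rng)[0])
            if s >= 1000 and s % 2 == 0:
                draws.append(w)
        grid = np.linspace(-1.5, 3.0, 2000)
        log_post = bernoulli_loglik_weight(grid, u, y, x) - grid**2 / 2.0
        assert ks_distance_to_grid(np.array(draws), grid, log_post) < 0.05

    def test_conditional_mean_respects_offset(self, rng):
        # shifting the whole trajectory by delta shifts only the intercept
        # burden; with a zero-mean covariate the weight mean is unchanged
        # in expectation under matched pseudo-data
        T = 500
        u = rng.standard_normal((T, 1))
        y = rng.integers(0, 2, T)
        subject = SubjectData(0, y, u)
        omega = rng.uniform(0.2, 1.0, T)
        mu_w, s2_w = np.array([0.0]), np.array([10.0])
        base = LatentTrajectory(np.zeros(T))
        shifted = LatentTrajectory(np.full(T, 2.0))
        m0 = np.mean([
            update_weights(subject, base, omega, mu_w, s2_w, rng)[0]
            for _ in range(4000)
        ])
        # analytic conditional means differ by the projection of the shift
        # onto u, scaled by the weighted regression
        prec = 1.0 / 10.0 + float((u.ravel()**2 * omega).sum())
        shift_term = 2.0 * float((u.ravel() * omega).sum()) / prec
        m1 = np.mean([
            update_weights(subject, shifted, omega, mu_w, s2_w, rng)[0]
            for _ in range(4000)
        ])
        assert (m0 - m1) == pytest.approx(shift_term, abs=0.02)

    def test_invalid_prior_variance_rejected(self, rng):
        subject = SubjectData(0, [0, 1], np.ones((2, 1)) * 0.5)
        with pytest.raises(ValueError):
            update_weights(subject, LatentTrajectory(np.zeros(2)),
                           np.ones(2), np.zeros(1), np.array([-1.0]), rng)


class TestPersistenceUpdate:
    def test_dogmatic_prior_pins_value(self, ar_trajectory, rng):
        params, traj = ar_trajectory
        draws = [update_a(traj, params, 0.7, 1e-12, rng) for _ in range(200)]
        assert np.allclose(draws, 0.7, atol=1e-4)

    def test_consistency_on_long_trajectory(self, rng):
        params = SubjectParams(w=[0.0], a=0.95, sigma2=0.2, mu_x=0.0)
        traj = simulate_ar1(params, 10**5, rng)
        draws = [update_a(traj, params, 0.5, 0.25, rng) for _ in range(300)]
        assert np.mean(draws) == pytest.approx(0.95, abs=0.01)

    def test_matches_grid_oracle(self, ar_trajectory, rng):
        params, traj = ar_trajectory
        mu_a, s2_a = 0.85, 0.05**2
        draws = np.array([update_a(traj, params, mu_a, s2_a, rng)
                          for _ in range(5000)])
        grid = np.linspace(1e-6, 1 - 1e-6, 3000)
        c = traj.x - params.mu_x
        sxx, sxy = float(c[:-1] @ c[:-1]), float(c[1:] @ c[:-1])
        log_post = (
            -((grid - mu_a) ** 2) / (2 * s2_a)
            - (sxx * grid**2 - 2 * sxy * grid) / (2 * params.sigma2)
        )
        assert ks_distance_to_grid(draws, grid, log_post) < 0.05

    def test_stationary_mode_includes_initial_state_factor(self, ar_trajectory, rng):
        # iterate the Metropolis-within-Gibbs kernel; its stationary law is
        # the full conditional including the sqrt(1-a^2) term
        params, traj = ar_trajectory
        mu_a, s2_a = 0.85, 0.05**2
        cur = params
        draws = []
        for _ in range(8000):
            a_new = update_a(traj, cur, mu_a, s2_a, rng, init_mode="stationary")
            cur = replace(cur, a=a_new)
            draws.append(a_new)
        draws = np.array(draws[2000:])
        grid = np.linspace(1e-6, 1 - 1e-6, 3000)
        c = traj.x - params.mu_x
        sxx, sxy = float(c[:-1] @ c[:-1]), float(c[1:] @ c[:-1])
        log_post = (
            -((grid - mu_a) ** 2) / (2 * s2_a)
            - (sxx * grid**2 - 2 * sxy * grid) / (2 * params.sigma2)
            + 0.5 * np.log1p(-grid**2)
            - (1 - grid**2) * c[0] ** 2 / (2 * params.sigma2)
        )
        assert ks_distance_to_grid(draws, grid, log_post) < 0.05

    def test_requires_two_trials(self, rng):
        p = SubjectParams(w=[0.0], a=0.5, sigma2=0.1, mu_x=0.0)
        with pytest.raises(ValueError):
            update_a(LatentTrajectory([0.1]), p, 0.9, 0.01, rng)


class TestVarianceUpdate:
    def test_zero_residual_trajectory_updates_shape_only(self, rng):
        # a perfectly smooth trajectory leaves the inverse-gamma scale at
        # (almost) its prior value while the shape grows by T/2
        params = SubjectParams(w=[0.0], a=1.0, sigma2=0.1, mu_x=0.0)
        traj = LatentTrajectory(np.full(50, 0.4))
        draws = np.array([
            update_sigma2(traj, params, 3.0, 0.5, rng, init_mode=None)
            for _ in range(50_000)
        ])
        shape = 3.0 + 49 / 2.0
        assert draws.mean() == pytest.approx(0.5 / (shape - 1), rel=0.02)

    def test_consistency_on_long_trajectory(self, rng):
        params = SubjectParams(w=[0.0], a=0.9, sigma2=0.2, mu_x=0.0)
        traj = simulate_ar1(params, 10**5, rng)
        draws = [update_sigma2(traj, params, 3.5, 0.5, rng) for _ in range(300)]
        assert np.mean(draws) == pytest.approx(0.2, rel=0.02)

    def test_matches_grid_oracle(self, ar_trajectory, rng):
        params, traj = ar_trajectory
        alpha, beta = 3.5, 0.5
        draws = np.array([update_sigma2(traj, params, alpha, beta, rng)
                          for _ in range(5000)])
        x, a, mu = traj.x, params.a, params.mu_x
        resid = x[1:] - mu * (1 - a) - a * x[:-1]
        ss = float(resid @ resid)
        grid = np.linspace(1e-3, 2.0, 3000)
        log_post = (
            -(alpha + 1) * np.log(grid) - beta / grid
            - (len(x) - 1) / 2 * np.log(grid) - ss / (2 * grid)
            - 0.5 * np.log(grid) - (x[0] - mu) ** 2 / (2 * grid)
        )
        assert ks_distance_to_grid(draws, grid, log_post) < 0.05


class TestTrajectoryMeanUpdate:
    def test_dogmatic_prior_pins_at_zero(self, ar_trajectory, rng):
        params, traj = ar_trajectory
        draws = [update_mux(traj, params, 1e-14, rng) for _ in range(200)]
        assert np.allclose(draws, 0.0, atol=1e-5)

    def test_memoryless_constant_trajectory_centres_at_level(self, rng):
        params = SubjectParams(w=[0.0], a=0.0, sigma2=0.01, mu_x=0.0)
        traj = LatentTrajectory(np.full(400, 1.3))
        # a=0: each state is an independent N(mu_x, sigma2) observation;
        # conjugate posterior mean = T*c/s2 / (1/s2_mux + T/s2)
        draws = np.array([update_mux(traj, params, 100.0, rng)
                          for _ in range(5000)])
        expected = (400 * 1.3 / 0.01) / (1 / 100.0 + 400 / 0.01)
        assert draws.mean() == pytest.approx(expected, abs=0.01)

    def test_matches_grid_oracle(self, ar_trajectory, rng):
        params, traj = ar_trajectory
        draws = np.array([update_mux(traj, params, 0.25, rng)
                          for _ in range(5000)])
        x, a = traj.x, params.a
        grid = np.linspace(-1.0, 2.0, 3000)
        trans = np.array([
            np.sum((x[1:] - m * (1 - a) - a * x[:-1]) ** 2) for m in grid
        ])
        log_post = (
            -(grid**2) / (2 * 0.25)
            - trans / (2 * params.sigma2)
            - (x[0] - grid) ** 2 / (2 * params.sigma2)
        )
        assert ks_distance_to_grid(draws, grid, log_post) < 0.05

    def test_fixed_criterion_variant_is_logistic_intercept_update(self, rng):
        # omega -> large makes the Gaussian approximation tight around the
        # weighted empirical logit
        T = 1000
        subject = SubjectData(0, np.ones(T, dtype=int), rng.standard_normal((T, 1)))
        omega = np.full(T, 0.25)
        draws = np.array([
            update_mux_fixed_criterion(subject, omega, np.zeros(T), 100.0, rng)
            for _ in range(2000)
        ])
        expected = (T * 0.5) / (1 / 100.0 + T * 0.25)  # kappa=+1/2 each trial
        assert draws.mean() == pytest.approx(expected, abs=0.05)


def _subject_params_from(a_vals, s2_vals, w_vals, mux_vals):
    return [
        SubjectParams(w=[w], a=a, sigma2=s, mu_x=m)
        for a, s, w, m in zip(a_vals, s2_vals, w_vals, mux_vals)
    ]


class TestGlobalNormalUpdates:
    def test_mu_w_concentrates_at_empirical_mean(self, rng):
        n = 4000
        ws = rng.normal(1.7, 0.5, n)
        params = _subject_params_from(
            np.full(n, 0.9), np.full(n, 0.2), ws, np.zeros(n)
        )
        eta = HyperParams(mu_w=[0.0], sigma2_w=[0.25], mu_a=0.9, sigma2_a=0.01,
                          mu_sigma2=0.2, beta_sigma2=0.5, sigma2_mux=1.0)
        new = update_global_normals(params, eta, HyperPriorConfig(), rng)
        assert new.mu_w[0] == pytest.approx(ws.mean(), abs=0.05)

    def test_single_subject_pulls_hyperprior_toward_value(self, rng):
        cfg = HyperPriorConfig(mu_w_mean=0.0, mu_w_var=1.0)
        params = _subject_params_from([0.9], [0.2], [2.0], [0.0])
        eta = HyperParams(mu_w=[0.0], sigma2_w=[1.0], mu_a=0.9, sigma2_a=0.01,
                          mu_sigma2=0.2, beta_sigma2=0.5, sigma2_mux=1.0)
        draws = np.array([
            update_global_normals(params, eta, cfg, rng).mu_w[0]
            for _ in range(20_000)
        ])
        # normal-normal with one observation: posterior mean = 2.0 * 1/(1+1)
        assert draws.mean() == pytest.approx(1.0, abs=0.02)

    def test_sigma2_mux_conjugate_draw(self, rng):
        cfg = HyperPriorConfig(sigma2_mux_shape=2.0, sigma2_mux_scale=0.5)
        muxs = rng.normal(0.0, 0.7, 2000)
        params = _subject_params_from(
            np.full(2000, 0.9), np.full(2000, 0.2), np.zeros(2000), muxs
        )
        eta = HyperParams(mu_w=[0.0], sigma2_w=[1.0], mu_a=0.9, sigma2_a=0.01,
                          mu_sigma2=0.2, beta_sigma2=0.5, sigma2_mux=1.0)
        draws = np.array([
            update_global_normals(params, eta, cfg, rng).sigma2_mux
            for _ in range(3000)
        ])
        shape = 2.0 + 1000.0
        rate = 0.5 + 0.5 * float(muxs @ muxs)
        assert draws.mean() == pytest.approx(rate / (shape - 1), rel=0.02)


class TestGlobalMHUpdates:
    def _eta(self):
        return HyperParams(mu_w=[0.0], sigma2_w=[1.0], mu_a=0.9, sigma2_a=0.01,
                           mu_sigma2=0.2, beta_sigma2=0.5, sigma2_mux=1.0)

    def test_vanishing_step_cannot_move(self, rng):
        params = _subject_params_from([0.9, 0.8], [0.2, 0.3], [0.0, 0.0], [0, 0])
        eta = self._eta()
        new, _ = update_global_mh(params, eta, (1e-14,) * 4,
                                  HyperPriorConfig(), rng)
        assert new.mu_a == pytest.approx(eta.mu_a, abs=1e-10)
        assert new.beta_sigma2 == pytest.approx(eta.beta_sigma2, abs=1e-10)

    def test_mu_a_consistency_against_known_population(self, rng):
        true_mu, true_sd = 0.85, 0.05
        a_vals = truncnorm_rvs(true_mu, true_sd, 0.0, 1.0, rng, size=500)
        params = _subject_params_from(
            a_vals, np.full(500, 0.2), np.zeros(500), np.zeros(500)
        )
        eta = self._eta()
        cfg = HyperPriorConfig()
        draws = []
        for s in range(4000):
            eta, _ = update_global_mh(params, eta, (0.01, 0.001, 0.05, 0.1),
                                      cfg, rng)
            if s >= 1000:
                draws.append(eta.mu_a)
        assert np.mean(draws) == pytest.approx(true_mu, abs=0.01)

    def test_rejects_out_of_domain_proposals(self, rng):
        params = _subject_params_from([0.9, 0.8], [0.2, 0.3], [0.0, 0.0], [0, 0])
        eta = self._eta()
        for _ in range(500):
            eta, _ = update_global_mh(params, eta, (0.2, 0.5, 0.5, 0.5),
                                      HyperPriorConfig(), rng)
            assert eta.sigma2_a > 0 and eta.mu_sigma2 > 0 and eta.beta_sigma2 > 0
            assert eta.alpha_sigma2 > 1.0
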