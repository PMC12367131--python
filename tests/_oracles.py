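"""Independent oracles used by the test suite.

These deliberately avoid the package's own filtering/sampling code paths:
the chain posterior is built as a dense multivariate Gaussian, and scalar
conditionals are integrated on a grid of the exact (unaugmented) density.
"""

import numpy as np
from scipy import integrate


def chain_prior_precision(T, a, sigma2, mu_x, init_var):
    """Dense precision matrix and mean of the AR(1) prior over x_{1:T}
    with an N(mu_x, init_var) first-state prior."""
    q = np.zeros((T, T))
    q[0, 0] = 1.0 / init_var
    for t in range(1, T):
        q[t, t] += 1.0 / sigma2
        q[t - 1, t - 1] += a * a / sigma2
        q[t, t - 1] -= a / sigma2
        q[t - 1, t] -= a / sigma2
    mean = np.full(T, mu_x)
    return q, mean


def dense_chain_posterior(T, a, sigma2, mu_x, init_var, omega, z):
    """Mean and covariance of x_{1:T} | pseudo-observations z (noise 1/omega)."""
    q, m = chain_prior_precision(T, a, sigma2, mu_x, init_var)
    h = q @ m
    q_post = q + np.diag(omega)
    h_post = h + omega * z
    cov = np.linalg.inv(q_post)
    return cov @ h_post, cov


def dense_filter_marginal(t, a, sigma2, mu_x, init_var, omega, z):
    """Mean/variance of x_t | z_{1:t} from the dense joint of the first t
    states only."""
    mean, cov = dense_chain_posterior(
        t + 1, a, sigma2, mu_x, init_var, omega[: t + 1], z[: t + 1]
    )
    return mean[-1], cov[-1, -1]


def grid_cdf(grid, log_density):
    """Normalised CDF of an unnormalised log-density tabulated on a grid."""
    lp = log_density - log_density.max()
    pdf = np.exp(lp)
    cdf = integrate.cumulative_trapezoid(pdf, grid, initial=0.0)
    return cdf / cdf[-1]


def ks_distance_to_grid(samples, grid, log_density):
    """Sup distance between the sample ECDF and a grid-integrated CDF."""
    cdf = grid_cdf(grid, log_density)
    ecdf = np.searchsorted(np.sort(samples), grid) / len(samples)
    return float(np.abs(ecdf - cdf).max())


def bernoulli_loglik_weight(w_grid, u, y, offset):
    """Exact Bernoulli log-likelihood of a single weight on a grid
    (1 covariate), with a known per-trial offset."""
    psi = w_grid[:, None] * u[None, :] + offset[None, :]
    # log sigmoid(psi) if y=1 else log sigmoid(-psi), stably
    s = np.where(y[None, :] == 1, psi, -psi)
    return (-np.logaddexp(0.0, -s)).sum(axis=1)
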