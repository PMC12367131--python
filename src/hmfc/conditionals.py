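"""Complete conditional updates for the blocked Gibbs sweep.

Per-subject blocks (given the trajectory x and PG auxiliaries omega):

* weights w   — exactly Gaussian after PG augmentation,
* a           — truncated-normal conditional from the AR(1) transitions,
                Metropolis-corrected for the stationary initial-state term,
* sigma2      — inverse-gamma (conjugate, including the initial state),
* mu_x        — Gaussian (conjugate; the mean enters every transition
                through b = mu_x (1 - a) and the initial-state prior).

Global blocks (given all subjects' parameters):

* (mu_w, sigma2_w, sigma2_mux) — closed-form normal / inverse-gamma draws,
* (mu_a, sigma2_a, mu_sigma2, beta_sigma2) — one-at-a-time random-walk
  Metropolis-Hastings with symmetric Gaussian proposals; out-of-domain
  proposals are rejected, and alpha_sigma2 = beta_sigma2/mu_sigma2 + 1 is
  re-derived after every move.

All hyperprior constants live in :class:`HyperPriorConfig`; defaults are
broad proper priors so every conditional stays well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import special
from scipy.linalg import cho_factor, cho_solve, cholesky

from .model import (
    HyperParams,
    LatentTrajectory,
    SubjectData,
    SubjectParams,
    derive_alpha,
    truncnorm_rvs,
)

__all__ = [
    "HyperPriorConfig",
    "update_weights",
    "update_a",
    "update_sigma2",
    "update_mux",
    "update_mux_fixed_criterion",
    "update_global_normals",
    "update_global_mh",
]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# hyperpriors


@dataclass
class HyperPriorConfig:
    """Weakly informative proper priors on the group-level parameters eta.

    mu_w components: N(mu_w_mean, mu_w_var); sigma2_w components:
    InvGamma(sigma2_w_shape, sigma2_w_scale); mu_a: N(mu_a_mean, mu_a_var)
    truncated to [0, 1] — constraining the location to the persistence
    domain removes a likelihood ridge along which (mu_a, sigma2_a) can
    drift jointly above 1 when every subject's a_i sits near the boundary;
    sigma2_a / mu_sigma2 / beta_sigma2: half-normal with the given scales
    (half-normals keep mass near zero, where e.g. sigma2_a plausibly lives);
    sigma2_mux: InvGamma(sigma2_mux_shape, sigma2_mux_scale).
    """

    mu_w_mean: float = 0.0
    mu_w_var: float = 4.0
    sigma2_w_shape: float = 2.0
    sigma2_w_scale: float = 1.0
    mu_a_mean: float = 0.5
    mu_a_var: float = 1.0
    sigma2_a_scale: float = 0.5
    mu_sigma2_scale: float = 1.0
    beta_sigma2_scale: float = 2.0
    sigma2_mux_shape: float = 2.0
    sigma2_mux_scale: float = 0.5

    def draw_eta(self, n_covariates: int, rng: np.random.Generator) -> HyperParams:
        """One draw of eta from the hyperprior (used by prior-predictive
        simulation and sampler validation)."""
        return HyperParams(
            mu_w=rng.normal(self.mu_w_mean, np.sqrt(self.mu_w_var), n_covariates),
            sigma2_w=1.0
            / rng.gamma(self.sigma2_w_shape, 1.0 / self.sigma2_w_scale, n_covariates),
            mu_a=float(
                truncnorm_rvs(self.mu_a_mean, np.sqrt(self.mu_a_var), 0.0, 1.0, rng)
            ),
            sigma2_a=float(abs(rng.normal(0.0, self.sigma2_a_scale))),
            mu_sigma2=float(abs(rng.normal(0.0, self.mu_sigma2_scale))),
            beta_sigma2=float(abs(rng.normal(0.0, self.beta_sigma2_scale))),
            sigma2_mux=float(
                1.0 / rng.gamma(self.sigma2_mux_shape, 1.0 / self.sigma2_mux_scale)
            ),
        )

    # log hyperprior densities (up to constants) for the MH block
    def log_mu_a(self, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            return -np.inf
        return -0.5 * (v - self.mu_a_mean) ** 2 / self.mu_a_var

    def log_sigma2_a(self, v: float) -> float:
        return -np.inf if v <= 0 else -0.5 * v**2 / self.sigma2_a_scale**2

    def log_mu_sigma2(self, v: float) -> float:
        return -np.inf if v <= 0 else -0.5 * v**2 / self.mu_sigma2_scale**2

    def log_beta_sigma2(self, v: float) -> float:
        return -np.inf if v <= 0 else -0.5 * v**2 / self.beta_sigma2_scale**2


# ---------------------------------------------------------------------------
# per-subject updates


def update_weights(
    subject: SubjectData,
    trajectory: LatentTrajectory,
    omega: np.ndarray,
    mu_w: np.ndarray,
    sigma2_w: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact Gaussian conditional draw of the covariate weights.

    Posterior precision = diag(1/sigma2_w) + U' diag(omega) U; the linear
    term uses the PG pseudo-observations kappa_t = y_t - 1/2 with the
    trajectory as a known offset.
    """
    u = subject.covariates
    kappa = subject.responses - 0.5
    prior_prec = 1.0 / np.asarray(sigma2_w, dtype=float)
    if (prior_prec <= 0).any() or not np.isfinite(prior_prec).all():
        raise ValueError("sigma2_w must be positive and finite")
    prec = np.diag(prior_prec) + (u * omega[:, None]).T @ u
    h = prior_prec * mu_w + u.T @ (kappa - omega * trajectory.x)
    try:
        cf = cho_factor(prec, lower=True)
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise ValueError("singular conditional precision for w") from err
    mean = cho_solve(cf, h)
    # draw: mean + L^{-T} z with L the lower Cholesky factor of the precision
    z = rng.standard_normal(mean.shape[0])
    lower = cholesky(prec, lower=True)
    return mean + np.linalg.solve(lower.T, z)


def _centered_sums(x: np.ndarray, mu_x: float):
    c = x - mu_x
    return float(c[:-1] @ c[:-1]), float(c[1:] @ c[:-1])


def _log_init_factor(a: float, x1: float, mu_x: float, sigma2: float) -> float:
    """Initial-state contribution to the conditional of a under the
    stationary prior x_1 ~ N(mu_x, sigma2/(1-a^2))."""
    one_m_a2 = 1.0 - a * a
    if one_m_a2 <= 0.0:
        return -np.inf
    return 0.5 * np.log(one_m_a2) - 0.5 * one_m_a2 * (x1 - mu_x) ** 2 / sigma2


def update_a(
    trajectory: LatentTrajectory,
    params: SubjectParams,
    mu_a: float,
    sigma2_a: float,
    rng: np.random.Generator,
    init_mode: str = "around_mean",
) -> float:
    """Draw the persistence a from its [0,1]-truncated conditional.

    The AR(1) transitions of the centred states give a truncated-normal
    conditional, which is exact under the ``around_mean`` initial-state
    convention (x_1 does not involve a).  Under the ``stationary``
    convention the trunc-normal is used as an independence proposal and
    accepted against the sqrt(1-a^2) exp(...) initial-state factor, which
    leaves the exact joint invariant.
    """
    x = trajectory.x
    if x.shape[0] < 2:
        raise ValueError("updating a requires at least two trials")
    sxx, sxy = _centered_sums(x, params.mu_x)
    prec = 1.0 / sigma2_a + sxx / params.sigma2
    if not np.isfinite(prec) or prec <= 0:
        raise ValueError("degenerate conditional precision for a")
    var = 1.0 / prec
    mean = var * (mu_a / sigma2_a + sxy / params.sigma2)
    prop = float(truncnorm_rvs(mean, np.sqrt(var), 0.0, 1.0, rng))
    if init_mode != "stationary":
        return prop
    log_r = _log_init_factor(prop, x[0], params.mu_x, params.sigma2) - _log_init_factor(
        params.a, x[0], params.mu_x, params.sigma2
    )
    if np.log(rng.random()) < log_r:
        return prop
    return params.a


def update_sigma2(
    trajectory: LatentTrajectory,
    params: SubjectParams,
    alpha_sigma2: float,
    beta_sigma2: float,
    rng: np.random.Generator,
    init_mode: str = "around_mean",
) -> float:
    """Exact inverse-gamma conditional draw of the fluctuation variance."""
    x = trajectory.x
    if x.shape[0] < 2:
        raise ValueError("updating sigma2 requires at least two trials")
    resid = x[1:] - params.b - params.a * x[:-1]
    ss = float(resid @ resid)
    shape = alpha_sigma2 + (x.shape[0] - 1) / 2.0
    rate = beta_sigma2 + 0.5 * ss
    if init_mode == "around_mean":
        shape += 0.5
        rate += 0.5 * (x[0] - params.mu_x) ** 2
    elif init_mode == "stationary" and params.a < 1.0:
        shape += 0.5
        rate += 0.5 * (1.0 - params.a**2) * (x[0] - params.mu_x) ** 2
    return float(1.0 / rng.gamma(shape, 1.0 / rate))


def update_mux(
    trajectory: LatentTrajectory,
    params: SubjectParams,
    sigma2_mux: float,
    rng: np.random.Generator,
    init_mode: str = "around_mean",
) -> float:
    """Exact Gaussian conditional draw of the trajectory mean mu_x.

    The mean enters each transition as b = mu_x (1 - a): the residual
    (x_t - a x_{t-1}) is N(mu_x (1-a), sigma2); the initial state
    contributes x_1 ~ N(mu_x, sigma2) (``around_mean``) or
    N(mu_x, sigma2/(1-a^2)) (``stationary``); the prior is the zero-mean
    hierarchical Gaussian.
    """
    x = trajectory.x
    a, s2 = params.a, params.sigma2
    one_m_a = 1.0 - a
    n_trans = x.shape[0] - 1
    prec = 1.0 / sigma2_mux + n_trans * one_m_a**2 / s2
    num = one_m_a * float(np.sum(x[1:] - a * x[:-1])) / s2
    if init_mode == "around_mean":
        prec += 1.0 / s2
        num += x[0] / s2
    elif init_mode == "stationary" and a < 1.0:
        one_m_a2 = 1.0 - a * a
        prec += one_m_a2 / s2
        num += one_m_a2 * x[0] / s2
    var = 1.0 / prec
    return float(rng.normal(var * num, np.sqrt(var)))


def update_mux_fixed_criterion(
    subject: SubjectData,
    omega: np.ndarray,
    linear_predictor: np.ndarray,
    sigma2_mux: float,
    rng: np.random.Generator,
) -> float:
    """mu_x conditional when fluctuations are switched off (x_t == mu_x):
    a PG-augmented random-intercept logistic update."""
    kappa = subject.responses - 0.5
    prec = 1.0 / sigma2_mux + float(np.sum(omega))
    num = float(np.sum(kappa - omega * linear_predictor))
    var = 1.0 / prec
    return float(rng.normal(var * num, np.sqrt(var)))


# ---------------------------------------------------------------------------
# global updates


def update_global_normals(
    subject_params: list[SubjectParams],
    eta: HyperParams,
    config: HyperPriorConfig,
    rng: np.random.Generator,
) -> HyperParams:
    """Closed-form conjugate draws of (mu_w, sigma2_w, sigma2_mux)."""
    ws = np.array([p.w for p in subject_params])
    muxs = np.array([p.mu_x for p in subject_params])
    n = ws.shape[0]

    # mu_w | {w_i}, sigma2_w : normal-normal, coordinatewise
    prec = 1.0 / config.mu_w_var + n / eta.sigma2_w
    mean = (config.mu_w_mean / config.mu_w_var + ws.sum(axis=0) / eta.sigma2_w) / prec
    mu_w = rng.normal(mean, np.sqrt(1.0 / prec))

    # sigma2_w | {w_i}, mu_w : inverse-gamma, coordinatewise
    ss = ((ws - mu_w) ** 2).sum(axis=0)
    shape = config.sigma2_w_shape + n / 2.0
    sigma2_w = 1.0 / rng.gamma(shape, 1.0 / (config.sigma2_w_scale + 0.5 * ss))

    # sigma2_mux | {mu_x,i} : inverse-gamma (zero-mean hierarchical prior)
    shape_m = config.sigma2_mux_shape + n / 2.0
    rate_m = config.sigma2_mux_scale + 0.5 * float(muxs @ muxs)
    sigma2_mux = float(1.0 / rng.gamma(shape_m, 1.0 / rate_m))

    return replace(eta, mu_w=mu_w, sigma2_w=sigma2_w, sigma2_mux=sigma2_mux)


def _truncnorm_logpdf_sum(a_vals, mu, sigma2):
    if sigma2 <= 0:
        return -np.inf
    sd = np.sqrt(sigma2)
    z = special.ndtr((1.0 - mu) / sd) - special.ndtr((0.0 - mu) / sd)
    if z <= 0.0:
        return -np.inf
    n = a_vals.shape[0]
    ll = -0.5 * np.sum((a_vals - mu) ** 2) / sigma2
    return float(ll - n * (np.log(sd) + np.log(z)))


def _invgamma_logpdf_sum(s2_vals, alpha, beta):
    if alpha <= 0 or beta <= 0:
        return -np.inf
    n = s2_vals.shape[0]
    return float(
        n * (alpha * np.log(beta) - special.gammaln(alpha))
        - (alpha + 1.0) * np.sum(np.log(s2_vals))
        - beta * np.sum(1.0 / s2_vals)
    )


def update_global_mh(
    subject_params: list[SubjectParams],
    eta: HyperParams,
    step_sizes,
    config: HyperPriorConfig,
    rng: np.random.Generator,
):
    """One random-walk MH sweep over (mu_a, sigma2_a, mu_sigma2, beta_sigma2).

    Each parameter is proposed from a symmetric Gaussian and accepted
    against the product of its per-subject prior densities times the
    hyperprior.  Returns (new eta, boolean acceptance indicators).
    """
    a_vals = np.array([p.a for p in subject_params])
    s2_vals = np.array([p.sigma2 for p in subject_params])
    step_mu_a, step_s2_a, step_mu_s2, step_beta_s2 = step_sizes
    accepted = np.zeros(4, dtype=bool)

    mu_a, s2_a = eta.mu_a, eta.sigma2_a
    mu_s2, beta_s2 = eta.mu_sigma2, eta.beta_sigma2

    # -- mu_a
    cur = _truncnorm_logpdf_sum(a_vals, mu_a, s2_a) + config.log_mu_a(mu_a)
    prop = mu_a + step_mu_a * rng.standard_normal()
    new = _truncnorm_logpdf_sum(a_vals, prop, s2_a) + config.log_mu_a(prop)
    if np.log(rng.random()) < new - cur:
        mu_a, accepted[0] = prop, True

    # -- sigma2_a
    cur = _truncnorm_logpdf_sum(a_vals, mu_a, s2_a) + config.log_sigma2_a(s2_a)
    prop = s2_a + step_s2_a * rng.standard_normal()
    if prop > 0:
        new = _truncnorm_logpdf_sum(a_vals, mu_a, prop) + config.log_sigma2_a(prop)
        if np.log(rng.random()) < new - cur:
            s2_a, accepted[1] = prop, True

    # -- mu_sigma2 (enters through alpha_sigma2 = beta/mu + 1)
    cur = _invgamma_logpdf_sum(
        s2_vals, derive_alpha(beta_s2, mu_s2), beta_s2
    ) + config.log_mu_sigma2(mu_s2)
    prop = mu_s2 + step_mu_s2 * rng.standard_normal()
    if prop > 0:
        new = _invgamma_logpdf_sum(
            s2_vals, derive_alpha(beta_s2, prop), beta_s2
        ) + config.log_mu_sigma2(prop)
        if np.log(rng.random()) < new - cur:
            mu_s2, accepted[2] = prop, True

    # -- beta_sigma2
    cur = _invgamma_logpdf_sum(
        s2_vals, derive_alpha(beta_s2, mu_s2), beta_s2
    ) + config.log_beta_sigma2(beta_s2)
    prop = beta_s2 + step_beta_s2 * rng.standard_normal()
    if prop > 0:
        new = _invgamma_logpdf_sum(
            s2_vals, derive_alpha(prop, mu_s2), prop
        ) + config.log_beta_sigma2(prop)
        if np.log(rng.random()) < new - cur:
            beta_s2, accepted[3] = prop, True

    new_eta = replace(
        eta, mu_a=mu_a, sigma2_a=s2_a, mu_sigma2=mu_s2, beta_sigma2=beta_s2
    )
    return new_eta, accepted
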