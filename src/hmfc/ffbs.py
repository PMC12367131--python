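"""Forward filtering / backward sampling for the latent criterion chain.

Conditional on the Pólya-gamma auxiliaries, each trial contributes a
Gaussian pseudo-observation of the criterion state:

    z_t = kappa_t / omega_t - w'u_t,   z_t | x_t ~ N(x_t, 1/omega_t),

with kappa_t = y_t - 1/2, while the state follows the AR(1) transition
x_t = b + a x_{t-1} + N(0, sigma2).  The full conditional of the whole
trajectory is then a chain-structured Gaussian, from which FFBS produces
an exact joint draw in O(T): a Kalman forward pass computes the filtering
distributions p(x_t | z_{1:t}), and a backward pass draws x_T from the
final filter and each earlier x_t from the exact Gaussian backward kernel
p(x_t | x_{t+1}, z_{1:t}).

Observation variances are floored at 1e-12 to keep the filter well posed
when an omega draw is extremely large (near-deterministic trials).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import LatentTrajectory, SubjectData, SubjectParams

__all__ = ["FilteringState", "forward_filter", "backward_sample", "kernel_evals"]

_VAR_FLOOR = 1e-12

# running count of per-trial kernel evaluations (filter + backward steps);
# used to assert the linear-in-T cost contract without timing anything
_KERNEL_EVALS = 0


def kernel_evals() -> int:
    return _KERNEL_EVALS


@dataclass
class FilteringState:
    """Means and variances of p(x_t | pseudo-observations 1..t)."""

    means: np.ndarray
    variances: np.ndarray
    a: float
    b: float
    sigma2: float

    def __post_init__(self):
        if self.means.shape != self.variances.shape:
            raise ValueError("means and variances must have equal length")
        if not (np.isfinite(self.variances).all() and (self.variances > 0).all()):
            raise ValueError("filtering variances must be positive and finite")


@njit(cache=True)
def _kalman_forward(z, obs_var, a, b, s2, m0, p0):
    T = z.shape[0]
    m = np.empty(T)
    p = np.empty(T)
    m_pred, p_pred = m0, p0
    for t in range(T):
        if t > 0:
            m_pred = b + a * m[t - 1]
            p_pred = a * a * p[t - 1] + s2
        v = p_pred + obs_var[t]
        k = p_pred / v
        m[t] = m_pred + k * (z[t] - m_pred)
        p[t] = (1.0 - k) * p_pred
        if p[t] < 1e-12:
            p[t] = 1e-12
    return m, p


@njit(cache=True)
def _backward_draw(m, p, a, b, s2, gen):
    T = m.shape[0]
    x = np.empty(T)
    x[T - 1] = m[T - 1] + np.sqrt(p[T - 1]) * gen.standard_normal()
    for t in range(T - 2, -1, -1):
        prec = 1.0 / p[t] + a * a / s2
        var = 1.0 / prec
        mean = var * (m[t] / p[t] + a * (x[t + 1] - b) / s2)
        x[t] = mean + np.sqrt(var) * gen.standard_normal()
    return x


def _initial_moments(params: SubjectParams, init_mode: str):
    if init_mode == "around_mean":
        # x_1 ~ N(mu_x, sigma2): session starts at the habitual bias
        return params.mu_x, params.sigma2
    if init_mode == "stationary":
        if params.a >= 1.0:
            raise ValueError("stationary initial prior undefined at a = 1")
        return params.mu_x, params.sigma2 / (1.0 - params.a**2)
    raise ValueError(f"unknown init_mode {init_mode!r}")


def forward_filter(
    subject: SubjectData,
    params: SubjectParams,
    linear_predictor: np.ndarray,
    omega: np.ndarray,
    init_mode: str = "around_mean",
) -> FilteringState:
    """Kalman filter over the PG pseudo-observations.

    ``linear_predictor`` is the covariate contribution w'u_t per trial;
    ``omega`` the PG auxiliaries (strictly positive).
    """
    global _KERNEL_EVALS
    omega = np.asarray(omega, dtype=float)
    if omega.shape[0] != subject.n_trials:
        raise ValueError("omega length does not match the subject's trial count")
    if (omega <= 0).any() or not np.isfinite(omega).all():
        raise ValueError("all PG auxiliaries must be positive and finite")
    kappa = subject.responses - 0.5
    z = kappa / omega - np.asarray(linear_predictor, dtype=float)
    obs_var = np.maximum(1.0 / omega, _VAR_FLOOR)
    m0, p0 = _initial_moments(params, init_mode)
    m, p = _kalman_forward(z, obs_var, params.a, params.b, params.sigma2, m0, p0)
    _KERNEL_EVALS += subject.n_trials
    return FilteringState(m, p, params.a, params.b, params.sigma2)


def backward_sample(
    filt: FilteringState, params: SubjectParams, rng: np.random.Generator
) -> LatentTrajectory:
    """Joint draw of x_{1:T} from its chain-structured Gaussian conditional."""
    global _KERNEL_EVALS
    if not (filt.a == params.a and filt.sigma2 == params.sigma2):
        raise ValueError("backward_sample must use the params the filter was run with")
    x = _backward_draw(
        filt.means, filt.variances, params.a, params.b, params.sigma2, rng
    )
    _KERNEL_EVALS += filt.means.shape[0]
    return LatentTrajectory(x)
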