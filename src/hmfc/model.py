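"""Generative model for binary choices under a slowly drifting decision criterion.

A subject's response on trial t is a weighted coin flip,

    y_t ~ Bernoulli( sigmoid( w' u_t + x_t ) ),

where ``u_t`` holds observed covariates (signed stimulus evidence, previous
response, ...), ``w`` their log-odds weights, and ``x_t`` the latent decision
criterion, which follows a stationary AR(1) process

    x_t = b + a x_{t-1} + eps_t,    eps_t ~ N(0, sigma2),

with persistence ``a`` in [0, 1] and innovation variance ``sigma2``.  The
intercept is never a free parameter: it is tied to the trajectory mean via
``b = mu_x (1 - a)``, the stationary-mean identity of an AR(1) process, so
that ``mu_x`` directly measures the subject's overall response bias.

Across a population, subject-level parameters are exchangeable draws from
global distributions:

    w_i      ~ N(mu_w, diag(sigma2_w))
    a_i      ~ TruncNorm(mu_a, sigma2_a, [0, 1])
    sigma2_i ~ InvGamma(alpha_sigma2, beta_sigma2)
    mu_x,i   ~ N(0, sigma2_mux)

The inverse-gamma shape is reparametrised through the fluctuation-scale mean:
``alpha_sigma2 = beta_sigma2 / mu_sigma2 + 1``, which makes
``E[sigma2_i] = mu_sigma2`` and decorrelates the shape/scale estimates.

This module holds the data containers, the deterministic reparametrisations,
and forward simulation of single subjects and whole hierarchical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "SubjectData",
    "SubjectParams",
    "HyperParams",
    "LatentTrajectory",
    "sigmoid",
    "derive_intercept",
    "derive_alpha",
    "truncnorm_rvs",
    "truncnorm_mean",
    "simulate_ar1",
    "simulate_subject",
    "draw_subject_params",
    "simulate_hierarchical_dataset",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class SubjectData:
    """One subject's observed trials.

    responses are coded {0, 1}; response 1 is the one whose log-odds
    increase with ``w'u + x``.  ``covariates`` is (T, p).
    """

    subject_id: object
    responses: np.ndarray
    covariates: np.ndarray

    def __post_init__(self):
        self.responses = np.asarray(self.responses)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.responses.shape[0]:
            raise ValueError(
                f"subject {self.subject_id}: covariate rows "
                f"({self.covariates.shape[0]}) != number of responses "
                f"({self.responses.shape[0]})"
            )
        if not np.isin(self.responses, (0, 1)).all():
            bad = np.flatnonzero(~np.isin(self.responses, (0, 1)))
            raise ValueError(
                f"subject {self.subject_id}: responses must be 0/1; "
                f"offending trial indices {bad[:10].tolist()}"
            )
        self.responses = self.responses.astype(np.int8)
        if not np.isfinite(self.covariates).all():
            raise ValueError(f"subject {self.subject_id}: non-finite covariates")

    @property
    def n_trials(self) -> int:
        return self.responses.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]


@dataclass
class SubjectParams:
    """theta_i = (w, a, sigma2, mu_x); the AR(1) intercept b is derived."""

    w: np.ndarray
    a: float
    sigma2: float
    mu_x: float

    def __post_init__(self):
        self.w = np.atleast_1d(np.asarray(self.w, dtype=float))
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"autoregressive coefficient a={self.a} outside [0, 1]")
        if self.sigma2 <= 0:
            raise ValueError(f"fluctuation variance sigma2={self.sigma2} must be > 0")

    @property
    def b(self) -> float:
        return derive_intercept(self.mu_x, self.a)


@dataclass
class HyperParams:
    """Global (group-level) parameters eta; alpha_sigma2 is derived."""

    mu_w: np.ndarray
    sigma2_w: np.ndarray
    mu_a: float
    sigma2_a: float
    mu_sigma2: float
    beta_sigma2: float
    sigma2_mux: float

    def __post_init__(self):
        self.mu_w = np.atleast_1d(np.asarray(self.mu_w, dtype=float))
        self.sigma2_w = np.atleast_1d(np.asarray(self.sigma2_w, dtype=float))
        if self.mu_w.shape != self.sigma2_w.shape:
            raise ValueError("mu_w and sigma2_w must have the same length")
        for name in ("sigma2_a", "mu_sigma2", "beta_sigma2", "sigma2_mux"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if (self.sigma2_w <= 0).any():
            raise ValueError("sigma2_w components must be strictly positive")

    @property
    def alpha_sigma2(self) -> float:
        return derive_alpha(self.beta_sigma2, self.mu_sigma2)

    @property
    def n_covariates(self) -> int:
        return self.mu_w.shape[0]

    @classmethod
    def reference(cls) -> "HyperParams":
        """Defaults of the package's validation studies: three standard-normal
        covariates with weight means (0, 0.2, -0.1), strongly persistent
        criteria (mu_a = 0.98, sd_a = 0.03), moderate fluctuation scale
        (mu_sigma2 = 0.2, beta_sigma2 = 0.5), and bias spread sd 0.5."""
        return cls(
            mu_w=np.array([0.0, 0.2, -0.1]),
            sigma2_w=np.array([1.0, 1.0, 1.0]),
            mu_a=0.98,
            sigma2_a=0.03**2,
            mu_sigma2=0.2,
            beta_sigma2=0.5,
            sigma2_mux=0.5**2,
        )


@dataclass
class LatentTrajectory:
    """The per-trial criterion states x_1..x_T of one subject."""

    x: np.ndarray

    def __post_init__(self):
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        if not np.isfinite(self.x).all():
            raise ValueError("latent trajectory contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.x.shape[0]


# ---------------------------------------------------------------------------
# deterministic pieces


def sigmoid(z):
    """Logistic function 1/(1+exp(-z)), overflow-safe for any finite z."""
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("sigmoid: log-odds must be finite")
    out = special.expit(z)
    return out if out.ndim else float(out)


def derive_intercept(mu_x: float, a: float) -> float:
    """AR(1) intercept from its stationary mean: b = mu_x (1 - a)."""
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"a={a} outside [0, 1]")
    return mu_x * (1.0 - a)


def derive_alpha(beta_sigma2: float, mu_sigma2: float) -> float:
    """Inverse-gamma shape such that the prior mean of sigma2 is mu_sigma2."""
    if beta_sigma2 <= 0 or mu_sigma2 <= 0:
        raise ValueError("beta_sigma2 and mu_sigma2 must be strictly positive")
    return beta_sigma2 / mu_sigma2 + 1.0


def truncnorm_rvs(mu, sd, lo, hi, rng, size=None):
    """Truncated-normal draws by inversion of the Gaussian CDF.

    Inversion stays exact when the untruncated mean sits near a boundary
    (e.g. mu_a close to 1), where naive rejection sampling stalls.
    """
    a = special.ndtr((lo - mu) / sd)
    b = special.ndtr((hi - mu) / sd)
    if np.ndim(mu) == 0 and np.ndim(sd) == 0 and b - a < 1e-300:
        # interval mass underflows: all mass effectively at the boundary
        # nearest the untruncated mean
        val = hi - 1e-12 * max(1.0, abs(hi - lo)) if mu > hi else lo
        return np.full(size, val) if size is not None else float(val)
    u = rng.uniform(a, b, size=size)
    # keep u strictly inside (0, 1) so ndtri cannot return +-inf
    u = np.clip(u, 1e-300, 1.0 - 1e-16)
    x = mu + sd * special.ndtri(u)
    eps = 1e-12 * max(1.0, abs(hi - lo)) if np.ndim(x) == 0 else 1e-12
    return np.clip(x, lo, hi - eps if hi > lo else hi)


def truncnorm_mean(mu, sd, lo, hi):
    """Mean of N(mu, sd^2) truncated to [lo, hi] (closed form)."""
    alpha = (lo - mu) / sd
    beta = (hi - mu) / sd
    phi = lambda t: np.exp(-0.5 * t * t) / np.sqrt(2 * np.pi)
    z = special.ndtr(beta) - special.ndtr(alpha)
    return mu + sd * (phi(alpha) - phi(beta)) / z


# ---------------------------------------------------------------------------
# forward simulation


def simulate_ar1(
    params: SubjectParams,
    n_trials: int,
    rng: np.random.Generator,
    init_mode: str = "around_mean",
    x0: float | None = None,
) -> LatentTrajectory:
    """Simulate the criterion trajectory.

    The first state is drawn around the trajectory mean, x_1 ~ N(mu_x,
    sigma2), under ``around_mean`` (the default): the session starts at the
    subject's habitual bias, up to one innovation.  ``stationary`` draws
    x_1 from the marginal law N(mu_x, sigma2/(1-a^2)) instead — note that
    for persistence near 1 its standard deviation diverges, and a session
    can then begin (and stay) with the criterion saturated far from the
    mean.  ``fixed_value`` starts at ``x0`` exactly.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    a, b, s2 = params.a, params.b, params.sigma2
    x = np.empty(n_trials)
    if init_mode == "around_mean":
        x[0] = rng.normal(params.mu_x, np.sqrt(s2))
    elif init_mode == "stationary":
        if a >= 1.0:
            raise ValueError(
                "stationary initialisation undefined at a = 1 (random walk)"
            )
        x[0] = rng.normal(params.mu_x, np.sqrt(s2 / (1.0 - a * a)))
    elif init_mode == "fixed_value":
        if x0 is None:
            raise ValueError("fixed_value initialisation requires x0")
        x[0] = x0
    else:
        raise ValueError(f"unknown init_mode {init_mode!r}")
    eps = rng.normal(0.0, np.sqrt(s2), size=n_trials - 1)
    for t in range(1, n_trials):
        x[t] = b + a * x[t - 1] + eps[t - 1]
    return LatentTrajectory(x)


def simulate_subject(
    params: SubjectParams,
    covariates: np.ndarray,
    rng: np.random.Generator,
    subject_id=0,
    init_mode: str = "around_mean",
    x0: float | None = None,
) -> tuple[SubjectData, LatentTrajectory]:
    """Simulate one subject's responses given covariates; returns the
    observables together with the ground-truth trajectory for recovery
    studies."""
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[1] != params.w.shape[0]:
        raise ValueError(
            f"covariate columns ({covariates.shape[1]}) != weight length "
            f"({params.w.shape[0]})"
        )
    traj = simulate_ar1(params, covariates.shape[0], rng, init_mode, x0)
    p = sigmoid(covariates @ params.w + traj.x)
    y = (rng.random(covariates.shape[0]) < p).astype(np.int8)
    return SubjectData(subject_id, y, covariates), traj


def draw_subject_params(eta: HyperParams, rng: np.random.Generator) -> SubjectParams:
    """One draw of theta_i from the hierarchical prior."""
    w = rng.normal(eta.mu_w, np.sqrt(eta.sigma2_w))
    a = float(truncnorm_rvs(eta.mu_a, np.sqrt(eta.sigma2_a), 0.0, 1.0, rng))
    sigma2 = float(1.0 / rng.gamma(eta.alpha_sigma2, 1.0 / eta.beta_sigma2))
    mu_x = float(rng.normal(0.0, np.sqrt(eta.sigma2_mux)))
    return SubjectParams(w=w, a=a, sigma2=sigma2, mu_x=mu_x)


def simulate_hierarchical_dataset(
    eta: HyperParams,
    n_subjects: int,
    n_trials: int,
    rng_or_seed,
    init_mode: str = "around_mean",
):
    """Simulate a full multi-subject dataset from the hierarchy.

    Covariates are i.i.d. standard normal (mean zero, identity covariance).
    One master seed expands to independent per-subject substreams, so
    changing N or T does not correlate draws across subjects.

    Returns (list[SubjectData], list[SubjectParams], list[LatentTrajectory]).
    """
    if n_subjects < 1 or n_trials < 2:
        raise ValueError("need n_subjects >= 1 and n_trials >= 2")
    if isinstance(rng_or_seed, np.random.Generator):
        children = rng_or_seed.bit_generator.seed_seq.spawn(n_subjects)
    else:
        children = np.random.SeedSequence(rng_or_seed).spawn(n_subjects)
    data, params, trajs = [], [], []
    for i, child in enumerate(children):
        sub_rng = np.random.default_rng(child)
        theta = draw_subject_params(eta, sub_rng)
        u = sub_rng.standard_normal((n_trials, eta.n_covariates))
        d, x = simulate_subject(theta, u, sub_rng, subject_id=i, init_mode=init_mode)
        data.append(d)
        params.append(theta)
        trajs.append(x)
    return data, params, trajs
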