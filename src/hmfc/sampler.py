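"""Blocked Gibbs sampler for the hierarchical criterion-fluctuation model.

One sweep visits, for every subject: the PG auxiliaries, the latent
trajectory (FFBS), the weights, the persistence a, the innovation variance
sigma2, and the trajectory mean mu_x; then the global blocks (conjugate
normals / inverse-gammas, and random-walk MH for the truncated-normal and
inverse-gamma hyperparameters).  The update order within a sweep is fixed:
blocked-Gibbs validity does not depend on it, but reproducibility does.

Two switches reproduce the degenerate fits used in the confound analyses:
``fixed_a`` clamps every subject's persistence (e.g. at 0.9995), and
``estimate_fluctuations=False`` pins the trajectory at x_t == mu_x,i,
reducing the model to logistic regression with a random intercept.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from ._pg import sample_pg1
from .conditionals import (
    HyperPriorConfig,
    update_a,
    update_global_mh,
    update_global_normals,
    update_mux,
    update_mux_fixed_criterion,
    update_sigma2,
    update_weights,
)
from .ffbs import backward_sample, forward_filter
from .model import (
    HyperParams,
    LatentTrajectory,
    SubjectData,
    SubjectParams,
    sigmoid,
)

__all__ = ["SamplerConfig", "GibbsState", "PosteriorChain", "run_gibbs", "gibbs_sweep"]


@dataclass
class SamplerConfig:
    """Knobs of one Gibbs run; defaults follow the package's standard fits
    (1000 iterations, 250 burn-in, no thinning)."""

    iterations: int = 1000
    burn_in: int = 250
    thinning: int = 1
    mh_step_sizes: tuple = (0.01, 0.005, 0.05, 0.1)
    adapt_mh: bool = True
    init_mode: str = "around_mean"
    fixed_a: float | None = None
    estimate_fluctuations: bool = True
    hyperprior: HyperPriorConfig = field(default_factory=HyperPriorConfig)
    store_trajectories: bool = True
    progress: bool = False

    def __post_init__(self):
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("need 0 <= burn_in < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if any(s <= 0 for s in self.mh_step_sizes) or len(self.mh_step_sizes) != 4:
            raise ValueError("mh_step_sizes must be four positive reals")
        if self.fixed_a is not None and not 0.0 <= self.fixed_a <= 1.0:
            raise ValueError("fixed_a must lie in [0, 1]")


@dataclass
class GibbsState:
    """Current value of every latent block."""

    subject_params: list
    trajectories: list
    eta: HyperParams


@dataclass
class PosteriorChain:
    """Per-iteration records of every sampled block.

    Trajectory samples are kept in float32 (one (iterations, T_i) array per
    subject) to bound memory on long runs.
    """

    w: np.ndarray          # (S, N, p)
    a: np.ndarray          # (S, N)
    sigma2: np.ndarray     # (S, N)
    mu_x: np.ndarray       # (S, N)
    x: list                # per subject: (S, T_i) float32, or None
    eta: dict              # name -> (S, ...) arrays
    mh_accept: np.ndarray  # (S, 4) booleans
    burn_in: int
    thinning: int
    seed: object
    config: SamplerConfig

    @property
    def n_iterations(self) -> int:
        return self.a.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.a.shape[1]

    def post_burn(self, name: str):
        """Post-burn-in samples of a parameter group, thinned."""
        sl = slice(self.burn_in, None, self.thinning)
        if name in self.eta:
            return self.eta[name][sl]
        return getattr(self, name)[sl]

    def subject_posterior_means(self) -> list[SubjectParams]:
        w = self.post_burn("w").mean(axis=0)
        a = self.post_burn("a").mean(axis=0)
        s2 = self.post_burn("sigma2").mean(axis=0)
        mx = self.post_burn("mu_x").mean(axis=0)
        return [
            SubjectParams(w=w[i], a=float(a[i]), sigma2=float(s2[i]), mu_x=float(mx[i]))
            for i in range(self.n_subjects)
        ]

    def eta_posterior_mean(self) -> HyperParams:
        e = {k: self.post_burn(k).mean(axis=0) for k in self.eta}
        return HyperParams(
            mu_w=e["mu_w"],
            sigma2_w=e["sigma2_w"],
            mu_a=float(e["mu_a"]),
            sigma2_a=float(e["sigma2_a"]),
            mu_sigma2=float(e["mu_sigma2"]),
            beta_sigma2=float(e["beta_sigma2"]),
            sigma2_mux=float(e["sigma2_mux"]),
        )

    def trajectory_samples(self, i: int) -> np.ndarray:
        if self.x[i] is None:
            raise ValueError("trajectories were not stored for this run")
        return self.x[i][self.burn_in :: self.thinning].astype(float)

    def trajectory_summary(self, i: int, level: float = 0.95):
        """(mean, lower, upper) arrays of the posterior criterion at each
        trial of subject i."""
        xs = self.trajectory_samples(i)
        lo = 100 * (1.0 - level) / 2.0
        return xs.mean(axis=0), np.percentile(xs, lo, axis=0), np.percentile(
            xs, 100 - lo, axis=0
        )

    def mh_acceptance_rates(self) -> np.ndarray:
        return self.mh_accept[self.burn_in :].mean(axis=0)


# ---------------------------------------------------------------------------


def _init_logistic(subject: SubjectData, ridge: float = 1.0):
    """Cheap fixed-criterion logistic fit (ridge-stabilised Newton) used to
    initialise w and the intercept."""
    u = np.column_stack([np.ones(subject.n_trials), subject.covariates])
    y = subject.responses.astype(float)
    beta = np.zeros(u.shape[1])
    for _ in range(25):
        p = sigmoid(u @ beta)
        wdiag = np.maximum(p * (1 - p), 1e-6)
        grad = u.T @ (y - p) - ridge * beta
        hess = (u * wdiag[:, None]).T @ u + ridge * np.eye(u.shape[1])
        step = np.linalg.solve(hess, grad)
        beta += step
        if np.abs(step).max() < 1e-8:
            break
    return beta[1:], float(beta[0])


def initial_state(
    dataset: list[SubjectData], config: SamplerConfig
) -> GibbsState:
    """Deterministic starting point: per-subject logistic fits for w, the
    clipped intercept for mu_x, a = 0.9, sigma2 = 0.1, flat trajectories."""
    params, trajs = [], []
    a0 = 0.9 if config.fixed_a is None else config.fixed_a
    for sub in dataset:
        w0, icpt = _init_logistic(sub)
        mu_x0 = float(np.clip(icpt, -2.0, 2.0))
        params.append(SubjectParams(w=w0, a=a0, sigma2=0.1, mu_x=mu_x0))
        trajs.append(LatentTrajectory(np.full(sub.n_trials, mu_x0)))
    ws = np.array([p.w for p in params])
    muxs = np.array([p.mu_x for p in params])
    eta = HyperParams(
        mu_w=ws.mean(axis=0),
        sigma2_w=np.clip(ws.var(axis=0), 0.1, None),
        mu_a=a0,
        sigma2_a=0.01,
        mu_sigma2=0.1,
        beta_sigma2=0.5,
        sigma2_mux=float(np.clip(muxs.var(), 0.1, None)),
    )
    return GibbsState(params, trajs, eta)


def gibbs_sweep(
    dataset: list[SubjectData],
    state: GibbsState,
    config: SamplerConfig,
    rng: np.random.Generator,
    mh_steps=None,
):
    """One full blocked-Gibbs sweep, in place.  Returns MH acceptances."""
    eta = state.eta
    alpha = eta.alpha_sigma2
    for i, sub in enumerate(dataset):
        p_i = state.subject_params[i]
        x_i = state.trajectories[i]
        lin = sub.covariates @ p_i.w
        omega = sample_pg1(lin + x_i.x, rng)

        if config.estimate_fluctuations:
            filt = forward_filter(sub, p_i, lin, omega, config.init_mode)
            x_i = backward_sample(filt, p_i, rng)
        else:
            x_i = LatentTrajectory(np.full(sub.n_trials, p_i.mu_x))

        w_new = update_weights(sub, x_i, omega, eta.mu_w, eta.sigma2_w, rng)
        p_i = replace(p_i, w=w_new)

        if config.estimate_fluctuations:
            if config.fixed_a is None:
                a_new = update_a(x_i, p_i, eta.mu_a, eta.sigma2_a, rng,
                                 init_mode=config.init_mode)
                p_i = replace(p_i, a=a_new)
            s2_new = update_sigma2(x_i, p_i, alpha, eta.beta_sigma2, rng,
                                   init_mode=config.init_mode)
            p_i = replace(p_i, sigma2=s2_new)
            mux_new = update_mux(x_i, p_i, eta.sigma2_mux, rng,
                                 init_mode=config.init_mode)
            p_i = replace(p_i, mu_x=mux_new)
        else:
            lin_new = sub.covariates @ w_new
            mux_new = update_mux_fixed_criterion(
                sub, omega, lin_new, eta.sigma2_mux, rng
            )
            p_i = replace(p_i, mu_x=mux_new)
            x_i = LatentTrajectory(np.full(sub.n_trials, mux_new))

        state.subject_params[i] = p_i
        state.trajectories[i] = x_i

    state.eta = update_global_normals(
        state.subject_params, state.eta, config.hyperprior, rng
    )
    steps = config.mh_step_sizes if mh_steps is None else mh_steps
    state.eta, accepted = update_global_mh(
        state.subject_params, state.eta, steps, config.hyperprior, rng
    )
    return accepted


def run_gibbs(
    dataset: list[SubjectData],
    config: SamplerConfig | None = None,
    seed=None,
) -> PosteriorChain:
    """Run the full sampler and record every iteration.

    ``seed`` may be an int, a SeedSequence, or a Generator; the chain is
    bit-reproducible given the same seed and dataset.
    """
    if not dataset:
        raise ValueError("dataset must contain at least one subject")
    p = dataset[0].n_covariates
    if any(d.n_covariates != p for d in dataset):
        raise ValueError("all subjects must share the same covariate count")
    _check_no_constant_column(dataset)
    config = config or SamplerConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = len(dataset)
    s_tot = config.iterations
    state = initial_state(dataset, config)

    chain = PosteriorChain(
        w=np.empty((s_tot, n, p)),
        a=np.empty((s_tot, n)),
        sigma2=np.empty((s_tot, n)),
        mu_x=np.empty((s_tot, n)),
        x=[
            np.empty((s_tot, d.n_trials), dtype=np.float32)
            if config.store_trajectories
            else None
            for d in dataset
        ],
        eta={
            "mu_w": np.empty((s_tot, p)),
            "sigma2_w": np.empty((s_tot, p)),
            "mu_a": np.empty(s_tot),
            "sigma2_a": np.empty(s_tot),
            "mu_sigma2": np.empty(s_tot),
            "beta_sigma2": np.empty(s_tot),
            "sigma2_mux": np.empty(s_tot),
        },
        mh_accept=np.zeros((s_tot, 4), dtype=bool),
        burn_in=config.burn_in,
        thinning=config.thinning,
        seed=seed,
        config=config,
    )

    steps = np.array(config.mh_step_sizes, dtype=float)
    accept_window = np.zeros(4)
    t0 = time.time()
    for s in range(s_tot):
        try:
            accepted = gibbs_sweep(dataset, state, config, rng, tuple(steps))
        except Exception as err:
            raise RuntimeError(f"Gibbs sweep failed at iteration {s}: {err}") from err
        chain.mh_accept[s] = accepted
        accept_window += accepted

        # Robbins-Monro-flavoured step adaptation, burn-in only (frozen
        # afterwards so the post-burn kernel satisfies detailed balance)
        if config.adapt_mh and s < config.burn_in and (s + 1) % 20 == 0:
            rates = accept_window / 20.0
            steps *= np.exp(1.2 * (rates - 0.3))
            steps = np.clip(steps, 1e-4, 2.0)
            accept_window[:] = 0.0

        for i in range(n):
            p_i = state.subject_params[i]
            chain.w[s, i] = p_i.w
            chain.a[s, i] = p_i.a
            chain.sigma2[s, i] = p_i.sigma2
            chain.mu_x[s, i] = p_i.mu_x
            if config.store_trajectories:
                chain.x[i][s] = state.trajectories[i].x
        e = state.eta
        chain.eta["mu_w"][s] = e.mu_w
        chain.eta["sigma2_w"][s] = e.sigma2_w
        chain.eta["mu_a"][s] = e.mu_a
        chain.eta["sigma2_a"][s] = e.sigma2_a
        chain.eta["mu_sigma2"][s] = e.mu_sigma2
        chain.eta["beta_sigma2"][s] = e.beta_sigma2
        chain.eta["sigma2_mux"][s] = e.sigma2_mux

        if config.progress and (s + 1) % 100 == 0:
            rate = chain.mh_accept[: s + 1].mean(axis=0)
            print(
                f"  sweep {s + 1}/{s_tot}  ({time.time() - t0:.1f}s)  "
                f"MH accept {np.array2string(rate, precision=2)}"
            )
    return chain


def _check_no_constant_column(dataset: list[SubjectData]):
    """A covariate column constant over all trials of all subjects is
    non-identifiable: the trajectory mean mu_x,i absorbs any intercept."""
    stacked = np.vstack([d.covariates for d in dataset])
    const = stacked.std(axis=0) == 0.0
    if const.any():
        cols = np.flatnonzero(const).tolist()
        raise ValueError(
            f"covariate column(s) {cols} are constant across all trials; "
            "remove them — the per-subject criterion mean already plays the "
            "role of an intercept"
        )
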