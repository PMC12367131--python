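"""Recovery, coverage and convergence metrics for simulation studies.

The evaluation surface of a parameter-recovery study: Pearson correlation
between generative and posterior-mean estimates (per parameter, across
subjects), per-subject trajectory correlation and RMSE, equal-tailed
credible intervals, and coverage counts of the global parameters across
replicate datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import HyperParams, LatentTrajectory, SubjectParams
from .sampler import PosteriorChain

__all__ = [
    "recovery_correlation",
    "trajectory_rmse",
    "credible_interval",
    "coverage_count",
    "chain_autocorrelation",
    "RecoveryReport",
    "evaluate_recovery",
    "plot_recovery_scatter",
    "plot_trajectory_overlay",
]

_GLOBAL_NAMES = (
    "mu_a",
    "sigma2_a",
    "mu_sigma2",
    "beta_sigma2",
    "sigma2_mux",
)


def recovery_correlation(true_values, estimates) -> float:
    """Pearson correlation between generative values and estimates."""
    t = np.asarray(true_values, dtype=float)
    e = np.asarray(estimates, dtype=float)
    if t.shape != e.shape or t.shape[0] < 3:
        raise ValueError("need two equal-length sequences of length >= 3")
    if t.std() == 0.0 or e.std() == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(t, e)[0, 1])


def trajectory_rmse(true_traj, estimate) -> float:
    """Root mean squared pointwise error between two trajectories."""
    t = true_traj.x if isinstance(true_traj, LatentTrajectory) else np.asarray(true_traj)
    e = estimate.x if isinstance(estimate, LatentTrajectory) else np.asarray(estimate)
    if t.shape != e.shape:
        raise ValueError("trajectory length mismatch")
    return float(np.sqrt(np.mean((t - e) ** 2)))


def credible_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Central equal-tailed posterior interval."""
    s = np.asarray(samples, dtype=float)
    if s.shape[0] < 100:
        raise ValueError("need at least 100 posterior samples")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    lo = 100 * (1.0 - level) / 2.0
    return float(np.percentile(s, lo)), float(np.percentile(s, 100 - lo))


def coverage_count(
    chains: list[PosteriorChain],
    true_eta: HyperParams,
    level: float = 0.95,
) -> dict[str, int]:
    """Per global parameter, the number of datasets whose equal-tailed
    credible interval contains the generative value.

    For mu_w and sigma2_w the within-dataset truth is the mean/variance of
    that dataset's realised per-subject weights (finite-sample analogue of
    the population values); counts for those are reported per coordinate
    as mu_w_0, sigma2_w_0, ...
    """
    if not chains:
        raise ValueError("need at least one fitted dataset")
    counts: dict[str, int] = {}
    for name in _GLOBAL_NAMES:
        truth = getattr(true_eta, name)
        c = 0
        for ch in chains:
            lo, hi = credible_interval(ch.post_burn(name), level)
            c += int(lo <= truth <= hi)
        counts[name] = c
    p = true_eta.n_covariates
    for j in range(p):
        counts[f"mu_w_{j}"] = 0
        counts[f"sigma2_w_{j}"] = 0
    for ch in chains:
        for j in range(p):
            lo, hi = credible_interval(ch.post_burn("mu_w")[:, j], level)
            counts[f"mu_w_{j}"] += int(lo <= true_eta.mu_w[j] <= hi)
            lo, hi = credible_interval(ch.post_burn("sigma2_w")[:, j], level)
            counts[f"sigma2_w_{j}"] += int(lo <= true_eta.sigma2_w[j] <= hi)
    return counts


def chain_autocorrelation(samples, max_lag: int) -> np.ndarray:
    """Sample autocorrelation of an MCMC trace at lags 1..max_lag."""
    s = np.asarray(samples, dtype=float)
    if s.shape[0] <= max_lag:
        raise ValueError("need more samples than max_lag")
    s = s - s.mean()
    var = float(s @ s)
    if var == 0.0:
        raise ValueError("autocorrelation undefined for a constant chain")
    return np.array([float(s[k:] @ s[:-k]) / var for k in range(1, max_lag + 1)])


@dataclass
class RecoveryReport:
    """Summary of one simulate-then-refit experiment."""

    parameter_correlations: dict
    trajectory_correlations: np.ndarray
    trajectory_rmses: np.ndarray
    mean_trajectory_correlation: float
    mean_trajectory_rmse: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": f"r_{k}", "value": v}
            for k, v in self.parameter_correlations.items()
        ]
        rows.append(
            {"metric": "mean_trajectory_r", "value": self.mean_trajectory_correlation}
        )
        rows.append({"metric": "mean_trajectory_rmse", "value": self.mean_trajectory_rmse})
        return pd.DataFrame(rows)

    def __str__(self):
        lines = ["Recovery report", "---------------"]
        for k, v in self.parameter_correlations.items():
            lines.append(f"  r({k:<8s}) = {v:+.3f}")
        lines.append(
            f"  trajectory: mean r = {self.mean_trajectory_correlation:.3f}, "
            f"mean RMSE = {self.mean_trajectory_rmse:.3f} "
            f"(n = {len(self.trajectory_correlations)} subjects)"
        )
        return "\n".join(lines)


def evaluate_recovery(
    chain: PosteriorChain,
    true_params: list[SubjectParams],
    true_trajectories: list[LatentTrajectory] | None = None,
) -> RecoveryReport:
    """Compare posterior means against the generative subject-level truth."""
    est = chain.subject_posterior_means()
    true_w = np.array([p.w for p in true_params])
    est_w = np.array([p.w for p in est])
    corr = {}
    for j in range(true_w.shape[1]):
        corr[f"w_{j}"] = recovery_correlation(true_w[:, j], est_w[:, j])
    for name in ("a", "sigma2", "mu_x"):
        corr[name] = recovery_correlation(
            [getattr(p, name) for p in true_params],
            [getattr(p, name) for p in est],
        )
    traj_r, traj_rmse = np.array([]), np.array([])
    if true_trajectories is not None:
        r, rm = [], []
        for i, truth in enumerate(true_trajectories):
            mean, _, _ = chain.trajectory_summary(i)
            r.append(recovery_correlation(truth.x, mean))
            rm.append(trajectory_rmse(truth, LatentTrajectory(mean)))
        traj_r, traj_rmse = np.array(r), np.array(rm)
    return RecoveryReport(
        parameter_correlations=corr,
        trajectory_correlations=traj_r,
        trajectory_rmses=traj_rmse,
        mean_trajectory_correlation=float(traj_r.mean()) if traj_r.size else np.nan,
        mean_trajectory_rmse=float(traj_rmse.mean()) if traj_rmse.size else np.nan,
    )


# ---------------------------------------------------------------------------
# plotting


def plot_recovery_scatter(true_params, chain: PosteriorChain, path=None):
    """Scatter of generative vs posterior-mean subject parameters, one
    panel per parameter, diagonal as reference."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    est = chain.subject_posterior_means()
    p = true_params[0].w.shape[0]
    names = [f"w_{j}" for j in range(p)] + ["a", "sigma2", "mu_x"]
    fig, axes = plt.subplots(1, len(names), figsize=(3 * len(names), 3))
    for ax, name in zip(np.atleast_1d(axes), names):
        if name.startswith("w_"):
            j = int(name[2:])
            t = [q.w[j] for q in true_params]
            e = [q.w[j] for q in est]
        else:
            t = [getattr(q, name) for q in true_params]
            e = [getattr(q, name) for q in est]
        ax.scatter(t, e, s=12, alpha=0.7)
        lim = [min(min(t), min(e)), max(max(t), max(e))]
        ax.plot(lim, lim, "k--", lw=0.8)
        ax.set_title(name)
        ax.set_xlabel("true")
    np.atleast_1d(axes)[0].set_ylabel("posterior mean")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_trajectory_overlay(chain: PosteriorChain, subject_index: int,
                            true_trajectory=None, path=None):
    """Posterior mean criterion with its 95% band, optionally overlaid on
    the generative trajectory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean, lo, hi = chain.trajectory_summary(subject_index)
    t = np.arange(1, mean.shape[0] + 1)
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.fill_between(t, lo, hi, alpha=0.3, label="95% credible band")
    ax.plot(t, mean, lw=1.2, label="posterior mean")
    if true_trajectory is not None:
        x = (
            true_trajectory.x
            if isinstance(true_trajectory, LatentTrajectory)
            else np.asarray(true_trajectory)
        )
        ax.plot(t, x, lw=1.0, color="k", alpha=0.7, label="true criterion")
    ax.set_xlabel("trial")
    ax.set_ylabel("criterion x_t")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
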