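"""Model / Results interface over the Gibbs sampler.

`CriterionFluctuationModel` wraps a multi-subject dataset; its `fit()`
runs the blocked Gibbs sampler and returns a
`CriterionFluctuationResults` carrying the posterior chain, point
estimates (posterior means), credible intervals, a text `summary()`, and
plotting/simulation helpers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from .diagnostics import chain_autocorrelation, credible_interval
from .model import HyperParams, SubjectData, simulate_subject
from .sampler import PosteriorChain, SamplerConfig, run_gibbs

__all__ = ["CriterionFluctuationModel", "CriterionFluctuationResults"]

_GLOBAL_ORDER = (
    "mu_a",
    "sigma2_a",
    "mu_sigma2",
    "beta_sigma2",
    "sigma2_mux",
)


class CriterionFluctuationModel:
    """Hierarchical Bernoulli state-space model of criterion drift.

    Parameters
    ----------
    data : list of SubjectData
        One entry per subject; covariate count must agree across subjects.
    covariate_names : sequence of str, optional
        Labels used in summaries; defaults to cov_1..cov_p.
    """

    def __init__(self, data: list[SubjectData], covariate_names=None):
        if not data:
            raise ValueError("empty dataset")
        p = data[0].n_covariates
        if any(d.n_covariates != p for d in data):
            raise ValueError("covariate count differs across subjects")
        self.data = list(data)
        self.covariate_names = (
            list(covariate_names)
            if covariate_names is not None
            else [f"cov_{j + 1}" for j in range(p)]
        )
        if len(self.covariate_names) != p:
            raise ValueError("covariate_names length mismatch")

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        response: str = "response",
        covariates=None,
        subject: str = "subject",
        trial: str = "trial",
    ) -> "CriterionFluctuationModel":
        """Build from a long-format trial table (one row per trial)."""
        if covariates is None:
            covariates = [c for c in frame.columns if c.startswith("cov_")]
        missing = [c for c in (response, subject, trial, *covariates)
                   if c not in frame.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        data = []
        for sid, g in frame.groupby(subject, sort=True):
            g = g.sort_values(trial)
            if g[trial].duplicated().any():
                dup = g.loc[g[trial].duplicated(), trial].tolist()[:5]
                raise ValueError(f"subject {sid}: duplicate trial indices {dup}")
            data.append(
                SubjectData(sid, g[response].to_numpy(), g[covariates].to_numpy())
            )
        return cls(data, covariate_names=list(covariates))

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_covariates(self) -> int:
        return self.data[0].n_covariates

    def fit(
        self,
        iterations: int = 1000,
        burn_in: int = 250,
        seed=None,
        config: SamplerConfig | None = None,
        **config_kwargs,
    ) -> "CriterionFluctuationResults":
        """Run the Gibbs sampler.

        Any extra keyword argument is forwarded to :class:`SamplerConfig`
        (e.g. ``fixed_a=0.9995`` or ``estimate_fluctuations=False``).
        """
        if config is None:
            config = SamplerConfig(
                iterations=iterations, burn_in=burn_in, **config_kwargs
            )
        chain = run_gibbs(self.data, config, seed=seed)
        return CriterionFluctuationResults(self, chain)


class CriterionFluctuationResults:
    """Posterior summaries of a fitted criterion-fluctuation model."""

    def __init__(self, model: CriterionFluctuationModel, chain: PosteriorChain):
        self.model = model
        self.chain = chain

    # -- point estimates ----------------------------------------------------

    @property
    def subject_params(self) -> pd.DataFrame:
        """Posterior-mean subject-level parameters, one row per subject."""
        est = self.chain.subject_posterior_means()
        rows = []
        for d, p in zip(self.model.data, est):
            row = {"subject": d.subject_id, "a": p.a, "sigma2": p.sigma2,
                   "mu_x": p.mu_x, "b": p.b}
            for name, val in zip(self.model.covariate_names, p.w):
                row[f"w_{name}"] = val
            rows.append(row)
        return pd.DataFrame(rows)

    @property
    def hyperparams(self) -> HyperParams:
        """Posterior-mean group-level parameters."""
        return self.chain.eta_posterior_mean()

    def weight_ci(self, covariate: int | str, subject_index: int | None = None,
                  level: float = 0.95):
        """Credible interval of one weight: a subject's, or (default) the
        group mean mu_w."""
        j = (
            self.model.covariate_names.index(covariate)
            if isinstance(covariate, str)
            else covariate
        )
        if subject_index is None:
            samples = self.chain.post_burn("mu_w")[:, j]
        else:
            samples = self.chain.post_burn("w")[:, subject_index, j]
        return credible_interval(samples, level)

    def trajectory(self, subject_index: int, level: float = 0.95):
        """(mean, lower, upper) of the posterior criterion per trial."""
        return self.chain.trajectory_summary(subject_index, level)

    # -- diagnostics --------------------------------------------------------

    def mh_acceptance(self) -> dict:
        rates = self.chain.mh_acceptance_rates()
        return dict(zip(("mu_a", "sigma2_a", "mu_sigma2", "beta_sigma2"), rates))

    def global_autocorrelation(self, name: str, max_lag: int = 20) -> np.ndarray:
        return chain_autocorrelation(self.chain.post_burn(name), max_lag)

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        """Text table of group-level posteriors (mean, sd, 95% CI)."""
        rows, labels = [], []
        eta = self.chain.eta
        for j, name in enumerate(self.model.covariate_names):
            s = self.chain.post_burn("mu_w")[:, j]
            rows.append(self._row(s))
            labels.append(f"mu_w[{name}]")
            s = self.chain.post_burn("sigma2_w")[:, j]
            rows.append(self._row(s))
            labels.append(f"sigma2_w[{name}]")
        for name in _GLOBAL_ORDER:
            rows.append(self._row(self.chain.post_burn(name)))
            labels.append(name)
        table = SimpleTable(
            rows,
            headers=["mean", "sd", "2.5%", "97.5%"],
            stubs=labels,
            title=(
                f"Criterion-fluctuation model: {self.model.n_subjects} subjects, "
                f"{sum(d.n_trials for d in self.model.data)} trials, "
                f"{self.chain.n_iterations} Gibbs iterations "
                f"({self.chain.burn_in} burn-in)"
            ),
        )
        return table.as_text()

    @staticmethod
    def _row(s):
        lo, hi = np.percentile(s, [2.5, 97.5])
        return [f"{s.mean():.4f}", f"{s.std():.4f}", f"{lo:.4f}", f"{hi:.4f}"]

    # -- posterior-predictive simulation ------------------------------------

    def simulate(self, subject_index: int, rng=None):
        """Simulate a replicate dataset for one subject from its
        posterior-mean parameters (same covariates)."""
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        params = self.chain.subject_posterior_means()[subject_index]
        d = self.model.data[subject_index]
        return simulate_subject(params, d.covariates, rng, subject_id=d.subject_id)

    def plot_trajectory(self, subject_index: int, true_trajectory=None, path=None):
        from .diagnostics import plot_trajectory_overlay

        return plot_trajectory_overlay(
            self.chain, subject_index, true_trajectory, path
        )
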