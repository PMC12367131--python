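"""Reading and writing datasets, ground truth and fitted chains.

Datasets travel as long-format CSV, one row per trial, with columns
``subject, trial, response, cov_1..cov_p`` (trial indices are 1-based
within subject).  Simulated ground truth goes to sidecar CSVs so recovery
studies can be run from files alone.  A fitted chain is persisted as
columnar CSVs plus a JSON manifest recording the configuration, seed and
versions needed to re-run the job bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import HyperParams, LatentTrajectory, SubjectData, SubjectParams
from .sampler import PosteriorChain

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_ground_truth",
    "read_ground_truth",
    "save_chain",
    "write_manifest",
]

FORMAT_VERSION = 1


def write_dataset(dataset: list[SubjectData], path):
    """Long-format CSV, one row per trial."""
    frames = []
    for d in dataset:
        f = pd.DataFrame(
            d.covariates, columns=[f"cov_{j + 1}" for j in range(d.n_covariates)]
        )
        f.insert(0, "response", d.responses)
        f.insert(0, "trial", np.arange(1, d.n_trials + 1))
        f.insert(0, "subject", d.subject_id)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_dataset(path, verbose: bool = False) -> list[SubjectData]:
    """Read and validate a long-format dataset.

    Raises ValueError naming the offending rows on non-binary responses,
    missing covariate values, or duplicate (subject, trial) pairs.
    """
    frame = pd.read_csv(path)
    required = {"subject", "trial", "response"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: missing required columns "
                         f"{sorted(required - set(frame.columns))}")
    cov_cols = sorted(
        (c for c in frame.columns if c.startswith("cov_")),
        key=lambda c: int(c.split("_", 1)[1]),
    )
    if not cov_cols:
        raise ValueError(f"{path}: no covariate columns (cov_1..cov_p) found")

    bad = ~frame["response"].isin((0, 1))
    if bad.any():
        rows = (frame.index[bad] + 2).tolist()[:10]  # +2: header + 0-base
        raise ValueError(f"{path}: non-binary responses at file line(s) {rows}")
    na = frame[cov_cols].isna().any(axis=1)
    if na.any():
        rows = (frame.index[na] + 2).tolist()[:10]
        raise ValueError(f"{path}: missing covariate values at file line(s) {rows}")
    dup = frame.duplicated(subset=["subject", "trial"])
    if dup.any():
        pairs = frame.loc[dup, ["subject", "trial"]].head(10).to_records(index=False)
        raise ValueError(f"{path}: duplicate (subject, trial) pairs {list(pairs)}")

    stacked = frame[cov_cols].to_numpy(dtype=float)
    const = stacked.std(axis=0) == 0.0
    if const.any():
        cols = [cov_cols[j] for j in np.flatnonzero(const)]
        raise ValueError(
            f"{path}: covariate column(s) {cols} are constant across all trials; "
            "the per-subject criterion mean absorbs any intercept, so a constant "
            "column is non-identifiable"
        )

    dataset = []
    for sid, g in frame.groupby("subject", sort=True):
        g = g.sort_values("trial")
        dataset.append(
            SubjectData(sid, g["response"].to_numpy(), g[cov_cols].to_numpy())
        )
    if verbose:
        ts = [d.n_trials for d in dataset]
        print(
            f"read {len(dataset)} subjects, T in [{min(ts)}, {max(ts)}], "
            f"{len(cov_cols)} covariates"
        )
    return dataset


def write_ground_truth(outdir, params: list[SubjectParams],
                       trajectories: list[LatentTrajectory],
                       eta: HyperParams | None = None):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, p in enumerate(params):
        row = {"subject": i, "a": p.a, "sigma2": p.sigma2, "mu_x": p.mu_x, "b": p.b}
        for j, v in enumerate(p.w):
            row[f"w_{j + 1}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "true_params.csv", index=False)
    frames = []
    for i, t in enumerate(trajectories):
        frames.append(pd.DataFrame({
            "subject": i, "trial": np.arange(1, t.n_trials + 1), "x": t.x,
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "true_trajectories.csv", index=False
    )
    if eta is not None:
        with open(outdir / "true_hyperparams.json", "w") as fh:
            json.dump(_eta_dict(eta), fh, indent=2)


def read_ground_truth(outdir):
    outdir = Path(outdir)
    pframe = pd.read_csv(outdir / "true_params.csv")
    w_cols = sorted((c for c in pframe.columns if c.startswith("w_")),
                    key=lambda c: int(c.split("_", 1)[1]))
    params = [
        SubjectParams(w=r[w_cols].to_numpy(dtype=float), a=r["a"],
                      sigma2=r["sigma2"], mu_x=r["mu_x"])
        for _, r in pframe.iterrows()
    ]
    tframe = pd.read_csv(outdir / "true_trajectories.csv")
    trajs = [
        LatentTrajectory(g.sort_values("trial")["x"].to_numpy())
        for _, g in tframe.groupby("subject", sort=True)
    ]
    return params, trajs


def _eta_dict(eta: HyperParams) -> dict:
    return {
        "mu_w": eta.mu_w.tolist(),
        "sigma2_w": eta.sigma2_w.tolist(),
        "mu_a": eta.mu_a,
        "sigma2_a": eta.sigma2_a,
        "mu_sigma2": eta.mu_sigma2,
        "beta_sigma2": eta.beta_sigma2,
        "sigma2_mux": eta.sigma2_mux,
        "alpha_sigma2": eta.alpha_sigma2,
    }


def save_chain(chain: PosteriorChain, outdir, subject_ids=None):
    """Persist a fitted chain: global-parameter draws, per-subject draws
    summarised as posterior means, per-trial trajectory summaries, and a
    manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    eta_frame = pd.DataFrame({
        k: (v if v.ndim == 1 else list(v))
        for k, v in (
            (k, chain.eta[k]) for k in
            ("mu_a", "sigma2_a", "mu_sigma2", "beta_sigma2", "sigma2_mux")
        )
    })
    p = chain.eta["mu_w"].shape[1]
    for j in range(p):
        eta_frame[f"mu_w_{j + 1}"] = chain.eta["mu_w"][:, j]
        eta_frame[f"sigma2_w_{j + 1}"] = chain.eta["sigma2_w"][:, j]
    eta_frame.insert(0, "iteration", np.arange(chain.n_iterations))
    eta_frame.to_csv(outdir / "global_params.csv", index=False)

    ids = subject_ids or list(range(chain.n_subjects))
    rows = []
    for i, est in enumerate(chain.subject_posterior_means()):
        row = {"subject": ids[i], "a": est.a, "sigma2": est.sigma2,
               "mu_x": est.mu_x, "b": est.b}
        for j, v in enumerate(est.w):
            row[f"w_{j + 1}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "subject_posterior_means.csv", index=False)

    if chain.x[0] is not None:
        frames = []
        for i in range(chain.n_subjects):
            mean, lo, hi = chain.trajectory_summary(i)
            frames.append(pd.DataFrame({
                "subject": ids[i],
                "trial": np.arange(1, mean.shape[0] + 1),
                "x_mean": mean, "x_lo": lo, "x_hi": hi,
            }))
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "trajectory_summary.csv", index=False
        )


def write_manifest(outdir, command: str, seed, config=None, extra=None):
    """JSON record sufficient to re-run a job bit-identically."""
    import hmfc

    manifest = {
        "format_version": FORMAT_VERSION,
        "package_version": hmfc.__version__,
        "numpy_version": np.__version__,
        "command": command,
        "seed": seed,
    }
    if config is not None:
        cfg = dataclasses.asdict(config)
        manifest["config"] = json.loads(json.dumps(cfg, default=str))
    if extra:
        manifest.update(extra)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
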