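"""End-to-end orchestration: simulate/preprocess -> split -> fit -> predict
-> evaluate, with table/figure artifacts and a run manifest.

Artifacts written to the run directory:

* ``cohort.csv`` (+ ``.constants.json`` sidecar) — canonical dataset
* ``posterior_multivariate.npz`` / ``posterior_univariate.npz``
* ``posterior_summary.csv`` — parameter, median, 2.5%, 97.5%, significance
* ``predictions.csv`` — sequential external predictions for test subjects
* ``report.json`` — RMSE/AB/AUC/DeLong/coverage
* ``fig_*.png`` — trajectory and prediction-interval figures
* ``manifest.json`` — seeds, config, artifact SHA-256 hashes
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortDataset, read_long_csv, split_train_test, standardize_covariates
from .metrics import evaluate_fit
from .model import MCMCConfig, ModelSpec, fit_mglmm, fit_univariate_set, summarize_posterior, cross_outcome_correlation
from .predict import sequential_prediction_table
from .simulate import SimulationConfig, apply_dropout, simulate_cohort

log = logging.getLogger("mvglmm")

__all__ = ["PipelineConfig", "run_pipeline", "plot_trajectories", "plot_predictions"]


@dataclass
class PipelineConfig:
    """Everything one run needs; ``seed`` feeds every stochastic stage."""

    out_dir: str = "mvglmm_run"
    data_csv: str | None = None          # real data; None -> simulate
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    apply_dropout: bool = True
    n_test: int = 6
    spec: ModelSpec = field(default_factory=ModelSpec)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    fit_univariate: bool = True
    seed: int = 0


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    log.info("stage=%s start", name)
    return time.time()


def plot_trajectories(dataset: CohortDataset, out_dir: str | Path) -> list[Path]:
    """Spaghetti plots of the two continuous outcomes and a per-visit
    stacked-proportion plot of the binary imbalance indicator."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = dataset.frame()
    paths = []
    for col, label in [("Y1", "MDS-UPDRS-II (motor)"), ("Y2", "MDS-UPDRS-I (non-motor)")]:
        fig, ax = plt.subplots(figsize=(5, 4))
        for _, g in df.groupby("subject_id"):
            g = g.dropna(subset=[col]).sort_values("visit_time")
            ax.plot(g["visit_time"], g[col], color="crimson", alpha=0.35, lw=1)
            ax.plot(g["visit_time"], g[col], "k.", ms=3)
        ax.set_xlabel("months since baseline")
        ax.set_ylabel(label)
        p = out_dir / f"fig_trajectories_{col}.png"
        fig.tight_layout(); fig.savefig(p, dpi=110); plt.close(fig)
        paths.append(p)
    fig, ax = plt.subplots(figsize=(5, 4))
    props = df.dropna(subset=["Y3"]).groupby("visit_time")["Y3"].mean()
    ax.bar(range(len(props)), 1 - props.values, color="white", edgecolor="k", label="no imbalance")
    ax.bar(range(len(props)), props.values, bottom=1 - props.values,
           color="crimson", edgecolor="k", label="imbalance")
    ax.set_xticks(range(len(props)), [f"{int(t)} mo" for t in props.index])
    ax.set_ylabel("proportion")
    ax.legend()
    p = out_dir / "fig_trajectories_Y3.png"
    fig.tight_layout(); fig.savefig(p, dpi=110); plt.close(fig)
    paths.append(p)
    return paths


def plot_predictions(table: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Per-subject predicted points with 95% interval bars and observed
    overlays, one panel per history window."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for window, sub in table.groupby("history_window"):
        fig, axes = plt.subplots(1, sub["outcome"].nunique(),
                                 figsize=(4 * sub["outcome"].nunique(), 4),
                                 squeeze=False)
        for ax, (name, g) in zip(axes[0], sub.groupby("outcome")):
            g = g.reset_index(drop=True)
            x = np.arange(len(g))
            ax.errorbar(x, g["predicted"],
                        yerr=[g["predicted"] - g["lo95"], g["hi95"] - g["predicted"]],
                        fmt="o", color="navy", capsize=3, label="predicted (95% CrI)")
            obs = g["observed"].to_numpy(float)
            ok = np.isfinite(obs)
            ax.plot(x[ok], obs[ok], "rx", label="observed")
            ax.set_title(f"{name} | history: {window}")
            ax.set_xticks(x, [f"{s}@{int(h)}" for s, h in
                              zip(g["subject_id"], g["horizon_months"])],
                          rotation=90, fontsize=6)
        axes[0][0].legend(fontsize=7)
        p = out_dir / f"fig_predictions_{window.replace('+', '_')}.png"
        fig.tight_layout(); fig.savefig(p, dpi=110); plt.close(fig)
        paths.append(p)
    return paths


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.  A stage failure
    raises with the stage name while earlier artifacts persist."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed, "stages": {}}
    stage = "simulate/load"
    try:
        t0 = _stage(stage)
        if config.data_csv is not None:
            dataset = read_long_csv(config.data_csv)
        else:
            sim = config.simulation
            if sim.seed != config.seed:
                sim = SimulationConfig(**{**asdict_shallow(sim), "seed": config.seed})
            dataset = simulate_cohort(sim)
            if config.apply_dropout:
                dataset = apply_dropout(dataset, sim.dropout_params,
                                        seed=config.seed + 1)
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2),
                                     "n_subjects": dataset.n_subjects}

        stage = "preprocess/split"
        t0 = _stage(stage)
        dataset = split_train_test(dataset, n_test=config.n_test,
                                   seed=config.seed + 2)
        dataset = standardize_covariates(dataset)
        cohort_csv = out / "cohort.csv"
        dataset.to_csv(cohort_csv)
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        stage = "fit"
        t0 = _stage(stage)
        mcmc = config.mcmc
        if mcmc.seed != config.seed:
            mcmc = MCMCConfig(**{**asdict(mcmc), "seed": config.seed + 3})
        post = fit_mglmm(dataset, config.spec, mcmc)
        post.save(out / "posterior_multivariate.npz")
        summary = summarize_posterior(post, force=True)
        summary.to_csv(out / "posterior_summary.csv", index=False)
        post_uni = None
        if config.fit_univariate:
            post_uni = fit_univariate_set(dataset, config.spec, mcmc)
            post_uni.save(out / "posterior_univariate.npz")
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2),
                                     "n_draws": post.n_draws}

        stage = "predict"
        t0 = _stage(stage)
        table = sequential_prediction_table(post, dataset, seed=config.seed + 4)
        table.to_csv(out / "predictions.csv", index=False)
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2),
                                     "rows": len(table)}

        stage = "evaluate"
        t0 = _stage(stage)
        report = evaluate_fit(post, dataset, samples_b=post_uni)
        covered = table["covered"].dropna()
        if len(covered):
            report.coverage = float(covered.astype(float).mean())
        if post.correlation_mode == "multivariate":
            cc = cross_outcome_correlation(post)
            report.provenance["corr_Y1_Y2_median"] = cc["median"]
        if post_uni is not None:
            rep_uni = evaluate_fit(post_uni, dataset)
            report.provenance["univariate"] = {
                "continuous": rep_uni.continuous, "binary": {
                    k: {kk: vv for kk, vv in v.items() if kk != "roc"}
                    for k, v in rep_uni.binary.items()},
            }
        report.to_json(out / "report.json")
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        stage = "figures"
        t0 = _stage(stage)
        figs = plot_trajectories(dataset, out) + plot_predictions(table, out)
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2),
                                     "files": [f.name for f in figs]}
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    manifest["artifacts"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.suffix in (".csv", ".json", ".npz")
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def asdict_shallow(cfg: SimulationConfig) -> dict:
    d = dict(cfg.__dict__)
    return d
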