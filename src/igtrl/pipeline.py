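"""End-to-end orchestration: cohort -> behavior -> model comparison ->
hierarchical fit -> group differences -> report.

A run is a pure function of its configuration and master seed: the cohort
generator, MLE multistarts, and MCMC chains all derive their seeds from
``RunConfig.seed`` by fixed rules, so replaying a config reproduces the
report byte for byte.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import group_behavior_summary
from .cohort import (
    CohortDataset,
    StudyDesign,
    generate_cohort,
    read_cohort_csv,
    write_cohort_csv,
)
from .inference import (
    MCMCConfig,
    Posterior,
    compare_models,
    compute_hdi,
    fit_hba,
    group_difference,
)
from .models import MODELS

log = logging.getLogger("igtrl")

PROFILES = {
    "smoke": {"chains": 2, "warmup": 200, "draws": 200, "thin": 5},
    "full": {"chains": 4, "warmup": 1000, "draws": 1000, "thin": 5},
}


@dataclass
class RunConfig:
    mode: str = "generate"  # "generate" | "load"
    cohort_path: str | None = None
    metadata_path: str | None = None
    n_trials: int = 100
    group_sizes: tuple[int, int, int, int] | None = None
    escalation_rate: float = 0.1
    models: tuple[str, ...] = MODELS
    fit_model: str = "pvl_decay"
    profile: str = "smoke"
    covariates: str | None = None
    mle_starts: int = 10
    out_dir: str = "igtrl_out"
    seed: int = 0
    compare: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.mode not in ("generate", "load"):
            raise ValueError(f"mode must be 'generate' or 'load', got {cfg.mode!r}")
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["models"] = list(self.models)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def mcmc_config(self) -> MCMCConfig:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        return MCMCConfig(seed=self.seed, **PROFILES[self.profile])


@dataclass
class RunReport:
    config: RunConfig
    behavioral: pd.DataFrame
    comparison: dict | None
    parameter_summary: pd.DataFrame
    differences: list[dict]
    diagnostics: dict
    depletion_rate: float

    def to_dict(self) -> dict:
        return {
            "config": {**asdict(self.config), "models": list(self.config.models)},
            "behavioral": self.behavioral.to_dict(orient="records"),
            "model_comparison": self.comparison,
            "parameter_summary": self.parameter_summary.to_dict(orient="records"),
            "group_differences": self.differences,
            "diagnostics": self.diagnostics,
            "depletion_rate": self.depletion_rate,
        }


def parameter_summary_table(posterior: Posterior) -> pd.DataFrame:
    """Group mean (SD) of subject-level posterior means per parameter —
    the layout of the published parameter-summary table."""
    rows = []
    for g, gp in posterior.groups.items():
        means = gp.subject_posterior_means()  # (n, k)
        row: dict = {"group": g, "n": len(gp.subject_ids)}
        for j, name in enumerate(gp.param_names):
            row[f"{name}_mean"] = float(means[:, j].mean())
            row[f"{name}_sd"] = float(means[:, j].std(ddof=1)) if means.shape[0] > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def posterior_draws_frame(posterior: Posterior) -> pd.DataFrame:
    """Long-format group-level draws: chain, iter, quantity, value."""
    rows = []
    for g, gp in posterior.groups.items():
        C, D, K = gp.mu.shape
        for j, name in enumerate(gp.param_names):
            for label, arr in (
                (f"group_mean_{name}", gp.group_mean),
                (f"mu_{name}", gp.mu),
                (f"sigma_{name}", gp.sigma),
            ):
                for c in range(C):
                    rows.append(
                        pd.DataFrame(
                            {
                                "group": g,
                                "chain": c,
                                "iter": np.arange(D),
                                "quantity": label,
                                "value": arr[c, :, j],
                            }
                        )
                    )
    return pd.concat(rows, ignore_index=True)


def posterior_summary_dict(posterior: Posterior) -> dict:
    """JSON-ready per-quantity summary: mean, SD, 95% HDI, split-Rhat, ESS."""
    out: dict = {}
    for g, gp in posterior.groups.items():
        gout = {}
        for j, name in enumerate(gp.param_names):
            draws = gp.group_mean[:, :, j].ravel()
            hdi = compute_hdi(draws)
            gout[f"group_mean_{name}"] = {
                "mean": float(draws.mean()),
                "sd": float(draws.std(ddof=1)),
                "hdi_low": hdi.low,
                "hdi_high": hdi.high,
                "rhat": gp.rhat.get(f"group_mean_{name}"),
                "ess": gp.ess.get(f"group_mean_{name}"),
            }
        gout["converged"] = gp.converged
        out[g] = gout
    return out


def export_posterior_histograms(posterior: Posterior, out_dir: Path) -> list[Path]:
    """Simple per-parameter histograms of natural-scale group-mean draws."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    names = next(iter(posterior.groups.values())).param_names
    for name in names:
        fig, ax = plt.subplots(figsize=(6, 4))
        for g, gp in posterior.groups.items():
            ax.hist(gp.group_mean_draws(name), bins=40, alpha=0.5, label=g, density=True)
        ax.set_xlabel(f"group-level {name}")
        ax.set_ylabel("posterior density")
        ax.legend(fontsize=7)
        p = out_dir / f"posterior_{name}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths.append(p)
    return paths


def run_pipeline(config: RunConfig, make_plots: bool = False) -> RunReport:
    """Execute all stages and write artifacts to ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        log.info("stage %s ...", name)
        return time.perf_counter()

    # --- cohort ---
    t0 = stage("cohort")
    if config.mode == "generate":
        design = StudyDesign.default(
            seed=config.seed,
            n_trials=config.n_trials,
            group_sizes=tuple(config.group_sizes) if config.group_sizes else None,
        )
        dataset = generate_cohort(design)
        write_cohort_csv(dataset, out / "cohort.csv", out / "cohort_metadata.csv")
    elif config.mode == "load":
        if not config.cohort_path:
            raise ValueError("load mode requires cohort_path")
        dataset = read_cohort_csv(config.cohort_path, config.metadata_path)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    timings["cohort"] = time.perf_counter() - t0
    log.info("cohort: %d subjects, groups %s", len(dataset), dataset.groups)

    # --- behavioral summary ---
    t0 = stage("behavior")
    behavioral = group_behavior_summary(dataset)
    behavioral.to_csv(out / "behavioral_summary.csv", index=False)
    timings["behavior"] = time.perf_counter() - t0

    # --- model comparison ---
    comparison_dict = None
    if config.compare:
        t0 = stage("compare")
        comparison = compare_models(
            dataset, list(config.models), n_starts=config.mle_starts, seed=config.seed
        )
        comparison_dict = {
            "bic": comparison.bic,
            "log_loss": comparison.log_loss,
            "selected": comparison.selected,
        }
        pd.DataFrame(
            [
                {"model": m, "bic": comparison.bic[m], "log_loss": comparison.log_loss[m]}
                for m in comparison.bic
            ]
        ).to_csv(out / "model_comparison.csv", index=False)
        timings["compare"] = time.perf_counter() - t0
        log.info("model comparison selected %s", comparison.selected)

    # --- hierarchical Bayesian fit ---
    t0 = stage("fit")
    posterior = fit_hba(
        dataset,
        model=config.fit_model,
        mcmc_config=config.mcmc_config(),
        covariates=config.covariates,
    )
    timings["fit"] = time.perf_counter() - t0
    param_summary = parameter_summary_table(posterior)
    param_summary.to_csv(out / "parameter_summary.csv", index=False)
    posterior_draws_frame(posterior).to_csv(out / "posterior_draws.csv", index=False)
    with open(out / "posterior_summary.json", "w") as fh:
        json.dump(posterior_summary_dict(posterior), fh, indent=2)
    if make_plots:
        export_posterior_histograms(posterior, out / "plots")

    # --- group differences ---
    t0 = stage("diff")
    names = next(iter(posterior.groups.values())).param_names
    differences = []
    for name in names:
        for ga, gb in itertools.combinations(dataset.groups, 2):
            d = group_difference(posterior, name, ga, gb)
            differences.append(
                {
                    "param": name,
                    "group_a": ga,
                    "group_b": gb,
                    "mean": d.mean,
                    "hdi_low": d.hdi.low,
                    "hdi_high": d.hdi.high,
                    "credible": d.credible,
                }
            )
    pd.DataFrame(differences).to_csv(out / "group_differences.csv", index=False)
    timings["diff"] = time.perf_counter() - t0

    diagnostics = {
        "timings_s": timings,
        "converged": posterior.converged,
        "rhat": {g: gp.rhat for g, gp in posterior.groups.items()},
    }
    report = RunReport(
        config=config,
        behavioral=behavioral,
        comparison=comparison_dict,
        parameter_summary=param_summary,
        differences=differences,
        diagnostics=diagnostics,
        depletion_rate=dataset.depletion_rate(),
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    log.info("report written to %s", out / "report.json")
    return report
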