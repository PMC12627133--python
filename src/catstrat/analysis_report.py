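"""Descriptive analysis and the end-to-end pipeline driver.

Covers the reporting layer: blockwise learning curves (per-stratum mean,
SD, SEM of participant accuracies), generalization transfer (test-block
accuracy minus final-training-block accuracy), the symptom-severity
correlation (Pearson r between ASRS score and each participant's mean
accuracy over all training blocks, tasks and modalities, with a Fisher-z
confidence interval), and ``run_pipeline``, which chains
generate -> simulate -> fit -> metrics -> report, writing tidy CSVs and a
manifest.  Inferential mixed models on these outputs are left to external
statistics environments; the CSVs are shaped for that.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .category_spaces import (
    make_generalization_grid,
    optimal_boundary,
    sample_category_set,
    task_distributions,
)
from .decision_bound_models import fit_dataset, write_fits
from .strategy_metrics import compute_metrics
from .synthetic_learners import CohortConfig, simulate_cohort, write_trials

__all__ = [
    "PerformanceSummary",
    "CorrelationResult",
    "PipelineConfig",
    "PipelineStageError",
    "MissingBlockError",
    "participant_block_accuracy",
    "blockwise_accuracy",
    "transfer_score",
    "symptom_correlation",
    "run_pipeline",
]


class MissingBlockError(ValueError):
    """A required block (e.g. the test block) is absent from the trial table."""


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class PerformanceSummary:
    """Stratum-level accuracy summary (one learning-curve point)."""

    group: str
    modality: str
    task: str
    block: object
    mean_accuracy: float
    sd: float
    sem: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def participant_block_accuracy(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant x modality x task x block accuracy and trial count."""
    keys = ["participant_id", "group", "modality", "task", "block"]
    out = (
        trials.groupby(keys, sort=False)["correct"]
        .agg(accuracy="mean", n_trials="size")
        .reset_index()
    )
    return out


def blockwise_accuracy(trials: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-participant block accuracies to stratum mean/SD/SEM."""
    per = participant_block_accuracy(trials)
    grouped = per.groupby(["group", "modality", "task", "block"], sort=False)["accuracy"]
    out = grouped.agg(mean_accuracy="mean", sd=lambda s: s.std(ddof=1), n="size").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out[["group", "modality", "task", "block", "mean_accuracy", "sd", "sem", "n"]]


def transfer_score(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant-task transfer: test-block minus final-training accuracy."""
    per = participant_block_accuracy(trials)
    keys = ["participant_id", "group", "modality", "task"]
    wide = per.pivot_table(index=keys, columns="block", values="accuracy", aggfunc="first")
    for needed in ("test", 8):
        if needed not in wide.columns or wide[needed].isna().any():
            raise MissingBlockError(f"block {needed!r} missing for some participant-task")
    out = wide.reset_index()[keys]
    out["transfer"] = (wide["test"] - wide[8]).to_numpy()
    return out


def symptom_correlation(participants: pd.DataFrame, trials: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation between ASRS score and overall learning accuracy.

    Overall accuracy is the unweighted mean of a participant's training
    block accuracies across blocks, tasks and modalities (32 values for
    the full design).  The 95% CI comes from the Fisher z-transform.
    """
    per = participant_block_accuracy(trials)
    per = per[per["block"] != "test"]
    overall = per.groupby("participant_id")["accuracy"].mean()
    merged = participants.set_index("participant_id").join(overall.rename("accuracy"), how="inner")
    if len(merged) < 4:
        raise ValueError("need at least 4 participants for a correlation")
    x = merged["asrs_score"].to_numpy(dtype=float)
    y = merged["accuracy"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero-variance input")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=0.95)
    return CorrelationResult(
        r=float(res.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=float(res.pvalue),
        n=len(merged),
    )


@dataclass
class PipelineConfig:
    """End-to-end run settings; loadable from a YAML key-value file."""

    seed: int = 20250925
    n_per_group: int = 15
    out_dir: str = "catstrat_output"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_random_starts: int = 10
    refine_top: int = 1
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {}) or {}
        cohort = CohortConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in cohort_raw.items()})
        return cls(cohort=cohort, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Hash of the run-defining settings (the output location is not one)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_plots(out: Path, trials: pd.DataFrame, summary: pd.DataFrame) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    written = []

    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharey=True)
    training = summary[summary["block"] != "test"]
    for ax, (modality, task) in zip(axes.ravel(), product(("auditory", "visual"), ("RB", "II"))):
        for group, style in (("control", "o-"), ("ADHD", "s--")):
            sub = training[
                (training["modality"] == modality)
                & (training["task"] == task)
                & (training["group"] == group)
            ].sort_values("block")
            ax.errorbar(sub["block"], sub["mean_accuracy"], yerr=sub["sem"], fmt=style, label=group)
        ax.axhline(0.5, color="gray", ls=":", lw=1)
        ax.set_title(f"{modality} {task}")
        ax.set_xlabel("block")
        ax.set_ylabel("accuracy")
    axes[0, 0].legend()
    fig.tight_layout()
    p = figdir / "learning_curves.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(str(p.relative_to(out)))
    return written


def run_pipeline(config: PipelineConfig) -> Path:
    """Run generate -> simulate -> fit -> metrics -> report; return out dir.

    Writes stimuli, trials, participants, fits, strategy metrics, accuracy
    summaries, transfer scores, the symptom correlation, and a
    ``manifest.json`` with seeds, version, config hash and per-file SHA-256
    hashes.  Reruns with the same config reproduce identical CSVs.  A stage
    failure raises a stage-named error; outputs of earlier stages remain.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
        "files": {},
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return deco

    @stage("generate")
    def _generate():
        rows = {}
        for modality, task in product(("auditory", "visual"), ("RB", "II")):
            distA, distB = task_distributions(modality, task)
            sset = sample_category_set(distA, distB, config.cohort.n_per_category,
                                       config.cohort.misclassified, seed=config.seed)
            sset.to_csv(out / f"stimuli_{modality}_{task.lower()}.csv")
            bound = optimal_boundary(distA, distB)
            grid = make_generalization_grid(distA.space, task, bound, training_set=sset)
            grid.to_csv(out / f"grid_{modality}_{task.lower()}.csv")
            rows[f"{modality}_{task}"] = len(sset)
        manifest["stages"]["generate"] = {"stimuli_per_task": rows}

    @stage("simulate")
    def _simulate():
        trials, participants = simulate_cohort(config.n_per_group, config.cohort, seed=config.seed)
        write_trials(trials, out / "trials.csv")
        participants.to_csv(out / "participants.csv", index=False)
        manifest["stages"]["simulate"] = {
            "n_trials": len(trials),
            "n_participants": len(participants),
            "groups": sorted(participants["group"].unique().tolist()),
            "tasks": 4,
        }
        return trials, participants

    trials, participants = _simulate

    @stage("fit")
    def _fit():
        fit_seed = (config.seed + 1) % 2**31
        fits = fit_dataset(trials, seed=fit_seed,
                           n_random_starts=config.n_random_starts,
                           refine_top=config.refine_top)
        write_fits(fits, out / "fits.csv")
        manifest["stages"]["fit"] = {
            "seed": fit_seed,
            "n_rows": len(fits),
            "n_best": int(fits["best_flag"].sum()),
        }
        return fits

    fits = _fit

    @stage("metrics")
    def _metrics():
        metrics = compute_metrics(fits, trials, participants)
        metrics.to_csv(out / "strategy_metrics.csv", index=False)
        manifest["stages"]["metrics"] = {"n_rows": len(metrics)}
        return metrics

    _metrics

    @stage("report")
    def _report():
        summary = blockwise_accuracy(trials)
        summary.to_csv(out / "summary_accuracy.csv", index=False)
        transfer = transfer_score(trials)
        transfer.to_csv(out / "transfer.csv", index=False)
        corr = symptom_correlation(participants, trials)
        pd.DataFrame([dataclasses.asdict(corr)]).to_csv(out / "correlation.csv", index=False)
        manifest["stages"]["report"] = {
            "summary_rows": len(summary),
            "transfer_rows": len(transfer),
            "correlation_r": corr.r,
        }
        if config.make_plots:
            manifest["stages"]["figures"] = _write_plots(out, trials, summary)

    _report

    for f in sorted(out.glob("*.csv")):
        manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
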