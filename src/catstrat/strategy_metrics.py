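"""Strategy-use measures derived from the per-block best-model table.

Best-fitting model families collapse to four strategy labels — procedural
(GLC), uni_x, uni_y (unidimensional on either dimension), and random (any
guessing model).  The task-optimal strategy is uni_x for RB categories
(the criterion dimension) and procedural for II categories.  From each
participant-task trajectory of 9 labels (training blocks 1-8 plus the
test block) we derive: the first training block using the optimal
strategy (9 if never, a censoring convention), the total number of
optimal training blocks, and final-block accuracy among participants
whose final-block strategy was optimal.  Test-block labels stay in the
trajectory for proportion summaries but never enter the first/total
counts, which are defined over training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STRATEGY_LABELS",
    "StrategyTrajectory",
    "EmptyStratumError",
    "collapse_family",
    "optimal_label_for",
    "trajectories",
    "first_optimal_block",
    "total_optimal_blocks",
    "accuracy_given_optimal",
    "strategy_proportions",
    "compute_metrics",
    "METRICS_COLUMNS",
]

STRATEGY_LABELS = ("procedural", "uni_x", "uni_y", "random")

METRICS_COLUMNS = [
    "participant_id",
    "group",
    "modality",
    "task",
    "first_optimal_block",
    "total_optimal_blocks",
    "final_block_label",
    "accuracy_given_optimal",
]

_COLLAPSE = {
    "glc": "procedural",
    "uni_x": "uni_x",
    "uni_y": "uni_y",
    "guess_fixed": "random",
    "guess_biased_A": "random",
    "guess_biased_B": "random",
}

_BLOCK_ORDER = tuple(range(1, 9)) + ("test",)


class EmptyStratumError(ValueError):
    """No participants in the requested stratum."""


def collapse_family(family: str, assignment: Optional[str] = None) -> str:
    """Map a model family (assignment ignored) onto its strategy label."""
    try:
        return _COLLAPSE[family]
    except KeyError:
        raise ValueError(f"unknown model family: {family!r}") from None


def optimal_label_for(task: str) -> str:
    """uni_x is optimal for RB categories; procedural for II."""
    if task == "RB":
        return "uni_x"
    if task == "II":
        return "procedural"
    raise ValueError(f"unknown task: {task!r}")


@dataclass(frozen=True)
class StrategyTrajectory:
    """Per-block strategy labels for one participant-task (blocks 1-8 + test)."""

    participant_id: str
    modality: str
    task: str
    labels: tuple[str, ...]
    optimal_label: str

    def __post_init__(self) -> None:
        if len(self.labels) != 9:
            raise ValueError("a trajectory carries exactly 9 labels (blocks 1-8 + test)")
        bad = set(self.labels) - set(STRATEGY_LABELS)
        if bad:
            raise ValueError(f"unknown strategy labels: {sorted(bad)}")
        if self.optimal_label != optimal_label_for(self.task):
            raise ValueError(
                f"optimal label for {self.task} task must be {optimal_label_for(self.task)!r}"
            )

    @property
    def training_labels(self) -> tuple[str, ...]:
        return self.labels[:8]

    @property
    def test_label(self) -> str:
        return self.labels[8]


def trajectories(fits: pd.DataFrame) -> list[StrategyTrajectory]:
    """Build per-participant-task trajectories from best-model rows."""
    best = fits[fits["best_flag"]]
    out = []
    for (pid, modality, task), sub in best.groupby(
        ["participant_id", "modality", "task"], sort=True
    ):
        by_block = dict(zip(sub["block"], zip(sub["family"], sub["assignment"])))
        missing = [b for b in _BLOCK_ORDER if b not in by_block]
        if missing:
            raise ValueError(f"{pid} {modality} {task}: missing best fits for blocks {missing}")
        labels = tuple(collapse_family(*by_block[b]) for b in _BLOCK_ORDER)
        out.append(
            StrategyTrajectory(
                participant_id=pid,
                modality=modality,
                task=task,
                labels=labels,
                optimal_label=optimal_label_for(task),
            )
        )
    return out


def first_optimal_block(traj: StrategyTrajectory) -> int:
    """First training block (1-8) using the optimal strategy; 9 if never."""
    for b, label in enumerate(traj.training_labels, start=1):
        if label == traj.optimal_label:
            return b
    return 9


def total_optimal_blocks(traj: StrategyTrajectory) -> int:
    """Number of training blocks (0-8) using the optimal strategy."""
    return sum(label == traj.optimal_label for label in traj.training_labels)


def accuracy_given_optimal(
    traj: StrategyTrajectory, trials: pd.DataFrame, block: int = 8
) -> Optional[float]:
    """Accuracy in ``block`` if its strategy was optimal, else None.

    Participants not using the optimal strategy in that block are excluded
    from this measure.
    """
    label = traj.labels[_BLOCK_ORDER.index(block)]
    if label != traj.optimal_label:
        return None
    mask = (
        (trials["participant_id"] == traj.participant_id)
        & (trials["modality"] == traj.modality)
        & (trials["task"] == traj.task)
        & (trials["block"] == block)
    )
    sub = trials[mask]
    if len(sub) == 0:
        raise ValueError(f"no trials for {traj.participant_id} {traj.modality} {traj.task} block {block}")
    return float(sub["correct"].mean())


def strategy_proportions(
    fits: pd.DataFrame,
    participants: pd.DataFrame,
    group: str,
    task: str,
    block,
    modality: Optional[str] = None,
) -> pd.Series:
    """Proportion of a stratum's participants using each strategy in a block.

    Proportions are over (procedural, uni_x, uni_y, random) and sum to 1.
    """
    ids = set(participants.loc[participants["group"] == group, "participant_id"])
    best = fits[fits["best_flag"]]
    mask = (
        best["participant_id"].isin(ids)
        & (best["task"] == task)
        & (best["block"] == block)
    )
    if modality is not None:
        mask &= best["modality"] == modality
    sub = best[mask]
    if len(sub) == 0:
        raise EmptyStratumError(f"no participants for group={group}, task={task}, block={block}")
    labels = [collapse_family(f, a) for f, a in zip(sub["family"], sub["assignment"])]
    counts = pd.Series(labels).value_counts()
    props = pd.Series([counts.get(s, 0) for s in STRATEGY_LABELS], index=STRATEGY_LABELS, dtype=float)
    return props / props.sum()


def compute_metrics(
    fits: pd.DataFrame, trials: pd.DataFrame, participants: pd.DataFrame
) -> pd.DataFrame:
    """One metrics row per participant-task: onset, totals, final-block label,
    and accuracy given an optimal final block (NaN when excluded)."""
    group_of = dict(zip(participants["participant_id"], participants["group"]))
    rows = []
    for traj in trajectories(fits):
        acc = accuracy_given_optimal(traj, trials)
        rows.append(
            {
                "participant_id": traj.participant_id,
                "group": group_of.get(traj.participant_id),
                "modality": traj.modality,
                "task": traj.task,
                "first_optimal_block": first_optimal_block(traj),
                "total_optimal_blocks": total_optimal_blocks(traj),
                "final_block_label": traj.labels[7],
                "accuracy_given_optimal": np.nan if acc is None else acc,
            }
        )
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)
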