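"""Synthetic cohorts of strategy-driven category learners.

Simulates trial-level categorization sessions for two groups (an ADHD-like
group and a control group) on the four tasks (auditory/visual x RB/II).
Each simulated learner follows an explicit per-block strategy schedule:
before an onset block the learner guesses or applies a suboptimal
unidimensional rule; from the onset block on, the task-optimal strategy is
applied with participant-specific perceptual/criterial noise.  Strategies
are scheduled, not learned — there is no trial-level learning dynamics.

Responses follow the shared decision-bound response rule
``P(A) = (1 - lapse) * Phi(h / sigma) + lapse / 2`` where ``h`` is the
signed perpendicular distance from the bound (positive on the A side) and
``Phi`` is the standard normal CDF; guessing strategies respond A with a
fixed stimulus-independent probability.

The ADHD-like group draws later optimal-strategy onsets, larger noise, and
ADHD-symptom (ASRS) scores above the screening cutoff of 51; controls draw
scores below it.  This yields, by construction, later first-optimal blocks,
fewer optimal blocks, and a negative ASRS-accuracy correlation at cohort
level.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .category_spaces import (
    DecisionBound,
    StimulusSet,
    make_generalization_grid,
    optimal_boundary,
    sample_category_set,
    task_distributions,
)

__all__ = [
    "StrategySpec",
    "LearnerProfile",
    "CohortConfig",
    "MissingStrategyError",
    "response_probability",
    "sample_responses",
    "simulate_session",
    "simulate_cohort",
    "write_trials",
    "read_trials",
    "TRIAL_COLUMNS",
    "ASRS_CUTOFF",
]

ASRS_CUTOFF = 51.0

TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "modality",
    "task",
    "block",
    "trial_index",
    "stimulus_id",
    "x_norm",
    "y_norm",
    "true_category",
    "response",
    "correct",
    "feedback_given",
]

_GUESS_FAMILIES = ("guess_fixed", "guess_biased")
_BOUND_FAMILIES = ("uni_x", "uni_y", "procedural")


class MissingStrategyError(KeyError):
    """A learner schedule lacks a strategy for some block."""


@dataclass(frozen=True)
class StrategySpec:
    """One block's response strategy: a noisy decision bound, or guessing."""

    family: str
    bound: Optional[DecisionBound] = None
    noise_sigma: Optional[float] = None
    guess_p_A: Optional[float] = None
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse_rate <= 0.5:
            raise ValueError("lapse_rate must lie in [0, 0.5]")
        if self.family in _GUESS_FAMILIES:
            if self.bound is not None or self.noise_sigma is not None:
                raise ValueError("guessing strategies take no bound or noise")
            if self.guess_p_A is None or not 0.0 <= self.guess_p_A <= 1.0:
                raise ValueError("guessing strategies need guess_p_A in [0, 1]")
        elif self.family in _BOUND_FAMILIES:
            if self.bound is None or self.noise_sigma is None:
                raise ValueError("boundary strategies need a bound and noise_sigma")
            if self.noise_sigma <= 0:
                raise ValueError("noise_sigma must be positive")
            if self.guess_p_A is not None:
                raise ValueError("boundary strategies take no guess_p_A")
            if self.family == "uni_x" and self.bound.b != 0.0:
                raise ValueError("uni_x strategy requires a vertical bound")
            if self.family == "uni_y" and self.bound.a != 0.0:
                raise ValueError("uni_y strategy requires a horizontal bound")
        else:
            raise ValueError(f"unknown strategy family: {self.family!r}")


def response_probability(strategy: StrategySpec, x_norm, y_norm) -> np.ndarray:
    """Probability of responding 'A' for stimuli at normalized coordinates."""
    x = np.asarray(x_norm, dtype=float)
    y = np.asarray(y_norm, dtype=float)
    if strategy.family in _GUESS_FAMILIES:
        return np.full(np.broadcast(x, y).shape, float(strategy.guess_p_A))
    h = strategy.bound.signed_distance_to_A(x, y)
    p = ndtr(h / strategy.noise_sigma)
    if strategy.lapse_rate:
        p = (1.0 - strategy.lapse_rate) * p + strategy.lapse_rate / 2.0
    return p


def sample_responses(strategy: StrategySpec, x_norm, y_norm, rng: np.random.Generator) -> np.ndarray:
    """Draw 'A'/'B' responses from the strategy's response probabilities."""
    p = response_probability(strategy, x_norm, y_norm)
    return np.where(rng.random(p.shape) < p, "A", "B")


BlockKey = Union[int, str]  # 1..8 or "test"

_SCHEDULE_KEYS = tuple(range(1, 9)) + ("test",)


@dataclass(frozen=True)
class LearnerProfile:
    """One simulated participant: group, symptom score, per-block strategies."""

    participant_id: str
    group: str  # "ADHD" or "control"
    asrs_score: float
    schedule: Mapping[BlockKey, StrategySpec]
    age: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in ("ADHD", "control"):
            raise ValueError(f"group must be 'ADHD' or 'control', got {self.group!r}")
        missing = [k for k in _SCHEDULE_KEYS if k not in self.schedule]
        if missing:
            raise MissingStrategyError(f"schedule missing blocks: {missing}")
        if self.asrs_score >= ASRS_CUTOFF and self.group != "ADHD":
            raise ValueError(
                f"ASRS score {self.asrs_score} >= {ASRS_CUTOFF} implies group 'ADHD' "
                "under the screening rule"
            )


def _balanced_block_indices(categories: np.ndarray, rng: np.random.Generator) -> list[np.ndarray]:
    """Deal the 200 stimuli into 8 blocks of 25 A + 25 B.

    Each half of training (blocks 1-4 and 5-8) exhausts the full set, so
    the whole category space has been presented after four blocks.
    """
    idx_A = np.flatnonzero(categories == "A")
    idx_B = np.flatnonzero(categories == "B")
    blocks: list[np.ndarray] = []
    for _half in range(2):
        pa = rng.permutation(idx_A)
        pb = rng.permutation(idx_B)
        for k in range(4):
            block = np.concatenate([pa[k * 25 : (k + 1) * 25], pb[k * 25 : (k + 1) * 25]])
            blocks.append(rng.permutation(block))
    return blocks


def simulate_session(
    profile: LearnerProfile,
    training_set: StimulusSet,
    grid: StimulusSet,
    seed: int,
) -> pd.DataFrame:
    """Simulate one participant-task session: 8 x 50 training trials + test.

    Training stimuli are sampled evenly: 25 per category per block, with
    each of the 200 stimuli appearing exactly once within each half of
    training.  The test block presents the generalization grid once, in
    shuffled order, without feedback.
    """
    if len(training_set) != 200:
        raise ValueError("training set must contain 200 stimuli")
    rng = np.random.default_rng(seed)
    modality = training_set.space.modality
    task = training_set.task

    frames = []
    cats = training_set.categories
    block_indices = _balanced_block_indices(cats, rng)
    stim_ids = training_set.data["id"].to_numpy()
    xs, ys = training_set.x_norm, training_set.y_norm

    def run_block(block: BlockKey, idx: np.ndarray, ids, x, y, true, feedback: bool):
        try:
            strategy = profile.schedule[block]
        except KeyError as exc:
            raise MissingStrategyError(f"no strategy scheduled for block {block!r}") from exc
        resp = sample_responses(strategy, x, y, rng)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": profile.participant_id,
                    "group": profile.group,
                    "modality": modality,
                    "task": task,
                    "block": block,
                    "trial_index": np.arange(1, len(idx) + 1),
                    "stimulus_id": ids,
                    "x_norm": x,
                    "y_norm": y,
                    "true_category": true,
                    "response": resp,
                    "correct": resp == true,
                    "feedback_given": feedback,
                }
            )
        )

    for b, idx in enumerate(block_indices, start=1):
        run_block(b, idx, stim_ids[idx], xs[idx], ys[idx], cats[idx], True)
    order = rng.permutation(len(grid))
    run_block(
        "test",
        order,
        grid.data["id"].to_numpy()[order],
        grid.x_norm[order],
        grid.y_norm[order],
        grid.categories[order],
        False,
    )
    out = pd.concat(frames, ignore_index=True)
    out["block"] = out["block"].astype(object)
    return out


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings for the two simulated groups.

    Onset blocks (first block using the task-optimal strategy) are uniform
    over inclusive integer ranges; perceptual/criterial noise is a
    per-participant draw around a group mean (normalized units); ASRS
    scores are normal draws truncated at the screening cutoff so controls
    score < 51 <= ADHD.  Defaults reproduce the studied groups' symptom
    spreads and the qualitative orderings (later onsets and larger noise in
    the ADHD-like group); every field is overridable.
    """

    control_onset: tuple[int, int] = (1, 4)
    adhd_onset: tuple[int, int] = (2, 7)
    control_sigma: float = 0.08
    adhd_sigma: float = 0.12
    sigma_jitter: float = 0.015
    sigma_floor: float = 0.02
    control_asrs: tuple[float, float] = (35.0, 6.4)
    adhd_asrs: tuple[float, float] = (60.0, 11.4)
    control_asrs_bounds: tuple[Optional[float], Optional[float]] = (None, ASRS_CUTOFF)
    adhd_asrs_bounds: tuple[Optional[float], Optional[float]] = (ASRS_CUTOFF, None)
    control_age: tuple[float, float] = (24.2, 2.2)
    adhd_age: tuple[float, float] = (26.2, 3.4)
    pre_guess_prob: float = 0.5
    lapse_rate: float = 0.0
    n_per_category: int = 100
    misclassified: int = 10

    def onset_range(self, group: str) -> tuple[int, int]:
        return self.adhd_onset if group == "ADHD" else self.control_onset

    def sigma_mean(self, group: str) -> float:
        return self.adhd_sigma if group == "ADHD" else self.control_sigma

    def asrs_params(self, group: str):
        if group == "ADHD":
            return self.adhd_asrs, self.adhd_asrs_bounds
        return self.control_asrs, self.control_asrs_bounds

    def age_params(self, group: str) -> tuple[float, float]:
        return self.adhd_age if group == "ADHD" else self.control_age


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if (lo is None or x >= lo) and (hi is None or x < hi):
            return float(x)
    raise RuntimeError("truncated normal draw failed; bounds too tight")


def _suboptimal_strategy(task: str, distA, distB, sigma: float, lapse: float, rng) -> StrategySpec:
    """A plausible wrong rule: a unidimensional criterion off the optimal family.

    For RB tasks the rule sits on the irrelevant dimension (chance-level by
    construction); for II tasks a single-dimension rule on either dimension
    captures part of the structure but is suboptimal.
    """
    muA, muB = distA.normalized_mean(), distB.normalized_mean()
    if task == "RB":
        dim = 1 - int(np.argmax(np.abs(muA - muB)))
    else:
        dim = int(rng.integers(2))
    crit = float((muA[dim] + muB[dim]) / 2.0)
    positive = "A" if rng.random() < 0.5 else "B"
    if dim == 0:
        return StrategySpec("uni_x", bound=DecisionBound.vertical(crit, positive),
                            noise_sigma=sigma, lapse_rate=lapse)
    return StrategySpec("uni_y", bound=DecisionBound.horizontal(crit, positive),
                        noise_sigma=sigma, lapse_rate=lapse)


def _optimal_strategy(task: str, bound: DecisionBound, sigma: float, lapse: float) -> StrategySpec:
    family = "uni_x" if task == "RB" else "procedural"
    return StrategySpec(family, bound=bound, noise_sigma=sigma, lapse_rate=lapse)


def simulate_cohort(
    n_per_group: int,
    config: Optional[CohortConfig] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort over all four tasks.

    Returns ``(trials, participants)``: trial-level records for every
    participant x modality x task session, and a participant table with
    group, ASRS score and age.  One shared training set and generalization
    grid per task (all learners see the same stimuli); everything is
    deterministic given ``seed``.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)

    tasks = {}
    for modality, task in product(("auditory", "visual"), ("RB", "II")):
        distA, distB = task_distributions(modality, task)
        set_seed = int(rng.integers(2**31))
        training = sample_category_set(distA, distB, cfg.n_per_category, cfg.misclassified, seed=set_seed)
        bound = optimal_boundary(distA, distB)
        grid = make_generalization_grid(distA.space, task, bound, training_set=training)
        tasks[(modality, task)] = (distA, distB, training, bound, grid)

    trial_frames = []
    participants = []
    for group, prefix in (("control", "C"), ("ADHD", "A")):
        for i in range(n_per_group):
            pid = f"{prefix}{i + 1:03d}"
            (mean, sd), bounds = cfg.asrs_params(group)
            asrs = _truncated_normal(rng, mean, sd, bounds[0], bounds[1])
            age_mean, age_sd = cfg.age_params(group)
            age = float(np.clip(rng.normal(age_mean, age_sd), 20.0, 35.0))
            sigma = max(cfg.sigma_floor, float(rng.normal(cfg.sigma_mean(group), cfg.sigma_jitter)))
            participants.append(
                {"participant_id": pid, "group": group, "asrs_score": asrs, "age": age}
            )
            for (modality, task), (distA, distB, training, bound, grid) in tasks.items():
                lo, hi = cfg.onset_range(group)
                onset = int(rng.integers(lo, hi + 1))
                optimal = _optimal_strategy(task, bound, sigma, cfg.lapse_rate)
                schedule: dict[BlockKey, StrategySpec] = {}
                for b in range(1, 9):
                    if b >= onset:
                        schedule[b] = optimal
                    elif rng.random() < cfg.pre_guess_prob:
                        schedule[b] = StrategySpec("guess_fixed", guess_p_A=0.5,
                                                   lapse_rate=cfg.lapse_rate)
                    else:
                        schedule[b] = _suboptimal_strategy(task, distA, distB, sigma,
                                                           cfg.lapse_rate, rng)
                schedule["test"] = schedule[8]
                profile = LearnerProfile(pid, group, asrs, schedule, age=age)
                session_seed = int(rng.integers(2**31))
                trial_frames.append(simulate_session(profile, training, grid, session_seed))

    trials = pd.concat(trial_frames, ignore_index=True)
    return trials, pd.DataFrame(participants)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write trial records as CSV with the canonical column order."""
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial CSV, restoring integer block keys (and the 'test' block)."""
    df = pd.read_csv(path, dtype={"block": str})
    df["block"] = [int(b) if b.isdigit() else b for b in df["block"]]
    df["block"] = df["block"].astype(object)
    return df[TRIAL_COLUMNS]
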