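"""Stimulus spaces, category distributions, and optimal decision bounds.

Two-dimensional auditory (temporal x spectral modulation of nonspeech
ripples) and visual (spatial frequency x orientation of Gabor patches)
stimulus spaces host two kinds of two-category structures:

* rule-based (RB): the categories differ only on one dimension, so the
  optimal decision bound is a criterion placed on that dimension alone;
* information-integration (II): the category means differ on both
  dimensions, so the optimal bound is a diagonal line that requires
  pre-decisional integration of the two dimensions.

Each category is a bivariate normal distribution over the physical
coordinates, truncated to the stated stimulus ranges.  All distributions
are first defined in physical units and mapped affinely onto a normalized
unit square so that the two modalities are commensurate; decision bounds
are represented in normalized coordinates throughout.

Category structures deliberately overlap: the packaged training sets are
repaired so that exactly 10 of 200 stimuli fall on the wrong side of the
optimal bound, capping ideal-observer accuracy at 95%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSpace",
    "CategoryDistribution",
    "DecisionBound",
    "StimulusSet",
    "ConstraintInfeasibleError",
    "DegenerateDistributionsError",
    "auditory_space",
    "visual_space",
    "get_space",
    "task_distributions",
    "normalized_to_physical",
    "physical_to_normalized",
    "optimal_boundary",
    "sample_category_set",
    "classify_with_bound",
    "make_generalization_grid",
    "DEFAULT_FIXTURE_SEED",
]

#: Seed used for the packaged fixture stimulus sets.
DEFAULT_FIXTURE_SEED = 20250925

#: Cap on per-stimulus redraws while repairing the overlap constraint.
REDRAW_CAP = 100_000

_UNIT_NORM_TOL = 1e-12


class ConstraintInfeasibleError(RuntimeError):
    """Overlap-repair could not reach the requested misclassified count."""

    def __init__(self, target: int, achieved: int, redraws: int):
        self.target = target
        self.achieved = achieved
        self.redraws = redraws
        super().__init__(
            f"could not reach {target} misclassified stimuli after "
            f"{redraws} redraws (achieved {achieved})"
        )


class DegenerateDistributionsError(ValueError):
    """The two category distributions have identical means on both dimensions."""


@dataclass(frozen=True)
class StimulusSpace:
    """A named 2-D physical stimulus space with hard coordinate ranges."""

    modality: str
    dim_x_name: str
    dim_y_name: str
    x_range: tuple[float, float]
    y_range: tuple[float, float]
    x_unit: str
    y_unit: str

    def __post_init__(self) -> None:
        for lo, hi in (self.x_range, self.y_range):
            if not lo < hi:
                raise ValueError(f"range lower bound must be < upper bound, got ({lo}, {hi})")

    @property
    def x_width(self) -> float:
        return self.x_range[1] - self.x_range[0]

    @property
    def y_width(self) -> float:
        return self.y_range[1] - self.y_range[0]

    def contains(self, x_phys, y_phys) -> np.ndarray:
        """Boolean mask of points lying within both physical ranges."""
        x = np.asarray(x_phys, dtype=float)
        y = np.asarray(y_phys, dtype=float)
        return (
            (x >= self.x_range[0])
            & (x <= self.x_range[1])
            & (y >= self.y_range[0])
            & (y <= self.y_range[1])
        )


_AUDITORY = StimulusSpace(
    modality="auditory",
    dim_x_name="temporal modulation",
    dim_y_name="spectral modulation",
    x_range=(2.0, 14.8),
    y_range=(-0.38, 2.67),
    x_unit="Hz",
    y_unit="cycles/octave",
)

_VISUAL = StimulusSpace(
    modality="visual",
    dim_x_name="spatial frequency",
    dim_y_name="orientation",
    x_range=(0.04, 0.072),
    y_range=(10.0, 104.0),
    x_unit="cycles/degree",
    y_unit="degrees",
)


def auditory_space() -> StimulusSpace:
    """Ripple space: temporal modulation (Hz) x spectral modulation (cyc/oct)."""
    return _AUDITORY


def visual_space() -> StimulusSpace:
    """Gabor space: spatial frequency (cyc/deg) x orientation (degrees)."""
    return _VISUAL


def get_space(modality: str) -> StimulusSpace:
    if modality == "auditory":
        return _AUDITORY
    if modality == "visual":
        return _VISUAL
    raise ValueError(f"unknown modality: {modality!r}")


def normalized_to_physical(space: StimulusSpace, x_norm, y_norm):
    """Affine map from the normalized unit square onto the physical ranges."""
    x_norm = np.asarray(x_norm, dtype=float)
    y_norm = np.asarray(y_norm, dtype=float)
    x_phys = space.x_range[0] + x_norm * space.x_width
    y_phys = space.y_range[0] + y_norm * space.y_width
    return x_phys, y_phys


def physical_to_normalized(space: StimulusSpace, x_phys, y_phys):
    """Inverse of :func:`normalized_to_physical` (round-trip identity)."""
    x_phys = np.asarray(x_phys, dtype=float)
    y_phys = np.asarray(y_phys, dtype=float)
    x_norm = (x_phys - space.x_range[0]) / space.x_width
    y_norm = (y_phys - space.y_range[0]) / space.y_width
    return x_norm, y_norm


@dataclass(frozen=True)
class CategoryDistribution:
    """One category's bivariate-normal parameters in physical units."""

    label: str  # "A" or "B"
    task: str  # "RB" or "II"
    space: StimulusSpace
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    covariance: float

    def __post_init__(self) -> None:
        if self.label not in ("A", "B"):
            raise ValueError(f"label must be 'A' or 'B', got {self.label!r}")
        if self.task not in ("RB", "II"):
            raise ValueError(f"task must be 'RB' or 'II', got {self.task!r}")
        if self.sd_x <= 0 or self.sd_y <= 0:
            raise ValueError("standard deviations must be positive")
        if abs(self.covariance) > self.sd_x * self.sd_y:
            raise ValueError("covariance implies |correlation| > 1")

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.mean_x, self.mean_y], dtype=float)

    @property
    def cov_matrix(self) -> np.ndarray:
        return np.array(
            [[self.sd_x**2, self.covariance], [self.covariance, self.sd_y**2]],
            dtype=float,
        )

    def normalized_mean(self) -> np.ndarray:
        xn, yn = physical_to_normalized(self.space, self.mean_x, self.mean_y)
        return np.array([float(xn), float(yn)])

    def normalized_cov(self) -> np.ndarray:
        sx, sy = self.space.x_width, self.space.y_width
        scale = np.array([[sx * sx, sx * sy], [sx * sy, sy * sy]], dtype=float)
        return self.cov_matrix / scale


# Per-category distribution parameters for the four tasks, in physical units:
# (mean_x, sd_x, mean_y, sd_y, covariance).
_DISTRIBUTION_PARAMS: dict[tuple[str, str, str], tuple[float, float, float, float, float]] = {
    ("auditory", "II", "A"): (10.0, 2.13, 0.72, 0.49, 0.43),
    ("auditory", "II", "B"): (6.62, 2.02, 1.53, 0.51, 0.43),
    ("auditory", "RB", "A"): (10.42, 1.58, 1.14, 0.66, 0.062),
    ("auditory", "RB", "B"): (5.59, 1.58, 1.14, 0.66, -0.062),
    ("visual", "II", "A"): (0.060, 0.0054, 43.2, 15.0, 0.034),
    ("visual", "II", "B"): (0.051, 0.0051, 68.5, 15.8, 0.034),
    ("visual", "RB", "A"): (0.061, 0.0039, 56.7, 20.4, 0.0048),
    ("visual", "RB", "B"): (0.049, 0.0039, 56.7, 20.4, -0.0048),
}


def task_distributions(modality: str, task: str) -> tuple[CategoryDistribution, CategoryDistribution]:
    """Return the (Category A, Category B) distribution pair for one task.

    Parameters are the study design's per-category means, standard
    deviations and covariances in physical units.
    """
    space = get_space(modality)
    if task not in ("RB", "II"):
        raise ValueError(f"unknown task: {task!r}")
    out = []
    for label in ("A", "B"):
        mx, sx, my, sy, cov = _DISTRIBUTION_PARAMS[(modality, task, label)]
        out.append(
            CategoryDistribution(
                label=label, task=task, space=space,
                mean_x=mx, mean_y=my, sd_x=sx, sd_y=sy, covariance=cov,
            )
        )
    return out[0], out[1]


@dataclass(frozen=True)
class DecisionBound:
    """A linear decision bound a*x + b*y + c = 0 in normalized coordinates.

    Coefficients are stored with the unit-normal constraint a^2 + b^2 = 1,
    so ``signed_distance`` returns true perpendicular distance.  The side
    where the signed distance is positive carries ``positive_label``; a
    point exactly on the bound is labeled "A" (deterministic tie rule).
    """

    a: float
    b: float
    c: float
    positive_label: str = "A"

    def __post_init__(self) -> None:
        norm = float(np.hypot(self.a, self.b))
        if norm == 0.0:
            raise ValueError("bound normal (a, b) must be nonzero")
        if abs(norm - 1.0) > _UNIT_NORM_TOL:
            object.__setattr__(self, "a", self.a / norm)
            object.__setattr__(self, "b", self.b / norm)
            object.__setattr__(self, "c", self.c / norm)
        if self.positive_label not in ("A", "B"):
            raise ValueError("positive_label must be 'A' or 'B'")

    @classmethod
    def vertical(cls, criterion: float, positive_label: str = "A") -> "DecisionBound":
        """Bound x = criterion; positive side is x > criterion."""
        return cls(a=1.0, b=0.0, c=-float(criterion), positive_label=positive_label)

    @classmethod
    def horizontal(cls, criterion: float, positive_label: str = "A") -> "DecisionBound":
        """Bound y = criterion; positive side is y > criterion."""
        return cls(a=0.0, b=1.0, c=-float(criterion), positive_label=positive_label)

    @property
    def is_unidimensional(self) -> bool:
        return self.a == 0.0 or self.b == 0.0

    @property
    def criterion_x(self) -> float:
        """Criterion on x for a vertical bound."""
        if self.b != 0.0:
            raise ValueError("not a vertical (x-criterion) bound")
        return -self.c / self.a

    @property
    def criterion_y(self) -> float:
        """Criterion on y for a horizontal bound."""
        if self.a != 0.0:
            raise ValueError("not a horizontal (y-criterion) bound")
        return -self.c / self.b

    def signed_distance(self, x_norm, y_norm) -> np.ndarray:
        """Perpendicular distance; positive on the ``positive_label`` side."""
        return self.a * np.asarray(x_norm, dtype=float) + self.b * np.asarray(y_norm, dtype=float) + self.c

    def signed_distance_to_A(self, x_norm, y_norm) -> np.ndarray:
        """Signed distance oriented so that positive values favour Category A."""
        h = self.signed_distance(x_norm, y_norm)
        return h if self.positive_label == "A" else -h

    def classify(self, x_norm, y_norm) -> np.ndarray:
        """Label points; exact zeros resolve to 'A'."""
        h = self.signed_distance(x_norm, y_norm)
        pos, neg = self.positive_label, ("B" if self.positive_label == "A" else "A")
        labels = np.where(h > 0, pos, neg)
        labels = np.where(h == 0, "A", labels)
        return labels

    def flipped(self) -> "DecisionBound":
        """Same line with the region labels swapped."""
        return replace(self, positive_label="B" if self.positive_label == "A" else "A")


def _oriented(a: float, b: float, c: float, mean_A: np.ndarray) -> DecisionBound:
    """Build a bound whose positive side contains Category A's mean."""
    h = a * mean_A[0] + b * mean_A[1] + c
    if h < 0:
        a, b, c = -a, -b, -c
    return DecisionBound(a=a, b=b, c=c, positive_label="A")


def optimal_boundary(distA: CategoryDistribution, distB: CategoryDistribution) -> DecisionBound:
    """Ideal-observer bound for a category pair, in normalized coordinates.

    RB pairs get the unidimensional criterion at the midpoint of the
    category means on the dimension where the means differ.  II pairs get
    the pooled-covariance Fisher linear discriminant through the midpoint
    of the means (the quadratic term induced by the slightly unequal
    per-category covariances is negligible at these parameter values and
    the optimal II strategy is treated as linear).
    """
    if distA.space != distB.space or distA.task != distB.task:
        raise ValueError("distributions must share a space and task")
    muA = distA.normalized_mean()
    muB = distB.normalized_mean()
    delta = muA - muB
    if np.allclose(delta, 0.0, atol=1e-15):
        raise DegenerateDistributionsError("category means identical on both dimensions")
    mid = (muA + muB) / 2.0
    if distA.task == "RB":
        # Criterion on the single dimension along which the means differ.
        dim = int(np.argmax(np.abs(delta)))
        if dim == 0:
            bound = DecisionBound.vertical(mid[0])
        else:
            bound = DecisionBound.horizontal(mid[1])
        return _oriented(bound.a, bound.b, bound.c, muA)
    pooled = (distA.normalized_cov() + distB.normalized_cov()) / 2.0
    w = np.linalg.solve(pooled, delta)
    c = -float(w @ mid)
    return _oriented(float(w[0]), float(w[1]), c, muA)


@dataclass
class StimulusSet:
    """A fixed roster of stimuli with physical and normalized coordinates.

    ``data`` columns: id, category, x_phys, y_phys, x_norm, y_norm.
    """

    data: pd.DataFrame
    task: str
    space: StimulusSpace
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.data)

    @property
    def x_norm(self) -> np.ndarray:
        return self.data["x_norm"].to_numpy()

    @property
    def y_norm(self) -> np.ndarray:
        return self.data["y_norm"].to_numpy()

    @property
    def categories(self) -> np.ndarray:
        return self.data["category"].to_numpy()

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(1, "task", self.task)
        out.insert(2, "modality", self.space.modality)
        out = out[["id", "task", "modality", "category", "x_phys", "y_phys", "x_norm", "y_norm"]]
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StimulusSet":
        df = pd.read_csv(path)
        modality = df["modality"].iloc[0]
        task = df["task"].iloc[0]
        data = df[["id", "category", "x_phys", "y_phys", "x_norm", "y_norm"]].copy()
        return cls(data=data, task=task, space=get_space(modality), seed=None)


def _draw_truncated(rng: np.random.Generator, dist: CategoryDistribution, n: int) -> np.ndarray:
    """Draw n points from the bivariate normal, rejecting out-of-range draws."""
    out = np.empty((n, 2), dtype=float)
    filled = 0
    while filled < n:
        draws = rng.multivariate_normal(dist.mean, dist.cov_matrix, size=max(n - filled, 8))
        ok = dist.space.contains(draws[:, 0], draws[:, 1])
        good = draws[ok]
        take = min(len(good), n - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out


def sample_category_set(
    distA: CategoryDistribution,
    distB: CategoryDistribution,
    n_per_cat: int = 100,
    misclassified_target: int = 10,
    seed: int = DEFAULT_FIXTURE_SEED,
) -> StimulusSet:
    """Sample a training stimulus set with an exact category-overlap count.

    Draws ``n_per_cat`` stimuli per category from the truncated bivariate
    normals, then repairs the draw so that exactly ``misclassified_target``
    stimuli fall on the wrong side of the optimal bound: while over target,
    a random wrong-side stimulus is redrawn from its own category; while
    under, a random right-side one is.  Deterministic given ``seed``.
    """
    if n_per_cat < 1:
        raise ValueError("n_per_cat must be >= 1")
    if not 0 <= misclassified_target <= 2 * n_per_cat:
        raise ValueError("misclassified_target must lie in [0, 2*n_per_cat]")
    rng = np.random.default_rng(seed)
    bound = optimal_boundary(distA, distB)
    space = distA.space

    coords = np.vstack([_draw_truncated(rng, distA, n_per_cat), _draw_truncated(rng, distB, n_per_cat)])
    true = np.array(["A"] * n_per_cat + ["B"] * n_per_cat)
    dists = (distA, distB)

    def wrong_mask() -> np.ndarray:
        xn, yn = physical_to_normalized(space, coords[:, 0], coords[:, 1])
        return bound.classify(xn, yn) != true

    wrong = wrong_mask()
    redraws = 0
    while int(wrong.sum()) != misclassified_target:
        if redraws >= REDRAW_CAP:
            raise ConstraintInfeasibleError(misclassified_target, int(wrong.sum()), redraws)
        pool = np.flatnonzero(wrong) if wrong.sum() > misclassified_target else np.flatnonzero(~wrong)
        i = int(rng.choice(pool))
        dist_i = dists[0] if i < n_per_cat else dists[1]
        coords[i] = _draw_truncated(rng, dist_i, 1)[0]
        redraws += 1
        xn_i, yn_i = physical_to_normalized(space, coords[i, 0], coords[i, 1])
        wrong[i] = bound.classify(xn_i, yn_i).item() != true[i]

    xn, yn = physical_to_normalized(space, coords[:, 0], coords[:, 1])
    data = pd.DataFrame(
        {
            "id": np.arange(2 * n_per_cat),
            "category": true,
            "x_phys": coords[:, 0],
            "y_phys": coords[:, 1],
            "x_norm": xn,
            "y_norm": yn,
        }
    )
    return StimulusSet(data=data, task=distA.task, space=space, seed=seed)


def classify_with_bound(bound: DecisionBound, stim_set: StimulusSet) -> tuple[np.ndarray, float]:
    """Score a stimulus set against a bound: (predicted labels, accuracy)."""
    if len(stim_set) == 0:
        raise ValueError("stimulus set is empty")
    labels = bound.classify(stim_set.x_norm, stim_set.y_norm)
    accuracy = float(np.mean(labels == stim_set.categories))
    return labels, accuracy


def make_generalization_grid(
    space: StimulusSpace,
    task: str,
    bound: DecisionBound,
    n_side: int = 8,
    training_set: Optional[StimulusSet] = None,
    start_id: int = 1000,
) -> StimulusSet:
    """Evenly spaced n_side x n_side grid spanning the space, labeled by ``bound``.

    The grid doubles as the feedback-free generalization test set; true
    labels are assigned by the task's optimal bound.  If ``training_set``
    is given, coincidence with any training stimulus raises.
    """
    if n_side < 2:
        raise ValueError("n_side must be >= 2")
    ticks = np.linspace(0.0, 1.0, n_side)
    gx, gy = np.meshgrid(ticks, ticks, indexing="ij")
    xn, yn = gx.ravel(), gy.ravel()
    if training_set is not None:
        clash = (xn[:, None] == training_set.x_norm[None, :]) & (yn[:, None] == training_set.y_norm[None, :])
        if clash.any():
            raise ValueError("grid point coincides with a training stimulus")
    xp, yp = normalized_to_physical(space, xn, yn)
    data = pd.DataFrame(
        {
            "id": start_id + np.arange(n_side * n_side),
            "category": bound.classify(xn, yn),
            "x_phys": xp,
            "y_phys": yp,
            "x_norm": xn,
            "y_norm": yn,
        }
    )
    return StimulusSet(data=data, task=task, space=space, seed=None)
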