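"""Decision-bound observer models: likelihoods, ML fitting, BIC selection.

Three model classes are fitted to each participant-block of responses:

* hypothesis-testing (unidimensional) models — a criterion on one stimulus
  dimension plus one perceptual/criterial noise parameter (r = 2);
* the General Linear Classifier (GLC) — an arbitrary linear bound, fitted
  as angle + offset to avoid the infinite-slope singularity, plus noise
  (r = 3);
* guessing models — a fixed equal-probability responder (r = 0 here) and
  two biased variants with the probability of responding "A" constrained
  to [0.5, 1] or [0, 0.5] (r = 1).

Boundary models share the response rule P(A) = Phi(h / sigma) with h the
signed perpendicular distance from the unit-normalized bound.  Both
response-to-region assignments are fitted for every boundary family.  Fits
maximize likelihood via a dense vectorized start grid with Nelder-Mead
refinement of the best starts; the winning model per block is the one with
the smallest BIC = r*ln(N) - 2*ln(L), ties broken toward fewer parameters
and then a fixed family order.

All fitting happens in normalized [0, 1]^2 coordinates so that one noise
scale serves both modalities.  Likelihood contributions are clamped to
[1e-10, 1 - 1e-10]; the clamp is part of the model and is applied
identically wherever the likelihood is evaluated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr

__all__ = [
    "ModelSpec",
    "ModelFit",
    "default_inventory",
    "negative_log_likelihood",
    "bic",
    "fit_model",
    "fit_block",
    "select_best",
    "fit_dataset",
    "write_fits",
    "read_fits",
    "FIT_COLUMNS",
]

EPS = 1e-10
SIGMA_MIN, SIGMA_MAX = 1e-4, 2.0
BIC_TIE_TOL = 1e-6

FIT_COLUMNS = [
    "participant_id",
    "modality",
    "task",
    "block",
    "family",
    "assignment",
    "r",
    "n_trials",
    "param1",
    "param2",
    "param3",
    "logL",
    "bic",
    "best_flag",
    "converged",
]

# Tie-break order among equal-BIC, equal-r candidates: guessing models
# first, then unidimensional, then GLC.
_FAMILY_ORDER = {
    "guess_fixed": 0,
    "guess_biased_A": 1,
    "guess_biased_B": 2,
    "uni_x": 3,
    "uni_y": 4,
    "glc": 5,
}

_BOUNDARY_FAMILIES = ("uni_x", "uni_y", "glc")
_GUESS_FAMILIES = ("guess_fixed", "guess_biased_A", "guess_biased_B")


@dataclass(frozen=True)
class ModelSpec:
    """One model to fit: family, response-region assignment, parameter count."""

    family: str
    assignment: Optional[str] = None  # "direct"/"flipped"; None for guessing
    r: int = 0

    def __post_init__(self) -> None:
        if self.family in _BOUNDARY_FAMILIES:
            if self.assignment not in ("direct", "flipped"):
                raise ValueError("boundary models need assignment 'direct' or 'flipped'")
        elif self.family in _GUESS_FAMILIES:
            if self.assignment is not None:
                raise ValueError("guessing models take no assignment")
        else:
            raise ValueError(f"unknown model family: {self.family!r}")
        if self.r < 0:
            raise ValueError("r must be >= 0")


def default_inventory(r_guess_fixed: int = 0) -> tuple[ModelSpec, ...]:
    """The nine models fitted to every block.

    ``r_guess_fixed`` is exposed because conventions differ on whether the
    fixed equal-probability guesser counts its (fixed) probability as a
    free parameter; the default charges it none.
    """
    specs = [
        ModelSpec("uni_x", "direct", 2),
        ModelSpec("uni_x", "flipped", 2),
        ModelSpec("uni_y", "direct", 2),
        ModelSpec("uni_y", "flipped", 2),
        ModelSpec("glc", "direct", 3),
        ModelSpec("glc", "flipped", 3),
        ModelSpec("guess_fixed", None, r_guess_fixed),
        ModelSpec("guess_biased_A", None, 1),
        ModelSpec("guess_biased_B", None, 1),
    ]
    return tuple(specs)


@dataclass(frozen=True)
class ModelFit:
    """One model fitted to one participant-block."""

    spec: ModelSpec
    params: dict
    log_likelihood: float
    bic: float
    n_trials: int
    converged: bool
    n_starts_used: int


def bic(r: int, n: int, log_likelihood: float) -> float:
    """Bayesian information criterion r*ln(n) - 2*ln(L); lower is better."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if r < 0:
        raise ValueError("r must be >= 0")
    return r * float(np.log(n)) - 2.0 * log_likelihood


def _p_response_A(spec: ModelSpec, params: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """P(respond A) for a (k, d) batch of parameter vectors; returns (k, n)."""
    fam = spec.family
    if fam == "guess_fixed":
        return np.full((params.shape[0], x.size), 0.5)
    if fam in ("guess_biased_A", "guess_biased_B"):
        return np.broadcast_to(params[:, 0:1], (params.shape[0], x.size))
    if fam == "uni_x":
        h = x[None, :] - params[:, 0:1]
    elif fam == "uni_y":
        h = y[None, :] - params[:, 0:1]
    else:  # glc: (theta, offset, sigma), unit normal (cos, sin)
        theta, c = params[:, 0:1], params[:, 1:2]
        h = np.cos(theta) * x[None, :] + np.sin(theta) * y[None, :] + c
    if spec.assignment == "flipped":
        h = -h
    sigma = params[:, -1:]
    return ndtr(h / sigma)


def _nll_batch(spec: ModelSpec, params: np.ndarray, x, y, resp_a: np.ndarray) -> np.ndarray:
    p = _p_response_A(spec, params, x, y)
    p = np.clip(p, EPS, 1.0 - EPS)
    like = np.where(resp_a[None, :], p, 1.0 - p)
    return -np.log(like).sum(axis=1)


def negative_log_likelihood(spec: ModelSpec, params: Sequence[float], x_norm, y_norm, resp_a) -> float:
    """-sum ln P(response_i | stimulus_i) for one parameter vector.

    ``resp_a`` is a boolean array (True where the response was "A").
    Raises for invalid parameters (sigma <= 0, probability outside [0, 1]).
    """
    x = np.asarray(x_norm, dtype=float)
    y = np.asarray(y_norm, dtype=float)
    resp_a = np.asarray(resp_a, dtype=bool)
    if x.size == 0:
        raise ValueError("trials must be nonempty")
    params = np.atleast_1d(np.asarray(params, dtype=float))
    if spec.family in _BOUNDARY_FAMILIES and params[-1] <= 0:
        raise ValueError("sigma must be positive")
    if spec.family in ("guess_biased_A", "guess_biased_B"):
        if not 0.0 <= params[0] <= 1.0:
            raise ValueError("guessing probability must lie in [0, 1]")
    if spec.family == "guess_fixed":
        params = np.zeros(1)
    return float(_nll_batch(spec, params[None, :], x, y, resp_a)[0])


# --- multi-start grids (module-level constants, built once) -----------------

def _uni_start_grid() -> np.ndarray:
    crit = np.linspace(0.05, 0.95, 19)
    sigma = np.geomspace(0.01, 0.6, 6)
    cc, ss = np.meshgrid(crit, sigma, indexing="ij")
    return np.column_stack([cc.ravel(), ss.ravel()])


def _glc_start_grid() -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, 16, endpoint=False)
    offset = np.linspace(-0.6, 0.6, 7)
    sigma = np.array([0.02, 0.05, 0.12, 0.3])
    tt, oo, ss = np.meshgrid(theta, offset, sigma, indexing="ij")
    return np.column_stack([tt.ravel(), oo.ravel(), ss.ravel()])


_UNI_STARTS = _uni_start_grid()
_GLC_STARTS = _glc_start_grid()


def _random_starts(spec: ModelSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    log_sigma = rng.uniform(np.log(1e-3), np.log(1.0), size=n)
    if spec.family == "glc":
        return np.column_stack(
            [rng.uniform(0, 2 * np.pi, n), rng.uniform(-0.8, 0.8, n), np.exp(log_sigma)]
        )
    return np.column_stack([rng.uniform(-0.1, 1.1, n), np.exp(log_sigma)])


def _fit_guessing(spec: ModelSpec, resp_a: np.ndarray) -> ModelFit:
    n = resp_a.size
    k = int(resp_a.sum())
    if spec.family == "guess_fixed":
        p = 0.5
    elif spec.family == "guess_biased_A":
        p = min(max(k / n, 0.5), 1.0)
    else:
        p = min(max(k / n, 0.0), 0.5)
    pc = min(max(p, EPS), 1.0 - EPS)
    logL = k * np.log(pc) + (n - k) * np.log(1.0 - pc)
    return ModelFit(
        spec=spec,
        params={"p_A": float(p)},
        log_likelihood=float(logL),
        bic=bic(spec.r, n, float(logL)),
        n_trials=n,
        converged=True,
        n_starts_used=0,
    )


def fit_model(
    spec: ModelSpec,
    x_norm,
    y_norm,
    resp_a,
    rng: Optional[np.random.Generator] = None,
    n_random_starts: int = 10,
    refine_top: int = 1,
    extra_starts: Optional[np.ndarray] = None,
) -> ModelFit:
    """Maximum-likelihood fit of one model to one block of trials.

    Guessing models have closed-form maxima.  Boundary models evaluate a
    dense fixed start grid plus seeded random starts (all vectorized),
    then refine the ``refine_top`` best starts with Nelder-Mead; sigma is
    constrained to [1e-4, 2] via a penalty.
    """
    x = np.asarray(x_norm, dtype=float)
    y = np.asarray(y_norm, dtype=float)
    resp_a = np.asarray(resp_a, dtype=bool)
    n = x.size
    if spec.family in _GUESS_FAMILIES:
        return _fit_guessing(spec, resp_a)

    rng = rng or np.random.default_rng(0)
    grid = _UNI_STARTS if spec.family != "glc" else _GLC_STARTS
    starts = [grid, _random_starts(spec, rng, n_random_starts)]
    if extra_starts is not None and len(extra_starts):
        starts.append(np.atleast_2d(np.asarray(extra_starts, dtype=float)))
    starts = np.vstack(starts)
    nll0 = _nll_batch(spec, starts, x, y, resp_a)
    order = np.argsort(nll0)

    def objective(params: np.ndarray) -> float:
        sigma = params[-1]
        if not SIGMA_MIN <= sigma <= SIGMA_MAX:
            return 1e12
        return float(_nll_batch(spec, params[None, :], x, y, resp_a)[0])

    best_params = starts[order[0]].copy()
    best_nll = float(nll0[order[0]])
    converged = False
    for idx in order[:refine_top]:
        res = minimize(
            objective,
            starts[idx],
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-8, "maxfev": 400},
        )
        if res.fun < best_nll:
            best_nll = float(res.fun)
            best_params = np.asarray(res.x, dtype=float)
        converged = converged or bool(res.success)

    logL = -best_nll
    if spec.family == "glc":
        theta, c, sigma = best_params
        a, b = float(np.cos(theta)), float(np.sin(theta))
        params_rec = {
            "theta": float(theta) % (2 * np.pi),
            "offset": float(c),
            "sigma": float(sigma),
            "slope": (-a / b) if abs(b) > 1e-8 else float("nan"),
            "intercept": (-c / b) if abs(b) > 1e-8 else float("nan"),
        }
    else:
        params_rec = {"criterion": float(best_params[0]), "sigma": float(best_params[1])}
    return ModelFit(
        spec=spec,
        params=params_rec,
        log_likelihood=logL,
        bic=bic(spec.r, n, logL),
        n_trials=n,
        converged=converged,
        n_starts_used=len(starts),
    )


def select_best(fits: Sequence[ModelFit]) -> ModelFit:
    """Minimum-BIC model; ties (delta BIC < 1e-6) go to fewer parameters,
    then the fixed family order guessing < unidimensional < GLC."""
    if not fits:
        raise ValueError("no fits to select from")
    bmin = min(f.bic for f in fits)
    tied = [f for f in fits if f.bic - bmin < BIC_TIE_TOL]
    tied.sort(key=lambda f: (f.spec.r, _FAMILY_ORDER[f.spec.family], f.spec.assignment or ""))
    return tied[0]


def _uni_as_glc_starts(uni_fits: Iterable[ModelFit]) -> np.ndarray:
    """Convert fitted unidimensional solutions into GLC (theta, offset, sigma)
    starts, so the GLC fit nests the best unidimensional bound."""
    rows = []
    for f in uni_fits:
        crit, sigma = f.params["criterion"], f.params["sigma"]
        theta = 0.0 if f.spec.family == "uni_x" else np.pi / 2.0
        if f.spec.assignment == "flipped":
            theta += np.pi
            crit = -crit
        rows.append([theta % (2 * np.pi), -crit, sigma])
    return np.array(rows, dtype=float)


def fit_block(
    x_norm,
    y_norm,
    resp_a,
    inventory: Optional[Sequence[ModelSpec]] = None,
    rng: Optional[np.random.Generator] = None,
    n_random_starts: int = 10,
    refine_top: int = 1,
) -> tuple[ModelFit, list[ModelFit]]:
    """Fit every model in the inventory to one block; return (best, all fits).

    Per-model failures are recorded and skipped; only a wholesale failure
    raises.  GLC fits receive the converted unidimensional solutions as
    extra starts (nesting), so the GLC log-likelihood can never fall below
    the best unidimensional one.
    """
    x = np.asarray(x_norm, dtype=float)
    if x.size < 10:
        raise ValueError("fit_block requires at least 10 trials")
    inventory = inventory or default_inventory()
    rng = rng or np.random.default_rng(0)
    fits: list[ModelFit] = []
    errors: list[tuple[ModelSpec, Exception]] = []
    uni_fits: list[ModelFit] = []
    glc_specs: list[ModelSpec] = []
    for spec in inventory:
        if spec.family == "glc":
            glc_specs.append(spec)
            continue
        try:
            f = fit_model(spec, x_norm, y_norm, resp_a, rng=rng,
                          n_random_starts=n_random_starts, refine_top=refine_top)
            fits.append(f)
            if spec.family in ("uni_x", "uni_y"):
                uni_fits.append(f)
        except Exception as exc:  # recorded, not fatal
            errors.append((spec, exc))
    nest_starts = _uni_as_glc_starts(uni_fits) if uni_fits else None
    for spec in glc_specs:
        try:
            fits.append(
                fit_model(spec, x_norm, y_norm, resp_a, rng=rng,
                          n_random_starts=n_random_starts, refine_top=refine_top,
                          extra_starts=nest_starts)
            )
        except Exception as exc:
            errors.append((spec, exc))
    if not fits:
        raise RuntimeError(f"all model fits failed: {errors}")
    return select_best(fits), fits


_BLOCK_SORT = {**{b: b for b in range(1, 9)}, "test": 9}


def _fit_row(keys: dict, fit: ModelFit, best: bool) -> dict:
    fam = fit.spec.family
    if fam in ("uni_x", "uni_y"):
        p1, p2, p3 = fit.params["criterion"], fit.params["sigma"], np.nan
    elif fam == "glc":
        p1, p2, p3 = fit.params["slope"], fit.params["intercept"], fit.params["sigma"]
    else:
        p1, p2, p3 = fit.params["p_A"], np.nan, np.nan
    return {
        **keys,
        "family": fam,
        "assignment": fit.spec.assignment or "",
        "r": fit.spec.r,
        "n_trials": fit.n_trials,
        "param1": p1,
        "param2": p2,
        "param3": p3,
        "logL": fit.log_likelihood,
        "bic": fit.bic,
        "best_flag": best,
        "converged": fit.converged,
    }


def fit_dataset(
    trials: pd.DataFrame,
    seed: int = 0,
    inventory: Optional[Sequence[ModelSpec]] = None,
    n_random_starts: int = 10,
    refine_top: int = 1,
    min_trials: int = 10,
) -> pd.DataFrame:
    """Fit the model inventory to every participant x modality x task x block.

    Includes the feedback-free test block.  Blocks with fewer than
    ``min_trials`` trials are skipped with a warning.  Returns one row per
    model per block with ``best_flag`` marking the BIC-selected model;
    deterministic given ``seed``.
    """
    if len(trials) == 0:
        return pd.DataFrame(columns=FIT_COLUMNS + (["group"] if "group" in trials.columns else []))
    has_group = "group" in trials.columns
    keys = ["participant_id", "modality", "task", "block"]
    x_all = trials["x_norm"].to_numpy(dtype=float)
    y_all = trials["y_norm"].to_numpy(dtype=float)
    resp_all = trials["response"].to_numpy() == "A"
    group_all = trials["group"].to_numpy() if has_group else None

    groups = trials.groupby(keys, sort=False).indices
    ordered = sorted(groups.keys(), key=lambda k: (k[0], k[1], k[2], _BLOCK_SORT[k[3]]))
    rows = []
    for counter, key in enumerate(ordered):
        idx = groups[key]
        if len(idx) < min_trials:
            warnings.warn(f"skipping block {key} with only {len(idx)} trials (< {min_trials})")
            continue
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), counter]))
        best, fits = fit_block(
            x_all[idx], y_all[idx], resp_all[idx],
            inventory=inventory, rng=rng,
            n_random_starts=n_random_starts, refine_top=refine_top,
        )
        key_rec = dict(zip(keys, key))
        if has_group:
            key_rec["group"] = group_all[idx[0]]
        rows.extend(_fit_row(key_rec, f, f is best) for f in fits)
    out = pd.DataFrame(rows)
    cols = FIT_COLUMNS + (["group"] if has_group else [])
    return out[cols]


def write_fits(fits: pd.DataFrame, path) -> None:
    """Write the fit table CSV (canonical header, no group column)."""
    fits[FIT_COLUMNS].to_csv(path, index=False)


def read_fits(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"block": str}, keep_default_na=False,
                     na_values=[""], converters={"assignment": str})
    df["block"] = [int(b) if b.isdigit() else b for b in df["block"]]
    df["block"] = df["block"].astype(object)
    df["best_flag"] = df["best_flag"].astype(bool)
    df["converged"] = df["converged"].astype(bool)
    return df
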