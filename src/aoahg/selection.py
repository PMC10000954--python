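"""Wrapper feature selection: binarization, classifier fitness, and the
population-based search drivers.

The hybrid driver (``run_aoahg``) gates, per solution and per coordinate,
between the arithmetic divide/multiply exploration rules and the hunger-
weighted HGS rules; the gate is the linear MOA schedule, so arithmetic
exploration dominates early iterations and hunger-driven refinement takes
over late.  Plain-AOA and plain-HGS drivers share the same fitness
protocol and serve as ablation baselines.  An exhaustive enumeration
oracle provides ground truth on small feature counts.

Fitness of a candidate mask is the convex combination

    Fit = lambda * gamma + (1 - lambda) * |mask| / Dim

where gamma is the hold-out validation loss (1 - accuracy) of a classifier
trained on the selected columns.  The validation split is a stratified
20% cut of the training partition, frozen per run seed, so fitness is a
deterministic function of the mask within a run and results are exactly
reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Callable, Optional, Union

import numpy as np
from sklearn.model_selection import train_test_split

from .classifiers import train_and_predict
from .data import EmbeddingDataset
from .optimizers import (
    ContinuousSolution,
    HungerState,
    OptimizerParams,
    Population,
    SearchBounds,
    aoa_exploit_rule,
    aoa_explore_rule,
    aoahg_hgs_rule,
    clip_unit,
    energy_E,
    hgs_position_update,
    hunger_weights,
    init_population,
    make_rng,
    moa,
    mop,
    update_bounds,
    update_hunger,
    variation_R,
)

EMPTY_MASK_FITNESS = 1.0  # sentinel: empty subsets survive but never win

__all__ = [
    "FeatureMask",
    "FitnessRecord",
    "FsResult",
    "binarize",
    "fitness",
    "evaluate_gamma",
    "FitnessEvaluator",
    "run_aoahg",
    "run_aoa",
    "run_hgs",
    "run_optimizer",
    "exhaustive_fs_oracle",
]


@dataclass
class FeatureMask:
    """Binary feature-inclusion vector obtained by thresholding a position."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("mask bits must be 0 or 1")

    @property
    def count(self) -> int:
        return int(self.bits.sum())

    @property
    def dim(self) -> int:
        return self.bits.size

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def key(self) -> bytes:
        return self.bits.tobytes()

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureMask) and np.array_equal(self.bits, other.bits)


@dataclass
class FitnessRecord:
    """Validation loss, subset ratio and their convex combination for one mask."""

    gamma: float
    ratio: float
    fitness: float
    mask: FeatureMask


@dataclass
class FsResult:
    """Outcome of one driver run: best subset, its fitness, and diagnostics."""

    best_mask: FeatureMask
    best_fitness: float
    selected_count: int
    convergence: list
    elapsed: float
    seed: int
    optimizer_name: str
    best_gamma: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "optimizer": self.optimizer_name,
            "seed": self.seed,
            "best_fitness": self.best_fitness,
            "best_gamma": self.best_gamma,
            "selected_count": self.selected_count,
            "elapsed": self.elapsed,
            "convergence": list(map(float, self.convergence)),
        }

    def save_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def save_mask_csv(self, path: Union[str, Path], feature_names=None) -> None:
        names = feature_names or [f"f{j:03d}" for j in range(self.best_mask.dim)]
        lines = ["feature_name,selected"]
        lines += [f"{n},{int(b)}" for n, b in zip(names, self.best_mask.bits)]
        Path(path).write_text("\n".join(lines) + "\n")


def binarize(x: Union[ContinuousSolution, np.ndarray], threshold: float = 0.5) -> FeatureMask:
    """Threshold a continuous position: bit j = 1 iff coordinate strictly > threshold."""
    pos = x.position if isinstance(x, ContinuousSolution) else np.asarray(x, dtype=float)
    return FeatureMask((pos > threshold).astype(np.int8))


def fitness(gamma: float, mask: FeatureMask, dim: int, lam: float) -> float:
    """Combined objective lambda*gamma + (1-lambda)*count/dim, minimised."""
    if dim <= 0:
        raise ValueError("dim must be positive")
    if not 0.0 < lam <= 1.0:
        raise ValueError("lam must lie in (0, 1]")
    return lam * gamma + (1.0 - lam) * mask.count / dim


class FitnessEvaluator:
    """Deterministic, memoised mask -> fitness map for one run.

    On construction the training partition is cut into fit/validation
    folds (stratified, 1 - ``val_frac`` / ``val_frac``) using ``seed``;
    the same folds serve every evaluation of the run.  Selected columns
    are standardised with fit-fold statistics before classifier training.
    """

    def __init__(
        self,
        data: EmbeddingDataset,
        classifier_spec: str = "svm",
        lam: float = 0.99,
        seed: int = 0,
        val_frac: float = 0.2,
    ) -> None:
        self.data = data
        self.classifier_spec = classifier_spec
        self.lam = lam
        self.seed = seed
        X_tr, y_tr = data.train_arrays()
        if np.unique(y_tr).size < 2:
            raise ValueError("training partition must contain at least two classes")
        fit_idx, val_idx = train_test_split(
            np.arange(len(y_tr)),
            test_size=val_frac,
            stratify=y_tr,
            random_state=seed % (2**32),
        )
        self.X_fit, self.y_fit = X_tr[fit_idx], y_tr[fit_idx]
        self.X_val, self.y_val = X_tr[val_idx], y_tr[val_idx]
        if np.unique(self.y_val).size < 2:
            raise ValueError("validation fold must contain at least two classes")
        self._cache: dict = {}
        self.n_evaluations = 0  # actual classifier fits (cache misses)

    def gamma(self, mask: FeatureMask) -> float:
        """Validation loss 1 - accuracy for the selected columns."""
        if mask.count == 0:
            raise ValueError("empty mask has no classifier loss")
        cols = mask.indices()
        Xf = self.X_fit[:, cols]
        Xv = self.X_val[:, cols]
        mu = Xf.mean(axis=0)
        sd = Xf.std(axis=0)
        sd[sd == 0] = 1.0
        pred = train_and_predict(
            self.classifier_spec, (Xf - mu) / sd, self.y_fit, (Xv - mu) / sd, self.seed
        )
        self.n_evaluations += 1
        return float(np.mean(pred != self.y_val))

    def record(self, mask: FeatureMask) -> FitnessRecord:
        key = mask.key()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        dim = mask.dim
        if mask.count == 0:
            rec = FitnessRecord(gamma=1.0, ratio=0.0, fitness=EMPTY_MASK_FITNESS, mask=mask)
        else:
            g = self.gamma(mask)
            rec = FitnessRecord(
                gamma=g, ratio=mask.count / dim, fitness=fitness(g, mask, dim, self.lam), mask=mask
            )
        self._cache[key] = rec
        return rec

    def fitness(self, mask: FeatureMask) -> float:
        return self.record(mask).fitness


def evaluate_gamma(
    mask: FeatureMask, data: EmbeddingDataset, classifier_spec: str = "svm", seed: int = 0
) -> float:
    """One-shot validation loss of a mask under the standard run protocol."""
    return FitnessEvaluator(data, classifier_spec, seed=seed).gamma(mask)


# --------------------------------------------------------------------------
# drivers
# --------------------------------------------------------------------------


def _evaluate(evaluator: FitnessEvaluator, positions: np.ndarray) -> np.ndarray:
    return np.array([evaluator.fitness(binarize(p)) for p in positions])


def _driver_shell(
    data: EmbeddingDataset,
    params: OptimizerParams,
    classifier_spec: str,
    name: str,
    step: Callable,
    callback: Optional[Callable] = None,
) -> FsResult:
    """Common loop: init, evaluate, elitist best tracking, convergence log.

    ``step(t, P, fits, best_pos, best_fit, state, rng)`` updates positions
    in place and returns its carried state (e.g. hunger).
    """
    t0 = time.perf_counter()
    rng = make_rng(params.seed)
    evaluator = FitnessEvaluator(data, classifier_spec, params.lam, params.seed)
    dim = data.n_features
    pop = init_population(params.pop_size, dim, SearchBounds.unit(dim), rng)
    P = pop.positions()
    fits = _evaluate(evaluator, P)
    i_best = int(np.argmin(fits))
    best_pos = P[i_best].copy()
    best_fit = float(fits[i_best])
    convergence = [best_fit]
    state = HungerState.zeros(params.pop_size)
    for t in range(1, params.max_iter + 1):
        state = step(t, P, fits, best_pos, best_fit, state, rng)
        np.clip(P, 0.0, 1.0, out=P)
        fits = _evaluate(evaluator, P)
        i_cur = int(np.argmin(fits))
        if fits[i_cur] < best_fit:  # strict: first-found ties kept
            best_fit = float(fits[i_cur])
            best_pos = P[i_cur].copy()
        convergence.append(best_fit)
        if callback is not None:
            callback(t, P.copy(), fits.copy(), state)
    best_mask = binarize(best_pos)
    rec = evaluator.record(best_mask)
    return FsResult(
        best_mask=best_mask,
        best_fitness=best_fit,
        selected_count=best_mask.count,
        convergence=convergence,
        elapsed=time.perf_counter() - t0,
        seed=params.seed,
        optimizer_name=name,
        best_gamma=rec.gamma if best_mask.count else 1.0,
    )


def run_aoahg(
    data: EmbeddingDataset,
    params: OptimizerParams,
    classifier_spec: str = "svm",
    callback: Optional[Callable] = None,
) -> FsResult:
    """Hybrid driver: MOA-gated mix of arithmetic and hunger-based rules.

    Each iteration: compute MOA/MOP, hunger weights from the carried
    hunger, then accumulate hunger; per solution draw the variation value
    R; per coordinate draw gates (Pi, PA, PH) — coordinates with
    Pi > MOA take an arithmetic divide/multiply step toward the best
    (scaled by the dynamic population bounds), the rest take a
    hunger-weighted step around the current coordinate.
    """
    T = max(params.max_iter, 1)
    unit = SearchBounds.unit(data.n_features)

    def step(t, P, fits, best_pos, best_fit, hunger, rng):
        dyn = update_bounds(P)  # feeds only the arithmetic (U-L)*mu+L scale
        moa_t = moa(t, T, params)
        mop_t = mop(t, T, params.alpha)
        fit_w = float(fits.max())
        hunger = hunger_weights(hunger, params, rng)
        W1, W2 = hunger.W1, hunger.W2
        hunger = update_hunger(fits, best_fit, fit_w, hunger, unit, params, rng)
        n, dim = P.shape
        for i in range(n):
            R = variation_R(t, T, rng.random())
            p_i = rng.random(dim)
            p_a = rng.random(dim)
            p_h = rng.random(dim)
            aoa_new = aoa_explore_rule(best_pos, mop_t, dyn.lower, dyn.upper, params, p_a)
            hgs_new = aoahg_hgs_rule(P[i], best_pos, float(W1[i]), float(W2[i]), R, p_h)
            P[i] = np.where(p_i > moa_t, aoa_new, hgs_new)
        return hunger

    return _driver_shell(data, params, classifier_spec, "aoahg", step, callback)


def run_aoa(
    data: EmbeddingDataset,
    params: OptimizerParams,
    classifier_spec: str = "svm",
    callback: Optional[Callable] = None,
) -> FsResult:
    """Plain arithmetic-optimization driver (ablation baseline).

    Per coordinate: r1 > MOA takes the divide/multiply exploration rule,
    otherwise the add/subtract exploitation rule; both move toward the
    best solution inside the fixed unit box.
    """
    T = max(params.max_iter, 1)
    unit = SearchBounds.unit(data.n_features)

    def step(t, P, fits, best_pos, best_fit, state, rng):
        moa_t = moa(t, T, params)
        mop_t = mop(t, T, params.alpha)
        n, dim = P.shape
        for i in range(n):
            r1 = rng.random(dim)
            r2 = rng.random(dim)
            r3 = rng.random(dim)
            explore = aoa_explore_rule(best_pos, mop_t, unit.lower, unit.upper, params, r2)
            exploit = aoa_exploit_rule(best_pos, mop_t, unit.lower, unit.upper, params, r3)
            P[i] = np.where(r1 > moa_t, explore, exploit)
        return state

    return _driver_shell(data, params, classifier_spec, "aoa", step, callback)


def run_hgs(
    data: EmbeddingDataset,
    params: OptimizerParams,
    classifier_spec: str = "svm",
    callback: Optional[Callable] = None,
) -> FsResult:
    """Plain hunger-games-search driver (ablation baseline).

    Whole-vector updates: with probability l a multiplicative
    self-perturbation, otherwise hunger-weighted attraction to the best
    with the sign gated by the energy term E = sech(|Fit_i - Fit_b|).
    """
    T = max(params.max_iter, 1)
    unit = SearchBounds.unit(data.n_features)

    def step(t, P, fits, best_pos, best_fit, hunger, rng):
        fit_w = float(fits.max())
        hunger = hunger_weights(hunger, params, rng)
        W1, W2 = hunger.W1, hunger.W2
        hunger = update_hunger(fits, best_fit, fit_w, hunger, unit, params, rng)
        best_sol = ContinuousSolution(best_pos)
        for i in range(P.shape[0]):
            R = variation_R(t, T, rng.random())
            E = energy_E(float(fits[i]), best_fit)
            new = hgs_position_update(
                ContinuousSolution(P[i]), best_sol, float(W1[i]), float(W2[i]), R, E, params, rng
            )
            P[i] = new.position
        return hunger

    return _driver_shell(data, params, classifier_spec, "hgs", step, callback)


_DRIVERS = {"aoahg": run_aoahg, "aoa": run_aoa, "hgs": run_hgs}


def run_optimizer(
    name: str,
    data: EmbeddingDataset,
    params: OptimizerParams,
    classifier_spec: str = "svm",
) -> FsResult:
    """Dispatch a driver by label ('aoahg', 'aoa' or 'hgs')."""
    try:
        driver = _DRIVERS[name]
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(_DRIVERS)}")
    return driver(data, params, classifier_spec)


# --------------------------------------------------------------------------
# exhaustive oracle
# --------------------------------------------------------------------------

MAX_ORACLE_DIM = 16


def exhaustive_fs_oracle(
    data: EmbeddingDataset,
    classifier_spec: str = "svm",
    lam: float = 0.99,
    seed: int = 0,
):
    """Global fitness optimum by enumerating every non-empty mask.

    Uses the identical gamma protocol (same seed, same folds) as the
    drivers, so its optimum is directly comparable with a driver run at
    that seed.  Ties are broken toward fewer features, then toward the
    lexicographically smallest bit vector.  Refuses dim > 16.
    """
    dim = data.n_features
    if dim > MAX_ORACLE_DIM:
        raise ValueError(f"exhaustive oracle limited to dim <= {MAX_ORACLE_DIM}")
    evaluator = FitnessEvaluator(data, classifier_spec, lam, seed)
    best_mask = None
    best_fit = np.inf
    best_tiebreak = None
    for size in range(1, dim + 1):  # by size: fewer-features tie-break for free
        for cols in combinations(range(dim), size):
            bits = np.zeros(dim, dtype=np.int8)
            bits[list(cols)] = 1
            mask = FeatureMask(bits)
            f = evaluator.fitness(mask)
            tiebreak = tuple(bits)
            if f < best_fit or (f == best_fit and size == best_mask.count and tiebreak < best_tiebreak):
                best_fit = f
                best_mask = mask
                best_tiebreak = tiebreak
    return best_mask, float(best_fit)
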