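"""Numeric primitives of the arithmetic optimization algorithm (AOA) and the
hunger games search (HGS).

This layer knows nothing about classifiers, feature masks or files: it holds
the iteration schedules (MOA/MOP), the per-coordinate arithmetic update rules,
the hunger bookkeeping and the hunger weights.  All positions live in the
global unit box [0, 1]; every update rule clips its output back into that box
so that downstream thresholding at 0.5 stays meaningful.  Dynamic per-dimension
bounds (the population envelope) only feed the ``(U - L) * mu + L`` scale term
of the arithmetic rules.

Randomness flows exclusively through a :class:`numpy.random.Generator`; the
same seed therefore reproduces a trajectory bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "OptimizerParams",
    "SearchBounds",
    "ContinuousSolution",
    "Population",
    "HungerState",
    "make_rng",
    "init_population",
    "moa",
    "mop",
    "aoa_explore_rule",
    "aoa_exploit_rule",
    "sech",
    "variation_R",
    "energy_E",
    "update_hunger",
    "weight_w1",
    "weight_w2",
    "hunger_weights",
    "hgs_position_update",
    "aoahg_hgs_rule",
    "update_bounds",
    "clip_unit",
]


@dataclass
class OptimizerParams:
    """Knobs shared by the AOA, HGS and hybrid drivers.

    Parameters
    ----------
    min_acc, max_acc
        Endpoints of the linear MOA schedule; MOA rises from ``min_acc`` at
        t=0 to ``max_acc`` at t=T and gates exploration vs. exploitation.
    alpha
        Sensitivity exponent of the decaying MOP step-scale schedule.
    mu
        Search-control constant multiplying the bound range in the
        arithmetic update rules.
    epsilon
        Small positive stabiliser for the divide rule denominator.
    lam
        Fitness weight ``lambda`` in (0, 1]: convex weight on classifier
        validation loss vs. selected-feature ratio.
    l_hgs
        HGS branch threshold ``l`` deciding the self-perturbation branch.
    lh
        Hunger lower bound ``LH``.
    pop_size, max_iter
        Population size N and iteration budget T.
    seed
        RNG seed; fixes the whole trajectory.
    """

    min_acc: float = 0.2
    max_acc: float = 1.0
    alpha: float = 5.0
    mu: float = 0.5
    epsilon: float = 1e-12
    lam: float = 0.99
    l_hgs: float = 0.08
    lh: float = 100.0
    pop_size: int = 50
    max_iter: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_acc < self.max_acc <= 1.0):
            raise ValueError("need 0 <= min_acc < max_acc <= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not (0.0 < self.lam <= 1.0):
            raise ValueError("lam must lie in (0, 1]")
        if not (0.0 < self.l_hgs < 1.0):
            raise ValueError("l_hgs must lie in (0, 1)")
        if self.lh <= 0:
            raise ValueError("lh must be positive")
        if self.pop_size < 2:
            raise ValueError("pop_size must be at least 2")
        if self.max_iter < 0:
            raise ValueError("max_iter must be non-negative")


@dataclass
class SearchBounds:
    """Per-dimension lower/upper bound vectors L and U."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower/upper must have the same shape")
        if np.any(self.lower > self.upper):
            raise ValueError("lower must not exceed upper")

    @classmethod
    def unit(cls, dim: int) -> "SearchBounds":
        return cls(np.zeros(dim), np.ones(dim))

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower


@dataclass
class ContinuousSolution:
    """A position vector in the unit box, one coordinate per candidate feature."""

    position: np.ndarray
    fitness: Optional[float] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)

    def copy(self) -> "ContinuousSolution":
        return ContinuousSolution(self.position.copy(), self.fitness)


@dataclass
class Population:
    """N candidate solutions plus elitist best-so-far bookkeeping."""

    solutions: list
    best: Optional[ContinuousSolution] = None
    worst_fitness: Optional[float] = None

    def __len__(self) -> int:
        return len(self.solutions)

    def positions(self) -> np.ndarray:
        return np.stack([s.position for s in self.solutions])

    def fitnesses(self) -> np.ndarray:
        return np.array([s.fitness for s in self.solutions], dtype=float)


@dataclass
class HungerState:
    """Per-solution hunger H_i, its aggregate SH and the derived weights."""

    H: np.ndarray
    W1: Optional[np.ndarray] = None
    W2: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)

    @property
    def SH(self) -> float:
        return float(self.H.sum())

    @classmethod
    def zeros(cls, n: int) -> "HungerState":
        return cls(np.zeros(n))


def make_rng(seed: int) -> np.random.Generator:
    """Single entry point for randomness: same seed, same draw sequence."""
    return np.random.default_rng(seed)


def clip_unit(x: ArrayLike) -> ArrayLike:
    """Clip coordinates to the global box [0, 1]."""
    return np.clip(x, 0.0, 1.0)


def init_population(
    n: int, dim: int, bounds: SearchBounds, rng: np.random.Generator
) -> Population:
    """Draw N agents uniformly inside the bounds: X = rand * (U - L) + L."""
    if n < 2:
        raise ValueError("population size must be at least 2")
    if dim < 1:
        raise ValueError("dimension must be at least 1")
    if bounds.dim != dim:
        raise ValueError("bounds dimension mismatch")
    pos = rng.random((n, dim)) * bounds.span + bounds.lower
    return Population([ContinuousSolution(p) for p in pos])


def moa(t: int, T: int, params: OptimizerParams) -> float:
    """Math-optimizer-accelerated schedule: Min + t * (Max - Min) / T."""
    if T < 1:
        raise ValueError("T must be at least 1")
    if not 0 <= t <= T:
        raise ValueError("t must lie in [0, T]")
    return params.min_acc + t * (params.max_acc - params.min_acc) / T


def mop(t: int, T: int, alpha: float) -> float:
    """Math-optimizer-probability schedule: 1 - t^(1/alpha) / T^(1/alpha)."""
    if T < 1:
        raise ValueError("T must be at least 1")
    if not 0 <= t <= T:
        raise ValueError("t must lie in [0, T]")
    return 1.0 - t ** (1.0 / alpha) / T ** (1.0 / alpha)


def aoa_explore_rule(
    best_j: ArrayLike,
    mop_val: float,
    lower_j: ArrayLike,
    upper_j: ArrayLike,
    params: OptimizerParams,
    r2: ArrayLike,
) -> ArrayLike:
    """AOA exploration: divide (r2 > 0.5) or multiply branch, clipped to [0,1].

    divide:   Xb / (MOP + eps) * ((U - L) * mu + L)
    multiply: Xb * MOP * ((U - L) * mu + L)
    """
    scale = (np.asarray(upper_j) - np.asarray(lower_j)) * params.mu + np.asarray(lower_j)
    divide = np.asarray(best_j) / (mop_val + params.epsilon) * scale
    multiply = np.asarray(best_j) * mop_val * scale
    return clip_unit(np.where(np.asarray(r2) > 0.5, divide, multiply))


def aoa_exploit_rule(
    best_j: ArrayLike,
    mop_val: float,
    lower_j: ArrayLike,
    upper_j: ArrayLike,
    params: OptimizerParams,
    r3: ArrayLike,
) -> ArrayLike:
    """AOA exploitation: subtract (r3 > 0.5) or add branch, clipped to [0,1]."""
    scale = (np.asarray(upper_j) - np.asarray(lower_j)) * params.mu + np.asarray(lower_j)
    step = mop_val * scale
    return clip_unit(
        np.where(np.asarray(r3) > 0.5, np.asarray(best_j) - step, np.asarray(best_j) + step)
    )


def sech(x: ArrayLike) -> ArrayLike:
    """Hyperbolic secant 2 / (e^x + e^-x); in (0, 1] for finite x."""
    out = 1.0 / np.cosh(x)
    return float(out) if np.isscalar(x) else out


def variation_R(t: int, T: int, rand: float) -> float:
    """Shrinking variation-control value: R = 2*s*rand - s with s = 2*(1 - t/T)."""
    if T < 1:
        raise ValueError("T must be at least 1")
    if not 0 <= t <= T:
        raise ValueError("t must lie in [0, T]")
    s = 2.0 * (1.0 - t / T)
    return 2.0 * s * rand - s


def energy_E(fit_i: float, fit_b: float) -> float:
    """Hunger 'energy' sech(|Fit_i - Fit_b|); equals 1 exactly at the best."""
    return float(sech(abs(fit_i - fit_b)))


def update_hunger(
    fits: np.ndarray,
    fit_b: float,
    fit_w: float,
    hunger: HungerState,
    bounds: SearchBounds,
    params: OptimizerParams,
    rng: np.random.Generator,
) -> HungerState:
    """Accumulate per-solution hunger.

    Solutions at the best fitness reset to H = 0.  Everyone else gains
    ``Hn``: the normalised fitness gap ``TH = 2*(Fit_i - Fit_b)/(Fit_w -
    Fit_b) * r6 * (UB - LB)`` floored at ``LH * (1 + r)`` when it falls
    below the hunger lower bound.  ``UB - LB`` is taken as the mean bound
    range so hunger stays scalar.  Degenerate populations with
    Fit_w == Fit_b contribute TH = 0 (all equally good).
    """
    fits = np.asarray(fits, dtype=float)
    n = fits.size
    if hunger.H.size != n:
        raise ValueError("hunger vector size mismatch")
    r6 = rng.random(n)
    r = rng.random(n)
    gap = fit_w - fit_b
    span = float(np.mean(bounds.span))
    if gap > 0:
        th = 2.0 * (fits - fit_b) / gap * r6 * span
    else:
        th = np.zeros(n)
    hn = np.where(th < params.lh, params.lh * (1.0 + r), th)
    H = np.where(fits == fit_b, 0.0, hunger.H + hn)
    return HungerState(H)


def weight_w1(
    H_i: ArrayLike,
    SH: float,
    n: int,
    params: OptimizerParams,
    r3: ArrayLike,
    r4: ArrayLike,
) -> ArrayLike:
    """Hunger weight W1: H_i * N / SH * r4 when r3 < l, else 1."""
    hungry = np.asarray(H_i) * n / (SH + params.epsilon) * np.asarray(r4)
    out = np.where(np.asarray(r3) < params.l_hgs, hungry, 1.0)
    return float(out) if out.ndim == 0 else out


def weight_w2(H_i: ArrayLike, SH: float, r5: ArrayLike) -> ArrayLike:
    """Hunger weight W2 = 2 * (1 - exp(-|H_i - SH|)) * r5, in [0, 2)."""
    out = 2.0 * (1.0 - np.exp(-np.abs(np.asarray(H_i) - SH))) * np.asarray(r5)
    return float(out) if out.ndim == 0 else out


def hunger_weights(
    hunger: HungerState, params: OptimizerParams, rng: np.random.Generator
) -> HungerState:
    """Draw r3/r4/r5 per solution and attach W1/W2 to the hunger state."""
    n = hunger.H.size
    r3 = rng.random(n)
    r4 = rng.random(n)
    r5 = rng.random(n)
    sh = hunger.SH
    hunger.W1 = np.asarray(weight_w1(hunger.H, sh, n, params, r3, r4), dtype=float)
    hunger.W2 = np.asarray(weight_w2(hunger.H, sh, r5), dtype=float)
    return hunger


def hgs_position_update(
    x: ContinuousSolution,
    best: ContinuousSolution,
    W1: float,
    W2: float,
    R: float,
    E: float,
    params: OptimizerParams,
    rng: np.random.Generator,
) -> ContinuousSolution:
    """Plain HGS position update (whole-vector, per solution).

    With probability l the solution perturbs itself multiplicatively,
    X * (1 + rand); otherwise it is attracted to (or repelled around) the
    best solution: W1*Xb +/- R*W2*(Xb - X), the sign gated by r2 vs. E.
    """
    r1 = rng.random()
    if r1 < params.l_hgs:
        rand = rng.random()
        pos = x.position * (1.0 + rand)
    else:
        r2 = rng.random()
        diff = best.position - x.position
        if r2 > E:
            pos = W1 * best.position + R * W2 * diff
        else:
            pos = W1 * best.position - R * W2 * diff
    return ContinuousSolution(clip_unit(pos))


def aoahg_hgs_rule(
    x_j: ArrayLike,
    best_j: ArrayLike,
    W1: float,
    W2: float,
    R: float,
    pH: ArrayLike,
) -> ArrayLike:
    """Hybrid-driver HGS coordinate rule.

    pH > 0.5: W1*x - R*W2*|x - best|;  otherwise W1*x + R*W2*|x - best|.
    Clipped to [0, 1].
    """
    step = R * W2 * np.abs(np.asarray(x_j) - np.asarray(best_j))
    out = np.where(np.asarray(pH) > 0.5, W1 * np.asarray(x_j) - step, W1 * np.asarray(x_j) + step)
    return clip_unit(out)


def update_bounds(pop: Union[Population, np.ndarray]) -> SearchBounds:
    """Dynamic search bounds: per-dimension min/max over the population."""
    positions = pop.positions() if isinstance(pop, Population) else np.asarray(pop)
    if positions.size == 0:
        raise ValueError("population must be non-empty")
    if positions.ndim == 1:
        positions = positions[None, :]
    return SearchBounds(positions.min(axis=0), positions.max(axis=0))
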