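"""Bald eagle search (BES): a three-phase population metaheuristic for
bounded continuous minimization.

Each iteration runs three phases over the whole population, mimicking an
eagle hunting over water:

1. *Select space* — each eagle moves toward a blend of the best-known and
   mean positions:  P_new = P_best + alpha * r * (P_mean - P_i),
   r ~ U(0, 1) fresh per eagle.
2. *Search prey* — a spiral sweep around the population.  With polar angle
   theta = a * pi * rand and radius r = theta + R * rand, the normalized
   spiral coordinates x, y (each scaled by the population's max |.|) drive
   P_new = P_i + x_i * (P_i - P_mean) + y_i * (P_i - P_next), where P_next
   is the (i+1)-th eagle's position, wrapping cyclically.
3. *Swoop* — a hyperbolic dive toward the best position:
   P_new = rand * P_best + x'_i * (P_i - c1 * P_mean)
                         + y'_i * (P_i - c2 * P_best),
   where x', y' use r = theta and sinh/cosh in place of sin/cos.

Candidates are clipped to the box bounds and accepted greedily (only if
their fitness improves on the eagle's current fitness), so the best-so-far
history is monotonically non-increasing.  One seeded generator drives all
randomness; draws are phase-major then eagle-major, making trajectories
bit-reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigError

__all__ = [
    "BESConfig",
    "SwarmState",
    "SpiralCoords",
    "OptimizeResult",
    "initialize",
    "select_space_phase",
    "spiral_coords",
    "search_prey_phase",
    "swoop_phase",
    "optimize",
]

FitnessFn = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class BESConfig:
    """BES settings.

    alpha in [1.5, 2] scales the pull toward the mean in the select phase;
    a in [5, 10] sets the spiral's angular sweep, R in [0.5, 2] its radial
    growth; c1, c2 in [1, 2] intensify the swoop toward the mean/best.
    Defaults sit at the aggressive end of each admissible range and are
    pinned for reproducibility.
    """

    pop_size: int = 10
    max_iter: int = 30
    lo: Sequence[float] = (-1.0,)
    hi: Sequence[float] = (1.0,)
    alpha: float = 2.0
    a_param: float = 10.0
    R_param: float = 1.5
    c1: float = 2.0
    c2: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo = np.asarray(self.lo, dtype=np.float64)
        hi = np.asarray(self.hi, dtype=np.float64)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ConfigError("lo and hi must be 1-D with equal length")
        if not np.all(lo < hi):
            raise ConfigError("need lo < hi elementwise")
        if self.pop_size < 1 or self.max_iter < 1:
            raise ConfigError("pop_size and max_iter must be >= 1")
        if not (1.5 <= self.alpha <= 2.0):
            raise ConfigError("alpha must lie in [1.5, 2]")
        if not (5.0 <= self.a_param <= 10.0):
            raise ConfigError("a_param must lie in [5, 10]")
        if not (0.5 <= self.R_param <= 2.0):
            raise ConfigError("R_param must lie in [0.5, 2]")
        if not (1.0 <= self.c1 <= 2.0 and 1.0 <= self.c2 <= 2.0):
            raise ConfigError("c1 and c2 must lie in [1, 2]")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @property
    def dim(self) -> int:
        return len(self.lo)


@dataclass
class SwarmState:
    """Population positions/fitness plus the running best and mean."""

    positions: np.ndarray  # (pop_size, dim)
    fitness: np.ndarray  # (pop_size,)
    best_position: np.ndarray
    best_fitness: float
    mean_position: np.ndarray
    iteration: int = 0
    history: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class SpiralCoords:
    """Per-eagle spiral geometry; x, y are normalized to [-1, 1]."""

    theta: np.ndarray
    r: np.ndarray
    xr: np.ndarray
    yr: np.ndarray
    x: np.ndarray
    y: np.ndarray


def _evaluate(fitness: FitnessFn, positions: np.ndarray) -> np.ndarray:
    vals = np.array([float(fitness(p)) for p in positions])
    if not np.all(np.isfinite(vals)):
        bad = positions[~np.isfinite(vals)][0]
        raise ConfigError(f"fitness returned a non-finite value at {bad}")
    return vals


def _refresh(state: SwarmState) -> None:
    i = int(np.argmin(state.fitness))
    if state.fitness[i] < state.best_fitness:
        state.best_fitness = float(state.fitness[i])
        state.best_position = state.positions[i].copy()
    state.mean_position = state.positions.mean(axis=0)


def initialize(cfg: BESConfig, fitness: FitnessFn, rng: np.random.Generator | None = None) -> SwarmState:
    """Uniform random population in the box, evaluated once."""
    rng = rng or np.random.default_rng(cfg.seed)
    positions = rng.uniform(cfg.lo, cfg.hi, size=(cfg.pop_size, cfg.dim))
    fit = _evaluate(fitness, positions)
    i = int(np.argmin(fit))
    return SwarmState(
        positions=positions,
        fitness=fit,
        best_position=positions[i].copy(),
        best_fitness=float(fit[i]),
        mean_position=positions.mean(axis=0),
    )


def _greedy_accept(
    state: SwarmState,
    candidates: np.ndarray,
    cfg: BESConfig,
    fitness: FitnessFn,
) -> None:
    candidates = np.clip(candidates, cfg.lo, cfg.hi)
    cand_fit = _evaluate(fitness, candidates)
    improved = cand_fit < state.fitness
    state.positions[improved] = candidates[improved]
    state.fitness[improved] = cand_fit[improved]
    _refresh(state)


def select_space_phase(
    state: SwarmState, cfg: BESConfig, fitness: FitnessFn, rng: np.random.Generator
) -> None:
    """Move eagles toward the best area: P_best + alpha*r*(P_mean - P_i)."""
    r = rng.random(cfg.pop_size)
    candidates = state.best_position + cfg.alpha * r[:, None] * (
        state.mean_position - state.positions
    )
    _greedy_accept(state, candidates, cfg, fitness)


def spiral_coords(
    cfg: BESConfig, rng: np.random.Generator, n: int, swoop: bool = False
) -> SpiralCoords:
    """Spiral flight geometry for ``n`` eagles.

    Search variant: theta = a*pi*rand, r = theta + R*rand, (xr, yr) =
    r*(sin, cos)(theta).  Swoop variant: r = theta and (xr, yr) =
    r*(sinh, cosh)(theta).  x and y are xr, yr divided by the population
    maxima of |xr| and |yr|.
    """
    if n == 0:
        empty = np.empty(0)
        return SpiralCoords(empty, empty, empty, empty, empty, empty)
    theta = cfg.a_param * np.pi * rng.random(n)
    if swoop:
        r = theta.copy()
        xr = r * np.sinh(theta)
        yr = r * np.cosh(theta)
    else:
        r = theta + cfg.R_param * rng.random(n)
        xr = r * np.sin(theta)
        yr = r * np.cos(theta)
    x_den = np.max(np.abs(xr)) or 1.0
    y_den = np.max(np.abs(yr)) or 1.0
    return SpiralCoords(theta=theta, r=r, xr=xr, yr=yr, x=xr / x_den, y=yr / y_den)


def search_prey_phase(
    state: SwarmState, cfg: BESConfig, fitness: FitnessFn, rng: np.random.Generator
) -> None:
    """Spiral sweep: P_i + x_i*(P_i - P_mean) + y_i*(P_i - P_next)."""
    c = spiral_coords(cfg, rng, cfg.pop_size, swoop=False)
    nxt = np.roll(state.positions, -1, axis=0)
    candidates = (
        state.positions
        + c.x[:, None] * (state.positions - state.mean_position)
        + c.y[:, None] * (state.positions - nxt)
    )
    _greedy_accept(state, candidates, cfg, fitness)


def swoop_phase(
    state: SwarmState, cfg: BESConfig, fitness: FitnessFn, rng: np.random.Generator
) -> None:
    """Dive at the prey from the best position, hyperbolic spiral weights."""
    c = spiral_coords(cfg, rng, cfg.pop_size, swoop=True)
    rand = rng.random(cfg.pop_size)
    candidates = (
        rand[:, None] * state.best_position
        + c.x[:, None] * (state.positions - cfg.c1 * state.mean_position)
        + c.y[:, None] * (state.positions - cfg.c2 * state.best_position)
    )
    _greedy_accept(state, candidates, cfg, fitness)


@dataclass
class OptimizeResult:
    """Best-ever position/fitness and the per-iteration best history."""

    best_position: np.ndarray
    best_fitness: float
    history: list[float]
    state: SwarmState


def optimize(fitness: FitnessFn, cfg: BESConfig) -> OptimizeResult:
    """Run select-space, search-prey and swoop for ``max_iter`` iterations.

    Returns the best position ever accepted; ``history[k]`` is the best
    fitness after iteration k+1 and is non-increasing.
    """
    rng = np.random.default_rng(cfg.seed)
    state = initialize(cfg, fitness, rng)
    for _ in range(cfg.max_iter):
        select_space_phase(state, cfg, fitness, rng)
        search_prey_phase(state, cfg, fitness, rng)
        swoop_phase(state, cfg, fitness, rng)
        state.iteration += 1
        state.history.append(state.best_fitness)
    return OptimizeResult(
        best_position=state.best_position.copy(),
        best_fitness=state.best_fitness,
        history=list(state.history),
        state=state,
    )
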