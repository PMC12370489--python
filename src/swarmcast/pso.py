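"""From-scratch particle swarm optimizer with linear inertia decay.

Velocity update per particle i and dimension d:

    v <- omega * v + c1 * r1 * (pbest - x) + c2 * r2 * (gbest - x)
    x <- x + v

with r1, r2 ~ U(0,1) drawn as scalars per particle per term. Positions are
clipped to bounds and velocities clamped to +/-(upper-lower). Integer
dimensions are searched as continuous internal coordinates and rounded at
decode time; log-scaled dimensions are searched in log10 space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from swarmcast.errors import ConfigError
from swarmcast.network import HyperParams

_HP_FIELD_NAMES = ("hidden_units", "dropout_rate", "learning_rate", "batch_size")


@dataclass(frozen=True)
class Dimension:
    name: str
    lower: float
    upper: float
    scale: str = "linear"  # "linear" | "log10"
    kind: str = "real"  # "real" | "integer"

    def __post_init__(self):
        if self.lower >= self.upper:
            raise ConfigError(f"{self.name}: lower {self.lower} >= upper {self.upper}")
        if self.scale not in ("linear", "log10"):
            raise ConfigError(f"{self.name}: unknown scale {self.scale}")
        if self.kind not in ("real", "integer"):
            raise ConfigError(f"{self.name}: unknown kind {self.kind}")
        if self.scale == "log10" and self.lower <= 0:
            raise ConfigError(f"{self.name}: log scale requires positive bounds")

    @property
    def internal_bounds(self) -> tuple[float, float]:
        if self.scale == "log10":
            return (np.log10(self.lower), np.log10(self.upper))
        return (self.lower, self.upper)

    def decode(self, internal: float):
        lo, hi = self.internal_bounds
        internal = float(np.clip(internal, lo, hi))
        value = 10.0**internal if self.scale == "log10" else internal
        if self.kind == "integer":
            value = int(np.clip(round(value), self.lower, self.upper))
        return value


@dataclass(frozen=True)
class SearchSpace:
    dimensions: tuple[Dimension, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.dimensions)

    @property
    def lower(self) -> np.ndarray:
        return np.array([d.internal_bounds[0] for d in self.dimensions])

    @property
    def upper(self) -> np.ndarray:
        return np.array([d.internal_bounds[1] for d in self.dimensions])

    def __len__(self) -> int:
        return len(self.dimensions)


def default_search_space() -> SearchSpace:
    """The four-knob hyperparameter space the tuner searches by default."""
    return SearchSpace(
        dimensions=(
            Dimension("hidden_units", 16, 64, "linear", "integer"),
            Dimension("dropout_rate", 0.0, 0.4, "linear", "real"),
            Dimension("learning_rate", 1e-4, 1e-2, "log10", "real"),
            Dimension("batch_size", 16, 64, "linear", "integer"),
        )
    )


def decode_position(position: Sequence[float], space: SearchSpace):
    """Map internal coordinates to concrete values (round integers,
    exponentiate log dims). Returns :class:`HyperParams` when the space has
    exactly the four hyperparameter dimensions, else a name->value dict."""
    values = {d.name: d.decode(p) for d, p in zip(space.dimensions, position)}
    if tuple(sorted(values)) == tuple(sorted(_HP_FIELD_NAMES)):
        return HyperParams(**values)
    return values


@dataclass
class SwarmState:
    """Positions/velocities/bests for the whole swarm plus the RNG."""

    space: SearchSpace
    positions: np.ndarray  # (n, d) internal coords
    velocities: np.ndarray
    pbest_positions: np.ndarray
    pbest_scores: np.ndarray
    gbest_position: np.ndarray
    gbest_score: float
    iteration: int
    stall: int
    rng: np.random.Generator
    n_failures: int = 0

    @classmethod
    def initialize(cls, space: SearchSpace, n_particles: int, seed: int) -> "SwarmState":
        if n_particles < 1:
            raise ConfigError("n_particles must be >= 1")
        rng = np.random.default_rng(seed)
        lo, hi = space.lower, space.upper
        pos = rng.uniform(lo, hi, size=(n_particles, len(space)))
        return cls(
            space=space,
            positions=pos,
            velocities=np.zeros_like(pos),
            pbest_positions=pos.copy(),
            pbest_scores=np.full(n_particles, np.inf),
            gbest_position=pos[0].copy(),
            gbest_score=np.inf,
            iteration=0,
            stall=0,
            rng=rng,
        )


def inertia_at(iteration: int, max_iter: int) -> float:
    """Linear decay 0.9 -> 0.5 over the run."""
    if max_iter <= 0 or not (0 <= iteration <= max_iter):
        raise ConfigError(f"need 0 <= iteration <= max_iter, got {iteration}/{max_iter}")
    return 0.9 - 0.4 * (iteration / max_iter)


def step(
    state: SwarmState,
    fitness: Callable[[np.ndarray], float],
    omega: float,
    c1: float = 2.0,
    c2: float = 2.0,
) -> SwarmState:
    """One generation: evaluate all particles, update bests, then move.

    A fitness callback that raises scores the particle +inf (logged on the
    state) instead of aborting the run.
    """
    lo, hi = state.space.lower, state.space.upper
    vmax = hi - lo
    n, d = state.positions.shape

    scores = np.empty(n)
    for i in range(n):
        try:
            scores[i] = float(fitness(state.positions[i]))
        except Exception:
            scores[i] = np.inf
            state.n_failures += 1
        if not np.isfinite(scores[i]):
            scores[i] = np.inf

    improved = scores < state.pbest_scores
    state.pbest_scores = np.where(improved, scores, state.pbest_scores)
    state.pbest_positions[improved] = state.positions[improved]
    best_i = int(np.argmin(state.pbest_scores))
    if state.pbest_scores[best_i] < state.gbest_score:
        state.gbest_score = float(state.pbest_scores[best_i])
        state.gbest_position = state.pbest_positions[best_i].copy()

    r1 = state.rng.uniform(size=(n, 1))
    r2 = state.rng.uniform(size=(n, 1))
    state.velocities = (
        omega * state.velocities
        + c1 * r1 * (state.pbest_positions - state.positions)
        + c2 * r2 * (state.gbest_position[None, :] - state.positions)
    )
    state.velocities = np.clip(state.velocities, -vmax, vmax)
    state.positions = np.clip(state.positions + state.velocities, lo, hi)
    state.iteration += 1
    return state


def optimize(
    fitness: Callable[[np.ndarray], float],
    space: SearchSpace,
    n_particles: int = 10,
    max_iter: int = 50,
    patience: int = 5,
    seed: int = 0,
    c1: float = 2.0,
    c2: float = 2.0,
    tol: float = 1e-9,
    cache_decoded: bool = True,
) -> tuple[np.ndarray, float, list[dict]]:
    """Run the swarm with the linear inertia schedule and a stall criterion.

    Stops when the global best improves by less than ``tol`` for ``patience``
    consecutive generations, or at ``max_iter``. When ``cache_decoded`` is
    set, fitness values are memoized on the decoded position so re-evaluating
    an identical rounded configuration is free.

    Returns (best internal position, best score, per-generation trace). The
    trace rows carry iteration, omega, best score so far, and the decoded
    best configuration; the best-score sequence is monotone non-increasing.
    """
    state = SwarmState.initialize(space, n_particles, seed)
    cache: dict = {}

    def wrapped(position: np.ndarray) -> float:
        if not cache_decoded:
            return fitness(position)
        decoded = decode_position(position, space)
        key = tuple(sorted(decoded.items())) if isinstance(decoded, dict) else decoded
        if key not in cache:
            cache[key] = fitness(position)
        return cache[key]

    trace: list[dict] = []
    for it in range(max_iter):
        omega = inertia_at(it, max_iter)
        prev_best = state.gbest_score
        step(state, wrapped, omega, c1=c1, c2=c2)
        decoded = decode_position(state.gbest_position, space)
        trace.append(
            {
                "iteration": it + 1,
                "omega": omega,
                "best_score": state.gbest_score,
                "best_decoded": decoded,
            }
        )
        if prev_best - state.gbest_score < tol:
            state.stall += 1
            if state.stall >= patience:
                break
        else:
            state.stall = 0
    return state.gbest_position.copy(), state.gbest_score, trace
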