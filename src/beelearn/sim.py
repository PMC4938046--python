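"""Agent-based simulation of foragers that learn patch quality individually or socially.

The model world holds a fixed amount of resource per time step, spread over
discrete patches.  In *no-variance* worlds every patch receives the same
share forever; in *high-variance* worlds the whole resource is concentrated
in a few rich patches whose identity is redrawn periodically.  Foragers pick
the patch their memory says is best (with a small exploration probability),
split a patch's payoff equally with every other occupant (exploitative
competition), and update their memory either from their own intake
(individual learners) or additionally from watching one random conspecific
(social learners).  Agents die at a constant per-step rate and are replaced
by offspring of surviving agents sampled proportionally to accumulated
fitness, so the mix of learning strategies evolves.

The module exposes the individual mechanisms (payoff draws, equal sharing,
patch choice, memory updates, mortality/replacement) as testable functions
and composes them in :func:`step` / :func:`run_replicate`.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np

__all__ = [
    "ConfigError",
    "WorldConfig",
    "Forager",
    "SimState",
    "ReplicateResult",
    "draw_patch_payoffs",
    "share_patch_payoff",
    "choose_patch",
    "update_memory_individual",
    "update_memory_social",
    "mortality_and_reproduction",
    "init_state",
    "step",
    "run_replicate",
]

REGIMES = ("no_variance", "high_variance")

#: integer codes used in strategy arrays
INDIVIDUAL, SOCIAL = 0, 1


class ConfigError(ValueError):
    """Raised for an invalid or inconsistent simulation configuration."""


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")


@dataclasses.dataclass
class WorldConfig:
    """All parameters of one simulated world.

    Parameters
    ----------
    n_patches:
        Number of resource patches.
    n_agents:
        Constant population size.
    total_resource:
        Resource units distributed across patches every time step (``R``).
    regime:
        ``"no_variance"`` (equal, constant patch payoffs) or
        ``"high_variance"`` (all resource in ``n_rich_patches`` patches,
        redrawn every ``turnover_interval`` steps).
    n_rich_patches:
        High-variance only: number of patches that jointly hold the whole
        resource.
    turnover_interval:
        High-variance only: steps between redraws of the rich-patch set.
    explore_prob:
        Probability that a forager ignores its memory and samples a
        uniformly random patch on a given step.
    death_rate:
        Per-step probability that each agent dies and is replaced.
    mutation_prob:
        Probability that a newborn flips its inherited learning strategy.
    initial_social_fraction:
        Fraction of the founding population using the social strategy
        (rounded to a whole number of agents).
    n_steps:
        Time steps per replicate.
    burn_in_fraction:
        Leading fraction of the trajectory discarded before averaging the
        evolved proportion of social learners.
    memory_init:
        Patch-quality estimate naive agents start with, for every patch.
    """

    n_patches: int = 12
    n_agents: int = 100
    total_resource: float = 100.0
    regime: str = "high_variance"
    n_rich_patches: int = 2
    turnover_interval: int = 10
    explore_prob: float = 0.03
    death_rate: float = 0.15
    mutation_prob: float = 0.005
    initial_social_fraction: float = 0.5
    n_steps: int = 5000
    burn_in_fraction: float = 0.8
    memory_init: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_patches", "n_agents", "turnover_interval", "n_steps"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        if self.total_resource <= 0:
            raise ConfigError(f"total_resource must be > 0, got {self.total_resource!r}")
        if self.regime not in REGIMES:
            raise ConfigError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if self.regime == "high_variance":
            if not isinstance(self.n_rich_patches, (int, np.integer)) or self.n_rich_patches < 1:
                raise ConfigError(
                    "n_rich_patches must be a positive integer in the "
                    f"high-variance regime, got {self.n_rich_patches!r}"
                )
            if self.n_rich_patches > self.n_patches:
                raise ConfigError(
                    f"n_rich_patches ({self.n_rich_patches}) exceeds n_patches ({self.n_patches})"
                )
        for name in ("explore_prob", "death_rate", "mutation_prob", "initial_social_fraction"):
            _check_prob(name, getattr(self, name))
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ConfigError(
                f"burn_in_fraction must lie in [0, 1), got {self.burn_in_fraction!r}"
            )

    def replace(self, **changes) -> "WorldConfig":
        """Return a copy with the given fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_dict(cls, data: dict) -> "WorldConfig":
        """Build a config from a plain mapping; unknown keys are rejected."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
        return cls(**data)

    @classmethod
    def from_json(cls, path) -> "WorldConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class Forager:
    """One agent: its strategy, per-patch memory, and accumulated fitness."""

    id: int
    strategy: int  # INDIVIDUAL (0) or SOCIAL (1)
    memory: np.ndarray
    fitness: float = 0.0
    current_patch: int | None = None
    last_intake: float | None = None


@dataclasses.dataclass
class SimState:
    """Full population state at one time step (array-of-records layout)."""

    step: int
    payoffs: np.ndarray  # (n_patches,) current patch resource values
    strategy: np.ndarray  # (n_agents,) int8, 1 = social
    fitness: np.ndarray  # (n_agents,) accumulated per-capita intake
    memory: np.ndarray  # (n_agents, n_patches) estimated per-capita intake
    current_patch: np.ndarray  # (n_agents,) patch index, -1 before first step
    last_intake: np.ndarray  # (n_agents,) realized intake this step
    rng: np.random.Generator

    @property
    def prop_social(self) -> float:
        return float(np.mean(self.strategy == SOCIAL))

    @property
    def population(self) -> list[Forager]:
        """Materialise the population as :class:`Forager` records (views)."""
        return [
            Forager(
                id=i,
                strategy=int(self.strategy[i]),
                memory=self.memory[i],
                fitness=float(self.fitness[i]),
                current_patch=int(self.current_patch[i]) if self.current_patch[i] >= 0 else None,
                last_intake=float(self.last_intake[i]),
            )
            for i in range(self.strategy.size)
        ]


@dataclasses.dataclass
class ReplicateResult:
    """Trajectory of the social-learner proportion for one seeded replicate."""

    seed: int
    trajectory: np.ndarray
    evolved_proportion: float

    def __post_init__(self) -> None:
        traj = np.asarray(self.trajectory, dtype=float)
        if np.any((traj < 0) | (traj > 1)):
            raise ValueError("trajectory values must lie in [0, 1]")
        if not 0.0 <= self.evolved_proportion <= 1.0:
            raise ValueError("evolved_proportion must lie in [0, 1]")
        self.trajectory = traj


def draw_patch_payoffs(config: WorldConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw a fresh patch-payoff vector summing to ``total_resource``.

    No-variance worlds split the resource equally; high-variance worlds
    concentrate it equally in ``n_rich_patches`` patches chosen uniformly at
    random, leaving all other patches empty.  The caller is responsible for
    holding the vector fixed between turnover events.
    """
    if config.regime == "no_variance":
        return np.full(config.n_patches, config.total_resource / config.n_patches)
    rich = rng.choice(config.n_patches, size=config.n_rich_patches, replace=False)
    payoffs = np.zeros(config.n_patches)
    payoffs[rich] = config.total_resource / config.n_rich_patches
    return payoffs


def share_patch_payoff(patch_value: float, n_occupants: int) -> float:
    """Per-capita intake under equal sharing: ``patch_value / n_occupants``.

    An unoccupied patch yields 0 (its resource is wasted, not carried over).
    """
    if patch_value < 0:
        raise ValueError(f"patch_value must be >= 0, got {patch_value!r}")
    if n_occupants < 0:
        raise ValueError(f"n_occupants must be >= 0, got {n_occupants!r}")
    if n_occupants == 0:
        return 0.0
    return patch_value / n_occupants


def _choose_patches(
    memory: np.ndarray, explore_prob: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised epsilon-greedy patch choice for every row of ``memory``.

    With probability ``explore_prob`` an agent samples a uniform random
    patch; otherwise it takes the argmax of its memory row, ties broken
    uniformly at random.
    """
    n_agents, n_patches = memory.shape
    row_max = memory.max(axis=1, keepdims=True)
    # among tied maxima pick the entry with the largest uniform draw
    tie_break = rng.random(memory.shape)
    choices = np.argmax(np.where(memory == row_max, tie_break, -1.0), axis=1)
    explore = rng.random(n_agents) < explore_prob
    n_explore = int(explore.sum())
    if n_explore:
        choices[explore] = rng.integers(0, n_patches, size=n_explore)
    return choices.astype(np.int64)


def choose_patch(forager: Forager, config: WorldConfig, rng: np.random.Generator) -> int:
    """Epsilon-greedy choice for a single forager (see :func:`_choose_patches`)."""
    memory = np.asarray(forager.memory, dtype=float)
    if memory.shape != (config.n_patches,):
        raise ValueError(
            f"memory must have length n_patches={config.n_patches}, got shape {memory.shape}"
        )
    return int(_choose_patches(memory[None, :], config.explore_prob, rng)[0])


def update_memory_individual(forager: Forager, patch: int, observed_intake: float) -> Forager:
    """Overwrite the memory entry for ``patch`` with the realized intake."""
    forager.memory[patch] = observed_intake
    return forager


def update_memory_social(
    forager: Forager, population: Sequence[Forager], rng: np.random.Generator
) -> Forager:
    """Record own intake, then copy one random conspecific's patch outcome.

    The observed agent is sampled uniformly among the *other* members of the
    population; the observer writes that agent's per-capita intake into the
    memory slot of the patch it occupied.  Social learners also experience
    their own payoff, so their own patch entry is updated first.
    """
    if forager.current_patch is not None and forager.last_intake is not None:
        forager.memory[forager.current_patch] = forager.last_intake
    others = [agent for agent in population if agent.id != forager.id]
    if others:
        observed = others[int(rng.integers(len(others)))]
        if observed.current_patch is not None and observed.last_intake is not None:
            forager.memory[observed.current_patch] = observed.last_intake
    return forager


def mortality_and_reproduction(
    strategy: np.ndarray,
    fitness: np.ndarray,
    memory: np.ndarray,
    death_rate: float,
    mutation_prob: float,
    rng: np.random.Generator,
    memory_init: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Constant-rate death with fitness-proportional replacement (in place).

    Each agent dies independently with probability ``death_rate``.  Every
    death slot is refilled by a newborn copying the strategy of a parent
    drawn from the *surviving* agents with probability proportional to
    accumulated fitness (uniformly if all surviving fitnesses are zero).  If
    the whole population dies in one step, parents are drawn from the
    pre-death population by the same rule.  Newborns start with zero fitness,
    memory reset to ``memory_init``, and flip strategy with probability
    ``mutation_prob``.  Population size never changes.
    """
    n = strategy.size
    dies = rng.random(n) < death_rate
    n_dead = int(dies.sum())
    if n_dead == 0:
        return strategy, fitness, memory
    survives = ~dies
    if survives.any():
        pool = np.flatnonzero(survives)
    else:
        pool = np.arange(n)
    weights = fitness[pool]
    total = weights.sum()
    if total > 0:
        parents = rng.choice(pool, size=n_dead, p=weights / total)
    else:
        parents = rng.choice(pool, size=n_dead)
    child_strategy = strategy[parents].copy()
    flips = rng.random(n_dead) < mutation_prob
    child_strategy[flips] = 1 - child_strategy[flips]
    strategy[dies] = child_strategy
    fitness[dies] = 0.0
    memory[dies, :] = memory_init
    return strategy, fitness, memory


def init_state(config: WorldConfig, rng: np.random.Generator) -> SimState:
    """Found a population at step 0 with the configured strategy mix."""
    n = config.n_agents
    n_social = round(config.initial_social_fraction * n)
    strategy = np.zeros(n, dtype=np.int8)
    strategy[:n_social] = SOCIAL
    rng.shuffle(strategy)
    if config.regime == "no_variance":
        payoffs = draw_patch_payoffs(config, rng)
    else:
        payoffs = np.zeros(config.n_patches)  # drawn on the first step
    return SimState(
        step=0,
        payoffs=payoffs,
        strategy=strategy,
        fitness=np.zeros(n),
        memory=np.full((n, config.n_patches), float(config.memory_init)),
        current_patch=np.full(n, -1, dtype=np.int64),
        last_intake=np.zeros(n),
        rng=rng,
    )


def step(state: SimState, config: WorldConfig) -> SimState:
    """Advance the world by one time step (in place).

    Order of events: payoff redraw if due, patch choice, equal sharing and
    fitness accrual, memory updates (own experience for everyone, then one
    random observation for each social learner), mortality/replacement.
    """
    rng = state.rng
    n = state.strategy.size
    if config.regime == "high_variance" and state.step % config.turnover_interval == 0:
        state.payoffs = draw_patch_payoffs(config, rng)

    choices = _choose_patches(state.memory, config.explore_prob, rng)
    occupancy = np.bincount(choices, minlength=config.n_patches)
    per_capita = np.zeros(config.n_patches)
    occupied = occupancy > 0
    per_capita[occupied] = state.payoffs[occupied] / occupancy[occupied]
    intake = per_capita[choices]

    state.fitness += intake
    state.current_patch = choices
    state.last_intake = intake

    # every forager experiences its own payoff
    state.memory[np.arange(n), choices] = intake
    # each social learner additionally observes one random other agent
    social = np.flatnonzero(state.strategy == SOCIAL)
    if social.size and n > 1:
        observed = rng.integers(0, n - 1, size=social.size)
        observed = observed + (observed >= social)  # skip self
        state.memory[social, choices[observed]] = intake[observed]

    mortality_and_reproduction(
        state.strategy,
        state.fitness,
        state.memory,
        config.death_rate,
        config.mutation_prob,
        rng,
        config.memory_init,
    )
    state.step += 1
    return state


def run_replicate(config: WorldConfig, seed) -> ReplicateResult:
    """Run one seeded replicate and return its social-proportion trajectory.

    ``seed`` is anything :func:`numpy.random.default_rng` accepts; the same
    seed and config reproduce the trajectory bit for bit.
    """
    rng = np.random.default_rng(seed)
    state = init_state(config, rng)
    trajectory = np.empty(config.n_steps)
    for t in range(config.n_steps):
        step(state, config)
        trajectory[t] = state.prop_social
    burn = int(config.burn_in_fraction * config.n_steps)
    evolved = float(trajectory[burn:].mean())
    seed_int = int(seed) if isinstance(seed, (int, np.integer)) else -1
    return ReplicateResult(seed=seed_int, trajectory=trajectory, evolved_proportion=evolved)
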