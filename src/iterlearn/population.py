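"""Population turnover and interaction loop.

Each iteration the oldest agent dies, a newborn (posterior = prior) enters,
and 20 producer→learner communication episodes take place: a meaning is drawn
uniformly, a producer emits a signal for it, and a uniformly chosen *other*
agent updates its posterior on the observed pair.  Two transmission conditions
select the producer:

* ``oldest`` — the most experienced agent always produces (vertical
  transmission, as in a village sign language);
* ``midlife`` — the agent half way through its lifespan produces (horizontal
  learning-from-learners transmission, as in a deaf-community school setting);
  over a focal agent's lifetime five of its nine producers are older than it
  and four are younger.

A "generation" is ``n_agents`` iterations — one complete population
replacement.  At the end of every iteration the oldest agent's posterior is
aggregated into the four language-class masses and recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import production
from .agents import Agent, make_initialized_agent, make_untrained_agent, update_posterior
from .language_space import (
    CLASS_NAMES,
    ConfigurationError,
    Language,
    LanguageSpace,
)

__all__ = [
    "CONDITIONS",
    "DEFAULT_INITIAL_LANGUAGE",
    "SimulationConfig",
    "PopulationState",
    "ClassMassTrace",
    "init_population",
    "turnover",
    "select_producer",
    "midlife_age",
    "lifetime_producer_profile",
    "run_episode",
    "run_simulation",
    "class_mass",
]

CONDITIONS = ("oldest", "midlife")

#: The holistic language every agent starts from: ac bd pr qs.
DEFAULT_INITIAL_LANGUAGE = Language((0, 1, 4, 7))


@dataclass(frozen=True)
class SimulationConfig:
    """Complete parameterization of one simulation run.

    ``epsilon`` is used both as the learner's likelihood noise and the
    producer's articulation-error rate, as in the underlying model.
    """

    n_agents: int = 10
    episodes_per_iteration: int = 20
    n_iterations: int = 2000
    epsilon: float = 0.05
    gamma: float = 100.0
    condition: str = "oldest"
    initial_language: Language = DEFAULT_INITIAL_LANGUAGE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ConfigurationError("need at least 2 agents")
        if self.episodes_per_iteration < 1:
            raise ConfigurationError("need at least 1 episode per iteration")
        if self.n_iterations < 1:
            raise ConfigurationError("need at least 1 iteration")
        if not 0.0 <= self.epsilon < 1.0:
            raise ConfigurationError(f"epsilon must be in [0, 1), got {self.epsilon}")
        if self.gamma < 0:
            raise ConfigurationError(f"gamma must be non-negative, got {self.gamma}")
        if self.condition not in CONDITIONS:
            raise ConfigurationError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


@dataclass
class PopulationState:
    """Mutable population: agents with pairwise-distinct ages, iteration counter."""

    agents: list[Agent]
    iteration: int = 0
    next_agent_id: int = 0

    def oldest(self) -> Agent:
        return max(self.agents, key=lambda a: a.age)

    def by_age(self, age: int) -> Agent:
        for agent in self.agents:
            if agent.age == age:
                return agent
        raise RuntimeError(f"no agent with age {age}; population state corrupt")


@dataclass
class ClassMassTrace:
    """Per-iteration class-aggregated posterior of the oldest agent.

    ``masses`` has shape (n_iterations, 4) in CLASS_NAMES order
    (degenerate, holistic, combinatorial, other); row i is recorded at the end
    of iteration i + 1.
    """

    masses: np.ndarray
    config: SimulationConfig
    metadata: dict = field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return self.masses.shape[0]

    def mass(self, class_name: str) -> np.ndarray:
        return self.masses[:, CLASS_NAMES.index(class_name)]


def class_mass(posterior: np.ndarray, space: LanguageSpace) -> np.ndarray:
    """Posterior mass per language class, in CLASS_NAMES order; sums to 1."""
    return space.class_masks @ posterior


def init_population(config: SimulationConfig, space: LanguageSpace) -> PopulationState:
    """All agents start as point masses on the shared initial (holistic) language.

    The initial agents are interchangeable, so ages 0..n_agents-1 are assigned
    arbitrarily by position to make turnover order well defined.
    """
    space.index_of(config.initial_language)  # validates membership
    agents = [
        make_initialized_agent(space, config.initial_language, agent_id=i, age=i)
        for i in range(config.n_agents)
    ]
    return PopulationState(agents=agents, iteration=0, next_agent_id=config.n_agents)


def turnover(state: PopulationState, space: LanguageSpace) -> PopulationState:
    """Remove the oldest agent, age survivors, add an untrained newborn."""
    oldest = state.oldest()
    survivors = [a for a in state.agents if a is not oldest]
    for agent in survivors:
        agent.age += 1
    newborn = make_untrained_agent(space, agent_id=state.next_agent_id)
    state.agents = survivors + [newborn]
    state.next_agent_id += 1
    return state


def midlife_age(n_agents: int) -> int:
    """Producer age in the learning-from-learners condition (5 for 10 agents).

    This is the unique choice under which a focal agent's lifetime producers
    split 5 older / 4 younger.
    """
    return n_agents // 2


def select_producer(state: PopulationState, condition: str) -> Agent:
    """The producing agent for an episode under the given transmission condition."""
    n_agents = len(state.agents)
    if condition == "oldest":
        return state.by_age(n_agents - 1)
    if condition == "midlife":
        return state.by_age(midlife_age(n_agents))
    raise ConfigurationError(f"unknown condition {condition!r}")


def lifetime_producer_profile(condition: str, n_agents: int = 10) -> dict[str, int]:
    """Deterministic producer schedule over one focal agent's lifetime.

    Follows a focal agent from age 0 to age n_agents-1.  Each iteration the
    producer occupies a fixed age slot, and one agent is replaced per
    iteration, so every iteration's producer is a distinct individual; the
    focal agent itself produces (and cannot learn) in the iteration where it
    occupies that slot.  Returns the number of distinct lifetime producers and
    how many are older/younger than the focal agent.
    """
    producer_age = n_agents - 1 if condition == "oldest" else midlife_age(n_agents)
    if condition not in CONDITIONS:
        raise ConfigurationError(f"unknown condition {condition!r}")
    older = younger = 0
    for focal_age in range(n_agents):
        if focal_age == producer_age:
            continue  # the focal agent is the producer; it cannot learn from itself
        if producer_age > focal_age:
            older += 1
        else:
            younger += 1
    return {"distinct": older + younger, "older": older, "younger": younger}


def run_episode(
    state: PopulationState,
    config: SimulationConfig,
    space: LanguageSpace,
    rng: np.random.Generator,
) -> PopulationState:
    """One communication/learning episode; exactly one learner's posterior changes."""
    meaning = int(rng.integers(space.n_meanings))
    producer = select_producer(state, config.condition)
    signal = production.produce_signal(
        producer.posterior, meaning, config.gamma, config.epsilon, space, rng
    )
    candidates = [a for a in state.agents if a is not producer]
    learner = candidates[int(rng.integers(len(candidates)))]
    update_posterior(learner, meaning, signal, config.epsilon, space)
    return state


def run_simulation(
    config: SimulationConfig,
    space: LanguageSpace,
    rng: Optional[np.random.Generator] = None,
    metadata: Optional[dict] = None,
) -> ClassMassTrace:
    """Run one full simulation and record the oldest agent's class masses.

    Each iteration: turnover, then ``episodes_per_iteration`` episodes, then a
    snapshot of the (post-turnover) oldest agent's class-aggregated posterior.
    Fully reproducible from the seed (or a supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = init_population(config, space)
    masses = np.empty((config.n_iterations, len(CLASS_NAMES)))
    for it in range(config.n_iterations):
        state.iteration = it + 1
        turnover(state, space)
        for _ in range(config.episodes_per_iteration):
            run_episode(state, config, space, rng)
        masses[it] = class_mass(state.oldest().posterior, space)
    return ClassMassTrace(masses=masses, config=config, metadata=dict(metadata or {}))
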