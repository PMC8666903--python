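"""Bayesian learning agents.

An agent carries a full posterior distribution over the enumerated language
space and updates it after every observed meaning–signal pair:

    P(l | d) ∝ P(l) · Π P(s_t | l, m_t)

with a noisy categorical likelihood: probability ``1 - ε`` when the signal is
the one the language pairs with the meaning, and ``ε / 3`` otherwise (the
production-error model assumes three incorrect alternatives; ``n_alternatives``
generalizes this).  The posterior is a sufficient statistic, so agents do not
store their observation history.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .language_space import ConfigurationError, Language, LanguageSpace

__all__ = [
    "Agent",
    "likelihood",
    "likelihood_vector",
    "make_untrained_agent",
    "make_initialized_agent",
    "update_posterior",
]


class DegenerateUpdateError(ArithmeticError):
    """All posterior weights vanished during an update (only possible at ε = 0)."""


@dataclass
class Agent:
    """One population member: identity, iterations survived, full posterior."""

    agent_id: int
    age: int
    posterior: np.ndarray

    def copy(self) -> "Agent":
        return Agent(self.agent_id, self.age, self.posterior.copy())


def _check_epsilon(epsilon: float) -> None:
    if not 0.0 <= epsilon < 1.0:
        raise ConfigurationError(f"epsilon must be in [0, 1), got {epsilon}")


def likelihood(
    signal: int,
    language: Language,
    meaning: int,
    epsilon: float,
    n_alternatives: int = 3,
) -> float:
    """P(s | l, m): ``1 - ε`` if the language pairs s with m, else ``ε / n_alternatives``.

    Used as an unnormalized update weight; for fixed (l, m) the values need not
    sum to 1 over signals.
    """
    _check_epsilon(epsilon)
    return 1.0 - epsilon if language.mapping[meaning] == signal else epsilon / n_alternatives


def likelihood_vector(
    space: LanguageSpace,
    meaning: int,
    signal: int,
    epsilon: float,
    n_alternatives: int = 3,
) -> np.ndarray:
    """Vector of P(s | l, m) over every language in the space, cached per (ε, m, s)."""
    _check_epsilon(epsilon)
    key = ("lik", float(epsilon), n_alternatives)
    table = space._cache.get(key)
    if table is None:
        # (n_meanings, n_signals, n_languages) table of update weights
        hit = (
            space.mapping_array.T[:, None, :]
            == np.arange(space.inventory.n_signals)[None, :, None]
        )
        table = np.where(hit, 1.0 - epsilon, epsilon / n_alternatives)
        space._cache[key] = table
    return table[meaning, signal]


def make_untrained_agent(space: LanguageSpace, agent_id: int) -> Agent:
    """A newborn: age 0, posterior equal to the simplicity prior (no data yet)."""
    return Agent(agent_id=agent_id, age=0, posterior=space.prior.copy())


def make_initialized_agent(
    space: LanguageSpace, language: Language, agent_id: int, age: int = 0
) -> Agent:
    """An agent committed to one language: a point-mass posterior on it."""
    index = space.index_of(language)
    posterior = np.zeros(space.n_languages)
    posterior[index] = 1.0
    return Agent(agent_id=agent_id, age=age, posterior=posterior)


def update_posterior(
    agent: Agent,
    meaning: int,
    signal: int,
    epsilon: float,
    space: LanguageSpace,
    n_alternatives: int = 3,
) -> Agent:
    """Bayes update in place from one observed (meaning, signal) pair.

    Sequential updates over a sequence of pairs equal the batch
    prior-times-product-of-likelihoods posterior, so observation order is
    irrelevant.
    """
    weights = agent.posterior * likelihood_vector(
        space, meaning, signal, epsilon, n_alternatives
    )
    total = weights.sum()
    if total <= 0.0:
        raise DegenerateUpdateError(
            "posterior collapsed to zero mass; observation impossible under every "
            "surviving hypothesis (requires epsilon = 0)"
        )
    agent.posterior = weights / total
    return agent
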