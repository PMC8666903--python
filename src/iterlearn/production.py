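"""Communicatively rational signal production.

A producer scores each signal by the posterior-weighted communication function

    C(s | l, m) = (1 / a)**γ   if l pairs s with m, else 0,

where ``a`` is the signal's ambiguity in ``l`` (how many meanings it expresses)
and γ is the communicative-rationality exponent: γ = 0 ignores ambiguity
entirely, large γ strongly penalizes ambiguous signals.  The produced signal is
the argmax of ``score(s) = Σ_l P(l|d) · C(s|l,m)`` (ties broken uniformly at
random), after which production noise replaces it with a uniformly chosen
other signal with probability ε.
"""

from __future__ import annotations

import numpy as np

from .language_space import ConfigurationError, Language, LanguageSpace, ambiguity

__all__ = [
    "communication_weight",
    "signal_scores",
    "choose_signal",
    "apply_production_noise",
    "produce_signal",
]


def communication_weight(
    language: Language, meaning: int, signal: int, gamma: float
) -> float:
    """C(s | l, m): ambiguity-penalized weight in [0, 1]."""
    if language.mapping[meaning] != signal:
        return 0.0
    return (1.0 / ambiguity(language, signal)) ** gamma


def _paired_weights(space: LanguageSpace, gamma: float) -> np.ndarray:
    """(n_meanings, n_languages) array of (1/a)**γ for each language's paired signal."""
    key = ("prod", float(gamma))
    weights = space._cache.get(key)
    if weights is None:
        amb = space.ambiguity_matrix  # (n_languages, n_signals)
        rows = np.arange(space.n_languages)
        chosen = np.stack(
            [amb[rows, space.mapping_array[:, m]] for m in range(space.n_meanings)]
        )
        weights = chosen.astype(float) ** -float(gamma)
        space._cache[key] = weights
    return weights


def signal_scores(
    posterior: np.ndarray, meaning: int, gamma: float, space: LanguageSpace
) -> np.ndarray:
    """score(s) = Σ_l posterior(l) · C(s | l, meaning) for every signal."""
    if gamma < 0:
        raise ConfigurationError(f"gamma must be non-negative, got {gamma}")
    contrib = posterior * _paired_weights(space, gamma)[meaning]
    return np.bincount(
        space.mapping_array[:, meaning],
        weights=contrib,
        minlength=space.inventory.n_signals,
    )


def choose_signal(scores: np.ndarray, rng: np.random.Generator) -> int:
    """Argmax over signals, ties broken uniformly at random."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ArithmeticError("non-finite signal scores")
    maxima = np.flatnonzero(scores == scores.max())
    if maxima.size == 1:
        return int(maxima[0])
    return int(rng.choice(maxima))


def apply_production_noise(
    chosen: int, epsilon: float, rng: np.random.Generator, n_signals: int
) -> int:
    """Emit the chosen signal with probability 1 − ε, else a uniform other signal."""
    if not 0.0 <= epsilon < 1.0:
        raise ConfigurationError(f"epsilon must be in [0, 1), got {epsilon}")
    if epsilon == 0.0 or rng.random() >= epsilon:
        return chosen
    other = int(rng.integers(n_signals - 1))
    return other if other < chosen else other + 1


def produce_signal(
    posterior: np.ndarray,
    meaning: int,
    gamma: float,
    epsilon: float,
    space: LanguageSpace,
    rng: np.random.Generator,
) -> int:
    """Full production pipeline: scores → argmax with random tie-break → noise."""
    scores = signal_scores(posterior, meaning, gamma, space)
    chosen = choose_signal(scores, rng)
    return apply_production_noise(chosen, epsilon, rng, space.inventory.n_signals)
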