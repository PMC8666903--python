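"""Hypothesis space of miniature languages: enumeration, taxonomy, simplicity prior.

A *language* maps each of a small set of atomic meanings to exactly one signal
drawn from a fixed finite inventory; several meanings may share a signal.  With
the default inventory of eight two-character signals (``ac bd ad bc pr ps qr
qs``) and four meanings there are 8**4 = 4096 languages.  Each language is
classified as

* **degenerate** — one signal for every meaning (maximally simple, inexpressive),
* **holistic** — a distinct signal per meaning with no systematic recombination,
* **combinatorial** — distinct signals built by fully recombining a small set of
  per-position elements (the signal set is a complete Cartesian product of its
  per-position character sets), i.e. the languages exhibiting duality of
  patterning,
* **other** — everything else (e.g. partially degenerate languages).

Simplicity is measured by a minimum-description-length style coding length
``L(l) = -sum_i log2 p(l_i)`` where ``p(l_i)`` is the relative frequency of the
i-th character within the language's own concatenated character string.  The
learning prior is ``P(l) proportional to 2**-L(l)``, so shorter (more
compressible) languages are a priori more probable.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SIGNALS",
    "CLASS_NAMES",
    "DEGENERATE",
    "HOLISTIC",
    "COMBINATORIAL",
    "OTHER",
    "SignalInventory",
    "Language",
    "LanguageSpace",
    "enumerate_languages",
    "classify",
    "coding_length",
    "compute_prior",
    "class_counts",
    "ambiguity",
]

#: Default signal inventory: onset in {a, b} pairs only with rhyme in {c, d},
#: and onset in {p, q} only with rhyme in {r, s}.
DEFAULT_SIGNALS: tuple[str, ...] = ("ac", "bd", "ad", "bc", "pr", "ps", "qr", "qs")

CLASS_NAMES: tuple[str, ...] = ("degenerate", "holistic", "combinatorial", "other")
DEGENERATE, HOLISTIC, COMBINATORIAL, OTHER = range(4)


class ConfigurationError(ValueError):
    """Raised for invalid inventories, languages or simulation settings."""


@dataclass(frozen=True)
class SignalInventory:
    """An ordered set of distinct, equal-length signal tokens."""

    signals: tuple[str, ...] = DEFAULT_SIGNALS

    def __post_init__(self) -> None:
        signals = tuple(self.signals)
        object.__setattr__(self, "signals", signals)
        if len(signals) == 0:
            raise ConfigurationError("signal inventory must be non-empty")
        if len(set(signals)) != len(signals):
            raise ConfigurationError("signals must be distinct")
        lengths = {len(s) for s in signals}
        if len(lengths) != 1:
            raise ConfigurationError("all signals must have the same length")

    @property
    def n_signals(self) -> int:
        return len(self.signals)

    @property
    def signal_length(self) -> int:
        return len(self.signals[0])

    def index(self, token: str) -> int:
        try:
            return self.signals.index(token)
        except ValueError:
            raise ConfigurationError(f"unknown signal token {token!r}") from None


@dataclass(frozen=True)
class Language:
    """A total meaning→signal mapping: ``mapping[m]`` indexes into the inventory."""

    mapping: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mapping", tuple(int(i) for i in self.mapping))

    @classmethod
    def from_signals(cls, tokens: Iterable[str], inventory: SignalInventory) -> "Language":
        """Build a language from signal tokens, e.g. ``["ac", "bd", "pr", "qs"]``."""
        return cls(tuple(inventory.index(t) for t in tokens))

    def signals(self, inventory: SignalInventory) -> tuple[str, ...]:
        return tuple(inventory.signals[i] for i in self.mapping)

    def validate(self, inventory: SignalInventory) -> None:
        if not self.mapping:
            raise ConfigurationError("language must map at least one meaning")
        if any(i < 0 or i >= inventory.n_signals for i in self.mapping):
            raise ConfigurationError("mapping entry out of inventory range")

    @property
    def n_meanings(self) -> int:
        return len(self.mapping)


def classify(language: Language, inventory: SignalInventory) -> int:
    """Assign one of the four class labels to a language.

    Degenerate: a single distinct signal.  With all meanings carrying distinct
    signals the language is combinatorial when its signal set is exactly the
    Cartesian product of its per-position character sets (maximal reuse of
    meaningless elements without collapsing any meaning distinction), holistic
    otherwise.  Everything in between is "other".
    """
    language.validate(inventory)
    tokens = language.signals(inventory)
    distinct = set(tokens)
    if len(distinct) == 1:
        return DEGENERATE
    if len(distinct) < language.n_meanings:
        return OTHER
    position_sets = [set(t[pos] for t in distinct) for pos in range(inventory.signal_length)]
    full_product = {"".join(chars) for chars in itertools.product(*position_sets)}
    return COMBINATORIAL if full_product == distinct else HOLISTIC


def coding_length(language: Language, inventory: SignalInventory) -> float:
    """Coding length in bits, ``-sum_i log2 p(l_i)``.

    ``p(l_i)`` is the frequency of the i-th character within the language's own
    concatenated signal string (8 characters in the default space), so e.g. the
    degenerate ``ac ac ac ac`` costs 8 bits, a combinatorial language 16 bits
    and a holistic one 24 bits.
    """
    language.validate(inventory)
    chars = "".join(language.signals(inventory))
    counts = Counter(chars)
    total = len(chars)
    return -sum(math.log2(counts[c] / total) for c in chars)


def ambiguity(language: Language, signal: int) -> int:
    """Number of meanings the signal expresses in this language (0..n_meanings)."""
    return sum(1 for i in language.mapping if i == signal)


def compute_prior(coding_lengths: np.ndarray) -> np.ndarray:
    """Normalized simplicity prior ``P(l) = 2**-L(l) / Z``."""
    weights = np.exp2(-np.asarray(coding_lengths, dtype=float))
    return weights / weights.sum()


@dataclass
class LanguageSpace:
    """The fully enumerated hypothesis space with classes, lengths and prior.

    ``mapping_array`` has shape (n_languages, n_meanings); row ``i`` is the
    signal index per meaning of language ``i``.  Enumeration order is
    mixed-radix with the last meaning's signal index varying fastest, so
    language indices are stable across runs and platforms.
    """

    inventory: SignalInventory
    n_meanings: int
    mapping_array: np.ndarray
    classes: np.ndarray
    coding_lengths: np.ndarray
    prior: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_languages(self) -> int:
        return self.mapping_array.shape[0]

    def language(self, index: int) -> Language:
        return Language(tuple(self.mapping_array[index]))

    def index_of(self, language: Language) -> int:
        """Language index under the mixed-radix enumeration order."""
        language.validate(self.inventory)
        if language.n_meanings != self.n_meanings:
            raise ConfigurationError(
                f"language has {language.n_meanings} meanings, space expects {self.n_meanings}"
            )
        idx = 0
        for signal_index in language.mapping:
            idx = idx * self.inventory.n_signals + signal_index
        return idx

    @property
    def class_masks(self) -> np.ndarray:
        """(4, n_languages) boolean membership masks in CLASS_NAMES order."""
        if "class_masks" not in self._cache:
            self._cache["class_masks"] = np.stack(
                [self.classes == k for k in range(len(CLASS_NAMES))]
            )
        return self._cache["class_masks"]

    @property
    def ambiguity_matrix(self) -> np.ndarray:
        """(n_languages, n_signals) count of meanings each signal expresses."""
        if "ambiguity" not in self._cache:
            eye = np.arange(self.inventory.n_signals)
            self._cache["ambiguity"] = (
                (self.mapping_array[:, :, None] == eye[None, None, :]).sum(axis=1)
            )
        return self._cache["ambiguity"]

    def to_frame(self) -> pd.DataFrame:
        tokens = np.array(self.inventory.signals)
        per_meaning = [" ".join(row) for row in tokens[self.mapping_array]]
        return pd.DataFrame(
            {
                "language_id": np.arange(self.n_languages),
                "signal_per_meaning": per_meaning,
                "class": [CLASS_NAMES[k] for k in self.classes],
                "coding_length_bits": self.coding_lengths,
                "prior": self.prior,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def enumerate_languages(
    inventory: SignalInventory | None = None, n_meanings: int = 4
) -> LanguageSpace:
    """Enumerate, classify and weight every language in the space.

    Raises :class:`ConfigurationError` for an empty inventory or fewer than one
    meaning.  The default space has 4096 languages with class counts
    8 / 1632 / 48 / 2408 (degenerate / holistic / combinatorial / other).
    """
    inventory = inventory if inventory is not None else SignalInventory()
    if n_meanings < 1:
        raise ConfigurationError("n_meanings must be at least 1")
    mapping_array = np.array(
        list(itertools.product(range(inventory.n_signals), repeat=n_meanings)),
        dtype=np.int64,
    )
    classes = np.empty(len(mapping_array), dtype=np.int8)
    lengths = np.empty(len(mapping_array), dtype=float)
    for i, row in enumerate(mapping_array):
        lang = Language(tuple(row))
        classes[i] = classify(lang, inventory)
        lengths[i] = coding_length(lang, inventory)
    return LanguageSpace(
        inventory=inventory,
        n_meanings=n_meanings,
        mapping_array=mapping_array,
        classes=classes,
        coding_lengths=lengths,
        prior=compute_prior(lengths),
    )


def class_counts(space: LanguageSpace) -> dict[str, int]:
    """Number of languages per class, in CLASS_NAMES order."""
    return {
        name: int((space.classes == k).sum()) for k, name in enumerate(CLASS_NAMES)
    }
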