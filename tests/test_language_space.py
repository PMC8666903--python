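"""The enumerated hypothesis space: taxonomy, coding lengths, simplicity prior."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import iterlearn as il
from iterlearn.language_space import COMBINATORIAL, DEGENERATE, HOLISTIC, OTHER

from conftest import lang


def brute_force_class(tokens: tuple[str, ...]) -> str:
    """Independent classifier working directly on signal strings."""
    distinct = set(tokens)
    if len(distinct) == 1:
        return "degenerate"
    if len(distinct) < len(tokens):
        return "other"
    firsts = {t[0] for t in distinct}
    seconds = {t[1] for t in distinct}
    if len(firsts) == 2 and len(seconds) == 2:
        return "combinatorial"
    return "holistic"


def brute_force_bits(tokens: tuple[str, ...]) -> float:
    chars = "".join(tokens)
    counts = Counter(chars)
    return -sum(math.log2(counts[c] / len(chars)) for c in chars)


class TestEnumeration:
    def test_default_space_size(self, space):
        assert space.n_languages == 8**4 == 4096

    def test_small_spaces(self):
        tiny = il.enumerate_languages(il.SignalInventory(("ac",)), n_meanings=1)
        assert tiny.n_languages == 1
        assert tiny.classes[0] == DEGENERATE
        assert tiny.prior[0] == pytest.approx(1.0)

        two = il.enumerate_languages(il.SignalInventory(("ac", "bd")), n_meanings=2)
        assert two.n_languages == 4

    def test_enumeration_order_is_mixed_radix(self, space):
        # last meaning's signal index varies fastest
        assert tuple(space.mapping_array[0]) == (0, 0, 0, 0)
        assert tuple(space.mapping_array[1]) == (0, 0, 0, 1)
        assert tuple(space.mapping_array[8]) == (0, 0, 1, 0)
        lang_ = space.language(4095)
        assert tuple(lang_.mapping) == (7, 7, 7, 7)
        assert space.index_of(lang_) == 4095

    def test_invalid_configuration(self):
        with pytest.raises(il.ConfigurationError):
            il.enumerate_languages(n_meanings=0)
        with pytest.raises(il.ConfigurationError):
            il.SignalInventory(())
        with pytest.raises(il.ConfigurationError):
            il.SignalInventory(("ac", "ac"))
        with pytest.raises(il.ConfigurationError):
            il.SignalInventory(("ac", "bdd"))


class TestClassification:
    @pytest.mark.parametrize(
        "tokens, expected",
        [
            (("ac", "ac", "ac", "ac"), DEGENERATE),
            (("ac", "bd", "pr", "qs"), HOLISTIC),
            (("ac", "ad", "bc", "bd"), COMBINATORIAL),
            (("pr", "ps", "qr", "qs"), COMBINATORIAL),
            (("ac", "ac", "pr", "qs"), OTHER),
            (("ac", "bd", "ad", "bc"), COMBINATORIAL),
            (("ac", "ad", "bc", "pr"), HOLISTIC),
        ],
    )
    def test_worked_examples(self, inventory, tokens, expected):
        assert il.classify(lang(inventory, *tokens), inventory) == expected

    def test_class_counts_match_published_taxonomy(self, space):
        counts = il.class_counts(space)
        assert counts == {
            "degenerate": 8,
            "holistic": 1632,
            "combinatorial": 48,
            "other": 2408,
        }
        assert sum(counts.values()) == space.n_languages

    def test_agrees_with_string_level_brute_force(self, space):
        tokens_per_lang = [
            space.language(i).signals(space.inventory) for i in range(space.n_languages)
        ]
        expected = [brute_force_class(t) for t in tokens_per_lang]
        got = [il.CLASS_NAMES[k] for k in space.classes]
        assert got == expected


class TestCodingLength:
    @pytest.mark.parametrize(
        "tokens, bits",
        [
            (("ac", "ac", "ac", "ac"), 8.0),
            (("ac", "ad", "bc", "bd"), 16.0),
            (("ac", "bd", "pr", "qs"), 24.0),
            (("ac", "ac", "pr", "qs"), 20.0),
        ],
    )
    def test_worked_examples(self, inventory, tokens, bits):
        assert il.coding_length(lang(inventory, *tokens), inventory) == pytest.approx(bits)

    def test_class_level_values_over_whole_space(self, space):
        """Degenerate and combinatorial classes have constant bit cost (8 / 16).

        Holistic languages vary: those reusing characters across signals cost
        less than the canonical all-characters-distinct example (24 bits).
        The full distribution is checked against a string-level oracle.
        """
        for class_id, bits in [(DEGENERATE, 8.0), (COMBINATORIAL, 16.0)]:
            lengths = space.coding_lengths[space.classes == class_id]
            assert np.allclose(lengths, bits)
        expected = Counter()
        for combo in itertools.product(space.inventory.signals, repeat=4):
            if brute_force_class(combo) == "holistic":
                expected[round(brute_force_bits(combo), 9)] += 1
        got = Counter(
            round(float(b), 9) for b in space.coding_lengths[space.classes == HOLISTIC]
        )
        assert got == expected == {20.0: 1152, 22.0: 384, 24.0: 96}

    def test_matches_counter_oracle_on_sample(self, space):
        picked = np.random.default_rng(7).choice(space.n_languages, size=200, replace=False)
        for i in picked:
            tokens = space.language(int(i)).signals(space.inventory)
            assert space.coding_lengths[i] == pytest.approx(brute_force_bits(tokens))

    @given(perm=st.permutations(range(4)))
    def test_invariant_under_meaning_permutation(self, space, perm):
        base = il.Language((0, 1, 4, 6))
        permuted = il.Language(tuple(base.mapping[p] for p in perm))
        assert il.coding_length(base, space.inventory) == pytest.approx(
            il.coding_length(permuted, space.inventory)
        )

    @given(mapping=st.lists(st.integers(0, 7), min_size=4, max_size=4))
    def test_invariant_under_positionwise_character_relabelling(self, mapping):
        """Swapping character labels within a position cannot change the bit cost."""
        base_inv = il.SignalInventory()
        swapped = tuple(
            t.translate(str.maketrans("abcd", "badc")) for t in base_inv.signals
        )
        swapped_inv = il.SignalInventory(swapped)
        l = il.Language(tuple(mapping))
        assert il.coding_length(l, base_inv) == pytest.approx(
            il.coding_length(l, swapped_inv)
        )


class TestPrior:
    def test_normalization(self, space):
        assert abs(space.prior.sum() - 1.0) < 1e-12
        assert (space.prior >= 0).all()

    def test_closed_form_class_ratios(self, space, inventory):
        degenerate = space.prior[space.index_of(lang(inventory, *["ac"] * 4))]
        holistic = space.prior[space.index_of(lang(inventory, "ac", "bd", "pr", "qs"))]
        combinatorial = space.prior[space.index_of(lang(inventory, "ac", "ad", "bc", "bd"))]
        assert degenerate / holistic == pytest.approx(2**16)
        assert degenerate / combinatorial == pytest.approx(2**8)

    def test_prior_matches_independent_enumeration(self, inventory):
        """Full brute-force 2**-L normalization over itertools enumeration."""
        weights = []
        for combo in itertools.product(inventory.signals, repeat=4):
            weights.append(2.0 ** -brute_force_bits(combo))
        z = sum(weights)
        space = il.enumerate_languages()
        assert np.allclose(space.prior, np.array(weights) / z, atol=1e-15)


class TestAmbiguity:
    @pytest.mark.parametrize(
        "tokens, signal, expected",
        [
            (("ac", "ac", "ac", "ac"), "ac", 4),
            (("ac", "bd", "pr", "qs"), "pr", 1),
            (("ac", "ac", "pr", "qs"), "ac", 2),
            (("ac", "ac", "pr", "qs"), "bd", 0),
        ],
    )
    def test_counts_meanings_per_signal(self, inventory, tokens, signal, expected):
        l = lang(inventory, *tokens)
        assert il.ambiguity(l, inventory.index(signal)) == expected

    def test_matrix_rows_sum_to_n_meanings(self, space):
        assert (space.ambiguity_matrix.sum(axis=1) == space.n_meanings).all()


def test_space_csv_export_round_trips(space, tmp_path):
    import pandas as pd

    path = tmp_path / "space.csv"
    space.to_csv(path)
    frame = pd.read_csv(path)
    assert list(frame.columns) == [
        "language_id",
        "signal_per_meaning",
        "class",
        "coding_length_bits",
        "prior",
    ]
    assert len(frame) == 4096
    assert frame["class"].value_counts()["combinatorial"] == 48
    assert frame.loc[0, "signal_per_meaning"] == "ac ac ac ac"
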