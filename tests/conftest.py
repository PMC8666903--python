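import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import iterlearn as il

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def space() -> il.LanguageSpace:
    """The default enumerated space: 8 signals x 4 meanings = 4096 languages."""
    return il.enumerate_languages()


@pytest.fixture(scope="session")
def inventory(space) -> il.SignalInventory:
    return space.inventory


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def lang(inventory, *tokens) -> il.Language:
    return il.Language.from_signals(tokens, inventory)
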