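import random

import pytest
from hypothesis import settings

from spiralfold.conformation import Conformation, HPSequence, initialise_saw
from spiralfold.search import RunConfig, initial_state

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture
def worked_square():
    """The worked 4-mer: H4 on a unit rhombus with one non-consecutive
    H-H contact (residues 0 and 3)."""
    return Conformation(
        HPSequence("HHHH"),
        [(0, 0, 0), (1, 1, 0), (2, 0, 0), (1, -1, 0)],
    )


def random_conformation(residues: str, seed: int) -> Conformation:
    return initialise_saw(HPSequence(residues), random.Random(seed))


def make_state(sequence, seed=0, **config_kwargs):
    """A fresh SearchState for unit tests of the selection operators."""
    config_kwargs.setdefault("max_iterations", 1000)
    return initial_state(sequence, RunConfig(seed=seed, **config_kwargs))


@pytest.fixture
def state_factory():
    return make_state
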