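import logging

import numpy as np
import pytest

from gmadapt import synth

logging.getLogger("gmadapt").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study shared by read-only tests."""
    return synth.simulate_study(synth.SynthConfig(seed=7))


@pytest.fixture
def small_tree(rng):
    return synth.generate_tree(["a", "b", "c", "d", "e"], seed=11)
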