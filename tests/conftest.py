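import numpy as np
import pytest

from gqpull.synth import StemBlueprint, build_ideal_stem


@pytest.fixture(scope="session")
def ideal_4q():
    """Default four-quartet ideal stem (trajectory, topology)."""
    return build_ideal_stem(StemBlueprint())


@pytest.fixture(scope="session")
def ideal_3q():
    return build_ideal_stem(StemBlueprint(n_quartets=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


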