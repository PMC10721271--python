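import numpy as np
import pytest

from myorod import cc_builder as cb
from myorod import synthetic_data as sd


@pytest.fixture(scope="session")
def canonical_params():
    return cb.CrickParameters()


@pytest.fixture(scope="session")
def canonical_pattern():
    return cb.make_pattern(91)


@pytest.fixture(scope="session")
def canonical_model(canonical_params, canonical_pattern):
    return cb.build(canonical_params, canonical_pattern)


@pytest.fixture(scope="session")
def ideal_traj(canonical_params, canonical_pattern):
    """Single-frame trajectory of the exact canonical build."""
    return sd.make_ideal_trajectory(canonical_params, canonical_pattern, 1, 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
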