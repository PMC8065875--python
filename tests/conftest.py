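"""Shared fixtures: small phantoms and protocols sized for fast tests."""

import numpy as np
import pytest

from bbbsim.config import demo_protocol, load_fixtures, make_aif
from bbbsim.phantom import PhantomSpec, build_synthetic_head

SMALL_SHAPE = (48, 48, 48)
SMALL_SPACING = (2.0, 2.0, 2.0)


@pytest.fixture(scope="session")
def table():
    _, t = load_fixtures()
    return t


@pytest.fixture(scope="session")
def small_labels():
    return build_synthetic_head(
        PhantomSpec(shape=SMALL_SHAPE, spacing=SMALL_SPACING), seed=1
    )


@pytest.fixture(scope="session")
def small_proto():
    return demo_protocol(SMALL_SHAPE, SMALL_SPACING, acquired_matrix=(24, 20, 12))


@pytest.fixture(scope="session")
def small_aif(small_proto):
    return make_aif(small_proto)


@pytest.fixture(scope="session")
def reference_proto():
    proto, _ = load_fixtures()
    return proto


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
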