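import numpy as np
import pytest

from crypticscreen.pocket_detection import PocketDetectionParams
from crypticscreen.synthetic import CavitySpec, make_cavity_structure


@pytest.fixture(scope="session")
def default_params() -> PocketDetectionParams:
    return PocketDetectionParams()


@pytest.fixture(scope="session")
def cavity_fixture(default_params):
    """A closed hollow shell and its brute-force cavity oracle (shared: slow-ish)."""
    return make_cavity_structure(CavitySpec(), default_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
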