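import numpy as np
import pytest

from kiwipol import Scenario, integrate


@pytest.fixture(scope="session")
def baseline():
    return Scenario()


@pytest.fixture(scope="session")
def baseline_result(baseline):
    """One full baseline run, shared across the suite (deterministic)."""
    return integrate(baseline)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
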