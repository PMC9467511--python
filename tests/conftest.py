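import numpy as np
import pytest

from sprint.fixtures import (detection_fixture, noiseless_model_spectrum,
                             short_transient_trial)


@pytest.fixture(scope="session")
def short_trial():
    """10 s transient-alpha miniature trial (deterministic seed)."""
    return short_transient_trial(seed=0)


@pytest.fixture()
def noiseless_spectrum():
    """Exact model spectrum with known parameters."""
    return noiseless_model_spectrum(seed=3)


@pytest.fixture()
def detection_table():
    return detection_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
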