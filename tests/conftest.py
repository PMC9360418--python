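import warnings

import numpy as np
import pytest

from n1dev import montage as mt

# statsmodels emits convergence chatter for boundary variance estimates on
# small synthetic fixtures; keep the test output readable
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def montage124():
    return mt.make_montage(124, seed=0)


@pytest.fixture(scope="session")
def montage20():
    return mt.make_montage(20, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pair_montage():
    """Minimal two-channel montage for filter unit tests."""
    return mt.Montage(
        channels=["A", "B"],
        positions=np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]]),
    )
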