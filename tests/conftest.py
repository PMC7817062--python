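import numpy as np
import pytest

from dynswitch import STANDARD_PARAMS, event_thresholds, midpoint_Xc, switch_folds_exact


@pytest.fixture(scope="session")
def params():
    """Standard feedback constants with the reference basal rate a = 0.3."""
    return STANDARD_PARAMS


@pytest.fixture(scope="session")
def thresholds(params):
    """(up, down, transition) event levels of the static switch at a = 0.3."""
    return event_thresholds(params, 0.3)


@pytest.fixture(scope="session")
def X_c(params):
    return midpoint_Xc(params, 0.3)


@pytest.fixture(scope="session")
def static_folds(params):
    """The two saddle nodes of the static switch at a = 0.3 (X_T, X)."""
    return switch_folds_exact(params, 0.3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20211)
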