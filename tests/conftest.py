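import warnings

import numpy as np
import pytest

from dmnec import default_partition


@pytest.fixture(scope="session")
def partition():
    return default_partition()


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="statsmodels")
        warnings.filterwarnings("ignore", category=RuntimeWarning,
                                module="statsmodels")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
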