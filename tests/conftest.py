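import numpy as np
import pytest

from vascade.containers import SystemPartition
from vascade.datasets import load_study_correlations
from vascade.synthetic import default_partition


@pytest.fixture(scope="session")
def study_R():
    """Published 12-variable correlation matrix of the 46-subject cohort."""
    return load_study_correlations()


@pytest.fixture(scope="session")
def small_partition() -> SystemPartition:
    """11 canonical networks, 3 ROIs each."""
    return default_partition(n_per_network=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
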