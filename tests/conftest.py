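import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def all_bit_vectors(L: int) -> np.ndarray:
    """Every vector of {0,1}^L as an (2^L, L) array, lexicographic order."""
    return np.array(list(itertools.product([0, 1], repeat=L)), dtype=np.int64)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def toy_dataset():
    from aaparzen import LabeledDataset

    patterns = np.array(
        [[1, 0, 1, 0], [1, 1, 1, 0], [1, 0, 0, 0], [0, 0, 1, 1], [0, 1, 1, 1]]
    )
    return LabeledDataset(patterns, ["A", "A", "A", "B", "B"])
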