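import numpy as np
import pytest

from bnscore import DagStructure, Dataset, forward_sample, random_cpts
from bnscore.rng import NumpyUniform


@pytest.fixture
def chain3() -> DagStructure:
    """X1 -> X2 -> X3."""
    return DagStructure(3, frozenset({(0, 1), (1, 2)}))


@pytest.fixture
def gold4() -> DagStructure:
    """A fixed connected 4-node structure used across scoring tests."""
    return DagStructure(4, frozenset({(0, 1), (1, 2), (0, 3)}))


@pytest.fixture
def bn4(gold4):
    """Random-CPT binary network on gold4, fixed seed."""
    return random_cpts(gold4, (2, 2, 2, 2), NumpyUniform(123))


@pytest.fixture
def data4(bn4) -> Dataset:
    """1000 forward-sampled cases from bn4, fixed seed."""
    return forward_sample(bn4, 1000, NumpyUniform(456))


def random_binary_dataset(seed: int, n_cases: int, n_vars: int) -> Dataset:
    rng = np.random.default_rng(seed)
    return Dataset(values=rng.integers(0, 2, size=(n_cases, n_vars)), arities=(2,) * n_vars)
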