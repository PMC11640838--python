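import numpy as np
import pytest

from epifinger import DEFAULT_SCHEME, make_layout


@pytest.fixture(scope="session")
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture(scope="session")
def small_layout():
    """18 peptides + 2 water groups as quadruples in two blocks."""
    ids = [f"pep_{i:03d}" for i in range(18)]
    return make_layout(ids)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
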