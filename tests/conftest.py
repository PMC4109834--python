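import numpy as np
import pytest

from figcat import fixtures


@pytest.fixture(scope="session")
def table_figure():
    return fixtures.generate_figure("table", seed=1, width=256, height=256)


@pytest.fixture(scope="session")
def multipanel_figure():
    return fixtures.generate_figure("multipanel", seed=7, width=300, height=200)


@pytest.fixture(scope="session")
def leaf_dataset_small():
    """2 figures per leaf class, deterministic."""
    return fixtures.generate_dataset(2, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
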