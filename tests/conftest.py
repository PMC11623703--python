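import numpy as np
import pytest

from molflows.synthetic_data import ToyConfig, fixtures, generate_toy_dataset


@pytest.fixture(scope="session")
def fixture_mols():
    return fixtures()


@pytest.fixture(scope="session")
def toy_cfg():
    return ToyConfig()


@pytest.fixture(scope="session")
def small_dataset(toy_cfg):
    """Small toy training set shared by denoiser tests."""
    return generate_toy_dataset(toy_cfg, 60, rng=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240925)
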