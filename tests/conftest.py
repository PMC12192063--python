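import numpy as np
import pytest

from segdistill.data import PhantomConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_config():
    return PhantomConfig.desk(64)


@pytest.fixture(scope="session")
def small_phantoms(desk_config):
    """Twelve 64x64 phantoms shared across tests (read-only)."""
    return generate_dataset(12, desk_config, base_seed=42)


@pytest.fixture(scope="session")
def tiny_phantoms():
    """32x32 phantoms for the fastest training smoke tests."""
    return generate_dataset(12, PhantomConfig.desk(32), base_seed=7)
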