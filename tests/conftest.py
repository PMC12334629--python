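import numpy as np
import pytest

from bcdnet.phantom import PhantomSpec, generate_dataset


@pytest.fixture(scope="session")
def small_phantoms():
    """20 default 64x64 phantoms (10 per class), shared across tests."""
    return generate_dataset(PhantomSpec(seed=42), 10)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
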