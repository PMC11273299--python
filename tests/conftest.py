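import numpy as np
import pytest

from cocoonsex.fasthog import HOGParams
from cocoonsex.synthgen import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def default_params() -> HOGParams:
    return HOGParams()


@pytest.fixture(scope="session")
def small_dataset():
    """A small seeded synthetic cocoon dataset shared across tests."""
    spec = SyntheticSpec(n_male=60, n_female=55, seed=11)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def random_canonical_images():
    """Seeded stack of random canonical 128x64 grayscale images."""
    rng = np.random.default_rng(42)
    return rng.uniform(0.0, 255.0, size=(50, 128, 64))
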