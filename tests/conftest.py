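import numpy as np
import pytest

from acam.phantoms import PhantomSpec, generate_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def worked_image():
    """The hand-evaluated 2x2 pattern tiled to a legal 8x8 image."""
    return np.tile(np.array([[0.0, 100.0], [100.0, 200.0]]), (4, 4))


@pytest.fixture
def random_image(rng):
    return rng.random((16, 16))


@pytest.fixture(scope="session")
def tiny_dataset():
    """120-sample in-memory phantom dataset shared across tests."""
    spec = PhantomSpec(n_samples=120, image_size=64, seed=7)
    clean, degraded, manifest = generate_arrays(spec)
    return spec, clean, degraded, manifest
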