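import numpy as np
import pytest

from comodseg.phantoms import PhantomSpec, generate_phantom
from comodseg.volume_io import map_labels, normalize_study


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom32():
    """One 32^3 phantom (study, labels) shared read-only across tests."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def tiny_spec():
    """16^3 spec for fast training smoke tests."""
    return PhantomSpec(grid_shape=(16, 16, 16), brain_axes=(7.0, 6.5, 6.0),
                       tumor_center_jitter=1.0, wt_radius=4.5, tc_radius=3.0,
                       et_radius=1.8, radius_jitter=0.05)


@pytest.fixture(scope="session")
def normalized32(phantom32):
    study, labels = phantom32
    return normalize_study(study), map_labels(labels)
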