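import numpy as np
import pytest

from wallwaxs import synthetic
from wallwaxs.microfibril import build_fibril


@pytest.fixture(scope="session")
def hydrated_spec():
    spec = synthetic.preset("hydrated")
    spec.exposure = 0.0
    return spec


@pytest.fixture(scope="session")
def dried_spec():
    spec = synthetic.preset("dried")
    spec.exposure = 0.0
    return spec


@pytest.fixture(scope="session")
def geometry():
    return synthetic.GeometryConfig()


@pytest.fixture(scope="session")
def hydrated_image(hydrated_spec, geometry):
    """Noiseless hydrated q-space render shared across reduction tests."""
    return synthetic.render_qspace_image(hydrated_spec, geometry)


@pytest.fixture(scope="session")
def toy_fibril():
    """Small 6-chain fibril (two layers of three) for Debye cross-checks."""
    return build_fibril("33", 1)
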