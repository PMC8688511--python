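import numpy as np
import pytest

from cervkin import SurfaceIndex, VertebraSpec, generate_vertebra, remesh


@pytest.fixture(scope="session")
def c5_mesh():
    """Moderate-resolution synthetic C5 vertebra shared across tests."""
    return generate_vertebra(VertebraSpec.for_level("C5", pitch=1.2))


@pytest.fixture(scope="session")
def c5_remeshed(c5_mesh):
    """Independently tessellated copy of the C5 fixture (no shared vertices)."""
    return remesh(c5_mesh, seed=11)


@pytest.fixture(scope="session")
def c5_index(c5_mesh):
    return SurfaceIndex(c5_mesh)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
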