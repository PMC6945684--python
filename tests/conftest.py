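import numpy as np
import pytest

from ecgitv.phantom import (
    build_heart_mesh,
    build_lead_field,
    default_lead_positions,
)


@pytest.fixture(scope="session")
def small_mesh():
    return build_heart_mesh(n_nodes=120, shell_radii=(25.0, 50.0), seed=1)


@pytest.fixture(scope="session")
def small_lead_field(small_mesh):
    return build_lead_field(small_mesh, default_lead_positions(32, 150.0))


@pytest.fixture(scope="session")
def default_mesh():
    """The default desk-scale phantom geometry (n=800, seed 1)."""
    return build_heart_mesh(n_nodes=800, shell_radii=(25.0, 50.0), seed=1)


@pytest.fixture(scope="session")
def default_lead_field(default_mesh):
    return build_lead_field(default_mesh, default_lead_positions(64, 150.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
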