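import numpy as np
import pytest

from eitsim import (
    build_disk_mesh,
    make_fixture,
    realize_phantom,
    select_electrodes,
)

RADIUS = 0.075  # m
SIGMA_B = 0.21  # S/m
AMPLITUDE = 1e-3  # A


@pytest.fixture(scope="session")
def mesh_m8():
    return build_disk_mesh(RADIUS, 8)


@pytest.fixture(scope="session")
def mesh_m16():
    return build_disk_mesh(RADIUS, 16)


@pytest.fixture(scope="session")
def electrodes_m8(mesh_m8):
    return select_electrodes(mesh_m8)


@pytest.fixture(scope="session")
def electrodes_m16(mesh_m16):
    return select_electrodes(mesh_m16)


@pytest.fixture(scope="session")
def offcentre_spec():
    """Single off-centre anomaly: r=37.5 mm, theta=45 deg, ri=25 mm."""
    return make_fixture("fig4")


@pytest.fixture(scope="session")
def offcentre_sigma_m8(offcentre_spec, mesh_m8):
    return realize_phantom(offcentre_spec, mesh_m8).sigma


@pytest.fixture(scope="session")
def uniform_sigma_m8(mesh_m8):
    return np.full(mesh_m8.n_elements, SIGMA_B)
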