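import numpy as np
import pytest

from suvphase.geometry import SurfaceOperators, build_sphere_mesh


@pytest.fixture(scope="session")
def unit_mesh_l2():
    return build_sphere_mesh(2, radius=1.0)


@pytest.fixture(scope="session")
def unit_mesh_l3():
    return build_sphere_mesh(3, radius=1.0)


@pytest.fixture(scope="session")
def unit_mesh_l4():
    return build_sphere_mesh(4, radius=1.0)


@pytest.fixture(scope="session")
def ops_l3(unit_mesh_l3):
    return SurfaceOperators(unit_mesh_l3)


@pytest.fixture(scope="session")
def ops_l4(unit_mesh_l4):
    return SurfaceOperators(unit_mesh_l4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def real_sph_harm(l, m, vertices):
    """Real spherical harmonic sampled at unit-sphere vertices."""
    from scipy.special import sph_harm_y

    theta = np.arccos(np.clip(vertices[:, 2], -1.0, 1.0))
    phi = np.arctan2(vertices[:, 1], vertices[:, 0])
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * y.real
    if m < 0:
        return np.sqrt(2.0) * y.imag
    return y.real
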