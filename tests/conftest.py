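import numpy as np
import pytest

from mmpinv.unitcell import BoxDomainSpec, build_box_mesh


@pytest.fixture(scope="session")
def unit_square_mesh():
    """Crossed triangulation of [0, 1]^2, h = 1/8."""
    return build_box_mesh(BoxDomainSpec(2, (0.0, 0.0), (1.0, 1.0), 1 / 8))


@pytest.fixture(scope="session")
def unit_cube_mesh():
    """Kuhn tetrahedralization of [0, 1]^3, h = 1/4."""
    return build_box_mesh(BoxDomainSpec(3, (0.0,) * 3, (1.0,) * 3, 1 / 4))


@pytest.fixture(scope="session")
def reference_triangle():
    from mmpinv.mesh import SimplicialMesh
    return SimplicialMesh(2, np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
                          np.array([[0, 1, 2]]))


def rng(seed=0):
    return np.random.default_rng(seed)
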