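import numpy as np
import pytest

from occlustress.synthetic import ArchParameters, generate_synthetic_dentition


@pytest.fixture(scope="session")
def interference_model():
    """Dentition with the planted balancing-side interference on FDI 47."""
    return generate_synthetic_dentition(
        ArchParameters(interference=(47, 0.5)), seed=1
    )


@pytest.fixture(scope="session")
def symmetric_model():
    """Mirror-symmetric dentition (no interference)."""
    return generate_synthetic_dentition(ArchParameters(), seed=3)


@pytest.fixture()
def simple_quad_mesh():
    from occlustress.mesh import SurfaceMesh

    verts = np.array(
        [[0.0, 0, 0], [1.0, 0, 0], [1.0, 0, 1.0], [0.0, 0, 1.0], [2.0, 0, 0.5]]
    )
    faces = np.array([[0, 1, 2, 3], [1, 4, 2, -1]])
    return SurfaceMesh(verts, faces)
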