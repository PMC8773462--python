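import numpy as np
import pytest

from campfem.generate import generate_cell_like_mesh, generate_sphere_shell_mesh
from campfem.mesh import TetMesh

R_O = 9.34
R_I = 5.26
SHELL_VOLUME = 4.0 / 3.0 * np.pi * (R_O**3 - R_I**3)

# reference signaling parameters (μM, μM/s)
E_AC = 0.1412
V_MAX = 0.295
K_M = 2.0
C_O = 0.05

REFERENCE_TET = np.array(
    [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
)

REGULAR_TET = np.array(
    [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
)


@pytest.fixture(scope="session")
def sphere_mesh() -> TetMesh:
    """Concentric-sphere cell mesh at the working resolution."""
    return generate_sphere_shell_mesh(R_O, R_I, target_edge_length=2.4, seed=1)


@pytest.fixture(scope="session")
def coarse_sphere_mesh() -> TetMesh:
    return generate_sphere_shell_mesh(R_O, R_I, target_edge_length=3.2, seed=1)


@pytest.fixture(scope="session")
def blob_mesh() -> TetMesh:
    """Synthetic cell-like geometry (flattened body with nuclear cavity)."""
    return generate_cell_like_mesh(seed=2, target_edge_length=2.2)


@pytest.fixture()
def two_tet_mesh() -> TetMesh:
    """Two tetrahedra sharing the face (0, 1, 2)."""
    nodes = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
            [0.4, 0.4, -1.0],
        ]
    )
    elements = np.array([[0, 1, 2, 3], [0, 2, 1, 4]])
    mesh = TetMesh(nodes, elements).orient()
    refs, _ = mesh.boundary_faces()
    mesh.boundary_face_sets = {"plasma_membrane": refs}
    return mesh
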