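"""P1 (four-node tetrahedral) finite element matrices and global assembly.

For each element with vertices x_1..x_4 and volume V the Galerkin matrices
are exact for linear shape functions:

* consistent mass  [K1] = (V/20) * (ones + I)
* stiffness        [K2] = V * D * B^T B, with B the constant 3x4 gradient
  operator of the P1 interpolant
* reaction         [K3] = a * [K1]  (quasi-linearized degradation, a in 1/s)
* boundary flux    {R1} = beta * A/3 on the three nodes of the loaded face
* volumetric load  {R2} = V * rate / 4 on every node

Positive flux ``beta`` (μM·μm/s) is an influx into the domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .mesh import (
    FACE_LOCAL_NODES,
    DegenerateElementError,
    MeshError,
    TetMesh,
    face_area,
    tet_volume,
)

__all__ = [
    "ElementMatrices",
    "AssembledSystem",
    "DirichletReduction",
    "element_mass_matrix",
    "element_gradient_matrix",
    "element_stiffness_matrix",
    "face_flux_vector",
    "element_source_vector",
    "element_matrices",
    "assemble_global",
    "apply_dirichlet",
    "export_matrix_market",
]

_GRAD_REF = np.array(
    [[-1.0, 1.0, 0.0, 0.0], [-1.0, 0.0, 1.0, 0.0], [-1.0, 0.0, 0.0, 1.0]]
)
_MASS_PATTERN = (np.ones((4, 4)) + np.eye(4)) / 20.0


def element_mass_matrix(coords: np.ndarray) -> np.ndarray:
    """Consistent 4x4 mass matrix (V/20)(ones + I) of one tetrahedron."""
    return tet_volume(coords) * _MASS_PATTERN


def element_gradient_matrix(coords: np.ndarray) -> np.ndarray:
    """Constant 3x4 gradient operator B of the P1 interpolant."""
    coords = np.asarray(coords, dtype=float)
    tet_volume(coords)  # degeneracy check
    edges = coords[1:] - coords[0]
    return np.linalg.solve(edges, _GRAD_REF)


def element_stiffness_matrix(coords: np.ndarray, D: float) -> np.ndarray:
    """4x4 diffusion stiffness V * D * B^T B (isotropic diffusivity D)."""
    if D < 0:
        raise ValueError(f"diffusion coefficient must be non-negative, got {D}")
    B = element_gradient_matrix(coords)
    return tet_volume(coords) * D * (B.T @ B)


def face_flux_vector(face_coords: np.ndarray, beta: float, local_face: int) -> np.ndarray:
    """Element load 4-vector for a prescribed flux ``beta`` on one face.

    ``beta * A / 3`` is placed on the three nodes of face ``local_face``
    (see :data:`campfem.mesh.FACE_LOCAL_NODES`), zero on the opposite node.
    """
    if local_face not in (0, 1, 2, 3):
        raise MeshError(f"local face id must be 0..3, got {local_face}")
    area = face_area(face_coords)
    vec = np.zeros(4)
    vec[list(FACE_LOCAL_NODES[local_face])] = beta * area / 3.0
    return vec


def element_source_vector(volume: float, rate: float) -> np.ndarray:
    """Element load 4-vector for a uniform volumetric rate (μM/s): V*rate/4 each."""
    if volume <= 0:
        raise ValueError(f"element volume must be positive, got {volume}")
    return np.full(4, volume * rate / 4.0)


@dataclass
class ElementMatrices:
    """Mass, stiffness and gradient operators of one tetrahedral element."""

    mass: np.ndarray
    stiffness: np.ndarray
    gradient: np.ndarray
    volume: float


def element_matrices(coords: np.ndarray, D: float) -> ElementMatrices:
    V = tet_volume(coords)
    B = element_gradient_matrix(coords)
    return ElementMatrices(
        mass=V * _MASS_PATTERN,
        stiffness=V * D * (B.T @ B),
        gradient=B,
        volume=V,
    )


@dataclass
class AssembledSystem:
    """Globally assembled sparse operators for one mesh + parameter set.

    ``K1`` (mass) and ``K2`` (stiffness) are constant; the reaction matrix
    ``K3`` depends on the quasi-linearization state and is rebuilt per inner
    iteration via :meth:`reaction_matrix`.  ``R1`` is the boundary-flux load,
    ``R2`` the volumetric-source load (synthesis only; the linearized source
    that replaces it during degradation comes from :meth:`linearized_source`).
    """

    mesh: TetMesh
    K1: sp.csr_matrix
    K2: sp.csr_matrix
    R1: np.ndarray
    R2: np.ndarray
    element_volumes: np.ndarray
    element_rates: np.ndarray  # volumetric synthesis rate per element (μM/s)
    _rows: np.ndarray = field(repr=False, default=None)
    _cols: np.ndarray = field(repr=False, default=None)
    _mass_data: np.ndarray = field(repr=False, default=None)  # (M, 16)

    @property
    def n_nodes(self) -> int:
        return self.mesh.n_nodes

    def reaction_matrix(self, a_elem: np.ndarray) -> sp.csr_matrix:
        """Assemble [K3] = sum_e a_e * [K1_e] for per-element coefficients a_e (1/s)."""
        data = (np.asarray(a_elem)[:, None] * self._mass_data).ravel()
        n = self.n_nodes
        return sp.coo_matrix((data, (self._rows, self._cols)), shape=(n, n)).tocsr()

    def linearized_source(self, b_elem: np.ndarray) -> np.ndarray:
        """Assemble {R2b}: V_e * b_e / 4 on each node of each element."""
        vec = np.zeros(self.n_nodes)
        contrib = (self.element_volumes * np.asarray(b_elem) / 4.0)[:, None]
        np.add.at(vec, self.mesh.elements, contrib)
        return vec

    def element_means(self, nodal: np.ndarray) -> np.ndarray:
        """Mean of the four nodal values per element."""
        return nodal[self.mesh.elements].mean(axis=1)


def assemble_global(
    mesh: TetMesh,
    D: float,
    face_flux_map: dict[str, float] | None = None,
    volumetric_rate_map: dict[str, float] | None = None,
) -> AssembledSystem:
    """Assemble global mass/stiffness matrices and load vectors.

    Parameters
    ----------
    mesh : the tetrahedral mesh (positively oriented).
    D : diffusion coefficient, μm²/s.
    face_flux_map : boundary-set label → flux β (μM·μm/s, positive = influx).
    volumetric_rate_map : region label → uniform synthesis rate (μM/s).
    """
    face_flux_map = dict(face_flux_map or {})
    volumetric_rate_map = dict(volumetric_rate_map or {})
    for label in face_flux_map:
        if label not in mesh.boundary_face_sets:
            raise MeshError(f"flux label {label!r} not among mesh boundary sets")
    regions = set(np.asarray(mesh.region_tags))
    for label in volumetric_rate_map:
        if label not in regions:
            raise MeshError(f"region label {label!r} not among mesh region tags")

    coords = mesh.element_coords()
    edges = coords[:, 1:, :] - coords[:, :1, :]
    vol = np.linalg.det(edges) / 6.0
    if (vol <= 0).any():
        raise MeshError("mesh has non-positive elements; call orient() first")
    span = mesh.nodes.max(axis=0) - mesh.nodes.min(axis=0)
    if (vol <= 1e-12 * float(np.linalg.norm(span)) ** 3).any():
        raise DegenerateElementError("degenerate element encountered in assembly")

    m, n = mesh.n_elements, mesh.n_nodes
    B = np.linalg.solve(edges, np.broadcast_to(_GRAD_REF, (m, 3, 4)).copy())
    ke = D * vol[:, None, None] * np.einsum("mki,mkj->mij", B, B)
    me = vol[:, None, None] * _MASS_PATTERN[None, :, :]

    rows = np.repeat(mesh.elements, 4, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, 4)).ravel()
    K1 = sp.coo_matrix((me.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    K2 = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    R1 = np.zeros(n)
    for label, beta in face_flux_map.items():
        if beta == 0.0:
            continue
        for e, f in mesh.boundary_face_sets[label]:
            idx = mesh.face_node_indices(e, f)
            R1[idx] += beta * face_area(mesh.nodes[idx]) / 3.0

    rates = np.zeros(m)
    tags = np.asarray(mesh.region_tags)
    for label, rate in volumetric_rate_map.items():
        rates[tags == label] = rate
    R2 = np.zeros(n)
    np.add.at(R2, mesh.elements, (vol * rates / 4.0)[:, None])

    return AssembledSystem(
        mesh=mesh,
        K1=K1,
        K2=K2,
        R1=R1,
        R2=R2,
        element_volumes=vol,
        element_rates=rates,
        _rows=rows,
        _cols=cols,
        _mass_data=me.reshape(m, 16),
    )


@dataclass
class DirichletReduction:
    """Bookkeeping to eliminate prescribed nodes and re-embed solutions."""

    free: np.ndarray
    prescribed: np.ndarray
    values: np.ndarray
    n_total: int

    def expand(self, reduced: np.ndarray) -> np.ndarray:
        full = np.empty(self.n_total)
        full[self.free] = reduced
        full[self.prescribed] = self.values
        return full


def apply_dirichlet(
    matrix: sp.spmatrix,
    rhs: np.ndarray,
    nodes: np.ndarray,
    values: np.ndarray,
) -> tuple[sp.csr_matrix, np.ndarray, DirichletReduction]:
    """Symmetric row/column elimination of prescribed nodal values.

    Known values are moved to the right-hand side; the reduced system keeps
    the symmetry of the input.  Conflicting prescriptions on one node raise.
    """
    n = matrix.shape[0]
    nodes = np.asarray(nodes, dtype=np.int64).ravel()
    values = np.asarray(values, dtype=float).ravel()
    if nodes.size != values.size:
        raise ValueError("nodes and values must have the same length")
    uniq, first = np.unique(nodes, return_index=True)
    if uniq.size != nodes.size:
        for u in uniq:
            vals = values[nodes == u]
            if not np.allclose(vals, vals[0]):
                raise ValueError(f"conflicting Dirichlet prescriptions on node {u}")
        nodes, values = uniq, values[first]
    free = np.setdiff1d(np.arange(n), nodes, assume_unique=False)
    A = matrix.tocsr()
    A_ff = A[np.ix_(free, free)].tocsr()
    rhs_f = np.asarray(rhs)[free] - A[np.ix_(free, nodes)] @ values
    return A_ff, rhs_f, DirichletReduction(free, nodes, values, n)


def export_matrix_market(matrix: sp.spmatrix, path) -> None:
    """Write a sparse operator to MatrixMarket format (debug aid)."""
    from scipy.io import mmwrite

    mmwrite(str(path), matrix)
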