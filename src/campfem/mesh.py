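"""Tetrahedral meshes of cellular geometries.

A cell is discretized into four-node (P1) tetrahedra.  The mesh carries two
named boundary surface sets — ``"plasma_membrane"`` (outer surface, where
adenylyl-cyclase activity can be imposed as a flux) and ``"perinuclear"``
(surface of the excluded nuclear cavity) — and a region tag per element
(``"cytosol"`` by default).  All coordinates are in μm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


class MeshError(Exception):
    """Base class for mesh construction and validation failures."""


class DegenerateElementError(MeshError):
    """A tetrahedron (or triangle) with vanishing measure."""


# Local faces of a four-node tetrahedron, ordered so that face k is opposite
# local node OPPOSITE_NODE[k]:  (1-2-3, 2-3-4, 3-4-1, 4-1-2 in 1-based terms).
FACE_LOCAL_NODES = ((0, 1, 2), (1, 2, 3), (2, 3, 0), (3, 0, 1))
OPPOSITE_NODE = (3, 0, 1, 2)

PLASMA_MEMBRANE = "plasma_membrane"
PERINUCLEAR = "perinuclear"

#: Solid angle subtended at a vertex of the regular tetrahedron, in sr.
REGULAR_TET_SOLID_ANGLE = float(np.arccos(23.0 / 27.0))


def tet_signed_volume(coords: np.ndarray) -> float:
    """Signed volume det([x2-x1; x3-x1; x4-x1]) / 6 of a tetrahedron."""
    coords = np.asarray(coords, dtype=float)
    edges = coords[1:] - coords[0]
    return float(np.linalg.det(edges)) / 6.0


def _degeneracy_tol(coords: np.ndarray) -> float:
    # element rejected if V < 1e-12 * (bounding-box diagonal)^3
    span = coords.max(axis=0) - coords.min(axis=0)
    diag = float(np.linalg.norm(span))
    return 1e-12 * diag**3


def tet_volume(coords: np.ndarray) -> float:
    """Volume (μm³) of the tetrahedron with vertex rows ``coords`` (4×3).

    Raises :class:`DegenerateElementError` for (near-)coplanar vertices.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (4, 3):
        raise MeshError(f"expected 4x3 coordinates, got {coords.shape}")
    vol = abs(tet_signed_volume(coords))
    if vol <= _degeneracy_tol(coords):
        raise DegenerateElementError(
            f"degenerate tetrahedron (volume {vol:.3e} μm³ below tolerance)"
        )
    return vol


def face_area(coords: np.ndarray) -> float:
    """Area (μm²) of the triangle with vertex rows ``coords`` (3×3).

    Raises :class:`DegenerateElementError` for collinear vertices.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (3, 3):
        raise MeshError(f"expected 3x3 coordinates, got {coords.shape}")
    cross = np.cross(coords[1] - coords[0], coords[2] - coords[0])
    area = 0.5 * float(np.linalg.norm(cross))
    span = coords.max(axis=0) - coords.min(axis=0)
    diag = float(np.linalg.norm(span))
    if area <= 1e-12 * max(diag, 1.0) ** 2:
        raise DegenerateElementError("zero-area (collinear) face")
    return area


@dataclass
class TetMesh:
    """An oriented tetrahedral mesh with tagged boundary surfaces.

    Parameters
    ----------
    nodes : (N, 3) float array of node coordinates in μm.
    elements : (M, 4) int array of node indices (0-based).
    boundary_face_sets : mapping of surface label to an (K, 2) int array of
        ``(element_index, local_face_id)`` pairs; local face ids follow
        :data:`FACE_LOCAL_NODES`.
    region_tags : length-M array of region labels (default ``"cytosol"``).
    """

    nodes: np.ndarray
    elements: np.ndarray
    boundary_face_sets: dict[str, np.ndarray] = field(default_factory=dict)
    region_tags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(np.asarray(self.nodes, dtype=float))
        self.elements = np.ascontiguousarray(np.asarray(self.elements, dtype=np.int64))
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshError("nodes must be an (N, 3) array")
        if self.elements.ndim != 2 or self.elements.shape[1] != 4:
            raise MeshError("elements must be an (M, 4) array")
        if self.region_tags is None:
            self.region_tags = np.full(self.n_elements, "cytosol", dtype=object)
        else:
            self.region_tags = np.asarray(self.region_tags, dtype=object)
        self.boundary_face_sets = {
            k: np.asarray(v, dtype=np.int64).reshape(-1, 2)
            for k, v in self.boundary_face_sets.items()
        }

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_coords(self) -> np.ndarray:
        """(M, 4, 3) coordinates of each element's vertices."""
        return self.nodes[self.elements]

    def signed_volumes(self) -> np.ndarray:
        coords = self.element_coords()
        edges = coords[:, 1:, :] - coords[:, :1, :]
        return np.linalg.det(edges) / 6.0

    def element_volumes(self) -> np.ndarray:
        return np.abs(self.signed_volumes())

    def total_volume(self) -> float:
        return float(self.element_volumes().sum())

    def face_node_indices(self, element: int, local_face: int) -> np.ndarray:
        return self.elements[element, list(FACE_LOCAL_NODES[local_face])]

    def face_set_nodes(self, label: str) -> np.ndarray:
        """Sorted unique node indices touched by the faces of a surface set."""
        faces = self.boundary_face_sets[label]
        idx = [self.face_node_indices(e, f) for e, f in faces]
        return np.unique(np.concatenate(idx)) if idx else np.empty(0, dtype=np.int64)

    def surface_area(self, label: str) -> float:
        """Total area (μm²) of a tagged surface set."""
        return float(
            sum(
                face_area(self.nodes[self.face_node_indices(e, f)])
                for e, f in self.boundary_face_sets[label]
            )
        )

    # -- orientation ---------------------------------------------------

    def orient(self) -> "TetMesh":
        """Canonically reorient elements to positive signed volume (in place).

        Swaps the last two vertices of negatively oriented elements and remaps
        boundary-face references accordingly.  Idempotent.
        """
        flipped = self.signed_volumes() < 0.0
        if flipped.any():
            els = self.elements
            els[flipped, 2], els[flipped, 3] = (
                els[flipped, 3].copy(),
                els[flipped, 2].copy(),
            )
            # swapping local nodes 2 and 3 exchanges the faces opposite them
            face_perm = np.array([3, 1, 2, 0])
            for faces in self.boundary_face_sets.values():
                mask = flipped[faces[:, 0]]
                faces[mask, 1] = face_perm[faces[mask, 1]]
        return self

    # -- boundary topology ---------------------------------------------

    def all_faces(self) -> tuple[np.ndarray, np.ndarray]:
        """All element faces as (4M, 3) node triples with (4M, 2) refs."""
        m = self.n_elements
        tris = np.empty((4 * m, 3), dtype=np.int64)
        refs = np.empty((4 * m, 2), dtype=np.int64)
        for k, loc in enumerate(FACE_LOCAL_NODES):
            tris[k::4] = self.elements[:, list(loc)]
            refs[k::4, 0] = np.arange(m)
            refs[k::4, 1] = k
        return tris, refs

    def boundary_faces(self) -> tuple[np.ndarray, np.ndarray]:
        """Faces on the mesh surface (appearing in exactly one element).

        Returns ``(refs, tris)`` — (B, 2) element/local-face pairs and the
        (B, 3) node triples, in matching order.
        """
        tris, refs = self.all_faces()
        key = np.sort(tris, axis=1)
        _, inverse, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        on_boundary = counts[inverse] == 1
        return refs[on_boundary], tris[on_boundary]

    # -- validation ----------------------------------------------------

    def validate(self, merge_tol_rel: float = 1e-9) -> None:
        """Check structural invariants; raise :class:`MeshError` on failure."""
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= self.n_nodes
        ):
            raise MeshError("element node index out of range")
        sv = self.signed_volumes()
        if (sv <= 0).any():
            raise MeshError(
                f"{int((sv <= 0).sum())} elements non-positively oriented "
                "(call orient()) or degenerate"
            )
        span = self.nodes.max(axis=0) - self.nodes.min(axis=0)
        diag = float(np.linalg.norm(span))
        tol = 1e-12 * diag**3
        if (np.abs(sv) <= tol).any():
            raise DegenerateElementError("mesh contains degenerate elements")
        if self.n_nodes > 1:
            d, _ = cKDTree(self.nodes).query(self.nodes, k=2)
            if d[:, 1].min() < merge_tol_rel * diag:
                raise MeshError("duplicate nodes within merge tolerance")
        bset = {(int(e), int(f)) for v in self.boundary_face_sets.values() for e, f in v}
        brefs, _ = self.boundary_faces()
        bound = {(int(e), int(f)) for e, f in brefs}
        stray = bset - bound
        if stray:
            raise MeshError(f"{len(stray)} tagged faces are not on the mesh surface")

    def is_watertight(self) -> bool:
        """True if every boundary edge is shared by exactly two boundary faces."""
        _, tris = self.boundary_faces()
        edges = np.sort(
            np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]]),
            axis=1,
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool((counts == 2).all())

    def copy(self) -> "TetMesh":
        return TetMesh(
            self.nodes.copy(),
            self.elements.copy(),
            {k: v.copy() for k, v in self.boundary_face_sets.items()},
            self.region_tags.copy(),
        )


# -- quality ------------------------------------------------------------


@dataclass
class MeshQualityReport:
    """Per-element shape quality, normalized to (0, 1] (1 = regular tet).

    ``aspect_ratio`` is 3·(inradius/circumradius); ``solid_angle`` is the
    minimum vertex solid angle divided by the regular tetrahedron's.
    Degenerate elements score 0.
    """

    aspect_ratio: np.ndarray
    solid_angle: np.ndarray

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, vals in (("aspect_ratio", self.aspect_ratio),
                           ("solid_angle", self.solid_angle)):
            rows.append(
                {"measure": name, "min": float(vals.min()),
                 "max": float(vals.max()), "mean": float(vals.mean())}
            )
        return pd.DataFrame(rows).set_index("measure")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "element_id": np.arange(len(self.aspect_ratio)),
                "aspect_ratio": self.aspect_ratio,
                "solid_angle": self.solid_angle,
            }
        ).to_csv(path, index=False)


def _vertex_solid_angles(coords: np.ndarray) -> np.ndarray:
    """Solid angles (sr) at the 4 vertices of each tet; coords is (M, 4, 3)."""
    m = coords.shape[0]
    omega = np.empty((m, 4))
    for v in range(4):
        others = [i for i in range(4) if i != v]
        a = coords[:, others[0]] - coords[:, v]
        b = coords[:, others[1]] - coords[:, v]
        c = coords[:, others[2]] - coords[:, v]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        nc = np.linalg.norm(c, axis=1)
        numer = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c)))
        denom = (
            na * nb * nc
            + np.einsum("ij,ij->i", a, b) * nc
            + np.einsum("ij,ij->i", a, c) * nb
            + np.einsum("ij,ij->i", b, c) * na
        )
        # van Oosterom–Strackee; atan2 handles obtuse configurations
        omega[:, v] = 2.0 * np.arctan2(numer, denom)
    return omega


def mesh_quality(mesh: TetMesh) -> MeshQualityReport:
    """Compute per-element aspect-ratio and solid-angle quality measures."""
    coords = mesh.element_coords()
    edges = coords[:, 1:, :] - coords[:, :1, :]
    vol = np.abs(np.linalg.det(edges)) / 6.0

    # surface area of each tet (sum of its four face areas)
    area = np.zeros(mesh.n_elements)
    for i, j, k in FACE_LOCAL_NODES:
        cr = np.cross(coords[:, j] - coords[:, i], coords[:, k] - coords[:, i])
        area += 0.5 * np.linalg.norm(cr, axis=1)

    # circumradius from |edge-matrix solve|: circumcenter relative to vertex 0
    sq = np.einsum("mij,mij->mi", edges, edges)
    degenerate = vol <= 1e-300
    circum_r = np.full(mesh.n_elements, np.inf)
    ok = ~degenerate
    if ok.any():
        rhs = 0.5 * sq[ok]
        centers = np.linalg.solve(edges[ok], rhs[:, :, None])[:, :, 0]
        circum_r[ok] = np.linalg.norm(centers, axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        in_r = np.where(area > 0, 3.0 * vol / area, 0.0)
        aspect = np.where(np.isfinite(circum_r) & (circum_r > 0),
                          3.0 * in_r / circum_r, 0.0)
    aspect = np.clip(aspect, 0.0, 1.0)

    omega = _vertex_solid_angles(coords)
    solid = np.clip(omega.min(axis=1) / REGULAR_TET_SOLID_ANGLE, 0.0, 1.0)
    solid[degenerate] = 0.0
    return MeshQualityReport(aspect_ratio=aspect, solid_angle=solid)


# -- probes --------------------------------------------------------------


def probe_nodes(
    mesh: TetMesh, points
) -> tuple[np.ndarray, np.ndarray]:
    """Snap probe coordinates to the nearest mesh nodes.

    Returns ``(indices, distances)``.  A warning is emitted when a point snaps
    from farther than the typical element edge length (it likely lies outside
    the meshed domain; the nearest surface node is returned).
    """
    if mesh.n_nodes == 0:
        raise MeshError("cannot probe an empty mesh")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    dist, idx = cKDTree(mesh.nodes).query(points)
    if mesh.n_elements:
        e01 = mesh.nodes[mesh.elements[:, 1]] - mesh.nodes[mesh.elements[:, 0]]
        edge_scale = float(np.median(np.linalg.norm(e01, axis=1)))
        far = dist > edge_scale
        if far.any():
            warnings.warn(
                f"{int(far.sum())} probe point(s) snapped from farther than the "
                f"typical edge length ({edge_scale:.3g} μm); they may lie "
                "outside the meshed domain",
                stacklevel=2,
            )
    return idx.astype(np.int64), dist
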