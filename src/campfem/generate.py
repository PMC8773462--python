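"""Synthetic tetrahedral mesh generators for cellular geometries.

Two geometries are provided:

* a concentric-sphere cell model — a spherical shell of cytosol between the
  nuclear envelope (radius ``R_i``) and the plasma membrane (radius ``R_o``),
  the nucleus itself being excluded from the domain;
* a flattened, irregular "cell-like" body (a super-ellipsoid with an
  off-center ellipsoidal nuclear cavity), standing in for image-derived
  endothelial-cell geometries.

Both samplers place points on the bounding surfaces and in the interior,
tetrahedralize with a Delaunay triangulation, and carve the domain out of the
convex hull by discarding tetrahedra whose centroid falls outside the signed
region.  Generation is deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import Delaunay

from .mesh import (
    PERINUCLEAR,
    PLASMA_MEMBRANE,
    MeshError,
    TetMesh,
)

__all__ = ["generate_sphere_shell_mesh", "generate_cell_like_mesh"]


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random 3x3 rotation matrix (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _sphere_points(radius: float, spacing: float, rng: np.random.Generator) -> np.ndarray:
    n = max(12, int(round(4.0 * np.pi * radius**2 / (0.77 * spacing**2))))
    return radius * (_fibonacci_sphere(n) @ _random_rotation(rng).T)


def _drop_degenerate(points: np.ndarray, tets: np.ndarray, scale: float) -> np.ndarray:
    coords = points[tets]
    vol = np.abs(np.linalg.det(coords[:, 1:] - coords[:, :1])) / 6.0
    return tets[vol > 1e-9 * scale**3]


def _boundary_refs(nodes: np.ndarray, tets: np.ndarray):
    mesh = TetMesh(nodes, tets)
    return mesh.boundary_faces()


def _strip_nonmanifold(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Remove tets until every boundary edge borders exactly two boundary faces.

    Delaunay carving occasionally leaves pinched configurations where a tet
    touches the surface along an edge only; dropping the smallest offending
    tet restores a 2-manifold boundary.  Also removes fully exposed tets
    (all four faces on the surface).
    """
    for _ in range(50):
        refs, tris = _boundary_refs(nodes, tets)
        # fully exposed tets
        exposure = np.bincount(refs[:, 0], minlength=len(tets))
        if (exposure >= 4).any():
            tets = tets[exposure < 4]
            continue
        edges = np.sort(
            np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]]),
            axis=1,
        )
        uniq, inverse, counts = np.unique(edges, axis=0, return_counts=True,
                                          return_inverse=True)
        bad = counts[inverse] > 2  # per boundary-face-edge flag, len 3B
        if not bad.any():
            return tets
        bad_faces = np.unique(np.nonzero(bad)[0] % len(tris))
        bad_tets = np.unique(refs[bad_faces, 0])
        coords = nodes[tets[bad_tets]]
        vol = np.abs(np.linalg.det(coords[:, 1:] - coords[:, :1])) / 6.0
        drop = bad_tets[np.argmin(vol)]
        tets = np.delete(tets, drop, axis=0)
    raise MeshError("failed to obtain a 2-manifold boundary surface")


def _compact(nodes: np.ndarray, tets: np.ndarray):
    """Drop unreferenced nodes and renumber connectivity."""
    used = np.unique(tets)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return nodes[used], remap[tets]


def generate_sphere_shell_mesh(
    R_o: float,
    R_i: float,
    target_edge_length: float,
    seed: int = 0,
) -> TetMesh:
    """Mesh the spherical-shell cell model (cytosol between nucleus and membrane).

    Parameters
    ----------
    R_o, R_i : outer (plasma membrane) and inner (nuclear envelope) radii, μm.
    target_edge_length : nominal point spacing, μm; must resolve the shell gap.
    seed : RNG seed controlling layer orientations and interior jitter.

    Returns a :class:`TetMesh` with outer faces tagged ``"plasma_membrane"``
    and inner faces tagged ``"perinuclear"``.
    """
    if not (0.0 < R_i < R_o):
        raise MeshError(f"require 0 < R_i < R_o, got R_i={R_i}, R_o={R_o}")
    h = float(target_edge_length)
    gap = R_o - R_i
    if h <= 0.0:
        raise MeshError("target_edge_length must be positive")
    if h > gap:
        raise MeshError(
            f"target edge length {h} μm is coarser than the shell gap {gap:.3g} μm"
        )
    rng = np.random.default_rng(seed)

    n_layers = max(2, int(round(gap / h)) + 1)
    radii = np.linspace(R_i, R_o, n_layers)
    layers = []
    for k, r in enumerate(radii):
        pts = _sphere_points(r, h, rng)
        if 0 < k < n_layers - 1:
            # jitter interior layers to break co-sphericity
            pts = pts + rng.uniform(-0.1 * h, 0.1 * h, size=pts.shape)
            rr = np.linalg.norm(pts, axis=1)
            keep = (rr > R_i + 0.25 * h) & (rr < R_o - 0.25 * h)
            pts = pts[keep]
        layers.append(pts)
    points = np.vstack(layers)

    tri = Delaunay(points)
    tets = tri.simplices.astype(np.int64)
    centroids = points[tets].mean(axis=1)
    r_c = np.linalg.norm(centroids, axis=1)
    tets = tets[r_c > R_i]  # carve the nuclear cavity
    tets = _drop_degenerate(points, tets, h)
    tets = _strip_nonmanifold(points, tets)
    nodes, tets = _compact(points, tets)

    mesh = TetMesh(nodes, tets).orient()
    refs, tris = mesh.boundary_faces()
    fc = nodes[tris].mean(axis=1)
    outer = np.linalg.norm(fc, axis=1) > 0.5 * (R_i + R_o)
    mesh.boundary_face_sets = {
        PLASMA_MEMBRANE: refs[outer],
        PERINUCLEAR: refs[~outer],
    }
    mesh.validate()
    return mesh


# -- cell-like (flattened super-ellipsoid with nuclear cavity) -----------


def _superellipsoid_value(p: np.ndarray, semi: np.ndarray, power: float) -> np.ndarray:
    return (np.abs(p / semi) ** power).sum(axis=-1)


def _ellipsoid_value(p: np.ndarray, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    return (((p - center) / semi) ** 2).sum(axis=-1)


def _project_radial(directions: np.ndarray, value_fn, bracket_hi: float) -> np.ndarray:
    """Scale each unit direction so the implicit value equals 1."""
    out = np.empty_like(directions)
    for i, d in enumerate(directions):
        f = lambda s: value_fn(s * d) - 1.0
        s = brentq(f, 1e-9, bracket_hi)
        out[i] = s * d
    return out


def generate_cell_like_mesh(seed: int = 0, target_edge_length: float = 1.6) -> TetMesh:
    """Mesh a flattened, irregular cell body with an off-center nuclear cavity.

    The plasma membrane is a super-ellipsoid (semi-axes 15 × 10 × 4 μm,
    exponent 2.5 — flat like a cultured endothelial cell); the nucleus is an
    ellipsoidal cavity (4 × 3 × 1.8 μm) centered at (3, 1, 0.3) μm.
    Deterministic for a fixed seed.
    """
    h = float(target_edge_length)
    if h <= 0.0:
        raise MeshError("target_edge_length must be positive")
    rng = np.random.default_rng(seed)

    semi = np.array([15.0, 10.0, 4.0])
    power = 2.5
    cav_c = np.array([3.0, 1.0, 0.3])
    cav_s = np.array([4.0, 3.0, 1.8])

    outer_val = lambda p: _superellipsoid_value(np.atleast_2d(p), semi, power)
    cav_val = lambda p: _ellipsoid_value(np.atleast_2d(p), cav_c, cav_s)

    # surface point clouds
    area_outer = 4.0 * np.pi * (semi.prod()) ** (2.0 / 3.0)  # rough scale
    n_out = max(64, int(round(2.2 * area_outer / (0.77 * h**2))))
    dirs = _fibonacci_sphere(n_out) @ _random_rotation(rng).T
    surf_out = _project_radial(dirs, lambda p: outer_val(p)[0], 2.5 * semi.max())

    n_cav = max(48, int(round(4.0 * np.pi * (cav_s.prod()) ** (2 / 3) / (0.77 * h**2))))
    dirs = _fibonacci_sphere(n_cav) @ _random_rotation(rng).T
    surf_cav = cav_c + _project_radial(
        dirs, lambda p: cav_val(cav_c + p)[0], 2.5 * cav_s.max()
    )

    # jittered interior grid
    axes = [np.arange(-s, s + h, h) for s in semi]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    grid = grid + rng.uniform(-0.2 * h, 0.2 * h, size=grid.shape)
    inside = (outer_val(grid) < (1.0 - 0.35 * h / semi.min()) ** power) & (
        cav_val(grid) > (1.0 + 0.35 * h / cav_s.min()) ** 2
    )
    points = np.vstack([surf_out, surf_cav, grid[inside]])

    tri = Delaunay(points)
    tets = tri.simplices.astype(np.int64)
    cen = points[tets].mean(axis=1)
    keep = (outer_val(cen) < 1.0) & (cav_val(cen) > 1.0)
    tets = tets[keep]
    tets = _drop_degenerate(points, tets, h)
    tets = _strip_nonmanifold(points, tets)
    nodes, tets = _compact(points, tets)

    mesh = TetMesh(nodes, tets).orient()
    refs, tris = mesh.boundary_faces()
    fc = nodes[tris].mean(axis=1)
    near_cavity = cav_val(fc) < 2.0
    mesh.boundary_face_sets = {
        PLASMA_MEMBRANE: refs[~near_cavity],
        PERINUCLEAR: refs[near_cavity],
    }
    mesh.validate()
    return mesh
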