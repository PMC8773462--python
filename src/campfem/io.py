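"""Mesh and field import/export in plain-text formats.

Supported: Gmsh MSH v2.2 ASCII and TetGen-style ``.node``/``.ele``
(+ optional ``.face``) for meshes, and legacy VTK / XML VTU unstructured
grids for simulation snapshots (write-only, one point scalar per field).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .mesh import FACE_LOCAL_NODES, MeshError, TetMesh

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_msh",
    "write_msh",
    "read_tetgen",
    "write_tetgen",
    "write_vtk_legacy",
    "write_vtu",
    "auto_classify_boundary",
]

_SURFACE_IDS = {"plasma_membrane": 1, "perinuclear": 2}


class ParseError(MeshError):
    """Malformed mesh file."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def auto_classify_boundary(mesh: TetMesh, warn: bool = True) -> None:
    """Tag boundary faces by an outer/inner distance heuristic (in place).

    Faces whose centroid is farther from the mesh centroid than the midpoint
    of the observed range are labeled ``plasma_membrane``; the rest (an inner
    cavity, if present) ``perinuclear``.  Used as a fallback when an imported
    mesh carries no surface tags.
    """
    refs, tris = mesh.boundary_faces()
    if len(refs) == 0:
        mesh.boundary_face_sets = {}
        return
    center = mesh.nodes.mean(axis=0)
    d = np.linalg.norm(mesh.nodes[tris].mean(axis=1) - center, axis=1)
    threshold = 0.5 * (d.min() + d.max())
    outer = d > threshold
    sets = {"plasma_membrane": refs[outer]}
    if (~outer).any():
        sets["perinuclear"] = refs[~outer]
    mesh.boundary_face_sets = sets
    if warn:
        warnings.warn(
            "imported mesh had no surface tags; boundary faces were "
            "auto-classified by an outer/inner distance heuristic",
            stacklevel=2,
        )


def _face_lookup(mesh: TetMesh) -> dict[tuple, tuple[int, int]]:
    refs, tris = mesh.boundary_faces()
    return {
        tuple(sorted(tri)): (int(e), int(f))
        for (e, f), tri in zip(refs, tris)
    }


# -- Gmsh MSH 2.2 --------------------------------------------------------


def write_msh(mesh: TetMesh, path) -> None:
    """Write Gmsh MSH v2.2 ASCII with tagged surface triangles and region tets."""
    path = Path(path)
    regions = sorted(set(np.asarray(mesh.region_tags)))
    region_ids = {name: 10 + k for k, name in enumerate(regions)}
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames",
             str(len(_SURFACE_IDS) + len(regions))]
    for name, pid in _SURFACE_IDS.items():
        lines.append(f'2 {pid} "{name}"')
    for name, pid in region_ids.items():
        lines.append(f'3 {pid} "{name}"')
    lines += ["$EndPhysicalNames", "$Nodes", str(mesh.n_nodes)]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {float(x)!r} {float(y)!r} {float(z)!r}")
    lines.append("$EndNodes")

    elems = []
    eid = 1
    for label, faces in mesh.boundary_face_sets.items():
        pid = _SURFACE_IDS.get(label)
        if pid is None:  # custom labels get ids after the reserved ones
            pid = 3 + sorted(
                set(mesh.boundary_face_sets) - set(_SURFACE_IDS)
            ).index(label)
        for e, f in faces:
            n = mesh.face_node_indices(int(e), int(f)) + 1
            elems.append(f"{eid} 2 2 {pid} {pid} {n[0]} {n[1]} {n[2]}")
            eid += 1
    for k, el in enumerate(mesh.elements):
        pid = region_ids[mesh.region_tags[k]]
        n = el + 1
        elems.append(f"{eid} 4 2 {pid} {pid} {n[0]} {n[1]} {n[2]} {n[3]}")
        eid += 1
    lines += ["$Elements", str(len(elems)), *elems, "$EndElements", ""]
    path.write_text("\n".join(lines))


def read_msh(path) -> TetMesh:
    """Read a Gmsh MSH v2.2 ASCII mesh with optional physical names."""
    path = Path(path)
    lines = path.read_text().splitlines()
    i = 0

    def expect(tag: str) -> None:
        nonlocal i
        while i < len(lines) and not lines[i].strip():
            i += 1
        if i >= len(lines) or lines[i].strip() != tag:
            raise ParseError(path, i + 1, f"expected {tag}")
        i += 1

    def find(tag: str) -> bool:
        nonlocal i
        while i < len(lines):
            if lines[i].strip() == tag:
                i += 1
                return True
            i += 1
        return False

    expect("$MeshFormat")
    version = lines[i].split()
    if not version or not version[0].startswith("2"):
        raise ParseError(path, i + 1, f"unsupported MSH version {version[:1]}")
    i += 1
    expect("$EndMeshFormat")

    names: dict[int, str] = {}
    mark = i
    if find("$PhysicalNames"):
        count = int(lines[i]); i += 1
        for _ in range(count):
            parts = lines[i].split(maxsplit=2)
            names[int(parts[1])] = parts[2].strip().strip('"')
            i += 1
        expect("$EndPhysicalNames")
    else:
        i = mark

    if not find("$Nodes"):
        raise ParseError(path, len(lines), "missing $Nodes section")
    n_nodes = int(lines[i]); i += 1
    nodes = np.empty((n_nodes, 3))
    index_of: dict[int, int] = {}
    for k in range(n_nodes):
        parts = lines[i].split()
        if len(parts) != 4:
            raise ParseError(path, i + 1, "node record must be 'id x y z'")
        index_of[int(parts[0])] = k
        nodes[k] = [float(v) for v in parts[1:]]
        i += 1
    expect("$EndNodes")

    if not find("$Elements"):
        raise ParseError(path, len(lines), "missing $Elements section")
    n_el = int(lines[i]); i += 1
    tets, tet_tags, tris, tri_tags = [], [], [], []
    for _ in range(n_el):
        parts = lines[i].split()
        line_no = i + 1
        i += 1
        etype = int(parts[1])
        ntags = int(parts[2])
        conn = parts[3 + ntags:]
        phys = int(parts[3]) if ntags else 0
        try:
            idx = [index_of[int(c)] for c in conn]
        except KeyError as exc:
            raise ParseError(path, line_no, f"node index {exc} out of range")
        if etype == 4:
            if len(idx) != 4:
                raise ParseError(path, line_no, "tetrahedron needs 4 nodes")
            tets.append(idx)
            tet_tags.append(phys)
        elif etype == 2:
            tris.append(tuple(sorted(idx)))
            tri_tags.append(phys)
        # other element types (points, lines) are ignored
    expect("$EndElements")
    if not tets:
        raise ParseError(path, len(lines), "no tetrahedral elements found")

    region = [names.get(t, "cytosol") for t in tet_tags]
    mesh = TetMesh(nodes, np.array(tets), region_tags=np.array(region, dtype=object))
    mesh.orient()

    if tris:
        lookup = _face_lookup(mesh)
        sets: dict[str, list] = {}
        id_to_name = {v: k for k, v in _SURFACE_IDS.items()}
        for tri, tag in zip(tris, tri_tags):
            ref = lookup.get(tri)
            if ref is None:
                continue  # triangle not on the surface of the tet mesh
            label = names.get(tag) or id_to_name.get(tag) or f"surface_{tag}"
            sets.setdefault(label, []).append(ref)
        mesh.boundary_face_sets = {k: np.array(v) for k, v in sets.items()}
    else:
        auto_classify_boundary(mesh)
    mesh.validate()
    return mesh


# -- TetGen .node / .ele / .face -----------------------------------------


def _strip_comments(lines, path):
    for no, raw in enumerate(lines, start=1):
        text = raw.split("#", 1)[0].strip()
        if text:
            yield no, text


def write_tetgen(mesh: TetMesh, base_path) -> None:
    """Write ``<base>.node``, ``<base>.ele`` and ``<base>.face`` (1-based)."""
    base = Path(base_path)
    base = base.with_suffix("") if base.suffix in {".node", ".ele", ".face"} else base

    node_lines = [f"{mesh.n_nodes} 3 0 0"]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        node_lines.append(f"{i} {float(x)!r} {float(y)!r} {float(z)!r}")
    base.with_suffix(".node").write_text("\n".join(node_lines) + "\n")

    ele_lines = [f"{mesh.n_elements} 4 0"]
    for i, el in enumerate(mesh.elements, start=1):
        n = el + 1
        ele_lines.append(f"{i} {n[0]} {n[1]} {n[2]} {n[3]}")
    base.with_suffix(".ele").write_text("\n".join(ele_lines) + "\n")

    face_records = []
    for label, faces in mesh.boundary_face_sets.items():
        marker = _SURFACE_IDS.get(label, 9)
        for e, f in faces:
            n = mesh.face_node_indices(int(e), int(f)) + 1
            face_records.append(f"{n[0]} {n[1]} {n[2]} {marker}")
    face_lines = [f"{len(face_records)} 1"]
    face_lines += ["# marker 1 = plasma_membrane, 2 = perinuclear"]
    face_lines += [f"{i} {rec}" for i, rec in enumerate(face_records, start=1)]
    base.with_suffix(".face").write_text("\n".join(face_lines) + "\n")


def read_tetgen(base_path) -> TetMesh:
    """Read TetGen-style ``.node``/``.ele`` (and ``.face`` when present)."""
    base = Path(base_path)
    base = base.with_suffix("") if base.suffix in {".node", ".ele", ".face"} else base
    node_path = base.with_suffix(".node")
    ele_path = base.with_suffix(".ele")

    records = list(_strip_comments(node_path.read_text().splitlines(), node_path))
    header = records[0][1].split()
    n_nodes = int(header[0])
    if len(records) - 1 < n_nodes:
        raise ParseError(node_path, records[-1][0], "fewer node records than declared")
    nodes = np.empty((n_nodes, 3))
    index_of: dict[int, int] = {}
    for k, (no, text) in enumerate(records[1 : n_nodes + 1]):
        parts = text.split()
        if len(parts) < 4:
            raise ParseError(node_path, no, "node record must be 'id x y z'")
        index_of[int(parts[0])] = k
        nodes[k] = [float(v) for v in parts[1:4]]

    records = list(_strip_comments(ele_path.read_text().splitlines(), ele_path))
    n_el = int(records[0][1].split()[0])
    tets = np.empty((n_el, 4), dtype=np.int64)
    for k, (no, text) in enumerate(records[1 : n_el + 1]):
        parts = text.split()
        if len(parts) < 5:
            raise ParseError(ele_path, no, "element record must be 'id n1 n2 n3 n4'")
        try:
            tets[k] = [index_of[int(p)] for p in parts[1:5]]
        except KeyError as exc:
            raise ParseError(ele_path, no, f"node index {exc} out of range")

    mesh = TetMesh(nodes, tets)
    mesh.orient()

    face_path = base.with_suffix(".face")
    if face_path.exists():
        records = list(_strip_comments(face_path.read_text().splitlines(), face_path))
        n_faces = int(records[0][1].split()[0])
        lookup = _face_lookup(mesh)
        id_to_name = {v: k for k, v in _SURFACE_IDS.items()}
        sets: dict[str, list] = {}
        for no, text in records[1 : n_faces + 1]:
            parts = text.split()
            if len(parts) < 4:
                raise ParseError(face_path, no, "face record must be 'id n1 n2 n3 [marker]'")
            try:
                tri = tuple(sorted(index_of[int(p)] for p in parts[1:4]))
            except KeyError as exc:
                raise ParseError(face_path, no, f"node index {exc} out of range")
            marker = int(parts[4]) if len(parts) > 4 else 0
            ref = lookup.get(tri)
            if ref is None:
                continue
            label = id_to_name.get(marker, f"surface_{marker}")
            sets.setdefault(label, []).append(ref)
        mesh.boundary_face_sets = {k: np.array(v) for k, v in sets.items()}
    else:
        auto_classify_boundary(mesh)
    mesh.validate()
    return mesh


# -- VTK writers ----------------------------------------------------------


def write_vtk_legacy(mesh: TetMesh, path, point_data: dict[str, np.ndarray] | None = None,
                     title: str = "campfem snapshot") -> None:
    """Write a legacy ASCII VTK unstructured grid with optional point scalars."""
    path = Path(path)
    out = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    out += [f"{float(x)!r} {float(y)!r} {float(z)!r}" for x, y, z in mesh.nodes]
    out.append(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}")
    out += [f"4 {a} {b} {c} {d}" for a, b, c, d in mesh.elements]
    out.append(f"CELL_TYPES {mesh.n_elements}")
    out += ["10"] * mesh.n_elements
    if point_data:
        out.append(f"POINT_DATA {mesh.n_nodes}")
        for name, values in point_data.items():
            values = np.asarray(values, dtype=float)
            out.append(f"SCALARS {name} double 1")
            out.append("LOOKUP_TABLE default")
            out += [f"{float(v)!r}" for v in values]
    path.write_text("\n".join(out) + "\n")


def write_vtu(mesh: TetMesh, path, point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write an XML VTU (ASCII) unstructured grid with optional point scalars."""
    path = Path(path)

    def block(values, fmt=str):
        return " ".join(fmt(v) for v in np.asarray(values).ravel())

    data_arrays = ""
    if point_data:
        for name, values in point_data.items():
            data_arrays += (
                f'        <DataArray type="Float64" Name="{name}" format="ascii">\n'
                f"          {block(values, lambda v: repr(float(v)))}\n        </DataArray>\n"
            )
    xml = f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
  <UnstructuredGrid>
    <Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{mesh.n_elements}">
      <PointData>
{data_arrays}      </PointData>
      <Points>
        <DataArray type="Float64" NumberOfComponents="3" format="ascii">
          {block(mesh.nodes, repr)}
        </DataArray>
      </Points>
      <Cells>
        <DataArray type="Int64" Name="connectivity" format="ascii">
          {block(mesh.elements)}
        </DataArray>
        <DataArray type="Int64" Name="offsets" format="ascii">
          {block(4 * np.arange(1, mesh.n_elements + 1))}
        </DataArray>
        <DataArray type="UInt8" Name="types" format="ascii">
          {block(np.full(mesh.n_elements, 10))}
        </DataArray>
      </Cells>
    </Piece>
  </UnstructuredGrid>
</VTKFile>
"""
    path.write_text(xml)


# -- dispatch --------------------------------------------------------------


def read_mesh(path, format: str | None = None) -> TetMesh:
    """Read a tetrahedral mesh; format inferred from the extension if omitted."""
    path = Path(path)
    fmt = format or {".msh": "msh", ".node": "tetgen", ".ele": "tetgen"}.get(
        path.suffix.lower()
    )
    if fmt == "msh":
        return read_msh(path)
    if fmt == "tetgen":
        return read_tetgen(path)
    raise MeshError(f"unknown mesh format for {path} (supported: msh, tetgen)")


def write_mesh(mesh: TetMesh, path, format: str | None = None) -> None:
    """Write a mesh; format inferred from the extension if omitted."""
    path = Path(path)
    fmt = format or {
        ".msh": "msh",
        ".node": "tetgen",
        ".ele": "tetgen",
        ".vtk": "vtk",
        ".vtu": "vtu",
    }.get(path.suffix.lower())
    if fmt == "msh":
        write_msh(mesh, path)
    elif fmt == "tetgen":
        write_tetgen(mesh, path)
    elif fmt == "vtk":
        write_vtk_legacy(mesh, path)
    elif fmt == "vtu":
        write_vtu(mesh, path)
    else:
        raise MeshError(
            f"unknown mesh format for {path} (supported: msh, tetgen, vtk, vtu)"
        )
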