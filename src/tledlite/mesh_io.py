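"""Mesh file readers and writers: VTK legacy ASCII, MSH ASCII, inline text.

Supported dialects
------------------
* VTK legacy ASCII unstructured grids (``DATASET UNSTRUCTURED_GRID``) with a
  single cell type, tetrahedra (type 10) or hexahedra (type 12).  Optional
  ``POINT_DATA``/``VECTORS`` blocks are preserved on read.
* MSH ASCII (Gmsh v2.2 ``$Nodes``/``$Elements`` blocks, element types 4 =
  tetrahedron, 5 = hexahedron).  MSH is 1-based on disk; connectivity is
  converted to the package's 0-based convention on read.
* Inline whitespace-separated node/element text blocks as embedded in the
  simulation XML.

Tetrahedron orientation is repaired on read (nodes 2 and 3 swapped with a
warning) so that every element has positive volume.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .mesh import Mesh, MeshError, element_volumes

__all__ = ["read_mesh", "write_mesh", "read_vtk", "write_vtk",
           "read_msh", "write_msh", "mesh_from_text_blocks"]

_VTK_CELL_TYPE = {"T4": 10, "T4ANP": 10, "H8": 12}
_MSH_ELEM_TYPE = {"T4": 4, "T4ANP": 4, "H8": 5}


def _repair_orientation(mesh: Mesh) -> Mesh:
    if mesh.element_type in ("T4", "T4ANP"):
        vol = element_volumes(mesh)
        if np.any(vol == 0):
            raise MeshError("degenerate (zero-volume) tetrahedron in file")
        neg = vol < 0
        if np.any(neg):
            warnings.warn(
                f"repaired winding of {int(neg.sum())} inverted tetrahedra "
                "(nodes 2 and 3 swapped)", stacklevel=3)
            elements = mesh.elements.copy()
            elements[neg] = elements[neg][:, [0, 1, 3, 2]]
            return Mesh(mesh.nodes, elements, mesh.element_type)
    return mesh


def read_mesh(path, format: str = None, element_type: str = None) -> Mesh:
    """Read a mesh file; ``format`` in {"vtk_legacy", "msh_ascii"}.

    If ``format`` is None it is inferred from the suffix (.vtk / .msh).
    ``element_type`` may force T4ANP for tetrahedral files (same geometry
    as T4, different solution formulation).
    """
    path = Path(path)
    if format is None:
        format = {"vtk": "vtk_legacy", "msh": "msh_ascii"}.get(
            path.suffix.lstrip(".").lower())
        if format is None:
            raise MeshError(f"cannot infer mesh format from {path.name!r}")
    if format == "vtk_legacy":
        mesh, _ = read_vtk(path)
    elif format == "msh_ascii":
        mesh = read_msh(path)
    else:
        raise MeshError(f"unknown mesh format {format!r}")
    if element_type == "T4ANP":
        if mesh.element_type != "T4":
            raise MeshError("T4ANP requested for a non-tetrahedral mesh")
        mesh = Mesh(mesh.nodes, mesh.elements, "T4ANP")
    return mesh


def write_mesh(mesh: Mesh, path, format: str = None):
    path = Path(path)
    if format is None:
        format = {"vtk": "vtk_legacy", "msh": "msh_ascii"}.get(
            path.suffix.lstrip(".").lower())
    if format == "vtk_legacy":
        write_vtk(mesh, path)
    elif format == "msh_ascii":
        write_msh(mesh, path)
    else:
        raise MeshError(f"unknown mesh format {format!r}")


# ---------------------------------------------------------------------------
# VTK legacy ASCII
# ---------------------------------------------------------------------------

def write_vtk(mesh: Mesh, path, point_vectors: dict = None):
    """Write a legacy ASCII unstructured grid; ``point_vectors`` maps field
    names to (N, 3) arrays written as POINT_DATA VECTORS blocks."""
    lines = ["# vtk DataFile Version 3.0", "tledlite mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.num_nodes} double"]
    lines += [" ".join(repr(float(v)) for v in row) for row in mesh.nodes]
    k = mesh.nodes_per_element
    lines.append(f"CELLS {mesh.num_elements} {mesh.num_elements * (k + 1)}")
    lines += [f"{k} " + " ".join(str(int(v)) for v in row)
              for row in mesh.elements]
    lines.append(f"CELL_TYPES {mesh.num_elements}")
    ct = _VTK_CELL_TYPE[mesh.element_type]
    lines += [str(ct)] * mesh.num_elements
    if point_vectors:
        lines.append(f"POINT_DATA {mesh.num_nodes}")
        for name, arr in point_vectors.items():
            arr = np.asarray(arr, float).reshape(mesh.num_nodes, 3)
            lines.append(f"VECTORS {name} double")
            lines += [" ".join(repr(float(v)) for v in row) for row in arr]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk(path):
    """Read a legacy ASCII unstructured grid.

    Returns (mesh, point_vectors) where point_vectors maps VECTORS field
    names to (N, 3) arrays (empty dict if none present).
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    it = iter(lines)
    try:
        header = [next(it) for _ in range(4)]
    except StopIteration:
        raise MeshError(f"{path}: truncated VTK header")
    if "UNSTRUCTURED_GRID" not in header[3].upper():
        raise MeshError(f"{path}: not a DATASET UNSTRUCTURED_GRID file")

    rest = list(it)
    i = 0
    nodes = cells = cell_types = None
    point_vectors = {}
    npoints = None
    while i < len(rest):
        parts = rest[i].split()
        kw = parts[0].upper()
        if kw == "POINTS":
            npoints = int(parts[1])
            vals, i = _take_floats(rest, i + 1, npoints * 3)
            nodes = np.array(vals).reshape(npoints, 3)
        elif kw == "CELLS":
            ncells, total = int(parts[1]), int(parts[2])
            vals, i = _take_floats(rest, i + 1, total)
            vals = [int(v) for v in vals]
            cells = []
            j = 0
            for _ in range(ncells):
                k = vals[j]
                cells.append(vals[j + 1:j + 1 + k])
                j += 1 + k
        elif kw == "CELL_TYPES":
            ncells = int(parts[1])
            vals, i = _take_floats(rest, i + 1, ncells)
            cell_types = [int(v) for v in vals]
        elif kw == "POINT_DATA":
            i += 1
        elif kw == "VECTORS":
            name = parts[1]
            vals, i = _take_floats(rest, i + 1, npoints * 3)
            point_vectors[name] = np.array(vals).reshape(npoints, 3)
        else:
            raise MeshError(f"{path}: unsupported VTK section {parts[0]!r}")
    if nodes is None or cells is None or cell_types is None:
        raise MeshError(f"{path}: missing POINTS/CELLS/CELL_TYPES section")
    types = set(cell_types)
    if len(types) != 1:
        raise MeshError(f"{path}: mixed element types are unsupported")
    ct = types.pop()
    if ct == 10:
        etype = "T4"
    elif ct == 12:
        etype = "H8"
    else:
        raise MeshError(f"{path}: unknown VTK cell type {ct}")
    mesh = _repair_orientation(Mesh(nodes, np.array(cells), etype))
    return mesh, point_vectors


def _take_floats(lines, i, n):
    vals = []
    while len(vals) < n:
        if i >= len(lines):
            raise MeshError("truncated data block in mesh file")
        vals += [float(t) for t in lines[i].split()]
        i += 1
    if len(vals) != n:
        raise MeshError("ragged data block in mesh file")
    return vals, i


# ---------------------------------------------------------------------------
# MSH ASCII (Gmsh v2.2)
# ---------------------------------------------------------------------------

def write_msh(mesh: Mesh, path):
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat",
             "$Nodes", str(mesh.num_nodes)]
    lines += [f"{i + 1} " + " ".join(repr(float(v)) for v in row)
              for i, row in enumerate(mesh.nodes)]
    lines += ["$EndNodes", "$Elements", str(mesh.num_elements)]
    et = _MSH_ELEM_TYPE[mesh.element_type]
    for i, row in enumerate(mesh.elements):
        lines.append(f"{i + 1} {et} 0 " + " ".join(str(int(v) + 1) for v in row))
    lines.append("$EndElements")
    Path(path).write_text("\n".join(lines) + "\n")


def read_msh(path) -> Mesh:
    """Read a Gmsh v2.2 ASCII mesh; indices converted from 1- to 0-based."""
    lines = Path(path).read_text().splitlines()
    i = 0
    node_map = {}
    coords = []
    raw_elems = []
    etypes = set()
    while i < len(lines):
        ln = lines[i].strip()
        if ln == "$Nodes":
            n = int(lines[i + 1])
            for j in range(n):
                parts = lines[i + 2 + j].split()
                node_map[int(parts[0])] = len(coords)
                coords.append([float(x) for x in parts[1:4]])
            i += 2 + n
        elif ln == "$Elements":
            n = int(lines[i + 1])
            for j in range(n):
                parts = lines[i + 2 + j].split()
                et = int(parts[1])
                ntags = int(parts[2])
                conn = [int(x) for x in parts[3 + ntags:]]
                if et in (4, 5):
                    etypes.add(et)
                    raw_elems.append(conn)
                # lower-dimensional entities (points/lines/surfaces) ignored
            i += 2 + n
        else:
            i += 1
    if not coords:
        raise MeshError(f"{path}: no $Nodes block found")
    if not raw_elems:
        raise MeshError(f"{path}: no volume elements found")
    if len(etypes) != 1:
        raise MeshError(f"{path}: mixed element types are unsupported")
    etype = "T4" if etypes.pop() == 4 else "H8"
    elements = np.array([[node_map[v] for v in row] for row in raw_elems])
    return _repair_orientation(Mesh(np.array(coords), elements, etype))


# ---------------------------------------------------------------------------
# Inline text blocks (for the simulation XML)
# ---------------------------------------------------------------------------

def mesh_from_text_blocks(node_text: str, element_text: str,
                          element_type: str) -> Mesh:
    """Build a mesh from whitespace-separated coordinate/connectivity text."""
    vals = np.array(node_text.split(), dtype=float)
    if vals.size % 3:
        raise MeshError("inline node block is not a multiple of 3 values")
    nodes = vals.reshape(-1, 3)
    conn = np.array([int(t) for t in element_text.split()])
    k = 8 if element_type == "H8" else 4
    if conn.size % k:
        raise MeshError(
            f"inline element block length {conn.size} is not a multiple of {k}")
    return _repair_orientation(Mesh(nodes, conn.reshape(-1, k), element_type))
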