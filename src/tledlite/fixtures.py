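"""Programmatic generation of structured test meshes.

All simulation inputs in the test-suite and examples are generated here:
structured boxes/beams of hexahedra or tetrahedra, with exact analytic
volumes for validation.
"""

from __future__ import annotations

import numpy as np

from .mesh import Mesh, element_volumes

__all__ = ["make_box_mesh", "merge_meshes"]

# Kuhn 6-tet split of the unit cell. Vertices indexed in VTK H8 order
# (0..7); every tetrahedron shares the 0-6 main diagonal, so the split is
# conforming across neighbouring cells without orientation alternation.
_KUHN_TETS = (
    (0, 1, 2, 6),
    (0, 2, 3, 6),
    (0, 3, 7, 6),
    (0, 7, 4, 6),
    (0, 4, 5, 6),
    (0, 5, 1, 6),
)


def make_box_mesh(nx: int, ny: int, nz: int,
                  lx: float, ly: float, lz: float,
                  element_type: str = "H8",
                  origin=(0.0, 0.0, 0.0)) -> Mesh:
    """Structured box mesh of ``nx*ny*nz`` cells covering ``lx*ly*lz`` metres.

    H8 produces one hexahedron per cell (VTK vertex ordering); T4/T4ANP
    split every cell into 6 tetrahedra (Kuhn split around the cell's main
    diagonal — deterministic and conforming).  Total element volume equals
    the analytic box volume to machine precision.
    """
    if min(nx, ny, nz) < 1:
        raise ValueError("cell counts must be >= 1")
    if min(lx, ly, lz) <= 0:
        raise ValueError("box lengths must be > 0")

    xs = np.linspace(0.0, lx, nx + 1) + origin[0]
    ys = np.linspace(0.0, ly, ny + 1) + origin[1]
    zs = np.linspace(0.0, lz, nz + 1) + origin[2]
    # node id (i, j, k) -> flat index; k fastest
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    cells = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                # VTK hexahedron ordering: bottom ring CCW, then top ring
                cells.append([
                    nid(i, j, k), nid(i + 1, j, k),
                    nid(i + 1, j + 1, k), nid(i, j + 1, k),
                    nid(i, j, k + 1), nid(i + 1, j, k + 1),
                    nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                ])
    cells = np.asarray(cells, dtype=np.int64)

    if element_type == "H8":
        return Mesh(nodes, cells, "H8")
    if element_type in ("T4", "T4ANP"):
        tets = np.concatenate([cells[:, t] for t in _KUHN_TETS])
        m = Mesh(nodes, tets, element_type)
        # enforce positive orientation (swap nodes 2<->3 where inverted)
        vol = element_volumes(m)
        neg = vol < 0
        if np.any(neg):
            tets[neg] = tets[neg][:, [0, 1, 3, 2]]
            m = Mesh(nodes, tets, element_type)
        return m
    raise ValueError(f"unknown element type {element_type!r}")


def merge_meshes(a: Mesh, b: Mesh) -> Mesh:
    """Concatenate two same-element-type meshes into one (disjoint bodies).

    No node welding is performed: the result holds both bodies in one node
    and element numbering, as used for multi-body contact problems.
    """
    if a.element_type != b.element_type:
        raise ValueError("cannot merge meshes of different element types")
    nodes = np.concatenate([a.nodes, b.nodes])
    elements = np.concatenate([a.elements, b.elements + a.num_nodes])
    return Mesh(nodes, elements, a.element_type)
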