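"""Solid mesh containers and surface extraction.

A :class:`Mesh` holds node coordinates (metres) and connectivity for one
solid element type: linear tetrahedra (``T4``), nodal-averaged-pressure
tetrahedra (``T4ANP``, same geometry as T4) or reduced-integration trilinear
hexahedra (``H8``, VTK vertex ordering).  All indexing is 0-based
internally; file-format offsets are handled at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Mesh", "SurfaceMesh", "extract_surface", "element_volumes"]

#: nodes per element for each supported element type
NODES_PER_ELEMENT = {"T4": 4, "T4ANP": 4, "H8": 8}

# Element faces with outward winding for positively oriented elements.
# T4: face opposite each vertex; H8: VTK hexahedron ordering.
_T4_FACES = ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1))
_H8_FACES = (
    (0, 3, 2, 1),  # bottom (zeta = -1)
    (4, 5, 6, 7),  # top
    (0, 1, 5, 4),
    (1, 2, 6, 5),
    (2, 3, 7, 6),
    (3, 0, 4, 7),
)


class MeshError(ValueError):
    """Raised for invalid or unsupported mesh data."""


@dataclass
class Mesh:
    """Nodes + single-element-type connectivity.

    Parameters
    ----------
    nodes : (N, 3) float array
        Node coordinates in metres.
    elements : (E, k) int array
        0-based connectivity; k = 4 (T4/T4ANP) or 8 (H8).
    element_type : {"T4", "T4ANP", "H8"}
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_type: str

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int64)
        if self.element_type not in NODES_PER_ELEMENT:
            raise MeshError(f"unknown element type {self.element_type!r}")
        k = NODES_PER_ELEMENT[self.element_type]
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshError("nodes must be an (N, 3) array")
        if self.elements.ndim != 2 or self.elements.shape[1] != k:
            raise MeshError(
                f"{self.element_type} connectivity must be (E, {k}), "
                f"got {self.elements.shape}"
            )
        if self.elements.size:
            if self.elements.min() < 0 or self.elements.max() >= len(self.nodes):
                raise MeshError("connectivity index out of range")
            # no repeated node within an element
            srt = np.sort(self.elements, axis=1)
            if np.any(srt[:, 1:] == srt[:, :-1]):
                raise MeshError("element with duplicate node indices")

    @property
    def num_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def num_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def nodes_per_element(self) -> int:
        return NODES_PER_ELEMENT[self.element_type]

    def diameter(self) -> float:
        """Diagonal of the axis-aligned bounding box (a length scale)."""
        if not len(self.nodes):
            return 0.0
        return float(np.linalg.norm(self.nodes.max(0) - self.nodes.min(0)))


@dataclass
class SurfaceMesh:
    """Triangulated boundary of a solid mesh.

    ``facets`` reference the *solid* mesh's node numbering; ``facet_normals``
    are outward unit normals in the reference configuration.
    """

    facets: np.ndarray
    facet_normals: np.ndarray = field(default=None)

    def __post_init__(self):
        self.facets = np.ascontiguousarray(self.facets, dtype=np.int64).reshape(-1, 3)
        if self.facet_normals is None:
            self.facet_normals = np.zeros((len(self.facets), 3))
        self.facet_normals = np.asarray(self.facet_normals, dtype=float).reshape(-1, 3)

    @property
    def num_facets(self) -> int:
        return self.facets.shape[0]

    def node_ids(self) -> np.ndarray:
        """Sorted unique node indices appearing in any facet."""
        return np.unique(self.facets)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (n, 2) sorted-index array."""
        e = np.concatenate(
            [self.facets[:, [0, 1]], self.facets[:, [1, 2]], self.facets[:, [2, 0]]]
        )
        return np.unique(np.sort(e, axis=1), axis=0)


def element_volumes(mesh: Mesh) -> np.ndarray:
    """Signed volumes of all elements (positive for valid winding).

    T4: det of the edge matrix / 6.  H8: exact trilinear volume obtained by
    splitting each hexahedron into 6 tetrahedra around the 0-6 diagonal
    (equals 8 det(J) only for affinely distorted cells; used for volume
    book-keeping and fixture checks).
    """
    X = mesh.nodes[mesh.elements]  # (E, k, 3)
    if mesh.element_type in ("T4", "T4ANP"):
        d = X[:, 1:] - X[:, :1]
        return np.linalg.det(d) / 6.0
    # 6-tet decomposition of the hexahedron (exact for trilinear geometry)
    tets = ((0, 1, 2, 6), (0, 2, 3, 6), (0, 3, 7, 6), (0, 7, 4, 6), (0, 4, 5, 6), (0, 5, 1, 6))
    vol = np.zeros(mesh.num_elements)
    for a, b, c, d in tets:
        e = np.stack([X[:, b] - X[:, a], X[:, c] - X[:, a], X[:, d] - X[:, a]], axis=1)
        vol += np.linalg.det(e) / 6.0
    return vol


def _boundary_faces(mesh: Mesh):
    """Element faces occurring exactly once, with their owner element index."""
    if mesh.element_type in ("T4", "T4ANP"):
        face_defs = _T4_FACES
    else:
        face_defs = _H8_FACES
    faces = []
    owners = []
    for fd in face_defs:
        faces.append(mesh.elements[:, fd])
        owners.append(np.arange(mesh.num_elements))
    faces = np.concatenate(faces) if faces else np.zeros((0, len(face_defs[0])), int)
    owners = np.concatenate(owners)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    on_boundary = counts[inv] == 1
    return faces[on_boundary], owners[on_boundary]


def extract_surface(mesh: Mesh) -> SurfaceMesh:
    """Extract the triangulated boundary surface of a solid mesh.

    Faces appearing in exactly one element form the boundary.  Hexahedral
    quad faces are split into two triangles along the diagonal from the
    lowest-index vertex (deterministic).  Normals point out of the solid;
    orientation is fixed against the owning element's centroid.
    """
    if mesh.num_elements == 0:
        return SurfaceMesh(np.zeros((0, 3), int), np.zeros((0, 3)))
    faces, owners = _boundary_faces(mesh)

    if faces.shape[1] == 4:
        tris = []
        tri_owner = []
        for quad, own in zip(faces, owners):
            i0 = int(np.argmin(quad))
            q = np.roll(quad, -i0)
            tris.append((q[0], q[1], q[2]))
            tris.append((q[0], q[2], q[3]))
            tri_owner += [own, own]
        tris = np.asarray(tris, dtype=np.int64)
        owners = np.asarray(tri_owner)
    else:
        tris = faces

    p = mesh.nodes[tris]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    # orient outward: away from the owning element centroid
    cent_el = mesh.nodes[mesh.elements[owners]].mean(axis=1)
    cent_f = p.mean(axis=1)
    flip = np.einsum("ij,ij->i", n, cent_f - cent_el) < 0
    tris[flip] = tris[flip][:, ::-1]
    n[flip] *= -1.0
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    if np.any(norm == 0):
        raise MeshError("degenerate (zero-area) boundary facet")
    return SurfaceMesh(tris, n / norm)
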