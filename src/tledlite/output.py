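"""Result writers: VTK mesh export and plain-ASCII solution histories."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import Mesh
from .mesh_io import write_vtk

__all__ = ["export_vtk", "write_history", "read_history", "export_membrane_vtk"]


def export_vtk(mesh: Mesh, U: np.ndarray, path, field_name: str = "displacement"):
    """Write the solid mesh with the displacement field as point data
    (legacy ASCII unstructured grid, re-readable by the package's reader)."""
    U = np.asarray(U, float).reshape(mesh.num_nodes, 3)
    write_vtk(mesh, path, point_vectors={field_name: U})


def export_membrane_vtk(nodes: np.ndarray, triangles: np.ndarray, U: np.ndarray,
                        path):
    """Write a membrane surface as legacy ASCII vtkPolyData with point
    displacements."""
    nodes = np.asarray(nodes, float)
    triangles = np.asarray(triangles, np.int64).reshape(-1, 3)
    used = np.unique(triangles)
    remap = {int(v): i for i, v in enumerate(used)}
    tri = np.vectorize(remap.get)(triangles) if len(triangles) else triangles
    lines = ["# vtk DataFile Version 3.0", "tledlite membrane", "ASCII",
             "DATASET POLYDATA", f"POINTS {len(used)} double"]
    lines += [" ".join(repr(float(v)) for v in nodes[i]) for i in used]
    lines.append(f"POLYGONS {len(tri)} {4 * len(tri)}")
    lines += ["3 " + " ".join(str(int(v)) for v in row) for row in tri]
    lines.append(f"POINT_DATA {len(used)}")
    lines.append("VECTORS displacement double")
    Uu = np.asarray(U, float).reshape(-1, 3)
    lines += [" ".join(repr(float(v)) for v in Uu[i]) for i in used]
    Path(path).write_text("\n".join(lines) + "\n")


def write_history(times, values, path, dt: float = 0.0, frequency: int = 1):
    """Write a displacement/force history as whitespace-delimited ASCII.

    Layout: a ``#``-header line with N (nodes), dt and the recording
    frequency, then one row per sample: the time followed by the 3N
    components (x0 y0 z0 x1 ...).  Loadable with any numeric text reader.
    """
    values = [np.asarray(v, float).reshape(-1) for v in values]
    if not values:
        raise ValueError("empty history record")
    n = values[0].size // 3
    with open(path, "w") as fh:
        fh.write(f"# N={n} dt={dt!r} frequency={frequency}\n")
        for t, v in zip(times, values):
            fh.write(" ".join([repr(float(t))] + [repr(float(x)) for x in v]))
            fh.write("\n")


def read_history(path):
    """Inverse of :func:`write_history`: returns (times, values (K, 3N))."""
    data = np.loadtxt(path, ndmin=2)
    return data[:, 0], data[:, 1:]
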