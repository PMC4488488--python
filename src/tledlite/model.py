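"""Simulation model description: XML schema, parsing and resolution.

Schema (all coordinates metres, forces newtons, times seconds)::

    <Model>
      <SystemParams dt="1e-3" total_time="1.0" damping="50.0"
                    density="1000" integrator="CDM" hourglass_kappa="0.075"/>
      <Geometry element_type="H8">
        <Nodes> x y z  x y z ... </Nodes>
        <Elements> i0 i1 ... </Elements>
        <!-- or: <MeshFile path="beam.vtk" format="vtk_legacy"/> -->
      </Geometry>
      <Material name="tissue" kind="neo_hookean" mu="1e3" bulk="1e5"
                density="1000" default="true"/>
      <ElementSet material="tissue" all="true"/>
      <!-- or: <ElementSet material="m2"> 0 1 2 </ElementSet> -->
      <ShellElementSet material="skin" thickness="1e-3" skin="true"/>
      <Constraint kind="fixed_disp|prescribed_disp|force|gravity"
                  dofs="xyz" magnitude="0 0 -9.81" load_shape="step|ramp">
        <Nodes> 0 1 2 3 </Nodes>
        <!-- or: <BoundarySelect normal="0 0 -1" max_angle="5"
                     box="xmin xmax ymin ymax zmin zmax"/> -->
      </Constraint>
      <ContactPlate a="0 0 -0.1" b="1 0 -0.1" c="0 1 -0.1"
                    displacement="0 0 0.05"/>
      <ContactCylinder origin="0 0 0" axis="0 0 1" radius="0.5" length="2"
                       radius_change="0"/>
      <DeformableContact on="true" margin="0"/>
      <Output variable="U" frequency="10"/>
    </Model>

Integrator is "CDM" (default) or "NewmarkExplicit".  ``damping`` is the
mass-proportional damping coefficient alpha_D (1/s).  Mesh file paths are
resolved relative to the XML file.  Sub-models are rejected as unsupported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from lxml import etree

from .contact import CylinderSurface, PlateSurface
from .materials import Material
from .mesh import Mesh, SurfaceMesh, extract_surface
from .mesh_io import mesh_from_text_blocks, read_mesh

__all__ = ["Model", "Constraint", "SystemParams", "parse_model",
           "select_boundary_nodes", "constraint_value_at", "ModelError"]

_DOF = {"x": 0, "y": 1, "z": 2}


class ModelError(ValueError):
    """Parse/validation error in a simulation description."""


def _err(elem, msg):
    line = getattr(elem, "sourceline", None)
    where = f" (XML element <{elem.tag}>, line {line})" if line else f" (<{elem.tag}>)"
    raise ModelError(msg + where)


@dataclass
class Constraint:
    """One boundary condition or load.

    kind: fixed_disp | prescribed_disp | force | gravity.
    dof_mask: tuple of active axes (subset of 0,1,2).
    magnitude: 3-vector payload (displacement m / total force N / gravity
    m/s^2); force is divided equally among the listed nodes.
    load_shape: "step" (full value from t=0) or "ramp" (linear up to
    ramp_time -- the full simulation time by default -- then held).
    """

    kind: str
    node_ids: np.ndarray
    magnitude: np.ndarray
    dof_mask: Tuple[int, ...] = (0, 1, 2)
    load_shape: str = "step"
    ramp_time: Optional[float] = None

    def __post_init__(self):
        self.node_ids = np.asarray(self.node_ids, np.int64).reshape(-1)
        self.magnitude = np.asarray(self.magnitude, float).reshape(3)
        if not np.all(np.isfinite(self.magnitude)):
            raise ModelError(f"non-finite magnitude in {self.kind} constraint")
        if self.kind not in ("fixed_disp", "prescribed_disp", "force", "gravity"):
            raise ModelError(f"unknown constraint kind {self.kind!r}")
        if self.load_shape not in ("step", "ramp"):
            raise ModelError(f"unknown load shape {self.load_shape!r}")


@dataclass
class SystemParams:
    dt: float
    total_time: float
    alpha_D: float = 0.0
    density: float = 1000.0
    integrator: str = "CDM"
    hourglass_kappa: float = 0.075

    def __post_init__(self):
        if self.dt <= 0:
            raise ModelError("dt must be > 0")
        if self.total_time < self.dt:
            raise ModelError("total_time must be >= dt")
        if self.integrator not in ("CDM", "NewmarkExplicit"):
            raise ModelError(f"unknown integrator {self.integrator!r}")

    @property
    def num_steps(self) -> int:
        return int(ceil(self.total_time / self.dt - 1e-12))


@dataclass
class ShellElementSet:
    """Membrane triangles with a membrane material and thickness.

    ``skin=True`` means the triangles are the extracted solid surface."""

    material: Material
    thickness: float
    triangles: np.ndarray
    skin: bool = False


@dataclass
class Model:
    mesh: Mesh
    element_sets: List[Tuple[np.ndarray, Material]]
    system: SystemParams
    constraints: List[Constraint] = field(default_factory=list)
    shell_sets: List[ShellElementSet] = field(default_factory=list)
    contact_plates: List[PlateSurface] = field(default_factory=list)
    contact_cylinders: List[CylinderSurface] = field(default_factory=list)
    deformable_contact: bool = False
    contact_margin: float = 0.0
    outputs: List[Tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        covered = np.zeros(self.mesh.num_elements, dtype=int)
        for ids, _ in self.element_sets:
            covered[ids] += 1
        if np.any(covered > 1):
            raise ModelError("overlapping element sets")
        if np.any(covered == 0):
            raise ModelError("elements not covered by any element set")
        for c in self.constraints:
            if len(c.node_ids) and (c.node_ids.min() < 0
                                    or c.node_ids.max() >= self.mesh.num_nodes):
                raise ModelError(f"constraint node index out of range ({c.kind})")

    def element_materials(self):
        """Per-element material list (index-aligned with the mesh)."""
        mats = [None] * self.mesh.num_elements
        for ids, mat in self.element_sets:
            for i in ids:
                mats[i] = mat
        return mats


def constraint_value_at(c: Constraint, t: float, total_time: float) -> np.ndarray:
    """Per-node constraint 3-vectors at time t.

    step: the full magnitude for all t; ramp: magnitude * t / T_ramp,
    clamped at the full magnitude (T_ramp = c.ramp_time or total_time).
    """
    if c.load_shape == "step":
        scale = 1.0
    else:
        T_ramp = c.ramp_time if c.ramp_time else total_time
        scale = min(t / T_ramp, 1.0)
    n = len(c.node_ids) if len(c.node_ids) else 1
    return np.tile(c.magnitude * scale, (n, 1))


def select_boundary_nodes(surface: SurfaceMesh, nodes: np.ndarray,
                          normal_dir=None, max_angle: float = 180.0,
                          box=None) -> np.ndarray:
    """Nodes of boundary facets selected by normal orientation and bounds.

    A facet is selected when its outward normal is within ``max_angle``
    degrees of ``normal_dir`` (skipped if None) and all its vertices lie
    inside the axis-aligned ``box`` (xmin, xmax, ymin, ymax, zmin, zmax;
    skipped if None).  Returns sorted, deduplicated node indices.
    """
    keep = np.ones(surface.num_facets, dtype=bool)
    if normal_dir is not None:
        nd = np.asarray(normal_dir, float).reshape(3)
        nd = nd / np.linalg.norm(nd)
        cosang = surface.facet_normals @ nd
        keep &= cosang >= np.cos(np.radians(max_angle)) - 1e-12
    if box is not None:
        b = np.asarray(box, float).reshape(3, 2)
        p = nodes[surface.facets]  # (F, 3, 3)
        inside = np.all((p >= b[:, 0] - 1e-12) & (p <= b[:, 1] + 1e-12), axis=(1, 2))
        keep &= inside
    return np.unique(surface.facets[keep])


# ---------------------------------------------------------------------------
# XML parsing
# ---------------------------------------------------------------------------

def _floats(text, n=None):
    v = np.array(str(text).split(), dtype=float)
    if n is not None and v.size != n:
        raise ModelError(f"expected {n} numbers, got {v.size}")
    return v


def _get(elem, attr, default=None, cast=float):
    val = elem.get(attr)
    if val is None:
        if default is None:
            _err(elem, f"missing required attribute {attr!r}")
        return default
    try:
        return cast(val)
    except ValueError:
        _err(elem, f"attribute {attr!r} is not a valid {cast.__name__}")


def parse_model(xml_path) -> Model:
    """Parse and fully resolve a simulation XML description."""
    xml_path = Path(xml_path)
    try:
        tree = etree.parse(str(xml_path))
    except (OSError, etree.XMLSyntaxError) as e:
        raise ModelError(f"cannot parse {xml_path}: {e}")
    root = tree.getroot()
    if root.tag != "Model":
        _err(root, "root element must be <Model>")
    if root.find("SubModel") is not None:
        _err(root.find("SubModel"), "sub-models are unsupported")

    sp = root.find("SystemParams")
    if sp is None:
        raise ModelError("missing <SystemParams> element")
    system = SystemParams(
        dt=_get(sp, "dt"),
        total_time=_get(sp, "total_time"),
        alpha_D=_get(sp, "damping", 0.0),
        density=_get(sp, "density", 1000.0),
        integrator=_get(sp, "integrator", "CDM", str),
        hourglass_kappa=_get(sp, "hourglass_kappa", 0.075),
    )

    mesh = _parse_geometry(root, xml_path)

    materials = {}
    default_mat = None
    for m in root.findall("Material"):
        mat = _parse_material(m, system.density)
        materials[mat.name] = mat
        if m.get("default", "false").lower() == "true":
            default_mat = mat

    element_sets = []
    covered = np.zeros(mesh.num_elements, dtype=bool)
    for es in root.findall("ElementSet"):
        name = _get(es, "material", cast=str)
        if name not in materials:
            _err(es, f"unknown material {name!r}")
        if es.get("all", "false").lower() == "true":
            ids = np.arange(mesh.num_elements)
        else:
            ids = np.array([int(t) for t in (es.text or "").split()], dtype=np.int64)
            if ids.size and (ids.min() < 0 or ids.max() >= mesh.num_elements):
                _err(es, "element index out of range")
        if np.any(covered[ids]):
            _err(es, "overlapping element sets")
        covered[ids] = True
        element_sets.append((ids, materials[name]))
    if not np.all(covered):
        if default_mat is None:
            raise ModelError(
                "elements not covered by any element set and no default material")
        element_sets.append((np.nonzero(~covered)[0], default_mat))

    surface = None  # extracted lazily for geometric selections / skins
    constraints = []
    for ce in root.findall("Constraint"):
        c, surface = _parse_constraint(ce, mesh, surface)
        constraints.append(c)

    shell_sets = []
    for se in root.findall("ShellElementSet"):
        name = _get(se, "material", cast=str)
        if name not in materials:
            _err(se, f"unknown material {name!r}")
        mat = materials[name]
        if mat.kind != "membrane":
            _err(se, f"shell element set needs a membrane material, got {mat.kind}")
        thickness = _get(se, "thickness")
        if se.get("skin", "false").lower() == "true":
            if surface is None:
                surface = extract_surface(mesh)
            tris = surface.facets.copy()
            skin = True
        else:
            tris = np.array([int(t) for t in (se.text or "").split()],
                            dtype=np.int64).reshape(-1, 3)
            skin = False
        shell_sets.append(ShellElementSet(mat, thickness, tris, skin))

    plates = []
    for pe in root.findall("ContactPlate"):
        plates.append(PlateSurface(
            _floats(_get(pe, "a", cast=str), 3),
            _floats(_get(pe, "b", cast=str), 3),
            _floats(_get(pe, "c", cast=str), 3),
            _floats(pe.get("displacement", "0 0 0"), 3)))
    cylinders = []
    for cy in root.findall("ContactCylinder"):
        cylinders.append(CylinderSurface(
            _floats(_get(cy, "origin", cast=str), 3),
            _floats(_get(cy, "axis", cast=str), 3),
            _get(cy, "radius"), _get(cy, "length"),
            _get(cy, "radius_change", 0.0)))

    dc = root.find("DeformableContact")
    deformable = dc is not None and dc.get("on", "true").lower() == "true"
    margin = _get(dc, "margin", 0.0) if dc is not None else 0.0

    outputs = []
    for oe in root.findall("Output"):
        var = _get(oe, "variable", "U", str)
        if var not in ("U", "F"):
            _err(oe, f"unknown output variable {var!r}")
        outputs.append((var, int(_get(oe, "frequency", 1.0))))

    return Model(mesh, element_sets, system, constraints, shell_sets,
                 plates, cylinders, deformable, margin, outputs)


def _parse_geometry(root, xml_path) -> Mesh:
    ge = root.find("Geometry")
    if ge is None:
        raise ModelError("missing <Geometry> element")
    etype = _get(ge, "element_type", cast=str)
    mf = ge.find("MeshFile")
    if mf is not None:
        path = Path(_get(mf, "path", cast=str))
        if not path.is_absolute():
            path = xml_path.parent / path
        fmt = mf.get("format")
        try:
            return read_mesh(path, fmt, element_type=etype if etype == "T4ANP" else None)
        except Exception as e:
            _err(mf, f"cannot read mesh file: {e}")
    nodes = ge.find("Nodes")
    elems = ge.find("Elements")
    if nodes is None or elems is None:
        _err(ge, "Geometry needs either <MeshFile> or <Nodes> + <Elements>")
    try:
        return mesh_from_text_blocks(nodes.text or "", elems.text or "", etype)
    except Exception as e:
        _err(ge, f"invalid inline mesh: {e}")


def _parse_material(m, default_density) -> Material:
    kind = _get(m, "kind", cast=str)
    kw = dict(
        kind=kind,
        mu=_get(m, "mu"),
        density=_get(m, "density", default_density),
        name=_get(m, "name", cast=str),
    )
    if kind != "membrane":
        kw["bulk"] = _get(m, "bulk")
    if kind == "transversely_isotropic":
        kw["eta"] = _get(m, "eta")
        kw["a0"] = _floats(_get(m, "a0", cast=str), 3)
    try:
        return Material(**kw)
    except ValueError as e:
        _err(m, str(e))


def _parse_constraint(ce, mesh, surface):
    kind = _get(ce, "kind", cast=str)
    dofs = _get(ce, "dofs", "xyz", str)
    try:
        dof_mask = tuple(sorted(_DOF[ch] for ch in dofs))
    except KeyError:
        _err(ce, f"invalid dofs spec {dofs!r}")
    magnitude = _floats(ce.get("magnitude", "0 0 0"), 3)
    load_shape = _get(ce, "load_shape", "step", str)
    ramp_time = _get(ce, "ramp_time", 0.0) or None

    if kind == "gravity":
        node_ids = np.arange(mesh.num_nodes)
    else:
        ne = ce.find("Nodes")
        bs = ce.find("BoundarySelect")
        if ne is not None:
            node_ids = np.array([int(t) for t in (ne.text or "").split()],
                                dtype=np.int64)
        elif bs is not None:
            if surface is None:
                surface = extract_surface(mesh)
            normal = bs.get("normal")
            normal = _floats(normal, 3) if normal else None
            box = bs.get("box")
            if box is not None:
                b = _floats(box, 6)
                box = (b[0], b[1], b[2], b[3], b[4], b[5])
            node_ids = select_boundary_nodes(
                surface, mesh.nodes, normal,
                _get(bs, "max_angle", 180.0), box)
        else:
            _err(ce, "constraint needs <Nodes> or <BoundarySelect>")
        if len(node_ids) and (node_ids.min() < 0 or node_ids.max() >= mesh.num_nodes):
            _err(ce, "dangling node index in constraint")
    try:
        return Constraint(kind, node_ids, magnitude, dof_mask, load_shape,
                          ramp_time), surface
    except ModelError as e:
        _err(ce, str(e))
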