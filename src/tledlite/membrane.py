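"""Large-deformation triangular membrane elements.

Iso-parametric triangles on the reference triangle
T_ref = {(0,0), (1,0), (0,1)}: the 3x2 Jacobians F0 = dX/dxi (initial) and
Fn = dx/dxi (current) give the 2x2 metrics C0, Cn from which the
incompressible neo-Hookean membrane stress S_xi is evaluated
(:func:`tledlite.materials.spk_membrane`).  Internal forces

    f_i = A^e H^e (Fn S_xi) dh_i/dxi

couple directly to the solid mesh's nodes; the element has no bending
stiffness.  Lumped mass rho A H / 3 is added per vertex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import InvalidStateError, spk_membrane, membrane_energy_density

__all__ = ["MembraneElement", "membrane_precompute", "membrane_internal_forces"]

# dh/dxi on the reference triangle, rows per vertex
DHDXI = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])


@dataclass
class MembraneElement:
    """Precomputed reference data for one membrane triangle."""

    node_ids: np.ndarray
    F0: np.ndarray       # 3x2 reference Jacobian dX/dxi
    C0: np.ndarray       # 2x2 reference metric
    area: float          # initial area A^e (m^2)
    thickness: float     # H^e (m)


def membrane_precompute(node_ids, coords: np.ndarray, thickness: float,
                        density: float):
    """Build a :class:`MembraneElement` and its 3 lumped vertex masses.

    coords: (3, 3) initial vertex positions.  A^e = sqrt(det C0) / 2; the
    element mass rho A H is split equally among the vertices.
    """
    coords = np.asarray(coords, float).reshape(3, 3)
    F0 = coords.T @ DHDXI  # columns are the edge vectors
    C0 = F0.T @ F0
    det = np.linalg.det(C0)
    if det <= 0:
        raise InvalidStateError("degenerate (zero-area) membrane triangle")
    area = 0.5 * np.sqrt(det)
    elem = MembraneElement(np.asarray(node_ids, np.int64).reshape(3),
                           F0, C0, float(area), float(thickness))
    masses = np.full(3, density * area * thickness / 3.0)
    return elem, masses


def membrane_internal_forces(elem: MembraneElement, current: np.ndarray,
                             mu: float) -> np.ndarray:
    """Nodal forces f_i = A H (Fn S_xi) dh_i/dxi for current vertex positions."""
    current = np.asarray(current, float).reshape(3, 3)
    Fn = current.T @ DHDXI
    Cn = Fn.T @ Fn
    S = spk_membrane(elem.C0, Cn, mu)
    return elem.area * elem.thickness * (DHDXI @ (Fn @ S).T)


def membrane_strain_energy(elem: MembraneElement, current: np.ndarray,
                           mu: float) -> float:
    """A H psi_mem for the incompressible neo-Hookean membrane energy."""
    current = np.asarray(current, float).reshape(3, 3)
    Fn = current.T @ DHDXI
    Cn = Fn.T @ Fn
    return elem.area * elem.thickness * float(membrane_energy_density(elem.C0, Cn, mu))
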