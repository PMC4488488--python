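"""Solid-element kernels: precomputation and internal nodal forces.

Total Lagrangian evaluation: shape-function derivatives with respect to the
reference coordinates (dhdX), element volumes and lumped masses are computed
once; each time step only evaluates, per element, the deformation gradient
F = I + sum_i U_i (x) dhdX_i, the stress S(C) and the nodal forces

    f_i = V^e  P dhdX_i,     P = F S   (first Piola-Kirchhoff),

which for the reduced-integration hexahedron uses V^e = 8 det(J) at the
element centre plus stabilisation forces against the four hourglass modes.
All kernels are vectorised over the element array.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .mesh import Mesh

__all__ = [
    "ElementPrecomp",
    "precompute",
    "deformation_gradient",
    "internal_forces_T4",
    "internal_forces_H8",
    "hourglass_forces",
    "anp_modified_deformation",
    "anp_internal_forces",
]


class InvertedElementError(ValueError):
    pass


# H8 natural coordinates, VTK vertex ordering
_H8_XI = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)

# hourglass base patterns: xi*eta, eta*zeta, xi*zeta, xi*eta*zeta at the nodes
_H8_HG = np.stack([
    _H8_XI[:, 0] * _H8_XI[:, 1],
    _H8_XI[:, 1] * _H8_XI[:, 2],
    _H8_XI[:, 0] * _H8_XI[:, 2],
    _H8_XI[:, 0] * _H8_XI[:, 1] * _H8_XI[:, 2],
])  # (4, 8)


@dataclass
class ElementPrecomp:
    """Batched once-per-simulation element data.

    dhdX: (E, k, 3) reference shape-function gradients; volume: (E,);
    detJ: (E,) centre Jacobian determinant (H8, volume/8); gamma: (E, 4, 8)
    hourglass shape vectors (H8 only, Flanagan-Belytschko construction,
    orthogonal to all affine nodal fields); hg_scale: (E,) = V^(2/3) used in
    the hourglass stiffness coefficient.
    """

    element_type: str
    dhdX: np.ndarray
    volume: np.ndarray
    detJ: Optional[np.ndarray] = None
    gamma: Optional[np.ndarray] = None
    hg_scale: Optional[np.ndarray] = None


def precompute(mesh: Mesh, densities: np.ndarray):
    """Shape-function derivatives, volumes and lumped nodal masses.

    densities: per-element mass density (kg/m^3).  The lumped mass assigns
    rho V^e / k to each of an element's k nodes, so the total mass equals
    sum(rho V) exactly.
    """
    densities = np.broadcast_to(np.asarray(densities, float), (mesh.num_elements,))
    if np.any(densities <= 0):
        raise ValueError("densities must be positive")
    X = mesh.nodes[mesh.elements]  # (E, k, 3)

    if mesh.element_type in ("T4", "T4ANP"):
        D = X[:, 1:] - X[:, :1]  # (E, 3, 3) rows = edge vectors
        det = np.linalg.det(D)
        if np.any(det <= 0):
            bad = int(np.argmax(det <= 0))
            raise InvertedElementError(f"element {bad} has non-positive volume")
        vol = det / 6.0
        Dinv = np.linalg.inv(D)  # (E, 3, 3)
        # h = (1 - s - t - u, s, t, u) in edge coordinates: grad h_i rows
        g = np.transpose(Dinv, (0, 2, 1))  # rows i=1..3 of dhdX
        dhdX = np.concatenate([-g.sum(axis=1, keepdims=True), g], axis=1)
        pre = ElementPrecomp(mesh.element_type, dhdX, vol)
    elif mesh.element_type == "H8":
        dhdxi = _H8_XI / 8.0  # (8, 3): d h_i / d xi at the centre
        J = np.einsum("eia,ib->eab", X, dhdxi)  # dX/dxi
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            bad = int(np.argmax(detJ <= 0))
            raise InvertedElementError(f"element {bad} has non-positive volume")
        Jinv = np.linalg.inv(J)
        dhdX = np.einsum("ib,eba->eia", dhdxi, Jinv)  # (E, 8, 3)
        vol = 8.0 * detJ
        # Flanagan-Belytschko hourglass shape vectors:
        #   gamma_a = h_a - dhdX (X^T h_a)  -> orthogonal to affine fields
        Xh = np.einsum("eia,ri->era", X, _H8_HG)  # (E, 4, 3)
        gamma = _H8_HG[None, :, :] - np.einsum("era,eia->eri", Xh, dhdX)
        pre = ElementPrecomp("H8", dhdX, vol, detJ=detJ, gamma=gamma,
                             hg_scale=vol ** (2.0 / 3.0))
    else:  # pragma: no cover
        raise ValueError(mesh.element_type)

    k = mesh.nodes_per_element
    masses = np.zeros(mesh.num_nodes)
    np.add.at(masses, mesh.elements.ravel(),
              np.repeat(densities * vol / k, k))
    return pre, masses


def deformation_gradient(pre: ElementPrecomp, U_elem: np.ndarray) -> np.ndarray:
    """F = I + sum_i U_i (x) dhdX_i for stacked per-element displacements.

    U_elem: (E, k, 3) nodal displacements gathered per element.
    """
    F = np.einsum("eia,eib->eab", U_elem, pre.dhdX)
    F += np.eye(3)
    return F


def _nodal_forces(volume, F, S, dhdX):
    P = F @ S  # first Piola-Kirchhoff
    return np.einsum("e,eab,eib->eia", volume, P, dhdX)


def internal_forces_T4(pre: ElementPrecomp, S: np.ndarray, F: np.ndarray) -> np.ndarray:
    """f^(e) = V^e dhdX S F^T, stacked: (E, 4, 3) nodal forces."""
    return _nodal_forces(pre.volume, F, S, pre.dhdX)


def internal_forces_H8(pre: ElementPrecomp, S: np.ndarray, F: np.ndarray,
                       U_elem: np.ndarray = None,
                       mu: np.ndarray = None, kappa: float = 0.075) -> np.ndarray:
    """f^(e) = 8 det(J) dhdX S F^T plus hourglass stabilisation.

    The hourglass term is added when ``U_elem`` and ``mu`` are given.
    """
    f = _nodal_forces(pre.volume, F, S, pre.dhdX)
    if U_elem is not None and mu is not None and kappa != 0.0:
        f = f + hourglass_forces(pre, U_elem, mu, kappa)
    return f


def hourglass_forces(pre: ElementPrecomp, U_elem: np.ndarray,
                     mu: np.ndarray, kappa: float = 0.075) -> np.ndarray:
    """Stiffness-type hourglass control forces for the H8 element.

    f_hg = k_e Gamma Gamma^T U per displacement component, with
    k_e = kappa * mu_e * V_e^(2/3).  The forces derive from the quadratic
    energy (k_e/2) sum_r |Gamma_r . U|^2, vanish identically on affine
    displacement fields and scale linearly with the control coefficient.
    """
    if pre.gamma is None:
        raise ValueError("hourglass control is defined for H8 elements only")
    k = kappa * np.broadcast_to(np.asarray(mu, float), pre.volume.shape) * pre.hg_scale
    q = np.einsum("eri,eia->era", pre.gamma, U_elem)  # modal amplitudes
    return np.einsum("e,eri,era->eia", k, pre.gamma, q)


def hourglass_energy(pre: ElementPrecomp, U_elem: np.ndarray,
                     mu: np.ndarray, kappa: float = 0.075) -> np.ndarray:
    """Per-element quadratic hourglass energy consistent with the forces."""
    k = kappa * np.broadcast_to(np.asarray(mu, float), pre.volume.shape) * pre.hg_scale
    q = np.einsum("eri,eia->era", pre.gamma, U_elem)
    return 0.5 * k * np.einsum("era,era->e", q, q)


# ---------------------------------------------------------------------------
# Nodal-averaged-pressure tetrahedron (T4ANP)
# ---------------------------------------------------------------------------

def anp_modified_deformation(mesh: Mesh, pre: ElementPrecomp, F: np.ndarray):
    """Volumetrically averaged deformation gradients for the ANP tetrahedron.

    Per element J = det F; nodal averages J_bar_a are volume-weighted means
    over the elements adjacent to each node; the element's effective
    J_tilde is the mean of its four nodal averages, and

        F_tilde = (J_tilde / J)^(1/3) F

    rescales the volumetric part while keeping the isochoric part.  Returns
    (F_tilde, J, J_tilde, alpha) with alpha the per-element scale factor.
    """
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise InvertedElementError("element inverted during ANP averaging")
    W = np.zeros(mesh.num_nodes)
    VJ = np.zeros(mesh.num_nodes)
    conn = mesh.elements
    np.add.at(W, conn.ravel(), np.repeat(pre.volume, 4))
    np.add.at(VJ, conn.ravel(), np.repeat(pre.volume * J, 4))
    Jbar = VJ / W
    Jtilde = Jbar[conn].mean(axis=1)
    alpha = (Jtilde / J) ** (1.0 / 3.0)
    return alpha[:, None, None] * F, J, Jtilde, alpha


def anp_internal_forces(mesh: Mesh, pre: ElementPrecomp, F: np.ndarray,
                        stress_fn: Callable[[np.ndarray], np.ndarray]):
    """Energy-consistent nodal forces for the ANP tetrahedron.

    The forces are the exact gradient of E(U) = sum_e V_e psi(C_tilde_e),
    where C_tilde couples neighbouring elements through the nodal volume
    averages.  Differentiating E gives, per element, a first
    Piola-Kirchhoff-like tensor

        P_hat = V alpha F_tilde S(C_tilde) + g J F^-T

    where the scalar g collects the volumetric coupling terms (it vanishes
    for homogeneous deformations, recovering the plain T4 forces).

    Returns (forces (E,4,3), C_tilde (E,3,3)).
    """
    Ft, J, Jtilde, alpha = anp_modified_deformation(mesh, pre, F)
    Ct = np.einsum("eab,eac->ebc", Ft, Ft)
    S = stress_fn(Ct)
    V = pre.volume
    P1 = V[:, None, None] * alpha[:, None, None] * (Ft @ S)

    # volumetric coupling: T_e = (V alpha / 3) (F_tilde S) : F
    T = (V * alpha / 3.0) * np.einsum("eab,eab->e", Ft @ S, F)
    conn = mesh.elements
    W = np.zeros(mesh.num_nodes)
    np.add.at(W, conn.ravel(), np.repeat(V, 4))
    q = np.zeros(mesh.num_nodes)
    np.add.at(q, conn.ravel(), np.repeat(T / (4.0 * Jtilde), 4))
    g = -T / J + V * (q / W)[conn].sum(axis=1)

    FinvT = np.transpose(np.linalg.inv(F), (0, 2, 1))
    P = P1 + (g * J)[:, None, None] * FinvT
    forces = np.einsum("eab,eib->eia", P, pre.dhdX)
    return forces, Ct
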