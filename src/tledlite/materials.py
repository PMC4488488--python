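"""Hyperelastic constitutive models: second Piola-Kirchhoff stress from C.

Solid models use a deviatoric/volumetric split of the strain energy with a
penalty bulk term for near-incompressibility:

    psi_NH  = mu/2 (I1_bar - 3) + kappa/2 (J - 1)^2
    psi_TI  = psi_NH + eta/2 (I4_bar - 1)^2

with I1_bar = J^(-2/3) tr C, I4_bar = J^(-2/3) a0.C.a0, J = sqrt(det C).
The membrane model is the plane-stress incompressible neo-Hookean stress
S_xi = mu (C0^-1 - (det C0 / det Cn) Cn^-1) on the 2D reference triangle.

All routines accept stacked inputs (..., 3, 3) and return stacked stresses;
each S is the exact derivative 2 d(psi)/dC of its stated energy (verified
against numeric gradients in the test-suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Material",
    "spk_neo_hookean",
    "spk_transversely_isotropic",
    "spk_membrane",
    "strain_energy_density",
]

_I3 = np.eye(3)


class InvalidStateError(ValueError):
    """Deformation state outside the admissible range (det C <= 0 etc.)."""


@dataclass
class Material:
    """Material parameters for one element set.

    kind: "neo_hookean" | "transversely_isotropic" | "membrane"
    mu: shear modulus (Pa); bulk: penalty bulk modulus (Pa, solids);
    eta: anisotropy modulus (Pa) with unit fibre direction a0 (TI only);
    density: kg/m^3.
    """

    kind: str
    mu: float
    density: float
    bulk: float = 0.0
    eta: float = 0.0
    a0: np.ndarray = field(default=None)
    name: str = ""

    def __post_init__(self):
        if self.kind not in ("neo_hookean", "transversely_isotropic", "membrane"):
            raise ValueError(f"unknown material kind {self.kind!r}")
        if self.mu <= 0 or self.density <= 0:
            raise ValueError("mu and density must be positive")
        if self.kind != "membrane" and self.bulk <= 0:
            raise ValueError("solid materials need a positive bulk modulus")
        if self.kind == "transversely_isotropic":
            a = np.asarray(self.a0, dtype=float).reshape(3)
            n = np.linalg.norm(a)
            if not n > 0:
                raise ValueError("fibre direction a0 must be nonzero")
            self.a0 = a / n

    def spk(self, C: np.ndarray) -> np.ndarray:
        """Second Piola-Kirchhoff stress for stacked right Cauchy-Green C."""
        if self.kind == "neo_hookean":
            return spk_neo_hookean(C, self.mu, self.bulk)
        if self.kind == "transversely_isotropic":
            return spk_transversely_isotropic(C, self.mu, self.bulk, self.eta, self.a0)
        raise InvalidStateError("membrane material used on a solid element set")

    def energy_density(self, C: np.ndarray) -> np.ndarray:
        return strain_energy_density(C, self)


def _check_detC(detC):
    if np.any(detC <= 0):
        raise InvalidStateError("det C <= 0: element inverted or collapsed")


def spk_neo_hookean(C: np.ndarray, mu: float, bulk: float) -> np.ndarray:
    """S = 2 d(psi)/dC for the deviatoric-split neo-Hookean energy."""
    C = np.asarray(C, dtype=float)
    detC = np.linalg.det(C)
    _check_detC(detC)
    J = np.sqrt(detC)
    Cinv = np.linalg.inv(C)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    Jm23 = J ** (-2.0 / 3.0)
    dev = mu * Jm23[..., None, None] * (_I3 - (I1 / 3.0)[..., None, None] * Cinv)
    vol = (bulk * (J - 1.0) * J)[..., None, None] * Cinv
    return dev + vol


def spk_transversely_isotropic(C: np.ndarray, mu: float, bulk: float,
                               eta: float, a0: np.ndarray) -> np.ndarray:
    """Isotropic NH stress plus the fibre-reinforcement term 2 d(psi_aniso)/dC."""
    C = np.asarray(C, dtype=float)
    a0 = np.asarray(a0, dtype=float).reshape(3)
    S = spk_neo_hookean(C, mu, bulk)
    if eta == 0.0:
        return S
    detC = np.linalg.det(C)
    J = np.sqrt(detC)
    Jm23 = J ** (-2.0 / 3.0)
    Cinv = np.linalg.inv(C)
    I4 = np.einsum("a,...ab,b->...", a0, C, a0)
    I4b = Jm23 * I4
    A = np.outer(a0, a0)
    dI4b = Jm23[..., None, None] * A - (I4b / 3.0)[..., None, None] * Cinv
    return S + 2.0 * eta * (I4b - 1.0)[..., None, None] * dI4b


def spk_membrane(C0: np.ndarray, Cn: np.ndarray, mu: float) -> np.ndarray:
    """Plane incompressible neo-Hookean membrane stress on the reference triangle.

    S_xi = mu (C0^-1 - (II_C0 / II_Cn) Cn^-1) with II_C = det(C), both C 2x2.
    """
    C0 = np.asarray(C0, dtype=float)
    Cn = np.asarray(Cn, dtype=float)
    d0 = np.linalg.det(C0)
    dn = np.linalg.det(Cn)
    if np.any(d0 <= 0) or np.any(dn <= 0):
        raise InvalidStateError("singular membrane metric (det C <= 0)")
    return mu * (np.linalg.inv(C0) - (d0 / dn)[..., None, None] * np.linalg.inv(Cn))


def strain_energy_density(C: np.ndarray, material: Material) -> np.ndarray:
    """psi(C) in Pa for the solid models (stacked input supported)."""
    C = np.asarray(C, dtype=float)
    detC = np.linalg.det(C)
    _check_detC(detC)
    J = np.sqrt(detC)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    psi = 0.5 * material.mu * (J ** (-2.0 / 3.0) * I1 - 3.0)
    psi = psi + 0.5 * material.bulk * (J - 1.0) ** 2
    if material.kind == "transversely_isotropic" and material.eta:
        I4b = J ** (-2.0 / 3.0) * np.einsum("a,...ab,b->...", material.a0, C, material.a0)
        psi = psi + 0.5 * material.eta * (I4b - 1.0) ** 2
    return psi


def membrane_energy_density(C0: np.ndarray, Cn: np.ndarray, mu: float) -> np.ndarray:
    """Membrane energy whose derivative 2 d(psi)/dCn reproduces :func:`spk_membrane`.

    psi = mu/2 (tr(C0^-1 Cn) + det C0 / det Cn - 3)
    """
    C0 = np.asarray(C0, dtype=float)
    Cn = np.asarray(Cn, dtype=float)
    tr = np.trace(np.linalg.inv(C0) @ Cn, axis1=-2, axis2=-1)
    return 0.5 * mu * (tr + np.linalg.det(C0) / np.linalg.det(Cn) - 3.0)
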