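"""Proper orthogonal decomposition (POD) reduced-order modelling.

The full nodal displacement vector U (3N) is approximated by U = Phi P with
Phi a 3N x M orthonormal mode basis obtained from the left singular vectors
of a matrix of full-model displacement snapshots.  Projecting the
semi-discrete equilibrium onto the basis (with lumped mass M and
mass-proportional damping) and integrating with the central-difference
scheme gives the reduced incremental update

    U_{n+1} = gamma1 Phi Mhat^-1 Phi^T R_eff + gamma2 U_n + gamma3 U_{n-1}

with gamma1 = 2 dt^2/(alpha_D dt + 2), gamma2 = 4/(alpha_D dt + 2),
gamma3 = 1 - gamma2, and Mhat = Phi^T M Phi the reduced mass matrix.
Element internal forces are still evaluated on the full (reconstructed)
displacement field; only the update is reduced, which enlarges the stable
time step by filtering out the stiff high-frequency content.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

__all__ = ["ReducedBasis", "build_pod_basis", "rom_coefficients", "rom_step",
           "save_basis", "load_basis"]


@dataclass
class ReducedBasis:
    """Orthonormal mode basis Phi (3N x M) with reduced mass Mhat (M x M)."""

    Phi: np.ndarray
    M_hat: np.ndarray

    def __post_init__(self):
        self.Phi = np.asarray(self.Phi, float)
        self.M_hat = np.asarray(self.M_hat, float)
        self._cho = scipy.linalg.cho_factor(self.M_hat)

    @property
    def num_modes(self) -> int:
        return self.Phi.shape[1]

    def solve_reduced(self, rhs: np.ndarray) -> np.ndarray:
        """Mhat^-1 rhs via the precomputed Cholesky factorisation."""
        return scipy.linalg.cho_solve(self._cho, rhs)


def build_pod_basis(snapshots: np.ndarray, num_modes: int,
                    masses: np.ndarray) -> ReducedBasis:
    """POD basis from a 3N x K snapshot matrix of full-model solutions.

    Phi holds the first ``num_modes`` left singular vectors (snapshots are
    taken about the U = 0 reference state, no centering); Mhat = Phi^T
    diag(mass) Phi.  Raises if ``num_modes`` exceeds the snapshot rank.
    """
    snapshots = np.asarray(snapshots, float)
    if snapshots.ndim != 2 or snapshots.shape[1] < 1:
        raise ValueError("snapshots must be a 3N x K matrix with K >= 1")
    U, s, _ = np.linalg.svd(snapshots, full_matrices=False)
    tol = max(snapshots.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    rank = int(np.sum(s > tol))
    if num_modes > rank:
        raise ValueError(
            f"requested {num_modes} modes but snapshot rank is {rank}")
    Phi = U[:, :num_modes]
    masses = np.asarray(masses, float).reshape(-1)
    M_hat = Phi.T @ (masses[:, None] * Phi)
    return ReducedBasis(Phi, M_hat)


def rom_coefficients(dt: float, alpha_D: float):
    """(gamma1, gamma2, gamma3) of the reduced central-difference update."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if alpha_D < 0:
        raise ValueError("alpha_D must be non-negative")
    g1 = 2.0 * dt**2 / (alpha_D * dt + 2.0)
    g2 = 4.0 / (alpha_D * dt + 2.0)
    return g1, g2, 1.0 - g2


def rom_step(basis: ReducedBasis, U_now: np.ndarray, U_prev: np.ndarray,
             R_eff: np.ndarray, gammas) -> np.ndarray:
    """One reduced displacement update (exactly the formula above)."""
    g1, g2, g3 = gammas
    red = basis.solve_reduced(basis.Phi.T @ R_eff)
    return g1 * (basis.Phi @ red) + g2 * U_now + g3 * U_prev


def save_basis(basis: ReducedBasis, path):
    """Store the basis as a plain-text matrix (one 3N-row per line pair).

    Layout: a header "3N M", then Phi row-wise, then Mhat row-wise.
    """
    n, m = basis.Phi.shape
    with open(path, "w") as fh:
        fh.write(f"{n} {m}\n")
        np.savetxt(fh, basis.Phi)
        np.savetxt(fh, basis.M_hat)


def load_basis(path) -> ReducedBasis:
    with open(path) as fh:
        n, m = (int(t) for t in fh.readline().split())
        data = np.loadtxt(fh)
    Phi = data[:n].reshape(n, m)
    M_hat = data[n:].reshape(m, m)
    return ReducedBasis(Phi, M_hat)
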