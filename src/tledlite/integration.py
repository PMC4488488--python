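"""Explicit time-ODE solvers: central difference (CDM) and explicit Newmark.

Both integrate M U'' + D U' + R_int(U) = R_ext with a lumped (diagonal)
mass matrix and mass-proportional damping D = alpha_D * M, advancing nodal
displacements from the effective load R_eff = R_ext - R_int.  Essential
(Dirichlet) boundary conditions are imposed by direct substitution of the
prescribed values after each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IntegratorCoeffs",
    "KinematicState",
    "cdm_coefficients",
    "cdm_step",
    "newmark_step",
    "apply_dirichlet",
    "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Raised when displacements blow up (time step too large)."""


@dataclass
class IntegratorCoeffs:
    """Precomputed per-DOF central-difference update diagonals.

    U_next = A * R_eff + B * U_now + C * U_prev, with
      A = 1 / (D/(2 dt) + M/dt^2)
      B = (2 M / dt^2) * A
      C = (D/(2 dt) - M/dt^2) * A
    For D = alpha_D M the identity B + C = 1 holds per DOF.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    dt: float
    alpha_D: float


@dataclass
class KinematicState:
    """Displacement history (and Newmark velocity/acceleration), 3N flat."""

    U_next: np.ndarray
    U_now: np.ndarray
    U_prev: np.ndarray
    v: np.ndarray = field(default=None)
    a: np.ndarray = field(default=None)

    @classmethod
    def zeros(cls, ndof: int, newmark: bool = False) -> "KinematicState":
        z = lambda: np.zeros(ndof)
        return cls(z(), z(), z(), v=z() if newmark else None,
                   a=z() if newmark else None)

    def shift(self):
        """Rotate history after a step: next -> now -> prev."""
        self.U_prev, self.U_now, self.U_next = self.U_now, self.U_next, self.U_prev


def cdm_coefficients(M: np.ndarray, dt: float, alpha_D: float) -> IntegratorCoeffs:
    """Central-difference diagonals for lumped mass M (per DOF, kg)."""
    M = np.asarray(M, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if alpha_D < 0:
        raise ValueError("alpha_D must be non-negative")
    if np.any(M <= 0):
        raise ValueError("all lumped masses must be positive")
    D = alpha_D * M
    denom = D / (2.0 * dt) + M / dt**2
    A = 1.0 / denom
    B = (2.0 * M / dt**2) * A
    C = (D / (2.0 * dt) - M / dt**2) * A
    return IntegratorCoeffs(A, B, C, dt, alpha_D)


def _check_finite(U, step=None, scale=None):
    bad = not np.all(np.isfinite(U))
    if not bad and scale is not None:
        bad = np.max(np.abs(U)) > 1e6 * scale
    if bad:
        at = f" at step {step}" if step is not None else ""
        raise DivergenceError(
            f"displacement diverged{at} (max |U| = {np.max(np.abs(U)):.3e}); "
            "the time step is likely above the stable limit"
        )


def cdm_step(coeffs: IntegratorCoeffs, state: KinematicState,
             R_eff: np.ndarray, step: int = None, scale: float = None):
    """One central-difference update; writes U_next and shifts the history."""
    state.U_next = coeffs.A * R_eff + coeffs.B * state.U_now + coeffs.C * state.U_prev
    _check_finite(state.U_next, step, scale)
    state.shift()
    return state


def newmark_step(state: KinematicState, M: np.ndarray, alpha_D: float,
                 dt: float, R_eff: np.ndarray, step: int = None,
                 scale: float = None):
    """One explicit Newmark update (numerical velocity and acceleration).

    a_n = (M^-1 R_eff - alpha_D v_{n-1} - (alpha_D dt/2) a_{n-1}) / (1 + alpha_D dt/2)
    v_n = v_{n-1} + dt/2 (a_n + a_{n-1})
    U_{n+1} = U_n + dt v_n + dt^2/2 a_n

    R_eff is evaluated at the current configuration U_n.
    """
    a_new = (R_eff / M - alpha_D * state.v - 0.5 * alpha_D * dt * state.a) \
        / (1.0 + 0.5 * alpha_D * dt)
    v_new = state.v + 0.5 * dt * (a_new + state.a)
    state.U_next = state.U_now + dt * v_new + 0.5 * dt**2 * a_new
    _check_finite(state.U_next, step, scale)
    state.a = a_new
    state.v = v_new
    state.shift()
    return state


def apply_dirichlet(state: KinematicState, dof_indices: np.ndarray,
                    values: np.ndarray):
    """Overwrite constrained components of the freshly computed displacement.

    Call after :func:`cdm_step`/:func:`newmark_step` (the new displacement
    then lives in ``U_now``).  Unconstrained components are untouched.
    """
    if len(dof_indices):
        state.U_now[dof_indices] = values
    return state


def critical_time_step(min_edge: float, bulk: float, mu: float,
                       density: float) -> float:
    """Advisory critical step dt_cr ~ L_min / c with c = sqrt((K + 4 mu/3)/rho).

    Logged, not enforced: the user-supplied dt governs the run.
    """
    c = np.sqrt((bulk + 4.0 * mu / 3.0) / density)
    return float(min_edge / c)
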