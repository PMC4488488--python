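"""Simulation orchestration: the explicit time-stepping main loop.

Per step the solver (i) assembles internal nodal forces in one vectorised
pass over all elements (deformation gradient -> C -> stress -> element
forces, plus hourglass and nodal-averaged-pressure handling where
applicable, plus membrane contributions), (ii) forms the effective load
R_eff = R_ext - R_int, (iii) computes a predictor displacement with the
chosen explicit integrator, (iv) resolves contacts (mesh-based response
forces followed by a second integrator evaluation, then analytic-surface
displacement corrections), and (v) substitutes essential boundary values.
Summation order is fixed, so identical inputs give bit-identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from . import contact as ct
from .elements import (anp_internal_forces, deformation_gradient,
                       hourglass_energy, hourglass_forces, precompute)
from .integration import (DivergenceError, KinematicState, apply_dirichlet,
                          cdm_coefficients, critical_time_step)
from .materials import strain_energy_density
from .membrane import (membrane_internal_forces, membrane_precompute,
                       membrane_strain_energy)
from .mesh import Mesh, extract_surface
from .model import Model, constraint_value_at
from .rom import ReducedBasis, rom_coefficients, rom_step

__all__ = ["Simulator", "SimulationResult", "run_simulation",
           "assemble_internal_forces", "compute_effective_loads"]

log = logging.getLogger("tledlite")


@dataclass
class SimulationResult:
    """Final displacement field plus requested histories and diagnostics."""

    u: np.ndarray
    times: Dict[str, List[float]] = field(default_factory=dict)
    histories: Dict[str, List[np.ndarray]] = field(default_factory=dict)
    snapshots: Optional[np.ndarray] = None
    kinetic_energy: float = 0.0
    strain_energy: float = 0.0
    steps_completed: int = 0


def compute_effective_loads(R_ext: np.ndarray, R_int: np.ndarray,
                            contact_forces: np.ndarray = None) -> np.ndarray:
    """R_eff = R_ext - R_int (+ contact response forces)."""
    R = R_ext - R_int
    if contact_forces is not None:
        R = R + contact_forces
    return R


def assemble_internal_forces(mesh: Mesh, pre, element_sets, U3: np.ndarray,
                             kappa: float = 0.075) -> np.ndarray:
    """Global (N, 3) internal force vector for nodal displacements U3."""
    R = np.zeros((mesh.num_nodes, 3))
    f = _element_forces(mesh, pre, element_sets, U3, kappa)
    np.add.at(R, mesh.elements.ravel(), f.reshape(-1, 3))
    return R


def _stress_fn(element_sets, num_elements):
    def fn(C):
        S = np.zeros_like(C)
        for ids, mat in element_sets:
            S[ids] = mat.spk(C[ids])
        return S
    return fn


def _per_element_mu(element_sets, num_elements):
    mu = np.zeros(num_elements)
    for ids, mat in element_sets:
        mu[ids] = mat.mu
    return mu


def _element_forces(mesh, pre, element_sets, U3, kappa):
    Ue = U3[mesh.elements]
    F = deformation_gradient(pre, Ue)
    if mesh.element_type == "T4ANP":
        f, _ = anp_internal_forces(mesh, pre, F,
                                   _stress_fn(element_sets, mesh.num_elements))
        return f
    C = np.einsum("eab,eac->ebc", F, F)
    S = _stress_fn(element_sets, mesh.num_elements)(C)
    P = F @ S
    f = np.einsum("e,eab,eib->eia", pre.volume, P, pre.dhdX)
    if mesh.element_type == "H8" and kappa != 0.0:
        f = f + hourglass_forces(pre, Ue, _per_element_mu(element_sets,
                                                          mesh.num_elements), kappa)
    return f


class Simulator:
    """Construct-from-model simulator (precomputation in the constructor).

    Parameters
    ----------
    model : Model
    dt : float, optional
        Override the model's time step (e.g. for enlarged-step ROM runs).
    reduced_basis : ReducedBasis, optional
        Run the POD-reduced displacement update instead of the full one.
    record_snapshots_every : int
        If > 0, store the full displacement vector every so many steps
        (for POD training); retrievable from the result as a 3N x K matrix.
    log_every : int
        If > 0, log progress (max displacement, kinetic energy).
    """

    def __init__(self, model: Model, dt: float = None,
                 reduced_basis: ReducedBasis = None,
                 record_snapshots_every: int = 0, log_every: int = 0,
                 track_contact_penetration: bool = False):
        self.model = model
        self.mesh = model.mesh
        sys = model.system
        self.dt = float(dt) if dt is not None else sys.dt
        self.num_steps = int(np.ceil(sys.total_time / self.dt - 1e-12))
        self.basis = reduced_basis
        self.record_snapshots_every = record_snapshots_every
        self.log_every = log_every
        self.track_contact_penetration = track_contact_penetration
        #: per contact-active step: (step, max penetration before response,
        #: max penetration after the second integrator evaluation)
        self.contact_penetration_log = []

        mats = model.element_materials()
        densities = np.array([m.density for m in mats])
        self.pre, self.masses = precompute(self.mesh, densities)
        self.kappa = sys.hourglass_kappa

        # membrane elements (coupled to the solid node numbering)
        self.membranes = []
        for ss in model.shell_sets:
            for tri in ss.triangles:
                elem, mm = membrane_precompute(tri, self.mesh.nodes[tri],
                                               ss.thickness, ss.material.density)
                self.membranes.append((elem, ss.material.mu))
                np.add.at(self.masses, tri, mm)

        self._setup_constraints()
        self.coeffs = cdm_coefficients(
            np.repeat(self.masses, 3), self.dt, sys.alpha_D)
        if self.basis is not None:
            self.gammas = rom_coefficients(self.dt, sys.alpha_D)
        self.contact_surface = None
        if model.deformable_contact:
            self.contact_surface = extract_surface(self.mesh)
            if model.contact_margin > 0:
                self.contact_margin = model.contact_margin
            else:
                edges = self.contact_surface.edges()
                el = np.linalg.norm(self.mesh.nodes[edges[:, 0]]
                                    - self.mesh.nodes[edges[:, 1]], axis=1)
                self.contact_margin = 0.1 * float(el.min())
        self.scale = max(self.mesh.diameter(), 1.0e-12)

        mu_max = max(m.mu for m in mats)
        bulk_max = max(m.bulk for m in mats)
        rho_min = min(m.density for m in mats)
        edge = self._min_edge_length()
        dt_cr = critical_time_step(edge, bulk_max, mu_max, rho_min)
        log.info("advisory critical time step ~ %.3e s (dt = %.3e s)",
                 dt_cr, self.dt)

    def _min_edge_length(self) -> float:
        conn = self.mesh.elements
        X = self.mesh.nodes[conn]
        k = conn.shape[1]
        d = []
        for i in range(k):
            for j in range(i + 1, k):
                d.append(np.linalg.norm(X[:, i] - X[:, j], axis=1).min())
        return float(min(d)) if d else 0.0

    # -- constraints --------------------------------------------------------

    def _setup_constraints(self):
        m = self.model
        dofs = []
        specs = []  # (dof slice start, constraint, axis list)
        for c in m.constraints:
            if c.kind in ("fixed_disp", "prescribed_disp"):
                for ax in c.dof_mask:
                    idx = 3 * c.node_ids + ax
                    specs.append((len(dofs), c, ax, len(idx)))
                    dofs.extend(idx.tolist())
        self.dirichlet_dofs = np.asarray(dofs, dtype=np.int64)
        self._dirichlet_specs = specs

    def _dirichlet_values(self, t: float) -> np.ndarray:
        vals = np.zeros(len(self.dirichlet_dofs))
        T = self.model.system.total_time
        for start, c, ax, n in self._dirichlet_specs:
            if c.kind == "fixed_disp":
                continue  # zeros
            v = constraint_value_at(c, t, T)[:, ax]
            vals[start:start + n] = v
        return vals

    def external_loads(self, t: float) -> np.ndarray:
        """(N, 3) external nodal loads at time t (forces + gravity)."""
        R = np.zeros((self.mesh.num_nodes, 3))
        T = self.model.system.total_time
        for c in self.model.constraints:
            if c.kind == "force":
                v = constraint_value_at(c, t, T) / max(len(c.node_ids), 1)
                R[c.node_ids] += v
            elif c.kind == "gravity":
                g = constraint_value_at(c, t, T)
                R += self.masses[:, None] * g
        return R

    # -- energies ------------------------------------------------------------

    def strain_energy(self, U3: np.ndarray) -> float:
        """Total hyperelastic energy sum_e V psi (+ hourglass + membranes)."""
        mesh = self.mesh
        Ue = U3[mesh.elements]
        F = deformation_gradient(self.pre, Ue)
        if mesh.element_type == "T4ANP":
            from .elements import anp_modified_deformation
            Ft, _, _, _ = anp_modified_deformation(mesh, self.pre, F)
            C = np.einsum("eab,eac->ebc", Ft, Ft)
        else:
            C = np.einsum("eab,eac->ebc", F, F)
        E = 0.0
        for ids, mat in self.model.element_sets:
            E += float(np.sum(self.pre.volume[ids]
                              * strain_energy_density(C[ids], mat)))
        if mesh.element_type == "H8" and self.kappa != 0.0:
            E += float(np.sum(hourglass_energy(
                self.pre, Ue, _per_element_mu(self.model.element_sets,
                                              mesh.num_elements), self.kappa)))
        x = mesh.nodes + U3
        for elem, mu in self.membranes:
            E += membrane_strain_energy(elem, x[elem.node_ids], mu)
        return E

    def kinetic_energy(self, state: KinematicState) -> float:
        v = (state.U_now - state.U_prev) / self.dt
        return 0.5 * float(np.repeat(self.masses, 3) @ (v * v))

    # -- assembly ------------------------------------------------------------

    def internal_forces(self, U3: np.ndarray) -> np.ndarray:
        R = assemble_internal_forces(self.mesh, self.pre,
                                     self.model.element_sets, U3, self.kappa)
        if self.membranes:
            x = self.mesh.nodes + U3
            for elem, mu in self.membranes:
                R[elem.node_ids] += membrane_internal_forces(
                    elem, x[elem.node_ids], mu)
        return R

    # -- main loop -----------------------------------------------------------

    def _predict(self, state, R_eff_flat):
        """Predictor displacement (flat 3N) without committing state."""
        if self.basis is not None:
            return rom_step(self.basis, state.U_now, state.U_prev,
                            R_eff_flat, self.gammas)
        c = self.coeffs
        if self.model.system.integrator == "CDM":
            return c.A * R_eff_flat + c.B * state.U_now + c.C * state.U_prev
        # explicit Newmark predictor
        M = np.repeat(self.masses, 3)
        aD = self.model.system.alpha_D
        dt = self.dt
        a_new = (R_eff_flat / M - aD * state.v - 0.5 * aD * dt * state.a) \
            / (1.0 + 0.5 * aD * dt)
        v_new = state.v + 0.5 * dt * (a_new + state.a)
        return state.U_now + dt * v_new + 0.5 * dt**2 * a_new, a_new, v_new

    def simulate(self) -> SimulationResult:
        """Run all time steps; returns the final displacement and histories."""
        mesh = self.mesh
        ndof = 3 * mesh.num_nodes
        newmark = (self.model.system.integrator == "NewmarkExplicit"
                   and self.basis is None)
        state = KinematicState.zeros(ndof, newmark=newmark)
        result = SimulationResult(u=np.zeros((mesh.num_nodes, 3)))
        for var, _ in self.model.outputs:
            result.times[var] = []
            result.histories[var] = []
        snapshots = []
        dt = self.dt
        n_steps = self.num_steps
        rigid = self.model.contact_plates or self.model.contact_cylinders
        T = self.model.system.total_time

        try:
            for step in range(1, n_steps + 1):
                t_new = min(step * dt, T)
                U3 = state.U_now.reshape(-1, 3)
                R_int = self.internal_forces(U3)
                R_ext = self.external_loads(t_new)
                R_eff = compute_effective_loads(R_ext, R_int).ravel()

                pred = self._predict(state, R_eff)
                if newmark:
                    U_pred, a_new, v_new = pred
                else:
                    U_pred = pred

                # mesh-based contact: response forces + second evaluation
                if self.contact_surface is not None:
                    x = mesh.nodes + U_pred.reshape(-1, 3)
                    events = ct.detect_contacts(
                        x, self.contact_surface, margin=self.contact_margin)
                    if events:
                        fc = ct.accumulate_response_forces(
                            events, self.masses, dt, mesh.num_nodes)
                        R_eff = R_eff + fc.ravel()
                        pred = self._predict(state, R_eff)
                        if newmark:
                            U_pred, a_new, v_new = pred
                        else:
                            U_pred = pred
                        if self.track_contact_penetration:
                            pen0 = max(-ev.g for ev in events)
                            x2 = mesh.nodes + U_pred.reshape(-1, 3)
                            ev2 = ct.detect_contacts(
                                x2, self.contact_surface,
                                margin=self.contact_margin)
                            pen1 = max((-e.g for e in ev2), default=0.0)
                            self.contact_penetration_log.append(
                                (step, pen0, pen1))

                # analytic rigid surfaces: displacement correction
                if rigid:
                    Uc = U_pred.reshape(-1, 3).copy()
                    s = t_new / T
                    x = mesh.nodes + Uc
                    for surf in (list(self.model.contact_plates)
                                 + list(self.model.contact_cylinders)):
                        g, n, active = surf.gap(x, s)
                        pen = active & (g < 0)
                        if np.any(pen):
                            ids = np.nonzero(pen)[0]
                            Uc = ct.apply_displacement_correction(
                                Uc, ids, g[ids], n[ids])
                            x = mesh.nodes + Uc
                    U_pred = Uc.ravel()

                if not np.all(np.isfinite(U_pred)) or \
                        np.max(np.abs(U_pred)) > 1e6 * self.scale:
                    raise DivergenceError(
                        f"displacement diverged at step {step} "
                        f"(max |U| = {np.max(np.abs(U_pred)):.3e}); "
                        "the time step is likely above the stable limit")

                state.U_next = U_pred
                if newmark:
                    state.a, state.v = a_new, v_new
                state.shift()
                apply_dirichlet(state, self.dirichlet_dofs,
                                self._dirichlet_values(t_new))

                result.steps_completed = step
                if self.record_snapshots_every and \
                        step % self.record_snapshots_every == 0:
                    snapshots.append(state.U_now.copy())
                for var, freq in self.model.outputs:
                    if step % freq == 0 or step == n_steps:
                        result.times[var].append(t_new)
                        if var == "U":
                            result.histories[var].append(
                                state.U_now.reshape(-1, 3).copy())
                        else:
                            result.histories[var].append(
                                self.internal_forces(
                                    state.U_now.reshape(-1, 3)))
                if self.log_every and step % self.log_every == 0:
                    log.info("step %d/%d  max|U| = %.4e  KE = %.4e",
                             step, n_steps,
                             float(np.max(np.abs(state.U_now))),
                             self.kinetic_energy(state))
        except DivergenceError:
            result.u = state.U_now.reshape(-1, 3).copy()
            if snapshots:
                result.snapshots = np.array(snapshots).T
            raise

        result.u = state.U_now.reshape(-1, 3).copy()
        if snapshots:
            result.snapshots = np.array(snapshots).T
        result.kinetic_energy = self.kinetic_energy(state)
        result.strain_energy = self.strain_energy(result.u)
        return result


def run_simulation(model: Model, **kwargs) -> SimulationResult:
    """Convenience wrapper: construct a :class:`Simulator` and run it."""
    return Simulator(model, **kwargs).simulate()
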