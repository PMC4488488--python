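"""Canonical simulation scenarios used for validation.

These builders define the package's reference study conditions — a
quasi-static uniaxial stretch of a unit neo-Hookean cube, a hexahedral
cantilever beam for reduced-order-model validation, and a two-cube
compression fixture for mesh-based contact — with all geometry generated
programmatically.  The same scenarios back the test-suite and the
acceptance script.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .fixtures import make_box_mesh, merge_meshes
from .materials import Material, spk_neo_hookean
from .model import Constraint, Model, SystemParams
from .rom import build_pod_basis
from .solver import Simulator

__all__ = [
    "uniaxial_stretch_model", "uniaxial_cauchy_stress_oracle",
    "cantilever_model", "run_rom_study", "two_cube_contact_model",
]


def uniaxial_cauchy_stress_oracle(stretch: float, mu: float, bulk: float):
    """Closed-form (root-found) uniaxial Cauchy stress for the NH solid.

    Finds the lateral stretch m solving the traction-free condition
    S_22(diag(stretch^2, m^2, m^2)) = 0, then returns (sigma_axial, m).
    """
    def lateral_residual(m):
        C = np.diag([stretch**2, m**2, m**2])
        return spk_neo_hookean(C, mu, bulk)[1, 1]

    m = brentq(lateral_residual, 0.2, 5.0, xtol=1e-14)
    F = np.diag([stretch, m, m])
    S = spk_neo_hookean(F.T @ F, mu, bulk)
    sigma = F @ S @ F.T / np.linalg.det(F)
    return float(sigma[0, 0]), float(m)


def uniaxial_stretch_model(element_type: str = "H8", n: int = 2,
                           stretch: float = 0.2, mu: float = 1e3,
                           bulk: float = 1e6, density: float = 1000.0,
                           dt: float = 5e-3, total_time: float = 14.0,
                           ramp_time: float = 3.0,
                           alpha_D: float = 10.0) -> Model:
    """Unit cube under prescribed axial (z) stretch with symmetry BCs.

    Symmetry faces x=0, y=0, z=0 are fixed in their normal direction, the
    z=1 face is ramp-displaced to the target engineering strain and then
    held while mass-proportional damping (chosen near critical for the
    dominant relaxation mode) settles the lateral contraction; the lateral
    faces are traction-free, so the settled state is homogeneous uniaxial
    stress.
    """
    mesh = make_box_mesh(n, n, n, 1.0, 1.0, 1.0, element_type)
    mat = Material("neo_hookean", mu=mu, bulk=bulk, density=density)
    X = mesh.nodes
    eps = 1e-9

    def face(mask):
        return np.nonzero(mask)[0]

    constraints = [
        Constraint("fixed_disp", face(X[:, 0] < eps), [0, 0, 0], (0,)),
        Constraint("fixed_disp", face(X[:, 1] < eps), [0, 0, 0], (1,)),
        Constraint("fixed_disp", face(X[:, 2] < eps), [0, 0, 0], (2,)),
        Constraint("prescribed_disp", face(X[:, 2] > 1 - eps),
                   [0, 0, stretch], (2,), "ramp", ramp_time),
    ]
    system = SystemParams(dt=dt, total_time=total_time, alpha_D=alpha_D)
    return Model(mesh, [(np.arange(mesh.num_elements), mat)], system,
                 constraints)


# ---------------------------------------------------------------------------
# Cantilever ROM study
# ---------------------------------------------------------------------------

#: training tip-load vectors (N, total over the tip face): distinct ramped
#: tip loads spanning both bending planes so the POD basis is filled with
#: smooth structural modes
TRAIN_TIP_LOADS = ((4e-3, 0.0), (0.0, 4e-3), (3e-3, 3e-3), (2e-3, -2e-3))


def cantilever_model(tip_load_xy, dt: float, total_time: float = 40.0,
                     ramp_time: float = 0.5, alpha_D: float = 0.2,
                     mu: float = 1e3, bulk: float = 1e5,
                     density: float = 1000.0) -> Model:
    """2x2x10-element hexahedral beam (0.1 x 0.1 x 1 m), clamped at z=0,
    with a transverse tip load ramped over ``ramp_time`` seconds."""
    mesh = make_box_mesh(2, 2, 10, 0.1, 0.1, 1.0, "H8")
    mat = Material("neo_hookean", mu=mu, bulk=bulk, density=density)
    X = mesh.nodes
    eps = 1e-9
    fixed = np.nonzero(X[:, 2] < eps)[0]
    tip = np.nonzero(X[:, 2] > 1.0 - eps)[0]
    fx, fy = tip_load_xy
    constraints = [
        Constraint("fixed_disp", fixed, [0, 0, 0], (0, 1, 2)),
        Constraint("force", tip, [fx, fy, 0.0], (0, 1, 2), "ramp", ramp_time),
    ]
    system = SystemParams(dt=dt, total_time=total_time, alpha_D=alpha_D)
    return Model(mesh, [(np.arange(mesh.num_elements), mat)], system,
                 constraints)


def run_rom_study(held_out_load=(2.8e-3, 1.4e-3), num_modes: int = 10,
                  dt_full: float = 2e-3, dt_factor: float = 10.0,
                  snapshot_every: int = 50, rng=None):
    """Train a POD basis on the cantilever, run the reduced model at an
    enlarged time step on a held-out load, and measure its error.

    Four full central-difference runs at the training tip loads provide
    displacement snapshots; the reduced update then integrates the
    held-out-load problem with the time step enlarged by ``dt_factor``.
    If ``rng`` is given, the held-out load is drawn from within the
    training hull instead of the default.

    Returns a dict with the relative L2 error of the final displacement
    (fraction, not %), the tip deflection, and the problem sizes.
    """
    if rng is not None:
        ang = rng.uniform(np.deg2rad(5.0), np.deg2rad(40.0))
        mag = rng.uniform(2.5e-3, 3.5e-3)
        held_out_load = (mag * np.cos(ang), mag * np.sin(ang))

    snaps = []
    for load in TRAIN_TIP_LOADS:
        sim = Simulator(cantilever_model(load, dt_full),
                        record_snapshots_every=snapshot_every)
        snaps.append(sim.simulate().snapshots)
    snapshots = np.concatenate(snaps, axis=1)

    sim_full = Simulator(cantilever_model(held_out_load, dt_full))
    full = sim_full.simulate()
    basis = build_pod_basis(snapshots, num_modes,
                            np.repeat(sim_full.masses, 3))
    rom = Simulator(cantilever_model(held_out_load, dt_full * dt_factor),
                    reduced_basis=basis).simulate()
    err = np.linalg.norm(rom.u - full.u) / np.linalg.norm(full.u)
    return {
        "relative_error": float(err),
        "tip_deflection": float(np.linalg.norm(
            full.u[sim_full.mesh.nodes[:, 2] > 1 - 1e-9].mean(axis=0))),
        "num_nodes": sim_full.mesh.num_nodes,
        "num_snapshots": snapshots.shape[1],
        "held_out_load": tuple(float(v) for v in held_out_load),
        "basis": basis,
        "full_result": full,
        "rom_result": rom,
    }


# ---------------------------------------------------------------------------
# Two-cube contact fixture
# ---------------------------------------------------------------------------

def two_cube_contact_model(gap: float = 0.02, press: float = 0.08,
                           dt: float = 0.02, total_time: float = 3.0,
                           ramp_time: float = 2.0,
                           alpha_D: float = 10.0) -> Model:
    """Two stacked unit cubes separated by ``gap``; the upper cube's top
    face is pressed down by ``press`` so the bodies collide and transmit
    load through mesh-based contact."""
    bottom = make_box_mesh(2, 2, 2, 1, 1, 1, "H8")
    top = make_box_mesh(2, 2, 2, 1, 1, 1, "H8", origin=(0, 0, 1 + gap))
    mesh = merge_meshes(bottom, top)
    mat = Material("neo_hookean", mu=1e3, bulk=1e4, density=1000.0)
    X = mesh.nodes
    eps = 1e-9
    base = np.nonzero(X[:, 2] < eps)[0]
    press_face = np.nonzero(X[:, 2] > 2 + gap - eps)[0]
    constraints = [
        Constraint("fixed_disp", base, [0, 0, 0], (0, 1, 2)),
        Constraint("prescribed_disp", press_face, [0, 0, -press], (2,),
                   "ramp", ramp_time),
    ]
    system = SystemParams(dt=dt, total_time=total_time, alpha_D=alpha_D)
    return Model(mesh, [(np.arange(mesh.num_elements), mat)], system,
                 constraints, deformable_contact=True)
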