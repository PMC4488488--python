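"""Solver orchestration: assembly, effective loads, full simulations."""

import numpy as np
import pytest

from tledlite import Simulator, make_box_mesh, run_simulation
from tledlite.elements import precompute
from tledlite.integration import DivergenceError
from tledlite.materials import Material
from tledlite.model import Constraint, Model, SystemParams
from tledlite.solver import assemble_internal_forces, compute_effective_loads


MAT = Material("neo_hookean", mu=1e3, bulk=1e5, density=1000)


def simple_model(mesh, constraints=(), dt=1e-3, T=0.01, aD=0.0, **kw):
    sets = [(np.arange(mesh.num_elements), MAT)]
    return Model(mesh, sets, SystemParams(dt=dt, total_time=T, alpha_D=aD),
                 list(constraints), **kw)


class TestAssembly:
    def test_zero_displacement_zero_forces(self, small_box):
        pre, _ = precompute(small_box, 1000.0)
        sets = [(np.arange(small_box.num_elements), MAT)]
        R = assemble_internal_forces(small_box, pre, sets,
                                     np.zeros((small_box.num_nodes, 3)))
        np.testing.assert_allclose(R, 0.0, atol=1e-12)

    def test_rigid_translation_no_forces(self, small_box):
        pre, _ = precompute(small_box, 1000.0)
        sets = [(np.arange(small_box.num_elements), MAT)]
        U = np.tile([0.3, -0.1, 0.7], (small_box.num_nodes, 1))
        R = assemble_internal_forces(small_box, pre, sets, U)
        np.testing.assert_allclose(R, 0.0, atol=1e-9)

    def test_rigid_rotation_forces_at_roundoff(self, small_box):
        from scipy.spatial.transform import Rotation
        Rm = Rotation.from_euler("xyz", [0.3, 0.6, -0.2]).as_matrix()
        pre, _ = precompute(small_box, 1000.0)
        sets = [(np.arange(small_box.num_elements), MAT)]
        U = small_box.nodes @ Rm.T - small_box.nodes
        R = assemble_internal_forces(small_box, pre, sets, U)
        scale = MAT.mu * 1.0  # stress scale x area scale
        assert np.abs(R).max() < 1e-9 * scale

    def test_global_force_sum_zero(self, small_box, rng):
        pre, _ = precompute(small_box, 1000.0)
        sets = [(np.arange(small_box.num_elements), MAT)]
        U = 0.05 * rng.standard_normal((small_box.num_nodes, 3))
        R = assemble_internal_forces(small_box, pre, sets, U)
        assert np.abs(R.sum(axis=0)).max() <= 1e-9 * np.abs(R).max()

    def test_two_element_additivity(self, rng):
        """Assembled forces equal the sum of independently computed
        single-element contributions."""
        from tledlite.mesh import Mesh
        mesh = make_box_mesh(1, 1, 2, 1, 1, 2, "H8")
        pre, _ = precompute(mesh, 1000.0)
        sets = [(np.arange(2), MAT)]
        U = 0.03 * rng.standard_normal((mesh.num_nodes, 3))
        R = assemble_internal_forces(mesh, pre, sets, U)
        R_ref = np.zeros_like(R)
        for e in range(2):
            sub = Mesh(mesh.nodes, mesh.elements[e:e + 1], "H8")
            pre1, _ = precompute(sub, 1000.0)
            R1 = assemble_internal_forces(sub, pre1, [(np.array([0]), MAT)],
                                          U)
            R_ref += R1
        np.testing.assert_allclose(R, R_ref, rtol=1e-12, atol=1e-12)


class TestEffectiveLoads:
    def test_zero_inputs(self):
        z = np.zeros(6)
        np.testing.assert_array_equal(compute_effective_loads(z, z), z)

    def test_difference_without_contact(self, rng):
        a, b = rng.standard_normal((2, 9))
        np.testing.assert_allclose(compute_effective_loads(a, b), a - b)

    def test_linearity_with_contact(self, rng):
        a, b, c = rng.standard_normal((3, 9))
        np.testing.assert_allclose(compute_effective_loads(a, b, c),
                                   a - b + c)


class TestSimulation:
    def test_no_loads_stays_at_rest(self, small_box):
        res = run_simulation(simple_model(small_box))
        np.testing.assert_array_equal(res.u, 0.0)

    def test_deterministic_bit_identical(self):
        mesh = make_box_mesh(2, 2, 2, 1, 1, 1, "T4")
        base = np.nonzero(mesh.nodes[:, 2] < 1e-9)[0]
        cons = [Constraint("fixed_disp", base, [0, 0, 0], (0, 1, 2)),
                Constraint("gravity", np.arange(mesh.num_nodes),
                           [0, 0, -9.81], (0, 1, 2), "ramp")]
        m = simple_model(mesh, cons, dt=2e-3, T=0.1, aD=5.0)
        u1 = run_simulation(m).u
        u2 = run_simulation(m).u
        assert np.array_equal(u1, u2)

    def test_gravity_external_loads_are_m_g(self):
        mesh = make_box_mesh(1, 1, 1, 1, 1, 1, "H8")
        cons = [Constraint("gravity", np.arange(8), [0, 0, -10.0],
                           (0, 1, 2), "step")]
        sim = Simulator(simple_model(mesh, cons))
        R = sim.external_loads(1.0)
        np.testing.assert_allclose(R[:, 2], -10.0 * sim.masses)

    def test_force_constraint_split_equally(self):
        mesh = make_box_mesh(1, 1, 1, 1, 1, 1, "H8")
        cons = [Constraint("force", [0, 1, 2, 3], [12.0, 0, 0],
                           (0, 1, 2), "step")]
        sim = Simulator(simple_model(mesh, cons))
        R = sim.external_loads(1.0)
        np.testing.assert_allclose(R[:4, 0], 3.0)
        np.testing.assert_allclose(R[4:, 0], 0.0)

    def test_free_body_momentum_conserved_under_no_load(self, rng):
        """Internal forces of a free body sum to zero, so the centre of
        mass stays put over the whole run (momentum conservation)."""
        mesh = make_box_mesh(2, 2, 2, 1, 1, 1, "T4")
        m = simple_model(mesh, [], dt=2e-3, T=0.05)
        res = run_simulation(m)
        np.testing.assert_array_equal(res.u, 0.0)

    def test_constrained_dofs_match_prescription_exactly(self):
        mesh = make_box_mesh(1, 1, 1, 1, 1, 1, "H8")
        top = np.nonzero(mesh.nodes[:, 2] > 1 - 1e-9)[0]
        bot = np.nonzero(mesh.nodes[:, 2] < 1e-9)[0]
        cons = [Constraint("fixed_disp", bot, [0, 0, 0], (0, 1, 2)),
                Constraint("prescribed_disp", top, [0, 0, -0.05], (2,),
                           "ramp")]
        m = simple_model(mesh, cons, dt=1e-3, T=0.1, aD=10.0)
        res = run_simulation(m)
        # at the final step the ramp is complete: exact substitution
        np.testing.assert_array_equal(res.u[top, 2], -0.05)
        np.testing.assert_array_equal(res.u[bot], 0.0)

    def test_divergence_reports_step(self):
        mesh = make_box_mesh(1, 1, 1, 1, 1, 1, "H8")
        top = np.nonzero(mesh.nodes[:, 2] > 1 - 1e-9)[0]
        bot = np.nonzero(mesh.nodes[:, 2] < 1e-9)[0]
        cons = [Constraint("fixed_disp", bot, [0, 0, 0], (0, 1, 2)),
                Constraint("prescribed_disp", top, [0, 0, -0.5], (2,),
                           "step")]
        # dt far above the stable limit
        m = simple_model(mesh, cons, dt=0.5, T=50.0)
        with pytest.raises(DivergenceError, match="step"):
            run_simulation(m)

    def test_newmark_tracks_cdm(self):
        mesh = make_box_mesh(1, 1, 2, 0.5, 0.5, 1.0, "H8")
        bot = np.nonzero(mesh.nodes[:, 2] < 1e-9)[0]
        cons = [Constraint("fixed_disp", bot, [0, 0, 0], (0, 1, 2)),
                Constraint("gravity", np.arange(mesh.num_nodes),
                           [0, 0, -5.0], (0, 1, 2), "ramp")]
        m_cdm = simple_model(mesh, cons, dt=1e-3, T=0.2, aD=2.0)
        m_nm = Model(mesh, m_cdm.element_sets,
                     SystemParams(dt=1e-3, total_time=0.2, alpha_D=2.0,
                                  integrator="NewmarkExplicit"), cons)
        u1 = run_simulation(m_cdm).u
        u2 = run_simulation(m_nm).u
        scale = max(np.abs(u1).max(), 1e-12)
        assert np.abs(u1 - u2).max() < 0.02 * scale

    def test_output_history_frequency_rule(self, small_box):
        bot = np.nonzero(small_box.nodes[:, 2] < 1e-9)[0]
        cons = [Constraint("fixed_disp", bot, [0, 0, 0], (0, 1, 2)),
                Constraint("gravity", np.arange(small_box.num_nodes),
                           [0, 0, -1.0], (0, 1, 2), "ramp")]
        m = simple_model(small_box, cons, dt=1e-3, T=0.025)
        m.outputs.append(("U", 10))
        res = run_simulation(m)
        # 25 steps at frequency 10 -> steps 10, 20 and the final step 25
        assert len(res.histories["U"]) == 3
        np.testing.assert_allclose(res.times["U"], [0.010, 0.020, 0.025])

    def test_skinned_cube_stiffer_than_bare(self):
        """Wrapping the solid in a membrane adds to R_int: compressing a
        skinned cube yields a different (smaller-lateral-bulge) final state
        than the bare cube."""
        from tledlite.model import ShellElementSet
        mesh = make_box_mesh(1, 1, 1, 1, 1, 1, "H8")
        top = np.nonzero(mesh.nodes[:, 2] > 1 - 1e-9)[0]
        bot = np.nonzero(mesh.nodes[:, 2] < 1e-9)[0]
        cons = [Constraint("fixed_disp", bot, [0, 0, 0], (2,)),
                Constraint("fixed_disp", [0], [0, 0, 0], (0, 1)),
                Constraint("fixed_disp", [2], [0, 0, 0], (0,)),
                Constraint("prescribed_disp", top, [0, 0, -0.1], (2,),
                           "ramp", 0.3)]
        bare = simple_model(mesh, cons, dt=2e-3, T=1.0, aD=20.0)
        u_bare = run_simulation(bare).u

        from tledlite import extract_surface
        skin_mat = Material("membrane", mu=2e3, density=1000)
        shell = ShellElementSet(skin_mat, 5e-3,
                                extract_surface(mesh).facets, skin=True)
        skinned = simple_model(mesh, cons, dt=2e-3, T=1.0, aD=20.0)
        skinned.shell_sets.append(shell)
        u_skin = run_simulation(skinned).u
        diff = np.abs(u_bare - u_skin).max()
        assert diff > 1e-4 * np.abs(u_bare).max()
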