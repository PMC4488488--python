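"""Contact: analytic gaps and corrections, detection, response forces."""

import numpy as np
import pytest

from tledlite import extract_surface, make_box_mesh
from tledlite.contact import (ContactEvent, CylinderSurface, PlateSurface,
                              apply_displacement_correction, detect_contacts,
                              edge_edge_response, node_facet_response)
from tledlite.fixtures import merge_meshes
from tledlite.mesh import SurfaceMesh


class TestPlate:
    @pytest.fixture
    def plate(self):
        # unit plate through the origin with normal +z
        return PlateSurface([0, 0, 0], [1, 0, 0], [0, 1, 0])

    def test_point_above_no_contact(self, plate):
        g, n, active = plate.gap(np.array([[0.5, 0.5, 0.2]]))
        assert g[0] == pytest.approx(0.2)
        assert active[0]

    def test_penetrating_point_corrected_to_zero_gap(self, plate):
        pts = np.array([[0.5, 0.5, -0.1]])
        g, n, active = plate.gap(pts)
        assert g[0] == pytest.approx(-0.1)
        U = apply_displacement_correction(np.zeros((1, 3)), np.array([0]),
                                          g, n)
        np.testing.assert_allclose(U[0], [0, 0, 0.1])
        g2, _, _ = plate.gap(pts + U)
        assert g2[0] == pytest.approx(0.0, abs=1e-12)

    def test_point_outside_extents_inactive(self, plate):
        _, _, active = plate.gap(np.array([[2.0, 0.5, -0.1]]))
        assert not active[0]

    def test_plate_displacement_ramp(self):
        p = PlateSurface([0, 0, 0], [1, 0, 0], [0, 1, 0],
                         displacement=[0, 0, 0.4])
        g, _, _ = p.gap(np.array([[0.5, 0.5, 0.3]]), s=0.5)
        assert g[0] == pytest.approx(0.1)

    def test_two_independent_corrections(self, plate):
        pts = np.array([[0.2, 0.2, -0.1], [0.8, 0.8, -0.05]])
        g, n, _ = plate.gap(pts)
        U = apply_displacement_correction(np.zeros((2, 3)),
                                          np.array([0, 1]), g, n)
        np.testing.assert_allclose(U[:, 2], [0.1, 0.05])


class TestCylinder:
    def test_interior_point_gap_and_normal(self):
        c = CylinderSurface([0, 0, 0], [0, 0, 1], radius=1.0, length=2.0)
        g, n, active = c.gap(np.array([[0.9, 0.0, 1.0]]))
        assert g[0] == pytest.approx(-0.1)
        np.testing.assert_allclose(n[0], [1, 0, 0])
        assert active[0]

    def test_outside_length_inactive(self):
        c = CylinderSurface([0, 0, 0], [0, 0, 1], radius=1.0, length=2.0)
        _, _, active = c.gap(np.array([[0.5, 0.0, 5.0]]))
        assert not active[0]

    def test_axis_point_uses_fixed_fallback_normal(self):
        c = CylinderSurface([0, 0, 0], [0, 0, 1], radius=1.0, length=2.0)
        g, n, _ = c.gap(np.array([[0.0, 0.0, 1.0]]))
        assert g[0] == pytest.approx(-1.0)
        assert np.linalg.norm(n[0]) == pytest.approx(1.0)
        assert abs(n[0] @ np.array([0, 0, 1.0])) < 1e-12


class TestDetection:
    def test_separated_bodies_no_events(self):
        a = make_box_mesh(1, 1, 1, 1, 1, 1, "H8")
        b = make_box_mesh(1, 1, 1, 1, 1, 1, "H8", origin=(0, 0, 1.5))
        m = merge_meshes(a, b)
        surf = extract_surface(m)
        assert detect_contacts(m.nodes, surf, margin=0.05) == []

    def test_node_below_master_triangle_centroid(self):
        # master triangle + one penetrating free node 0.05 under the plane
        tri = np.array([[0., 0, 0], [1, 0, 0], [0, 1, 0]])
        x = np.vstack([tri, [1 / 3, 1 / 3, -0.05]])
        master = SurfaceMesh(np.array([[0, 1, 2]]), np.array([[0, 0, 1.0]]))
        slave = SurfaceMesh(np.array([[3, 3, 3]]))  # a lone node
        evs = [e for e in detect_contacts(x, master, slave=slave, margin=0.2,
                                          edge_edge=False)]
        assert len(evs) == 1
        ev = evs[0]
        assert ev.kind == "node_facet"
        assert ev.g == pytest.approx(-0.05)
        assert ev.xi == pytest.approx(1 / 3, abs=1e-9)
        assert ev.eta == pytest.approx(1 / 3, abs=1e-9)

    def test_node_outside_silhouette_not_flagged(self):
        # a node just above a cube's top surface but behind the plane of a
        # bulging side facet is outside the body: the closest feature's
        # pseudo-normal sign test must not flag it
        cube = make_box_mesh(1, 1, 1, 1, 1, 1, "H8")
        master = extract_surface(cube)
        x = np.vstack([cube.nodes, [0.5, 1.005, 1.02]])
        slave = SurfaceMesh(np.array([[8, 8, 8]]))
        evs = detect_contacts(x, master, slave=slave, margin=0.3,
                              max_depth=0.3, edge_edge=False)
        assert evs == []

    def test_node_just_inside_face_flagged(self):
        cube = make_box_mesh(1, 1, 1, 1, 1, 1, "H8")
        master = extract_surface(cube)
        x = np.vstack([cube.nodes, [0.5, 0.995, 0.5]])
        slave = SurfaceMesh(np.array([[8, 8, 8]]))
        evs = detect_contacts(x, master, slave=slave, margin=0.3,
                              edge_edge=False)
        assert len(evs) == 1
        assert evs[0].g == pytest.approx(-0.005)

    def test_perpendicular_crossing_edges(self):
        # slave edge crossing the master facet edge at both midpoints,
        # overlapping 0.02 on the inner (-z) side of the master surface
        x = np.array([
            [-1.0, 0, 0], [1.0, 0, 0],          # master edge along x
            [0.0, -2, -0.02], [0.0, 2, -0.02],  # slave edge along y, below
            [0.0, 1, 0.0],                      # third master facet node
        ])
        master = SurfaceMesh(np.array([[0, 1, 4]]))  # facet normal +z
        slave = SurfaceMesh(np.array([[2, 3, 3]]))
        evs = detect_contacts(x, master, slave=slave, margin=0.5,
                              max_depth=0.5)
        ee = [e for e in evs if e.kind == "edge_edge"]
        assert len(ee) == 1
        ev = ee[0]
        assert ev.r == pytest.approx(0.5, abs=1e-9)
        assert ev.q == pytest.approx(0.5, abs=1e-9)
        assert ev.g == pytest.approx(-0.02, abs=1e-9)
        np.testing.assert_allclose(ev.n, [0, 0, 1.0], atol=1e-9)


class TestResponses:
    def make_event(self, xi, eta, g=-0.01):
        return ContactEvent("node_facet", np.int64(0),
                            np.array([1, 2, 3]), g,
                            np.array([0, 0, 1.0]), xi=xi, eta=eta)

    def test_beta_partition(self):
        # m_s = 1, uniform facet masses 3 at the vertex contact point
        ev = self.make_event(0.0, 0.0)
        f_s, f_m = node_facet_response(ev, 1.0, np.array([3.0, 3.0, 3.0]),
                                       dt=0.1)
        # beta_s = m_m/(m_s+m_m) = 3/4: slave force = beta_s m_s |g|/dt^2
        assert f_s[2] == pytest.approx(0.75 * 1.0 * 0.01 / 0.01)

    def test_vertex_contact_all_force_on_vertex(self):
        ev = self.make_event(0.0, 0.0)
        _, f_m = node_facet_response(ev, 1.0, np.array([2.0, 5.0, 7.0]), 0.1)
        assert f_m[1, 2] == 0.0 and f_m[2, 2] == 0.0
        assert f_m[0, 2] < 0  # opposite to the slave push-out

    def test_centroid_gamma_equals_one(self):
        # h = (1/3, 1/3, 1/3): gamma_i = h_i / sum h^2 = 1 for all vertices
        ev = self.make_event(1 / 3, 1 / 3)
        _, f_m = node_facet_response(ev, 1.0, np.array([2.0, 2.0, 2.0]), 0.1)
        # each vertex gets beta_m * m_i * 1 * g / dt^2 along -n
        expected = (1.0 / 3.0) * 2.0 * (-0.01) / 0.01
        np.testing.assert_allclose(f_m[:, 2], expected)

    def test_slave_force_pushes_out_of_master(self):
        ev = self.make_event(0.2, 0.3, g=-0.02)
        f_s, _ = node_facet_response(ev, 1.0, np.ones(3), 0.1)
        assert f_s @ ev.n > 0

    def test_rigid_master_takes_no_force(self):
        ev = self.make_event(0.25, 0.25)
        f_s, f_m = node_facet_response(ev, 1.0, np.ones(3), 0.1,
                                       rigid_master=True)
        np.testing.assert_allclose(f_m, 0.0)
        # beta_s -> 1 in the rigid limit
        assert f_s[2] == pytest.approx(1.0 * 0.01 / 0.01)

    def test_edge_midpoint_gamma_one_and_opposite_forces(self):
        ev = ContactEvent("edge_edge", np.array([0, 1]), np.array([2, 3]),
                          -0.01, np.array([0, 0, 1.0]), r=0.5, q=0.5)
        f_s, f_m = edge_edge_response(ev, np.array([2.0, 2.0]),
                                      np.array([2.0, 2.0]), 0.1)
        # h = (1/2, 1/2): gamma_i = 1; beta_s = beta_m = 1/2
        np.testing.assert_allclose(f_s[:, 2], 0.5 * 2.0 * 0.01 / 0.01)
        np.testing.assert_allclose(f_m[:, 2], -0.5 * 2.0 * 0.01 / 0.01)
        assert np.all(f_s[:, 2] * f_m[:, 2] < 0)

    def test_edge_endpoint_contact_loads_single_endpoint(self):
        ev = ContactEvent("edge_edge", np.array([0, 1]), np.array([2, 3]),
                          -0.01, np.array([0, 0, 1.0]), r=0.5, q=0.0)
        f_s, _ = edge_edge_response(ev, np.array([2.0, 2.0]),
                                    np.array([2.0, 2.0]), 0.1)
        assert f_s[1, 2] == 0.0
        assert f_s[0, 2] > 0


class TestAnalyticContactInSolver:
    def test_cube_rests_on_plate_under_gravity(self):
        """A soft cube dropped onto a rigid plate settles with no node
        below the plate (corrected gaps >= -1e-12)."""
        from tledlite.materials import Material
        from tledlite.model import Constraint, Model, SystemParams
        from tledlite.solver import Simulator
        mesh = make_box_mesh(2, 2, 2, 1, 1, 1, "H8", origin=(0, 0, 0.05))
        mat = Material("neo_hookean", mu=1e3, bulk=1e4, density=1000)
        plate = PlateSurface([-1, -1, 0], [2, -1, 0], [-1, 2, 0])
        cons = [Constraint("gravity", np.arange(mesh.num_nodes),
                           [0, 0, -9.81], (0, 1, 2), "ramp", 0.5)]
        model = Model(mesh, [(np.arange(mesh.num_elements), mat)],
                      SystemParams(dt=5e-3, total_time=2.0, alpha_D=10.0),
                      cons, contact_plates=[plate])
        res = Simulator(model).simulate()
        x = mesh.nodes + res.u
        g, _, active = plate.gap(x)
        assert np.all(g[active] >= -1e-12)
        # the cube actually fell into contact
        assert res.u[:, 2].min() < -0.04


class TestTwoCubeCompression:
    def test_response_reduces_penetration_and_transmits_load(self):
        from tledlite.scenarios import two_cube_contact_model
        from tledlite.solver import Simulator
        model = two_cube_contact_model()
        sim = Simulator(model, track_contact_penetration=True)
        res = sim.simulate()
        log = sim.contact_penetration_log
        assert log, "the cubes never came into contact"
        step, pre, post = max(log, key=lambda t: t[1])
        assert post <= 0.1 * pre
        # load transmitted: the bottom cube is compressed
        X = model.mesh.nodes
        bottom_top = np.abs(X[:, 2] - 1.0) < 1e-9
        assert res.u[bottom_top, 2].mean() < -0.005
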