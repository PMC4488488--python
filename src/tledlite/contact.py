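"""Prediction-correction contact modelling.

Two families of contact are supported, both driven by a predictor
displacement computed with the ordinary explicit update:

* **Analytic master surfaces** (plate, cylinder): the gap function g --
  the signed distance to the master surface, negative on penetration -- is
  evaluated in closed form and penetrating nodes receive the displacement
  correction  du = -g n_m  directly.
* **Mesh-based contact**: node-facet and edge-edge penetrations between
  triangulated surfaces are detected with a brute-force, AABB-prefiltered
  search, and resolved with explicit Lagrange-multiplier response forces
  (Heinstein-style, mass-weighted) that enter the effective load for a
  second evaluation of the integrator formulas.

Rigid masters take the limit beta_s -> 1, beta_m -> 0 (forces act on the
deformable body only).  Friction is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .mesh import SurfaceMesh

__all__ = [
    "PlateSurface", "CylinderSurface", "ContactEvent",
    "analytic_gap", "apply_displacement_correction",
    "detect_contacts", "node_facet_response", "edge_edge_response",
]


@dataclass
class PlateSurface:
    """Rigid rectangular plate: corner ``a`` plus corners ``b``, ``c``
    spanning the edges.  ``displacement`` is the total plate translation
    over the simulation (applied as a linear ramp)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    displacement: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.a = np.asarray(self.a, float).reshape(3)
        self.b = np.asarray(self.b, float).reshape(3)
        self.c = np.asarray(self.c, float).reshape(3)
        self.displacement = np.asarray(self.displacement, float).reshape(3)
        e1 = self.b - self.a
        e2 = self.c - self.a
        n = np.cross(e1, e2)
        ln = np.linalg.norm(n)
        if ln == 0:
            raise ValueError("degenerate contact plate (collinear corners)")
        self._e1, self._e2, self._n = e1, e2, n / ln

    def gap(self, points: np.ndarray, s: float = 1.0):
        """Signed distance along the plate normal at load fraction ``s``.

        Returns (g, n, active): ``active`` marks points whose in-plane
        projection falls within the plate extents.
        """
        points = np.atleast_2d(points)
        a = self.a + s * self.displacement
        rel = points - a
        g = rel @ self._n
        u = (rel @ self._e1) / (self._e1 @ self._e1)
        v = (rel @ self._e2) / (self._e2 @ self._e2)
        active = (u >= 0) & (u <= 1) & (v >= 0) & (v <= 1)
        n = np.broadcast_to(self._n, points.shape)
        return g, n, active


@dataclass
class CylinderSurface:
    """Rigid cylinder (exterior-constraint semantics: nodes are kept
    outside).  ``radius_change`` is the total radius variation over the
    simulation, applied as a linear ramp."""

    origin: np.ndarray
    axis: np.ndarray
    radius: float
    length: float
    radius_change: float = 0.0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float).reshape(3)
        axis = np.asarray(self.axis, float).reshape(3)
        ln = np.linalg.norm(axis)
        if ln == 0 or self.radius <= 0:
            raise ValueError("cylinder needs a nonzero axis and positive radius")
        self.axis = axis / ln
        # fixed fallback normal for the on-axis degeneracy
        ref = np.array([1.0, 0.0, 0.0])
        if abs(self.axis @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        self._fallback = np.cross(self.axis, ref)
        self._fallback /= np.linalg.norm(self._fallback)

    def gap(self, points: np.ndarray, s: float = 1.0):
        points = np.atleast_2d(points)
        r = self.radius + s * self.radius_change
        rel = points - self.origin
        t = rel @ self.axis
        radial = rel - np.outer(t, self.axis)
        d = np.linalg.norm(radial, axis=1)
        n = np.where(d[:, None] > 0, radial / np.where(d[:, None] > 0, d[:, None], 1.0),
                     self._fallback)
        g = d - r
        active = (t >= 0) & (t <= self.length)
        return g, n, active


def analytic_gap(surface, points: np.ndarray, s: float = 1.0):
    """Gap function of an analytic master surface at load fraction ``s``."""
    return surface.gap(points, s)


def apply_displacement_correction(U_pred: np.ndarray, node_ids: np.ndarray,
                                  g: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Move penetrating nodes by du = -g n_m (Lagrange-free projection).

    U_pred: (N, 3) predictor displacements (modified copy returned);
    node_ids, g, n: per-event node index, gap (< 0) and master normal.
    """
    U = np.array(U_pred, copy=True)
    if len(node_ids):
        U[node_ids] -= g[:, None] * n
    return U


# ---------------------------------------------------------------------------
# Mesh-based contact
# ---------------------------------------------------------------------------

@dataclass
class ContactEvent:
    """One detected penetration.

    node_facet: ``slave`` is a node index, ``master`` the 3 facet vertex
    indices, (xi, eta) the facet projection coordinates.  edge_edge:
    ``slave``/``master`` are 2-node edge index pairs with closest-point
    parameters q (slave) and r (master).  ``g`` is the signed gap (< 0) and
    ``n`` the outward master-side unit normal.
    """

    kind: str
    slave: np.ndarray
    master: np.ndarray
    g: float
    n: np.ndarray
    xi: float = 0.0
    eta: float = 0.0
    r: float = 0.0
    q: float = 0.0


def _facet_aabbs(x, facets, margin):
    p = x[facets]
    return p.min(axis=1) - margin, p.max(axis=1) + margin


def surface_components(surface: SurfaceMesh) -> np.ndarray:
    """Connected-component label per facet (bodies sharing no nodes).

    Used to designate master/slave roles between disjoint bodies: for a
    pair of components the lower label acts as master, mirroring the
    one-way node-facet treatment of pair-wise contact search (two-pass
    detection between the same pair would over-correct).
    """
    import scipy.sparse as sp
    import scipy.sparse.csgraph as csg
    f = surface.facets
    nf = len(f)
    nodes = surface.node_ids()
    remap = np.zeros(nodes.max() + 1 if len(nodes) else 1, dtype=np.int64)
    remap[nodes] = np.arange(len(nodes))
    rows = np.repeat(np.arange(nf), 3)
    cols = remap[f.ravel()]
    inc = sp.coo_matrix((np.ones(3 * nf), (rows, cols)),
                        shape=(nf, len(nodes)))
    adj = (inc @ inc.T) > 0
    _, labels = csg.connected_components(adj, directed=False)
    return labels


def _closest_point_triangle(p, a, b, c):
    """Barycentric (xi, eta) of the point on triangle abc closest to p
    (h = (1-xi-eta, xi, eta); Ericson's region-based algorithm)."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = ab @ ap
    d2 = ac @ ap
    if d1 <= 0 and d2 <= 0:
        return 0.0, 0.0
    bp = p - b
    d3 = ab @ bp
    d4 = ac @ bp
    if d3 >= 0 and d4 <= d3:
        return 1.0, 0.0
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        return float(d1 / (d1 - d3)), 0.0
    cp = p - c
    d5 = ab @ cp
    d6 = ac @ cp
    if d6 >= 0 and d5 <= d6:
        return 0.0, 1.0
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        return 0.0, float(d2 / (d2 - d6))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return float(1.0 - w), float(w)
    denom = va + vb + vc
    return float(vb / denom), float(vc / denom)


def _feature_normal(surface, fn_all, fac, xi, eta, facet_normal, tol=1e-9):
    """Outward normal of the closest feature: the facet normal for interior
    points, the summed normal of the facets sharing the edge/vertex
    otherwise (pseudo-normal sign test)."""
    h = (1.0 - xi - eta, xi, eta)
    active = [i for i, v in enumerate(h) if v > tol]
    if len(active) == 3:
        return facet_normal
    feature_nodes = {int(fac[i]) for i in active}
    acc = np.zeros(3)
    for f, nf in zip(surface.facets, fn_all):
        if feature_nodes <= {int(v) for v in f}:
            acc += nf
    ln = np.linalg.norm(acc)
    return acc / ln if ln > 0 else facet_normal


def _node_in_facet_onering(surface: SurfaceMesh):
    """node -> set of nodes sharing a facet with it (adjacency exclusion)."""
    ring = {}
    for f in surface.facets:
        for a in f:
            ring.setdefault(int(a), set()).update(int(b) for b in f)
    return ring


def detect_contacts(x: np.ndarray, master: SurfaceMesh,
                    slave: Optional[SurfaceMesh] = None,
                    margin: float = 0.0, max_depth: float = None,
                    exclude_adjacent: bool = True,
                    edge_edge: bool = True):
    """Find node-facet and edge-edge penetrations at configuration ``x``.

    ``master`` (and optionally a distinct ``slave``) are triangulated
    surfaces referencing rows of ``x``.  With ``slave=None`` the surface is
    checked against itself (self-collision / multi-body) with topologically
    adjacent primitive pairs excluded.  Broad phase: brute-force AABB pair
    filtering inflated by ``margin``.  ``max_depth`` bounds the penetration
    depth considered a genuine contact (defaults to ``margin``): deeper
    apparent overlaps between far-apart primitives are discarded.
    """
    if max_depth is None:
        max_depth = margin if margin > 0 else np.inf
    self_contact = slave is None
    if self_contact:
        slave = master
    events = []

    ring = _node_in_facet_onering(master) if (self_contact and exclude_adjacent) else {}

    # disjoint-body master/slave designation: for a pair of components the
    # lower label is the master; the pair is searched in one direction only
    if self_contact:
        comp = surface_components(master)
        node_comp = {}
        for f, c in zip(master.facets, comp):
            for v in f:
                node_comp[int(v)] = c
    else:
        comp = None
        node_comp = None

    slave_nodes = slave.node_ids()
    fn_all = _facet_normals_at(x, master)
    lo, hi = _facet_aabbs(x, master.facets, margin)
    pts = x[slave_nodes]
    # (n_nodes, n_facets) AABB containment mask
    inside = np.all((pts[:, None, :] >= lo[None]) & (pts[:, None, :] <= hi[None]), axis=2)
    cand_n, cand_f = np.nonzero(inside)
    # slave node -> (|d|, event): penetration is decided by the signed
    # distance to the *closest* candidate facet, so nodes lying outside the
    # body but behind the plane of a bulging silhouette facet are not
    # flagged as false contacts
    best = {}
    for ni, fi in zip(cand_n, cand_f):
        s = int(slave_nodes[ni])
        fac = master.facets[fi]
        if s in fac:
            continue
        if self_contact:
            cs, cf = node_comp[s], comp[fi]
            if cs < cf:
                continue  # searched with roles swapped
            if cs == cf and exclude_adjacent and s in \
                    ring.get(int(fac[0]), set()) | ring.get(int(fac[1]), set()) \
                    | ring.get(int(fac[2]), set()):
                continue
        p0, p1, p2 = x[fac]
        n = np.cross(p1 - p0, p2 - p0)
        nn = np.linalg.norm(n)
        if nn == 0:
            continue
        n = n / nn
        xi, eta = _closest_point_triangle(x[s], p0, p1, p2)
        cp = (1.0 - xi - eta) * p0 + xi * p1 + eta * p2
        diff = x[s] - cp
        dist = np.linalg.norm(diff)
        # inside/outside sign: facet normal for interior closest points,
        # summed adjacent-facet (pseudo) normal for edge/vertex features
        n_sign = _feature_normal(master, fn_all, fac, xi, eta, n)
        g = float(diff @ n) if dist < 1e-14 else \
            float(np.sign(diff @ n_sign) * dist)
        if abs(g) > max_depth and g < 0:
            continue
        prev = best.get(s)
        if prev is None or abs(g) < prev[0] - 1e-14:
            ev = None
            if g < 0:
                ev = ContactEvent("node_facet", np.int64(s), fac.copy(),
                                  g, n, xi=float(xi), eta=float(eta))
            best[s] = (abs(g), ev)
    events.extend(best[s][1] for s in sorted(best) if best[s][1] is not None)

    if edge_edge:
        # nodes already handled through node-facet events: edge crossings
        # touching them are the same geometric contact and are suppressed
        involved = set()
        for ev in events:
            involved.add(int(ev.slave))
            involved.update(int(v) for v in ev.master)
        events += _detect_edge_edge(x, master, slave, self_contact,
                                    margin, max_depth, exclude_adjacent,
                                    ring, node_comp, involved)
    return events


def _facet_normals_at(x, surface):
    p = x[surface.facets]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    ln = np.linalg.norm(n, axis=1, keepdims=True)
    return n / np.where(ln > 0, ln, 1.0)


def _edge_normals(x, surface):
    """Averaged adjacent-facet normal for every unique surface edge."""
    edges = surface.edges()
    key = {tuple(e): i for i, e in enumerate(edges)}
    acc = np.zeros((len(edges), 3))
    fn = _facet_normals_at(x, surface)
    for f, n in zip(surface.facets, fn):
        for a, b in ((0, 1), (1, 2), (2, 0)):
            acc[key[tuple(sorted((int(f[a]), int(f[b]))))]] += n
    ln = np.linalg.norm(acc, axis=1, keepdims=True)
    return edges, acc / np.where(ln > 0, ln, 1.0)


def _segment_closest(p0, p1, q0, q1):
    """Closest-point parameters (s on p, t on q) between two segments."""
    u = p1 - p0
    v = q1 - q0
    w = p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    den = a * c - b * b
    if den <= 1e-14 * a * c or den == 0.0:
        return None  # near-parallel: handled by node-facet path
    s = (b * e - c * d) / den
    t = (a * e - b * d) / den
    return s, t


def _detect_edge_edge(x, master, slave, self_contact, margin, max_depth,
                      exclude_adjacent, ring, node_comp=None, involved=()):
    events = []
    m_edges, m_normals = _edge_normals(x, master)
    s_edges = m_edges if self_contact else slave.edges()
    # AABB prefilter on edges
    mp = x[m_edges]
    mlo, mhi = mp.min(axis=1) - margin, mp.max(axis=1) + margin
    sp = x[s_edges]
    slo, shi = sp.min(axis=1), sp.max(axis=1)
    overlap = np.all((slo[:, None] <= mhi[None]) & (shi[:, None] >= mlo[None]), axis=2)
    cand_s, cand_m = np.nonzero(overlap)
    for si, mi in zip(cand_s, cand_m):
        se = s_edges[si]
        me = m_edges[mi]
        if self_contact:
            cs, cm = node_comp[int(se[0])], node_comp[int(me[0])]
            if cs < cm:
                continue  # roles swapped: handled as (mi, si)
            if cs == cm and si >= mi:
                continue
        shared = set(int(v) for v in se) & set(int(v) for v in me)
        if shared:
            continue
        if any(int(v) in involved for v in (*se, *me)):
            continue
        if self_contact and exclude_adjacent:
            if any(int(a) in ring.get(int(b), set()) for a in se for b in me):
                continue
        res = _segment_closest(x[se[0]], x[se[1]], x[me[0]], x[me[1]])
        if res is None:
            continue
        q, r = res  # q: slave parameter, r: master parameter
        # strictly interior crossings only: endpoint contacts are node-facet
        # events and would otherwise be double-counted
        eps = 1e-3
        if not (eps < q < 1 - eps and eps < r < 1 - eps):
            continue
        cs = x[se[0]] + q * (x[se[1]] - x[se[0]])
        cm = x[me[0]] + r * (x[me[1]] - x[me[0]])
        diff = cs - cm
        dist = np.linalg.norm(diff)
        nbar = m_normals[mi]
        if dist > 0:
            n = diff / dist
            # orient to the outward master side
            if n @ nbar < 0:
                n = -n
        else:
            n = nbar
        g = diff @ n
        if g >= 0 or g < -max_depth:
            continue
        events.append(ContactEvent("edge_edge", se.copy(), me.copy(),
                                   float(g), n, r=float(r), q=float(q)))
    return events


# ---------------------------------------------------------------------------
# Lagrange-multiplier collision response forces
# ---------------------------------------------------------------------------

def _gamma(h):
    """Force-distribution coefficients gamma_i = h_i / sum_j h_j^2."""
    h = np.asarray(h, float)
    return h / np.dot(h, h)


def node_facet_response(event: ContactEvent, m_s: float,
                        facet_masses: np.ndarray, dt: float,
                        rigid_master: bool = False):
    """Response forces for a node-facet penetration.

    Returns (f_s (3,), f_m (3, 3)): slave-node force and per-vertex master
    forces.  beta_s = m_m/(m_s + m_m) with m_m the virtual-node mass
    interpolated at the projection point; for a rigid master the limit
    beta_s = 1, beta_m = 0 is taken.
    """
    h = np.array([1.0 - event.xi - event.eta, event.xi, event.eta])
    if rigid_master:
        beta_s, beta_m = 1.0, 0.0
        m_m = np.inf
    else:
        m_m = float(h @ np.asarray(facet_masses, float))
        beta_s = m_m / (m_s + m_m)
        beta_m = 1.0 - beta_s
    f_s = -event.n * beta_s * m_s * event.g / dt**2
    if rigid_master:
        f_m = np.zeros((3, 3))
    else:
        gam = _gamma(h)
        f_m = event.n[None, :] * (beta_m * np.asarray(facet_masses, float)
                                  * gam * event.g / dt**2)[:, None]
    return f_s, f_m


def edge_edge_response(event: ContactEvent, slave_masses: np.ndarray,
                       master_masses: np.ndarray, dt: float,
                       rigid_master: bool = False):
    """Response forces for an edge-edge penetration (2-node shape functions).

    Returns (f_s (2, 3), f_m (2, 3)) for the slave and master edge
    endpoints.
    """
    hq = np.array([1.0 - event.q, event.q])
    hr = np.array([1.0 - event.r, event.r])
    slave_masses = np.asarray(slave_masses, float)
    master_masses = np.asarray(master_masses, float)
    if rigid_master:
        beta_s, beta_m = 1.0, 0.0
    else:
        ms_v = float(hq @ slave_masses)
        mm_v = float(hr @ master_masses)
        beta_s = mm_v / (ms_v + mm_v)
        beta_m = 1.0 - beta_s
    f_s = -event.n[None, :] * (beta_s * slave_masses * _gamma(hq)
                               * event.g / dt**2)[:, None]
    if rigid_master:
        f_m = np.zeros((2, 3))
    else:
        f_m = event.n[None, :] * (beta_m * master_masses * _gamma(hr)
                                  * event.g / dt**2)[:, None]
    return f_s, f_m


def accumulate_response_forces(events, masses: np.ndarray, dt: float,
                               num_nodes: int, rigid_master: bool = False):
    """Sum all event response forces into a global (N, 3) force array.

    ``masses`` are node-lumped masses of the (single, global) mesh; for
    deformable-rigid contact only the slave side receives forces.
    """
    f = np.zeros((num_nodes, 3))
    for ev in events:
        if ev.kind == "node_facet":
            fs, fm = node_facet_response(ev, masses[int(ev.slave)],
                                         masses[ev.master], dt, rigid_master)
            f[int(ev.slave)] += fs
            if not rigid_master:
                for i, vid in enumerate(ev.master):
                    f[int(vid)] += fm[i]
        else:
            fs, fm = edge_edge_response(ev, masses[ev.slave], masses[ev.master],
                                        dt, rigid_master)
            for i, vid in enumerate(ev.slave):
                f[int(vid)] += fs[i]
            if not rigid_master:
                for i, vid in enumerate(ev.master):
                    f[int(vid)] += fm[i]
    return f
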