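"""Membrane polygon mechanics and filament-membrane coupling.

The spine-head membrane is a single counterclockwise polygon.  Its energy
has three terms: an areal term ``-P·Ω`` (the absolute pressure difference
inflates the compartment), a line-tension term ``τ·S`` on the perimeter, and a
discrete Helfrich term ``2κ Σ H_i² z_i`` built from a five-vertex mean-
curvature stencil.  Vertices move by overdamped descent with a per-arclength
mobility; uncapped filament ends that poke through the polygon (within a
pseudo-extended "overgrowth" length) are attached to a freshly inserted
membrane vertex by a harmonic spring (rest length = the gap at attachment), which pins the pressurized
membrane to the cytoskeleton; polymerization into pressure-opened gaps
ratchets the pinned front outward (attach / elongate / detach cycles).

Geometry here is in unit lengths; energies in joules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import state as st
from .params import ModelParams


# ----------------------------------------------------------------------
# polygon observables
# ----------------------------------------------------------------------

def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a simple polygon (positive for CCW orientation)."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    w = np.roll(v, -1, axis=0)
    return 0.5 * abs(float(np.sum(v[:, 0] * w[:, 1] - w[:, 0] * v[:, 1])))


def polygon_signed_area(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=float)
    w = np.roll(v, -1, axis=0)
    return 0.5 * float(np.sum(v[:, 0] * w[:, 1] - w[:, 0] * v[:, 1]))


def polygon_perimeter(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=float)
    return float(np.sum(np.hypot(*(np.roll(v, -1, axis=0) - v).T)))


def circularity(area: float, perimeter: float) -> float:
    """4π·A/P²: 1 for a circle, < 1 for any other shape."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * math.pi * area / perimeter**2


# ----------------------------------------------------------------------
# discrete mean curvature
# ----------------------------------------------------------------------

def _curvature_terms(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex |dT/dw| and arc weights z for the whole cycle.

    For vertex k: t_k = (x_k - x_{k-1})/v_k is the inbound unit tangent,
    g_k = |t_{k+1} - t_k| the tangent turn, z_k = (v_k + v_{k+1})/2 the local
    arc length; g_k / z_k is the discrete curvature at k (exactly 1/R on a
    regular polygon inscribed in a circle of radius R).
    """
    v = np.asarray(v, dtype=float)
    edges = np.roll(v, -1, axis=0) - v          # edge k: x_k -> x_{k+1}
    lens = np.hypot(edges[:, 0], edges[:, 1])
    if np.any(lens == 0):
        raise ValueError("coincident consecutive vertices")
    tang = edges / lens[:, None]                # outbound tangent at vertex k
    t_in = np.roll(tang, 1, axis=0)             # inbound tangent at vertex k
    g = np.hypot(*(tang - t_in).T)
    z = 0.5 * (np.roll(lens, 1) + lens)
    return g / z, z


def discrete_mean_curvature(vertices: np.ndarray, i: int) -> float:
    """Mean curvature at vertex i from the five-vertex neighborhood.

    The three per-vertex tangent-turn estimates g/z centered at i-1, i, i+1
    are averaged; the estimate converges to the circle curvature 1/R and is
    invariant under rigid motions (it is built from differences and norms).
    """
    v = np.asarray(vertices, dtype=float)
    if len(v) < 5:
        raise ValueError("curvature stencil needs at least 5 vertices")
    gz, _ = _curvature_terms(v)
    n = len(v)
    return float(gz[(i - 1) % n] + gz[i % n] + gz[(i + 1) % n]) / 3.0


# ----------------------------------------------------------------------
# membrane energy
# ----------------------------------------------------------------------

@dataclass
class MembraneEnergyTerms:
    area_term: float       # -P·Ω, J (positive P drives outward inflation)
    tension_term: float    # τ·S, J
    curvature_term: float  # 2κ Σ H² z, J

    @property
    def total(self) -> float:
        return self.area_term + self.tension_term + self.curvature_term


def membrane_energy(vertices: np.ndarray, p: ModelParams) -> MembraneEnergyTerms:
    v = np.asarray(vertices, dtype=float)
    area = polygon_signed_area(v)
    if area <= 0:
        raise ValueError("membrane cycle must be counterclockwise")
    per = polygon_perimeter(v)
    if len(v) >= 5:
        gz, z = _curvature_terms(v)
        h = (np.roll(gz, 1) + gz + np.roll(gz, -1)) / 3.0
        if p.curvature_arclength_weighted:
            curv = 2.0 * p.kappa_u * float(np.sum(h * h * z))
        else:
            curv = 2.0 * p.kappa_u * float(np.sum(h * h))
    else:
        curv = 0.0
    return MembraneEnergyTerms(area_term=-p.pressure_u * area,
                               tension_term=p.tension_u * per,
                               curvature_term=curv)


def membrane_energy_state(state: st.SimState, p: ModelParams) -> MembraneEnergyTerms:
    return membrane_energy(state.membrane_coords(), p)


def attachment_energy(state: st.SimState, p: ModelParams) -> float:
    e = 0.0
    for end, vid in state.attach_end2vert.items():
        gap = math.hypot(*(state.a_pos[end] - state.m_pos[vid]))
        e += 0.5 * p.k_att_u * (gap - state.attach_rest.get(end, 0.0)) ** 2
    return e


def attachment_force_on_vertex(state: st.SimState, vid: int,
                               p: ModelParams) -> np.ndarray:
    """Spring force on an attached membrane vertex (toward/away its end)."""
    end = state.attach_vert2end.get(vid)
    if end is None:
        return np.zeros(2)
    d = state.a_pos[end] - state.m_pos[vid]
    gap = math.hypot(*d)
    if gap < 1e-12:
        return np.zeros(2)
    rest = state.attach_rest.get(end, 0.0)
    return p.k_att_u * (gap - rest) * (d / gap)


# ----------------------------------------------------------------------
# vertex gradient and step
# ----------------------------------------------------------------------

def membrane_gradient(state: st.SimState, vid: int, p: ModelParams,
                      fd_h: float = 1e-6) -> np.ndarray:
    """∇ of the membrane energy wrt vertex ``vid``.

    Area and tension gradients are analytic; the curvature-term gradient is
    taken by central finite differences of the stencil energy (the vertex
    enters the Helfrich sum only through its 5-vertex neighborhood).
    """
    prv, nxt = int(state.m_prev[vid]), int(state.m_next[vid])
    x = state.m_pos[vid]
    xp, xn = state.m_pos[prv], state.m_pos[nxt]
    # area: dA/dx_b = 0.5 (x_{b+1}.y - x_{b-1}.y, x_{b-1}.x - x_{b+1}.x)
    g_area = 0.5 * np.array([xn[1] - xp[1], xp[0] - xn[0]])
    dp = x - xp
    dn = x - xn
    g_ten = dp / max(math.hypot(*dp), 1e-300) + dn / max(math.hypot(*dn), 1e-300)
    g = -p.pressure_u * g_area + p.tension_u * g_ten
    if p.kappa_u != 0.0 and state.n_mem >= 5:
        g += _curvature_gradient_fd(state, vid, p, fd_h)
    return g


def _stencil_ids(state: st.SimState, vid: int, half: int = 3) -> list[int]:
    ids = [vid]
    j = vid
    for _ in range(half):
        j = int(state.m_prev[j])
        ids.insert(0, j)
    j = vid
    for _ in range(half):
        j = int(state.m_next[j])
        ids.append(j)
    return ids


def _local_curvature_energy(state: st.SimState, ids: list[int],
                            p: ModelParams) -> float:
    """Helfrich energy of the curvature terms touched by the center vertex."""
    v = state.m_pos[np.asarray(ids, dtype=int)]
    edges = v[1:] - v[:-1]
    lens = np.hypot(edges[:, 0], edges[:, 1])
    lens = np.maximum(lens, 1e-300)
    tang = edges / lens[:, None]
    g = np.hypot(*(tang[1:] - tang[:-1]).T)      # turn at interior vertices
    z = 0.5 * (lens[:-1] + lens[1:])
    gz = g / z
    e = 0.0
    # H at interior vertices of the window (need gz at j-1, j, j+1)
    for j in range(1, len(gz) - 1):
        h = (gz[j - 1] + gz[j] + gz[j + 1]) / 3.0
        w = z[j] if p.curvature_arclength_weighted else 1.0
        e += h * h * w
    return 2.0 * p.kappa_u * e


def _curvature_gradient_fd(state: st.SimState, vid: int, p: ModelParams,
                           h: float) -> np.ndarray:
    # moving vid perturbs tangent turns at vid-1..vid+1 and thereby the
    # Helfrich terms at vid-2..vid+2, so the window must span vid±4 for all
    # affected terms to appear in the difference
    half = min(4, (state.n_mem - 1) // 2)
    ids = _stencil_ids(state, vid, half=half)
    x0 = state.m_pos[vid].copy()
    g = np.zeros(2)
    for d in (0, 1):
        for sgn, acc in ((1.0, 1.0), (-1.0, -1.0)):
            state.m_pos[vid, d] = x0[d] + sgn * h
            g[d] += acc * _local_curvature_energy(state, ids, p)
        state.m_pos[vid, d] = x0[d]
    return g / (2.0 * h)


def _move_self_intersects(state: st.SimState, vid: int,
                          new_pos: np.ndarray) -> bool:
    """Would moving ``vid`` to ``new_pos`` break polygon simplicity?"""
    cyc = state.membrane_cycle()
    pts = state.m_pos[cyc].copy()
    k = int(np.flatnonzero(cyc == vid)[0])
    pts[k] = new_pos
    n = len(pts)
    # only edges (k-1,k) and (k,k+1) moved: test them against all others
    for ei in ((k - 1) % n, k):
        a, b = pts[ei], pts[(ei + 1) % n]
        for j in range(n):
            if j in (ei, (ei - 1) % n, (ei + 1) % n):
                continue
            if st.segment_intersection(a, b, pts[j], pts[(j + 1) % n]) is not None:
                return True
    return False


def _sweeps_over_actin(state: st.SimState, vid: int,
                       new_pos: np.ndarray) -> bool:
    """Would moving ``vid`` sweep a membrane edge across an actin node?

    The membrane is impenetrable to the cytoskeleton: the two adjacent
    edges sweep the triangles (prev, old, new) and (next, old, new); any
    live actin node inside either triangle blocks the move.
    """
    ids = state.actin_ids()
    if len(ids) == 0:
        return False
    x_old = state.m_pos[vid]
    xp = state.m_pos[int(state.m_prev[vid])]
    xn = state.m_pos[int(state.m_next[vid])]
    reach = max(math.hypot(*(x_old - xp)), math.hypot(*(x_old - xn))) \
        + math.hypot(*(new_pos - x_old))
    pos = state.a_pos[ids]
    near = ids[np.hypot(*(pos - x_old).T) <= reach]
    for q in near:
        qp = state.a_pos[q]
        for anchor in (xp, xn):
            if _point_in_triangle(qp, anchor, x_old, new_pos):
                return True
    return False


def _point_in_triangle(q, a, b, c) -> bool:
    d1 = (q[0] - b[0]) * (a[1] - b[1]) - (a[0] - b[0]) * (q[1] - b[1])
    d2 = (q[0] - c[0]) * (b[1] - c[1]) - (b[0] - c[0]) * (q[1] - c[1])
    d3 = (q[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (q[1] - a[1])
    neg = (d1 < 0) or (d2 < 0) or (d3 < 0)
    pos = (d1 > 0) or (d2 > 0) or (d3 > 0)
    return not (neg and pos)


def membrane_step(state: st.SimState, vid: int, p: ModelParams,
                  apply: bool = True, check_intersection: bool = True):
    """One viscous vertex update Δx = ζ_mem · (F / z) / k_kinetic.

    F is the negative membrane-energy gradient plus the attachment-spring
    reaction from any attached filament end; z is the local arc length, so
    ζ_mem acts as a per-length mobility.  Steps that would self-intersect
    the polygon or sweep an edge across an actin node are rejected
    (returns None).
    """
    prv, nxt = int(state.m_prev[vid]), int(state.m_next[vid])
    x = state.m_pos[vid]
    z = 0.5 * (math.hypot(*(x - state.m_pos[prv]))
               + math.hypot(*(x - state.m_pos[nxt])))
    z = max(z, 1e-9)
    scale = p.mem_step_coeff / (z * p.k_kinetic)
    # soft forces (pressure, tension, attachment springs) are stable at the
    # generic step cap; the Helfrich term is stiff at this update rate, so
    # its contribution is clipped separately at the fine cap to bound the
    # resulting vertex oscillation well below the mesh scale
    g_area = 0.5 * np.array([state.m_pos[nxt][1] - state.m_pos[prv][1],
                             state.m_pos[prv][0] - state.m_pos[nxt][0]])
    dp = x - state.m_pos[prv]
    dn = x - state.m_pos[nxt]
    g_ten = dp / max(math.hypot(*dp), 1e-300) + dn / max(math.hypot(*dn), 1e-300)
    f_soft = p.pressure_u * g_area - p.tension_u * g_ten
    f_soft += attachment_force_on_vertex(state, vid, p)
    f_curv = np.zeros(2)
    if p.kappa_u != 0.0 and state.n_mem >= 5:
        f_curv = -_curvature_gradient_fd(state, vid, p, 1e-6)
        nc = math.hypot(*f_curv) * scale
        if nc > p.mem_step_cap:
            f_curv = f_curv * (p.mem_step_cap / nc)
    dx = scale * (f_soft + f_curv)
    norm = math.hypot(*dx)
    if norm > p.step_cap:
        dx = dx * (p.step_cap / norm)
    new = x + dx
    if check_intersection and (_move_self_intersects(state, vid, new)
                               or _sweeps_over_actin(state, vid, new)):
        return None
    if apply:
        state.m_pos[vid] = new
    return dx


# ----------------------------------------------------------------------
# attachment / Brownian ratchet
# ----------------------------------------------------------------------

def _terminal_rod(state: st.SimState, end_id: int, p: ModelParams):
    """(base, tip) of the end's rod extended by the overgrowth length."""
    nb = state.filament_neighbors(end_id)
    if len(nb) != 1:
        return None
    base = state.a_pos[nb[0]]
    tip = state.a_pos[end_id]
    d = tip - base
    n = math.hypot(*d)
    if n < 1e-12:
        return None
    return base, tip + (p.overgrowth / n) * d


def attach_filament(state: st.SimState, end_id: int, p: ModelParams) -> bool:
    """Attach an uncapped end whose extended rod crosses a membrane edge.

    A new membrane vertex is inserted at the (nearest-to-tip) crossing and
    bonded to the end.  Returns True if an attachment was created.
    """
    if end_id in state.attach_end2vert:
        return False
    if int(state.a_sub[end_id]) not in (st.END, st.ARP_END):
        return False
    rod = _terminal_rod(state, end_id, p)
    if rod is None:
        return False
    base, tip = rod
    best = None
    best_d = np.inf
    cyc = state.membrane_cycle()
    pts = state.m_pos[cyc]
    nxt = np.roll(pts, -1, axis=0)
    x_end = state.a_pos[end_id]
    for k in range(len(cyc)):
        hit = st.segment_intersection(base, tip, pts[k], nxt[k])
        if hit is None:
            continue
        d = math.hypot(*(hit - x_end))
        if d < best_d:
            best_d = d
            best = (int(cyc[k]), hit)
    if best is None:
        return False
    vid_before, point = best
    # snap to an existing unattached vertex if the hit lands on one
    rest = min(best_d, p.overgrowth)
    for cand in (vid_before, int(state.m_next[vid_before])):
        if (math.hypot(*(state.m_pos[cand] - point)) < 1e-9
                and cand not in state.attach_vert2end):
            state.attach(end_id, cand, rest=rest)
            return True
    new_vid = state.insert_vertex_after(vid_before, point)
    state.attach(end_id, new_vid, rest=rest)
    return True


def ratchet_detach(state: st.SimState, end_id: int, p: ModelParams) -> bool:
    """Release an attachment whose end-to-vertex gap exceeds the threshold.

    The gap typically opens when the attached end elongates past its vertex
    (the Brownian-ratchet hand-off), but an overstretched bond also ruptures
    when the membrane is pulled away mechanically.  The membrane vertex is
    retained; the end may re-attach at a new crossing later.
    """
    vid = state.attach_end2vert.get(end_id)
    if vid is None:
        return False
    gap = math.hypot(*(state.a_pos[end_id] - state.m_pos[vid]))
    # release at twice the overgrowth length: attachments are created with
    # rest gaps up to one overgrowth, so the factor gives the bond a finite
    # working range instead of a release boundary at its rest point
    if gap > 2.0 * p.overgrowth:
        state.detach(end_id)
        return True
    return False


# ----------------------------------------------------------------------
# remeshing
# ----------------------------------------------------------------------

def remesh(state: st.SimState, p: ModelParams, l0: float,
           min_vertices: int = 8) -> int:
    """Split long edges (> 2 l0) and merge short ones (< l0/4).

    Attachment vertices are never removed.  Returns the net vertex-count
    change.  Keeps the curvature stencil well conditioned as the polygon
    deforms.
    """
    changed = 0
    cyc = [int(i) for i in state.membrane_cycle()]
    for i in cyc:
        j = int(state.m_next[i])
        d = state.m_pos[j] - state.m_pos[i]
        if math.hypot(*d) > 2.0 * l0:
            state.insert_vertex_after(i, state.m_pos[i] + 0.5 * d)
            changed += 1
    cyc = [int(i) for i in state.membrane_cycle()]
    if len(cyc) <= min_vertices:
        return changed
    removed = set()
    for i in cyc:
        if state.n_mem <= min_vertices:
            break
        if i in removed or i in state.attach_vert2end:
            continue
        if not state.m_alive[i]:
            continue
        dp = math.hypot(*(state.m_pos[i] - state.m_pos[int(state.m_prev[i])]))
        dn = math.hypot(*(state.m_pos[i] - state.m_pos[int(state.m_next[i])]))
        if min(dp, dn) < 0.25 * l0:
            state.remove_vertex(i)
            removed.add(i)
            changed -= 1
    return changed


def point_in_polygon(pts: np.ndarray, x) -> bool:
    """Even-odd ray test for a point against a closed polygon."""
    n = len(pts)
    inside = False
    px, py = float(x[0]), float(x[1])
    for k in range(n):
        x1, y1 = pts[k]
        x2, y2 = pts[(k + 1) % n]
        if (y1 > py) != (y2 > py):
            xc = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if xc > px:
                inside = not inside
    return inside


def crosses_membrane(state: st.SimState, x_old, x_new) -> bool:
    """Does the path x_old → x_new cross any membrane edge?

    Used to make the membrane impenetrable to actin nodes: a mechanics move
    whose path crosses the polygon is vetoed.  Vectorized over edges.
    """
    cyc = state.membrane_cycle()
    if len(cyc) < 3:
        return False
    a = state.m_pos[cyc]
    b = state.m_pos[np.roll(cyc, -1)]
    p0 = np.asarray(x_old, dtype=float)
    p1 = np.asarray(x_new, dtype=float)
    r = p1 - p0
    s_ = b - a
    w = a - p0
    denom = r[0] * s_[:, 1] - r[1] * s_[:, 0]
    ok = np.abs(denom) > 1e-300
    t = np.where(ok, (w[:, 0] * s_[:, 1] - w[:, 1] * s_[:, 0])
                 / np.where(ok, denom, 1.0), -1.0)
    u = np.where(ok, (w[:, 0] * r[1] - w[:, 1] * r[0])
                 / np.where(ok, denom, 1.0), -1.0)
    return bool(np.any(ok & (t >= 0) & (t <= 1) & (u >= 0) & (u <= 1)))


def membrane_wkt(state: st.SimState) -> str:
    """Membrane polygon as WKT text (closed ring, unit lengths)."""
    pts = state.membrane_coords()
    coords = ", ".join(f"{x:.9g} {y:.9g}" for x, y in pts)
    first = f"{pts[0, 0]:.9g} {pts[0, 1]:.9g}"
    return f"POLYGON (({coords}, {first}))"
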