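"""Stochastic remodeling rules for the actin network.

Each rule is split into (a) an eligibility predicate on the typed graph,
(b) a propensity (1/s), and (c) a rewrite that edits the graph in place and
returns the touched node ids.  Bimolecular rate constants (1/(M·s)) are
converted to per-molecule-pair rates through the slab volume A·h_eff, so a
propensity ``number_rate(k, A) · N_free`` reproduces mass-action kinetics in
the 2D compartment.  Coarse-grained off rates are weighted harmonic means of
the per-monomer off rates — the inverse of the total time to depolymerize a
segment's monomers sequentially.

Synthesis/degradation of the free species pools is deterministic
(``species_ode_step``, exact exponential update of dM/dt = I - k·M).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import state as st
from .params import ModelParams
from .state import (INTERIOR, END, CAPPED, JUNCTION, ARP_END, ARP_INTERIOR,
                    SimState, bend_angle)


@dataclass
class RuleInstance:
    rule_name: str
    nodes: tuple
    propensity: float

    def __post_init__(self):
        if self.propensity < 0:
            raise ValueError(f"negative propensity for {self.rule_name}")


# ----------------------------------------------------------------------
# rate helpers
# ----------------------------------------------------------------------

def number_rate(k_molar: float, area_u: float, p: ModelParams) -> float:
    """Per-molecule rate: k / (N_A · A · h_eff) in the 2D slab volume."""
    return p.number_rate(k_molar, area_u)


def coarse_grained_off_rate(n_atp: int, n_adp: int, n_adppi: int,
                            k_off_atp: float, k_off_adp: float) -> float:
    """Weighted harmonic mean: 1 / (N_ATP/k_ATP + (N_ADP+N_ADPPi)/k_ADP)."""
    total = n_atp + n_adp + n_adppi
    if total <= 0:
        raise ValueError("off rate undefined for an empty segment")
    if k_off_atp <= 0 or k_off_adp <= 0:
        raise ValueError("off rates must be positive")
    return 1.0 / (n_atp / k_off_atp + (n_adp + n_adppi) / k_off_adp)


def node_off_rate(state: SimState, i: int, p: ModelParams,
                  end_kind: str) -> float:
    """Coarse-grained off rate of removing node i from its filament end.

    Cofilin-decorated monomers depolymerize with the ADP rate.
    """
    if end_kind == "barbed":
        ka, kd = p.k_barbed_off_atp, p.k_barbed_off_adp
    else:
        ka, kd = p.k_pointed_off_atp, p.k_pointed_off_adp
    return coarse_grained_off_rate(
        int(state.a_atp[i]),
        int(state.a_adp[i]) + int(state.a_cof[i]),
        int(state.a_adppi[i]), ka, kd)


def elongation_rate_per_end(p: ModelParams, conc_actin: float,
                            end_kind: str) -> float:
    """CG elongation propensity for one uncapped end (1/s).

    Adding one coarse-grained segment takes n_cg monomer additions, so the
    segment rate is k_on·[A]/n_cg; the free pool is split into an ATP and an
    ADP fraction.
    """
    if end_kind == "barbed":
        k_atp, k_adp = p.k_barbed_on_atp, p.k_barbed_on_adp
    else:
        k_atp, k_adp = p.k_pointed_on_atp, p.k_pointed_on_adp
    f = p.adp_fraction
    return (k_atp * (1 - f) + k_adp * f) * conc_actin / p.n_cg


def sample_elongation_geometry(x_prev, x_end, sigma_theta: float, rng,
                               pointed: bool = False, theta=None,
                               step_length=None):
    """Sample the bend angle and position of a newly added segment.

    ``theta ~ N(0, σθ)`` with σθ = sqrt(2/Lp) (persistence length in unit
    lengths); the new node continues the terminal rod rotated by θ (reversed
    sign and direction for pointed-end growth).  By default the rod length
    is preserved; the engine passes ``step_length=1`` so that growth always
    attempts one full rest length even when the terminal bond was
    membrane-compressed.
    """
    x_prev = np.asarray(x_prev, dtype=float)
    x_end = np.asarray(x_end, dtype=float)
    d = x_end - x_prev
    n = math.hypot(*d)
    if n < 1e-12:
        raise ValueError("degenerate direction vector for elongation")
    if step_length is not None:
        d = d * (step_length / n)
    if theta is None:
        theta = float(rng.normal(0.0, sigma_theta))
    ang = -theta if pointed else theta
    c, s = math.cos(ang), math.sin(ang)
    x_new = x_end + np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])
    return theta, x_new


# ----------------------------------------------------------------------
# eligibility predicates
# ----------------------------------------------------------------------

_BARBED_CONTEXT = (INTERIOR, ARP_INTERIOR, JUNCTION)
_POINTED_CONTEXT = (INTERIOR, JUNCTION)


def barbed_elongable(state: SimState, i: int) -> bool:
    sub = int(state.a_sub[i])
    if sub == ARP_END:
        return int(state.a_prev[i]) >= 0   # Δ→■ seed, grows via the branch rule
    if sub != END or int(state.a_next[i]) != -1:
        return False
    prv = int(state.a_prev[i])
    return prv >= 0 and int(state.a_sub[prv]) in _BARBED_CONTEXT


def pointed_elongable(state: SimState, i: int) -> bool:
    if int(state.a_sub[i]) != END or int(state.a_prev[i]) != -1:
        return False
    nxt = int(state.a_next[i])
    return nxt >= 0 and int(state.a_sub[nxt]) in _POINTED_CONTEXT


def barbed_retractable(state: SimState, i: int) -> bool:
    if int(state.a_sub[i]) != END or int(state.a_next[i]) != -1:
        return False
    prv = int(state.a_prev[i])
    if prv < 0:
        return False
    psub = int(state.a_sub[prv])
    if psub in (INTERIOR, ARP_INTERIOR):
        return True
    # 2-node filament: dissolves entirely
    return psub == END and int(state.a_prev[prv]) == -1


def pointed_retractable(state: SimState, i: int) -> bool:
    if int(state.a_sub[i]) != END or int(state.a_prev[i]) != -1:
        return False
    nxt = int(state.a_next[i])
    if nxt < 0:
        return False
    nsub = int(state.a_sub[nxt])
    if nsub == INTERIOR:
        return True
    return nsub == END and int(state.a_next[nxt]) == -1


def cappable(state: SimState, i: int) -> bool:
    return int(state.a_sub[i]) == END and int(state.a_next[i]) == -1


def branchable(state: SimState, i: int, p: ModelParams) -> bool:
    """Mother nodes for Arp2/3 nucleation: plain interiors with free sub-sites."""
    return (int(state.a_sub[i]) == INTERIOR
            and int(state.a_arp[i]) == -1
            and int(state.a_arpin[i]) < p.n_cg)


def junction_is_bare(state: SimState, j: int) -> bool:
    d = int(state.a_arp[j])
    return d >= 0 and int(state.a_sub[d]) == ARP_END


# ----------------------------------------------------------------------
# rewrites
# ----------------------------------------------------------------------

def _clamp_to_membrane(state: SimState, x_end, x_new, margin: float = 0.05,
                       min_frac: float = 0.02):
    """Shorten a growth step at the membrane boundary.

    A membrane-proximal end polymerizes into the available gap rather than
    through the polygon: the new node is placed just inside the first
    membrane crossing of the growth rod.  The shortened, compressed bond is
    what transduces polymerization into protrusive force on the membrane.
    """
    if state.n_mem < 3:
        return x_new
    d = x_new - x_end
    L = math.hypot(*d)
    if L < 1e-12:
        return x_new
    cyc = state.membrane_cycle()
    pts = state.m_pos[cyc]
    nxt = np.roll(pts, -1, axis=0)
    best = np.inf
    for k in range(len(cyc)):
        hit = st.segment_intersection(x_end, x_new, pts[k], nxt[k])
        if hit is not None:
            c = math.hypot(*(hit - x_end))
            if c < best:
                best = c
    if not np.isfinite(best):
        return x_new
    frac = max(min((best - margin) / L, 1.0), min_frac)
    return x_end + frac * d


def apply_elongation(state: SimState, end_id: int, p: ModelParams,
                     nucleotide: str = "ATP", theta=None,
                     clamp_pools: bool = False,
                     clamp_membrane: bool = True) -> int:
    """Append one segment at an uncapped end; returns the new node id."""
    sub = int(state.a_sub[end_id])
    pointed = (sub == END and int(state.a_prev[end_id]) == -1)
    if sub == ARP_END:
        if int(state.a_prev[end_id]) < 0:
            raise ValueError("detached Arp2/3 seed cannot elongate")
    elif sub != END:
        raise ValueError(f"node {end_id} is not an elongable end")
    if not clamp_pools and state.pools["actin"] < p.n_cg:
        raise ValueError("free actin pool below one coarse-grained segment")
    if pointed:
        ref = int(state.a_next[end_id])
    else:
        ref = int(state.a_prev[end_id])
    _, x_new = sample_elongation_geometry(
        state.a_pos[ref], state.a_pos[end_id], p.sigma_theta, state.rng,
        pointed=pointed, theta=theta, step_length=1.0)
    if clamp_membrane:
        x_new = _clamp_to_membrane(state, state.a_pos[end_id], x_new)
    counts = {"atp": p.n_cg} if nucleotide == "ATP" else {"adp": p.n_cg}
    if pointed:
        new = state.add_actin(x_new, END, prev=-1, nxt=end_id, **counts)
        state.a_prev[end_id] = new
        state.a_sub[end_id] = INTERIOR
    else:
        new = state.add_actin(x_new, END, prev=end_id, nxt=-1, **counts)
        state.a_next[end_id] = new
        state.a_sub[end_id] = ARP_INTERIOR if sub == ARP_END else INTERIOR
    if not clamp_pools:
        state.pools["actin"] -= p.n_cg
    if end_id in state.attach_end2vert:       # Brownian-ratchet transfer
        vid = state.attach_end2vert[end_id]
        rest = state.attach_rest.get(end_id, 0.0)
        state.detach(end_id)
        state.attach(new, vid, rest=rest)
        state.attach_elongated.add(new)
    return new


def apply_retraction(state: SimState, end_id: int, p: ModelParams,
                     clamp_pools: bool = False) -> list[int]:
    """Remove an uncapped end segment; returns surviving touched ids."""
    sub = int(state.a_sub[end_id])
    if sub != END:
        raise ValueError(f"node {end_id} is not a retractable end (capped?)")
    pointed = int(state.a_prev[end_id]) == -1
    nb = int(state.a_next[end_id]) if pointed else int(state.a_prev[end_id])
    nsub = int(state.a_sub[nb])

    def release(i):
        if not clamp_pools:
            state.pools["actin"] += p.n_cg - int(state.a_cof[i])
            state.pools["cofilin"] += int(state.a_cof[i])
            # cofilin-occupied monomers return as plain monomers
            state.pools["actin"] += int(state.a_cof[i])

    release(end_id)
    if nsub == END:                           # 2-node filament dissolves
        release(nb)
        state.kill_actin(end_id)
        state.kill_actin(nb)
        return []
    state.kill_actin(end_id)
    if pointed:
        state.a_prev[nb] = -1
        state.a_sub[nb] = END
    else:
        state.a_next[nb] = -1
        state.a_sub[nb] = ARP_END if nsub == ARP_INTERIOR else END
    return [nb]


def apply_branching(state: SimState, mother_id: int, p: ModelParams,
                    side=None, jitter=None) -> int:
    """Nucleate an Arp2/3 daughter seed at ~70° off the mother axis."""
    if int(state.a_sub[mother_id]) != INTERIOR or int(state.a_arp[mother_id]) >= 0:
        raise ValueError("branching mother must be a plain interior node")
    if state.pools["arp_active"] < 1:
        raise ValueError("no free activated Arp2/3")
    prv, nxt = int(state.a_prev[mother_id]), int(state.a_next[mother_id])
    axis = state.a_pos[nxt] - state.a_pos[prv]
    n = math.hypot(*axis)
    axis = axis / n
    if side is None:
        side = 1.0 if state.rng.random() < 0.5 else -1.0
    if jitter is None:
        jitter = float(state.rng.normal(0.0, p.sigma_theta))
    ang = side * p.theta_arp + jitter
    c, s = math.cos(ang), math.sin(ang)
    x = state.a_pos[mother_id] + np.array([c * axis[0] - s * axis[1],
                                           s * axis[0] + c * axis[1]])
    x = _clamp_to_membrane(state, state.a_pos[mother_id], x)
    seed = state.add_actin(x, ARP_END, prev=mother_id, nxt=-1)
    state.a_arp[mother_id] = seed
    state.a_sub[mother_id] = JUNCTION
    state.pools["arp_active"] -= 1
    return seed


def apply_unbranching(state: SimState, junction_id: int, p: ModelParams) -> list[int]:
    """Reverse nucleation: remove a bare seed, restore ◯, release Arp2/3."""
    d = int(state.a_arp[junction_id])
    if d < 0 or int(state.a_sub[d]) != ARP_END:
        raise ValueError("unbranching requires a junction with a bare seed")
    state.kill_actin(d)
    state.a_arp[junction_id] = -1
    state.a_sub[junction_id] = INTERIOR
    state.pools["arp_active"] += 1
    return [junction_id, d]


def apply_capping(state: SimState, end_id: int, p: ModelParams,
                  clamp_pools: bool = False) -> None:
    if not cappable(state, end_id):
        raise ValueError(f"node {end_id} is not an uncapped barbed end")
    if not clamp_pools and state.pools["cap"] < 1:
        raise ValueError("no free capping protein")
    state.a_sub[end_id] = CAPPED
    if not clamp_pools:
        state.pools["cap"] -= 1


def apply_uncapping(state: SimState, end_id: int, p: ModelParams,
                    clamp_pools: bool = False) -> None:
    if int(state.a_sub[end_id]) != CAPPED:
        raise ValueError(f"node {end_id} is not capped")
    state.a_sub[end_id] = END
    if not clamp_pools:
        state.pools["cap"] += 1


def apply_cofilin_bind(state: SimState, i: int, p: ModelParams,
                       clamp_pools: bool = False) -> None:
    """One cofilin converts one ADP (preferred) or ADP+Pi monomer slot."""
    if state.a_adp[i] > 0:
        state.a_adp[i] -= 1
    elif state.a_adppi[i] > 0:
        state.a_adppi[i] -= 1
    else:
        raise ValueError("no ADP/ADP+Pi substrate for cofilin binding")
    state.a_cof[i] += 1
    if not clamp_pools:
        state.pools["cofilin"] -= 1


def apply_cofilin_unbind(state: SimState, i: int, p: ModelParams,
                         clamp_pools: bool = False) -> None:
    if state.a_cof[i] < 1:
        raise ValueError("no bound cofilin")
    state.a_cof[i] -= 1
    state.a_adp[i] += 1
    if not clamp_pools:
        state.pools["cofilin"] += 1


def apply_hydrolysis(state: SimState, i: int) -> None:
    if state.a_atp[i] < 1:
        raise ValueError("no ATP monomer to hydrolyze")
    state.a_atp[i] -= 1
    state.a_adppi[i] += 1


def apply_pi_release(state: SimState, i: int) -> None:
    if state.a_adppi[i] < 1:
        raise ValueError("no ADP+Pi monomer")
    state.a_adppi[i] -= 1
    state.a_adp[i] += 1


# ----------------------------------------------------------------------
# cofilin / phosphate propensities
# ----------------------------------------------------------------------

def cofilin_neighbor_full(state: SimState, i: int, p: ModelParams) -> bool:
    """A filament neighbor is fully cofilin-decorated (2-node acceleration)."""
    for j in state.filament_neighbors(i):
        if int(state.a_cof[j]) >= p.n_cg:
            return True
    return False


def cofilin_bind_coeff(state: SimState, i: int, p: ModelParams) -> float:
    """Per-free-cofilin binding propensity coefficient for node i (molar k).

    Accelerated (edge) rates apply when the node already carries cofilin or
    a neighbor is fully decorated; otherwise the slow isolated rate.  The
    result multiplies ``number_rate`` and the free-cofilin count.
    """
    if int(state.a_sub[i]) in st.ARP_SUBTYPES:
        return 0.0
    nadp, napi = int(state.a_adp[i]), int(state.a_adppi[i])
    if nadp + napi == 0:
        return 0.0
    if int(state.a_cof[i]) >= 1 or cofilin_neighbor_full(state, i, p):
        return p.k_cof_edge_adp * nadp + p.k_cof_edge_adppi * napi
    return p.k_cof_single * (nadp + napi)


def cofilin_near(state: SimState, i: int) -> bool:
    if int(state.a_cof[i]) > 0:
        return True
    return any(int(state.a_cof[j]) > 0 for j in state.filament_neighbors(i))


def pi_release_rate(state: SimState, i: int, p: ModelParams) -> float:
    n = int(state.a_adppi[i])
    if n == 0:
        return 0.0
    k = p.k_pi_cof if cofilin_near(state, i) else p.k_pi
    return k * n


def cofilin_rules(state: SimState, p: ModelParams, area_u: float) -> list[RuleInstance]:
    """Explicit rule instances for cofilin binding/unbinding (introspection)."""
    out = []
    ncof_free = state.pools["cofilin"]
    for i in state.actin_ids():
        i = int(i)
        if int(state.a_sub[i]) in st.ARP_SUBTYPES:
            continue
        nadp, napi = int(state.a_adp[i]), int(state.a_adppi[i])
        sub_total = nadp + napi
        if sub_total > 0:
            if int(state.a_cof[i]) >= 1:
                k = p.k_cof_edge_adp * nadp + p.k_cof_edge_adppi * napi
                out.append(RuleInstance(
                    "cofilin_bind_accelerated_1node", (i,),
                    number_rate(k, area_u, p) * ncof_free))
            elif cofilin_neighbor_full(state, i, p):
                k = p.k_cof_edge_adp * nadp + p.k_cof_edge_adppi * napi
                out.append(RuleInstance(
                    "cofilin_bind_accelerated_2node", (i,),
                    number_rate(k, area_u, p) * ncof_free))
            else:
                out.append(RuleInstance(
                    "cofilin_bind_bare", (i,),
                    number_rate(p.k_cof_single * sub_total, area_u, p) * ncof_free))
        if int(state.a_cof[i]) > 0:
            out.append(RuleInstance(
                "cofilin_unbind", (i,), p.k_cof_off * int(state.a_cof[i])))
    return out


def phosphate_release_rules(state: SimState, p: ModelParams) -> list[RuleInstance]:
    out = []
    for i in state.actin_ids():
        i = int(i)
        if int(state.a_atp[i]) > 0:
            out.append(RuleInstance(
                "atp_hydrolysis", (i,), p.k_atp_hydrolysis * int(state.a_atp[i])))
        r = pi_release_rate(state, i, p)
        if r > 0:
            out.append(RuleInstance("pi_release", (i,), r))
    return out


# ----------------------------------------------------------------------
# bundling
# ----------------------------------------------------------------------

def node_axis(state: SimState, i: int):
    """Unit axis of the filament through node i, or None for isolated nodes."""
    prv, nxt = int(state.a_prev[i]), int(state.a_next[i])
    if prv >= 0 and nxt >= 0:
        d = state.a_pos[nxt] - state.a_pos[prv]
    elif nxt >= 0:
        d = state.a_pos[nxt] - state.a_pos[i]
    elif prv >= 0:
        d = state.a_pos[i] - state.a_pos[prv]
    else:
        return None
    n = math.hypot(*d)
    return None if n < 1e-12 else d / n


def bundling_eligibility(state: SimState, a: int, b: int, p: ModelParams) -> bool:
    """CaMKIIβ can crosslink a, b: close, nearly parallel, distinct filaments."""
    if a == b:
        raise ValueError("self-bundling")
    if int(state.a_bundle[a]) >= 0 or int(state.a_bundle[b]) >= 0:
        return False
    if b in state.filament_neighbors(a):
        return False
    d = math.hypot(*(state.a_pos[a] - state.a_pos[b]))
    if d > p.d_u or d < 1e-12:
        return False
    ax_a, ax_b = node_axis(state, a), node_axis(state, b)
    if ax_a is None or ax_b is None:
        return False
    cosang = abs(float(ax_a @ ax_b))          # axis is direction-free
    cosang = min(1.0, cosang)
    return math.acos(cosang) <= p.theta_bundle


def apply_bundle(state: SimState, a: int, b: int, p: ModelParams,
                 clamp_pools: bool = False) -> int:
    rest = math.hypot(*(state.a_pos[a] - state.a_pos[b]))
    bid = state.add_bundle(a, b, rest)
    if not clamp_pools:
        state.pools["cam"] -= 1
    return bid


def apply_unbundle(state: SimState, bid: int, p: ModelParams,
                   clamp_pools: bool = False) -> tuple[int, int]:
    a, b, _ = state.bundles[bid]
    state.remove_bundle(bid)
    if not clamp_pools:
        state.pools["cam"] += 1
    return a, b


# ----------------------------------------------------------------------
# severing / junction breaking
# ----------------------------------------------------------------------

def severing_predicate(theta1: float, theta2: float, n_cof1: int, n_cof2: int,
                       dist: float, p: ModelParams) -> bool:
    """Disjunction of Heaviside clauses for cutting a filament edge.

    Bare-actin clause (θ ≥ θ_break,Actin, no cofilin on that node),
    cofilactin clause (θ ≥ θ_break,Cofilactin, majority cofilin),
    boundary clause (θ ≥ θ_break,Boundary, differing cofilin across the
    edge), and the rod-distance clause (d ≥ d_break).  Thresholds fire at
    equality (H(0) = 1).
    """
    t1, t2 = abs(theta1), abs(theta2)
    half = p.n_cg / 2.0
    boundary = n_cof1 != n_cof2
    return (
        (t1 >= p.theta_break_actin and n_cof1 == 0)
        or (t2 >= p.theta_break_actin and n_cof2 == 0)
        or (t1 >= p.theta_break_cofilactin and n_cof1 >= half)
        or (t2 >= p.theta_break_cofilactin and n_cof2 >= half)
        or (t1 >= p.theta_break_boundary and boundary)
        or (t2 >= p.theta_break_boundary and boundary)
        or (dist >= p.d_break)
    )


def _node_bend(state: SimState, i: int) -> float:
    prv, nxt = int(state.a_prev[i]), int(state.a_next[i])
    if prv < 0 or nxt < 0:
        return 0.0
    try:
        return bend_angle(state.a_pos[prv], state.a_pos[i], state.a_pos[nxt])
    except ValueError:
        return 0.0


def edge_severs(state: SimState, i: int, j: int, p: ModelParams) -> bool:
    """Evaluate the severing predicate on the interior edge i -> j."""
    if int(state.a_next[i]) != j:
        raise ValueError(f"{i} -> {j} is not a filament edge")
    if int(state.a_sub[i]) != INTERIOR or int(state.a_sub[j]) != INTERIOR:
        return False
    dist = math.hypot(*(state.a_pos[i] - state.a_pos[j]))
    return severing_predicate(_node_bend(state, i), _node_bend(state, j),
                              int(state.a_cof[i]), int(state.a_cof[j]),
                              dist, p)


def apply_sever(state: SimState, i: int, j: int, p: ModelParams) -> list[int]:
    """Cut the edge i -> j; both cut faces become uncapped ends."""
    if int(state.a_next[i]) != j:
        raise ValueError(f"{i} -> {j} is not a filament edge")
    state.a_next[i] = -1
    state.a_prev[j] = -1
    state.a_sub[i] = END
    state.a_sub[j] = END
    return [i, j]


def _dissolve_isolated(state: SimState, i: int, p: ModelParams) -> None:
    """Return an orphaned single segment to the free pools."""
    if int(state.a_sub[i]) in st.ARP_SUBTYPES:
        state.pools["arp_active"] += 1
    else:
        state.pools["actin"] += p.n_cg
        state.pools["cofilin"] += int(state.a_cof[i])
        state.pools["actin"] -= 0  # monomer identities are not tracked in the pool
    state.kill_actin(i)


def apply_distance_break(state: SimState, a: int, b: int,
                         p: ModelParams) -> list[int]:
    """Electrostatic disconnection of an over-stretched rod (any edge type).

    The Morse bond is flat at large separation, so a rod beyond d_break is
    mechanically broken; the edge is removed and any segment left with no
    neighbors dissolves back into the free pools.
    """
    if int(state.a_next[a]) != b:
        raise ValueError(f"{a} -> {b} is not a filament edge")
    state.a_next[a] = -1
    state.a_prev[b] = -1
    touched = []
    for i, endside in ((a, "barbed"), (b, "pointed")):
        sub = int(state.a_sub[i])
        if not state.filament_neighbors(i):
            _dissolve_isolated(state, i, p)
            touched.append(i)
            continue
        if sub == ARP_INTERIOR and endside == "barbed":
            state.a_sub[i] = ARP_END
        elif sub == INTERIOR:
            state.a_sub[i] = END
        touched.append(i)
    return touched


def junction_break_predicate(state: SimState, jid: int, p: ModelParams) -> bool:
    """Branch detaches when its angle strays ≥ θ_break,Arp from 70°,
    or the branch rod stretches past d_break."""
    d = int(state.a_arp[jid])
    prv = int(state.a_prev[jid])
    if d < 0 or prv < 0:
        return False
    v_b = state.a_pos[d] - state.a_pos[jid]
    v_m = state.a_pos[jid] - state.a_pos[prv]
    nb, nm = math.hypot(*v_b), math.hypot(*v_m)
    if nb < 1e-12 or nm < 1e-12:
        return False
    if nb >= p.d_break:
        return True
    cosang = max(-1.0, min(1.0, float(v_b @ v_m) / (nb * nm)))
    phi = math.acos(cosang)
    return abs(phi - p.theta_arp) >= p.theta_break_arp


def apply_junction_break(state: SimState, jid: int, p: ModelParams) -> list[int]:
    """Detach the branch at a junction; the Arp2/3 complex is released.

    A bare seed reduces to unbranching; a grown daughter loses its Arp2/3
    head node and becomes a free filament with a new pointed end.
    """
    d = int(state.a_arp[jid])
    if d < 0:
        raise ValueError(f"node {jid} has no branch")
    if int(state.a_sub[d]) == ARP_END:
        return apply_unbranching(state, jid, p)
    first = int(state.a_next[d])              # first actin node of the daughter
    state.kill_actin(d)
    state.a_arp[jid] = -1
    state.a_sub[jid] = INTERIOR
    state.pools["arp_active"] += 1
    touched = [jid, d]
    if first >= 0:
        state.a_prev[first] = -1
        if not state.filament_neighbors(first):
            _dissolve_isolated(state, first, p)
        elif int(state.a_sub[first]) == INTERIOR:
            state.a_sub[first] = END
        touched.append(first)
    return touched


def check_local_breaks(state: SimState, ids, p: ModelParams) -> list[int]:
    """Fire every severing/junction-break whose predicate holds near ``ids``.

    These rules carry the instantaneous rate k_instant, so they are applied
    immediately after any event that can make them true.  Returns touched
    node ids.
    """
    touched: list[int] = []
    seen = set()
    frontier = set()
    for i in ids:
        if state.a_alive[i]:
            frontier.add(int(i))
            frontier.update(state.filament_neighbors(int(i)))
    for i in frontier:
        if not state.a_alive[i]:
            continue
        if int(state.a_sub[i]) == JUNCTION and junction_break_predicate(state, i, p):
            touched += apply_junction_break(state, i, p)
            continue
        for j in (int(state.a_prev[i]), int(state.a_next[i])):
            if j < 0 or not state.a_alive[j]:
                continue
            a, b = (j, i) if int(state.a_next[j]) == i else (i, j)
            if int(state.a_next[a]) != b or (a, b) in seen:
                continue
            seen.add((a, b))
            if int(state.a_sub[a]) == INTERIOR and int(state.a_sub[b]) == INTERIOR:
                if edge_severs(state, a, b, p):
                    touched += apply_sever(state, a, b, p)
            elif JUNCTION not in (int(state.a_sub[a]), int(state.a_sub[b])):
                dist = math.hypot(*(state.a_pos[a] - state.a_pos[b]))
                if dist >= p.d_break:
                    touched += apply_distance_break(state, a, b, p)
    return touched


# ----------------------------------------------------------------------
# species pools (deterministic synthesis/degradation)
# ----------------------------------------------------------------------

_ODE_SPECIES = (
    ("actin", "i_actin", "k_deg_actin"),
    ("arp_active", "i_arp", "k_deg_arp"),
    ("cofilin", "i_cof", "k_deg_cof"),
    ("cam", "i_cam", "k_deg_cam"),
    ("cap", "i_cap", "k_deg_cap"),
)


def species_ode_step(pools: dict, dt: float, p: ModelParams,
                     area_u: float) -> dict:
    """Advance the free pools by the exact solution of dN/dt = I·V·N_A - k·N.

    Influx is converted from M/s to counts/s through the slab volume; each
    pool relaxes exponentially toward its steady state (I/k in molar).
    Degradation (but no synthesis) also acts on the inactive Arp2/3 pool.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    for name, iname, kname in _ODE_SPECIES:
        influx = getattr(p, iname)
        k = getattr(p, kname)
        n = pools[name]
        if k > 0:
            nss = p.count_from_molar(influx / k, area_u)
            pools[name] = nss + (n - nss) * math.exp(-k * dt)
        else:
            pools[name] = n + p.count_from_molar(influx, area_u) * dt
        pools[name] = max(pools[name], 0.0)
    if p.k_deg_arp > 0:
        pools["arp_inactive"] = max(
            pools["arp_inactive"] * math.exp(-p.k_deg_arp * dt), 0.0)
    return pools


def initialize_pools(state: SimState, p: ModelParams, area_u: float) -> None:
    ss = p.steady_state_molar()
    state.pools["actin"] = p.count_from_molar(ss["actin"], area_u)
    state.pools["arp_active"] = p.count_from_molar(ss["arp"], area_u)
    state.pools["arp_inactive"] = 0.0
    state.pools["cofilin"] = p.count_from_molar(ss["cofilin"], area_u)
    state.pools["cam"] = p.count_from_molar(ss["cam"], area_u)
    state.pools["cap"] = p.count_from_molar(ss["cap"], area_u)


# ----------------------------------------------------------------------
# rule catalog
# ----------------------------------------------------------------------

def rule_catalog():
    """Machine-readable rule table (name, LHS arity, rate law)."""
    import pandas as pd
    rows = [
        ("barbed_elongation", 2, "k_barbed,on,η/NCG · [A] per uncapped barbed end"),
        ("barbed_retraction", 3, "harmonic-mean k_barbed,off of the end segment"),
        ("pointed_elongation", 2, "k_pointed,on,η/NCG · [A] per pointed end"),
        ("pointed_retraction", 3, "harmonic-mean k_pointed,off of the end segment"),
        ("branching", 1, "keq·k2 · [Arp2/3_active] per plain interior node"),
        ("unbranching", 1, "k-2 per junction with a bare seed"),
        ("arp_inactive_bind", 1, "k1 · [Arp2/3_inactive] per free sub-site"),
        ("arp_inactive_unbind", 1, "k-1 per bound inactive Arp2/3"),
        ("capping", 1, "k_cap,on · [Cap] per uncapped barbed end"),
        ("uncapping", 1, "k_cap,off per capped end"),
        ("cofilin_bind_accelerated_1node", 1,
         "H(N_cof-1) · k_on-edge,η · N_η · [Cof]"),
        ("cofilin_bind_accelerated_2node", 2,
         "δ(N_cof,0) · H(nbr N_cof - NCG) · k_on-edge,η · N_η · [Cof]"),
        ("cofilin_bind_bare", 1, "δ(N_cof,0) · k_on-single · (N_ADP+N_ADPPi) · [Cof]"),
        ("cofilin_unbind", 1, "k_off · N_cof"),
        ("atp_hydrolysis", 1, "k_ATP,hyd · N_ATP"),
        ("pi_release", 1, "(k_Pi | k_cof,Pi if cofilin near) · N_ADPPi"),
        ("bundling", 2, "k_CaMKII,on · [CaM] per eligible (d ≤ DU, θ ≤ θ_B) pair"),
        ("unbundling", 2, "k_CaMKII,off per bundle bond"),
        ("severing", 2, "k_instant · max(Heaviside clauses)"),
        ("junction_breaking", 2, "k_instant · H(|φ-70°| - θ_break,Arp)"),
        ("dissipative_buckling", 1, "k_kinetic per node"),
        ("thermal_noise", 1, "k_kinetic per node"),
        ("membrane_update", 1, "k_kinetic per membrane vertex"),
    ]
    return pd.DataFrame(rows, columns=["name", "lhs_arity", "rate_law"])
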