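"""Hybrid stochastic simulation engine.

One exact-SSA clock (direct method) drives every rule instance: remodeling
grammar events, per-node dissipative and thermal mechanics updates (each at
rate ``k_kinetic`` per eligible node), and membrane vertex updates.  Between
stochastic events the free species pools advance deterministically by the
exact exponential solution of their synthesis/degradation equations, at
fixed checkpoint intervals where propensities are also refreshed, the
membrane is remeshed, bundling candidate pairs are rescanned, and flagged
Brownian-ratchet attachments are released.

Severing and junction breaking carry the instantaneous rate, so they are
applied eagerly after any event that can enable them.  Matches are
re-validated at firing time; an invalidated match consumes the time step
but rewrites nothing (rejection SSA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import grammar as gr
from . import mechanics as mech
from . import membrane as mb
from . import state as st
from .params import ModelParams
from .state import SimState

ALL_GROUPS = frozenset({
    "elongation", "retraction", "capping", "branching", "cofilin",
    "phosphate", "bundling", "arp_inactive", "mechanics", "thermal",
    "membrane", "breaks", "attach", "ode",
})


@dataclass
class RunConfig:
    params: ModelParams = field(default_factory=ModelParams)
    t_end: float = 0.6                 # s of biological time
    seed: int = 0
    sample_interval: float = 0.01      # s between observable rows
    dt_ode: float = 0.001              # s, pool/propensity checkpoint interval
    mem_radius_um: float = 0.18        # initial membrane circumradius (snug around the seed)
    n_mem_vertices: int = 32
    thermal_noise: bool = True
    membrane_on: bool = True
    clamp_pools: bool = False
    rule_groups: frozenset = ALL_GROUPS
    bundle_scan_every: int = 10        # checkpoints between pair rescans
    remesh_every: int = 10             # checkpoints between remeshes
    trajectory_path: str | None = None

    def __post_init__(self):
        if self.t_end < 0:
            raise ValueError("t_end must be >= 0")
        if self.sample_interval <= 0 or self.dt_ode <= 0:
            raise ValueError("sampling and checkpoint intervals must be > 0")
        self.rule_groups = frozenset(self.rule_groups)
        unknown = self.rule_groups - ALL_GROUPS
        if unknown:
            raise ValueError(f"unknown rule groups: {sorted(unknown)}")


class ListSet:
    """Set with O(1) add/discard and O(1) uniform sampling by index."""

    __slots__ = ("items", "pos")

    def __init__(self):
        self.items: list[int] = []
        self.pos: dict[int, int] = {}

    def add(self, x: int) -> None:
        if x not in self.pos:
            self.pos[x] = len(self.items)
            self.items.append(x)

    def discard(self, x: int) -> None:
        k = self.pos.pop(x, None)
        if k is None:
            return
        last = self.items.pop()
        if k < len(self.items):
            self.items[k] = last
            self.pos[last] = k

    def __contains__(self, x) -> bool:
        return x in self.pos

    def __len__(self) -> int:
        return len(self.items)

    def sample(self, rng) -> int:
        return self.items[int(rng.integers(len(self.items)))]


# ----------------------------------------------------------------------
# initial state
# ----------------------------------------------------------------------

def build_initial_state(config: RunConfig) -> SimState:
    """Default spine scenario: a four-object seed network with one Arp2/3
    junction inside a small regular membrane polygon; pools at their
    synthesis/degradation steady states."""
    p = config.params
    state = SimState(seed=config.seed)
    r_units = config.mem_radius_um * 1e-6 / p.unit_m
    n = config.n_mem_vertices
    ang = 2 * np.pi * np.arange(n) / n
    poly = r_units * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    state.set_membrane_polygon(poly)

    n1 = state.add_actin((-1.0, 0.0), st.END, atp=p.n_cg)
    n2 = state.add_actin((0.0, 0.0), st.JUNCTION, atp=p.n_cg)
    n3 = state.add_actin((1.0, 0.0), st.END, atp=p.n_cg)
    seed = state.add_actin(
        (math.cos(p.theta_arp), math.sin(p.theta_arp)), st.ARP_END)
    state.a_next[n1] = n2
    state.a_prev[n2] = n1
    state.a_next[n2] = n3
    state.a_prev[n3] = n2
    state.a_arp[n2] = seed
    state.a_prev[seed] = n2

    area = mb.polygon_area(state.membrane_coords())
    gr.initialize_pools(state, p, area)
    max_r = max(float(np.hypot(*state.a_pos[i])) for i in state.actin_ids())
    if max_r >= r_units:
        raise ValueError("seed actin network lies outside the membrane polygon")
    errs = st.validate_state(state, p.n_cg)
    if errs:
        raise RuntimeError(f"initial state invalid: {errs}")
    return state


# ----------------------------------------------------------------------
# engine
# ----------------------------------------------------------------------

class Engine:
    def __init__(self, config: RunConfig, state: SimState | None = None):
        self.config = config
        self.p = config.params
        self.state = state if state is not None else build_initial_state(config)
        self.groups = config.rule_groups
        self.rule_counts: dict[str, int] = {}
        self.rejected = 0

        s = self.state
        self.all_actin = ListSet()
        self.ends = ListSet()          # uncapped filament ends (END or ■)
        self.elig_barbed = ListSet()
        self.elig_pointed = ListSet()
        self.retr_barbed = ListSet()
        self.retr_pointed = ListSet()
        self.cappable = ListSet()
        self.capped = ListSet()
        self.branchable = ListSet()
        self.bare_junctions = ListSet()
        self.mem_verts = ListSet()
        for i in s.actin_ids():
            self.refresh_node(int(i))
        for v in s.membrane_cycle():
            self.mem_verts.add(int(v))

        self.area = mb.polygon_area(s.membrane_coords())
        coords = s.membrane_coords()
        self.l0 = mb.polygon_perimeter(coords) / len(coords)
        self._update_mem_bounds()
        self.eligible_pairs: list[tuple[int, int]] = []
        self._chem_dirty = True
        self._chem: dict = {}
        self._cp_count = 0
        self._scan_pairs()

    # -- index maintenance ---------------------------------------------

    def refresh_node(self, i: int) -> None:
        s, p = self.state, self.p
        for ls in (self.all_actin, self.ends, self.elig_barbed,
                   self.elig_pointed, self.retr_barbed, self.retr_pointed,
                   self.cappable, self.capped, self.branchable,
                   self.bare_junctions):
            ls.discard(i)
        if not s.a_alive[i]:
            return
        self.all_actin.add(i)
        sub = int(s.a_sub[i])
        if sub in (st.END, st.ARP_END):
            self.ends.add(i)
        if gr.barbed_elongable(s, i):
            self.elig_barbed.add(i)
        if gr.pointed_elongable(s, i):
            self.elig_pointed.add(i)
        if gr.barbed_retractable(s, i):
            self.retr_barbed.add(i)
        if gr.pointed_retractable(s, i):
            self.retr_pointed.add(i)
        if gr.cappable(s, i):
            self.cappable.add(i)
        if sub == st.CAPPED:
            self.capped.add(i)
        if gr.branchable(s, i, p):
            self.branchable.add(i)
        if sub == st.JUNCTION and gr.junction_is_bare(s, i):
            self.bare_junctions.add(i)

    def refresh_around(self, ids) -> None:
        seen = set()
        for i in ids:
            i = int(i)
            if i in seen:
                continue
            seen.add(i)
            self.refresh_node(i)
            if self.state.a_alive[i]:
                for j in self.state.filament_neighbors(i):
                    if j not in seen:
                        seen.add(j)
                        self.refresh_node(j)
        self._chem_dirty = True

    # -- chemistry propensity cache --------------------------------------

    def _recompute_chem(self) -> None:
        s, p = self.state, self.p
        # the per-node count scans are only needed for chemistry channels;
        # a mechanics/kinetics-only configuration skips them entirely
        need_counts = bool({"cofilin", "phosphate", "arp_inactive",
                            "branching"} & self.groups)
        ids = s.actin_ids() if need_counts else np.zeros(0, dtype=np.intp)
        self._ids = ids
        if len(ids) == 0:
            self._fill_retr()
            self._chem = dict(hyd=0.0, pi=0.0, cof=0.0, cofoff=0.0,
                              arpin_sites=0.0, arpin_bound=0.0,
                              retr_b=float(self._w_retr_b.sum()),
                              retr_p=float(self._w_retr_p.sum()))
            self._chem_dirty = False
            return
        atp = s.a_atp[ids].astype(float)
        adp = s.a_adp[ids].astype(float)
        api = s.a_adppi[ids].astype(float)
        cof = s.a_cof[ids].astype(float)
        prev = s.a_prev[ids]
        nxt = s.a_next[ids]
        arp = s.a_arp[ids]

        def gather(arr, idx):
            out = np.zeros(len(idx), dtype=bool)
            m = idx >= 0
            out[m] = arr[idx[m]]
            return out

        cof_pos = s.a_cof[: s.n_actin_rows] > 0
        cof_full = s.a_cof[: s.n_actin_rows] >= p.n_cg
        near = (cof > 0) | gather(cof_pos, prev) | gather(cof_pos, nxt) \
            | gather(cof_pos, arp)
        nbr_full = gather(cof_full, prev) | gather(cof_full, nxt) \
            | gather(cof_full, arp)

        self._w_hyd = atp
        self._w_pi = api * np.where(near, p.k_pi_cof, p.k_pi)
        acc = (cof >= 1) | nbr_full
        self._w_cof = np.where(
            acc, p.k_cof_edge_adp * adp + p.k_cof_edge_adppi * api,
            p.k_cof_single * (adp + api))
        self._w_cofoff = cof
        interior = s.a_sub[ids] == st.INTERIOR
        arpin = s.a_arpin[ids].astype(float)
        self._fill_retr()
        self._chem = dict(
            hyd=float(atp.sum()),
            pi=float(self._w_pi.sum()),
            cof=float(self._w_cof.sum()),
            cofoff=float(cof.sum()),
            arpin_sites=float(np.where(interior, p.n_cg - arpin, 0.0).sum()),
            arpin_bound=float(arpin.sum()),
            retr_b=float(self._w_retr_b.sum()),
            retr_p=float(self._w_retr_p.sum()),
        )
        self._chem_dirty = False

    def _fill_retr(self) -> None:
        s, p = self.state, self.p
        self._retr_ids_b = list(self.retr_barbed.items)
        self._w_retr_b = np.array([gr.node_off_rate(s, i, p, "barbed")
                                   for i in self._retr_ids_b])
        self._retr_ids_p = list(self.retr_pointed.items)
        self._w_retr_p = np.array([gr.node_off_rate(s, i, p, "pointed")
                                   for i in self._retr_ids_p])

    def _pick_weighted(self, weights: np.ndarray) -> int:
        c = np.cumsum(weights)
        u = self.state.rng.random() * c[-1]
        k = int(np.searchsorted(c, u))
        return int(self._ids[min(k, len(self._ids) - 1)])

    # -- bundling pair scan ----------------------------------------------

    def _scan_pairs(self) -> None:
        if "bundling" not in self.groups:
            self.eligible_pairs = []
            return
        s, p = self.state, self.p
        ids = s.actin_ids()
        if len(ids) < 2:
            self.eligible_pairs = []
            return
        from scipy.spatial import cKDTree
        pos = s.a_pos[ids]
        tree = cKDTree(pos)
        raw = tree.query_pairs(r=p.d_u, output_type="ndarray")
        pairs = []
        for a_k, b_k in raw:
            a, b = int(ids[a_k]), int(ids[b_k])
            try:
                if gr.bundling_eligibility(s, a, b, p):
                    pairs.append((a, b) if a < b else (b, a))
            except ValueError:
                continue
        pairs.sort()
        self.eligible_pairs = pairs

    # -- propensity table -------------------------------------------------

    def _channels(self):
        s, p, g = self.state, self.p, self.groups
        if self._chem_dirty:
            self._recompute_chem()
        ch = []
        conc_a = p.concentration(s.pools["actin"], self.area)
        if "elongation" in g and s.pools["actin"] >= p.n_cg:
            r = gr.elongation_rate_per_end(p, conc_a, "barbed")
            ch.append((r * len(self.elig_barbed), self._fire_barbed_elong))
            r = gr.elongation_rate_per_end(p, conc_a, "pointed")
            ch.append((r * len(self.elig_pointed), self._fire_pointed_elong))
        if "retraction" in g:
            ch.append((self._chem["retr_b"], self._fire_barbed_retr))
            ch.append((self._chem["retr_p"], self._fire_pointed_retr))
        if "capping" in g:
            r = p.number_rate(p.k_cap_on, self.area) * s.pools["cap"]
            ch.append((r * len(self.cappable), self._fire_cap))
            ch.append((p.k_cap_off * len(self.capped), self._fire_uncap))
        if "branching" in g:
            # activated Arp2/3 nucleates on any one of a segment's n_cg
            # sub-sites, so each eligible mother contributes its free-site
            # count to the propensity
            r = p.number_rate(p.k_branch, self.area) * s.pools["arp_active"]
            ch.append((r * self._chem["arpin_sites"], self._fire_branch))
            ch.append((p.k_unbranch * len(self.bare_junctions),
                       self._fire_unbranch))
        if "arp_inactive" in g:
            r = p.number_rate(p.k_arp_inactive_on, self.area) \
                * s.pools["arp_inactive"]
            ch.append((r * self._chem["arpin_sites"], self._fire_arpin_bind))
            ch.append((p.k_arp_inactive_off * self._chem["arpin_bound"],
                       self._fire_arpin_unbind))
        if "cofilin" in g:
            r = p.number_rate(1.0, self.area) * s.pools["cofilin"]
            ch.append((r * self._chem["cof"], self._fire_cof_bind))
            ch.append((p.k_cof_off * self._chem["cofoff"], self._fire_cof_unbind))
        if "phosphate" in g:
            ch.append((p.k_atp_hydrolysis * self._chem["hyd"], self._fire_hyd))
            ch.append((self._chem["pi"], self._fire_pi))
        if "bundling" in g:
            r = p.number_rate(p.k_cam_on, self.area) * s.pools["cam"]
            ch.append((r * len(self.eligible_pairs), self._fire_bundle))
            ch.append((p.k_cam_off * len(s.bundles), self._fire_unbundle))
        if "mechanics" in g:
            ch.append((p.k_kinetic * len(self.all_actin), self._fire_diss))
        if "thermal" in g and self.config.thermal_noise:
            ch.append((p.k_kinetic * len(self.all_actin), self._fire_thermal))
        if "membrane" in g and self.config.membrane_on:
            ch.append((p.k_kinetic * len(self.mem_verts), self._fire_mem))
        return ch

    def _retr_total(self, kind: str) -> float:
        if self._chem_dirty:
            self._recompute_chem()
        return self._chem["retr_b" if kind == "barbed" else "retr_p"]

    # -- event handlers ---------------------------------------------------

    def _count(self, name: str) -> None:
        self.rule_counts[name] = self.rule_counts.get(name, 0) + 1

    def _post_event(self, touched) -> None:
        if "breaks" in self.groups:
            extra = gr.check_local_breaks(self.state, touched, self.p)
            touched = list(touched) + extra
        self.refresh_around(touched)
        if "attach" in self.groups and self.config.membrane_on:
            for i in touched:
                self._try_attach(int(i))

    def _update_mem_bounds(self) -> None:
        pts = self.state.membrane_coords()
        self._mem_centroid = pts.mean(axis=0)
        self._mem_rmin = float(np.hypot(*(pts - self._mem_centroid).T).min())

    def _try_attach(self, i: int) -> None:
        s = self.state
        if not s.a_alive[i] or i in s.attach_end2vert:
            return
        if int(s.a_sub[i]) not in (st.END, st.ARP_END):
            return
        # quick reject: the extended rod cannot reach the membrane from deep
        # inside the polygon (2.5 units covers a stretched rod + overgrowth)
        r = math.hypot(*(s.a_pos[i] - self._mem_centroid))
        if r < self._mem_rmin - 2.5:
            return
        if mb.attach_filament(s, i, self.p):
            vid = s.attach_end2vert[i]
            self.mem_verts.add(vid)
            self._count("attach")

    def _pick_nucleotide(self) -> str:
        p = self.p
        if p.adp_fraction <= 0:
            return "ATP"
        # choice weighted by on-rate × pool fraction (barbed rates as proxy)
        w_atp = p.k_barbed_on_atp * (1 - p.adp_fraction)
        w_adp = p.k_barbed_on_adp * p.adp_fraction
        return "ATP" if self.state.rng.random() < w_atp / (w_atp + w_adp) else "ADP"

    def _fire_barbed_elong(self):
        if not len(self.elig_barbed):
            return None
        i = self.elig_barbed.sample(self.state.rng)
        if not (self.state.a_alive[i] and gr.barbed_elongable(self.state, i)):
            self.refresh_node(i)
            self.rejected += 1
            return None
        new = gr.apply_elongation(self.state, i, self.p,
                                  nucleotide=self._pick_nucleotide(),
                                  clamp_pools=self.config.clamp_pools)
        if new in self.state.attach_end2vert and "attach" in self.groups:
            if mb.ratchet_detach(self.state, new, self.p):
                self._count("ratchet_detach")
        self._post_event([i, new])
        return "barbed_elongation"

    def _fire_pointed_elong(self):
        if not len(self.elig_pointed):
            return None
        i = self.elig_pointed.sample(self.state.rng)
        if not (self.state.a_alive[i] and gr.pointed_elongable(self.state, i)):
            self.refresh_node(i)
            self.rejected += 1
            return None
        new = gr.apply_elongation(self.state, i, self.p,
                                  nucleotide=self._pick_nucleotide(),
                                  clamp_pools=self.config.clamp_pools)
        self._post_event([i, new])
        return "pointed_elongation"

    def _fire_retr(self, kind: str):
        if self._chem_dirty:
            self._recompute_chem()
        ids = self._retr_ids_b if kind == "barbed" else self._retr_ids_p
        w = self._w_retr_b if kind == "barbed" else self._w_retr_p
        if not ids:
            return None
        tot = float(w.sum())
        if tot <= 0:
            return None
        c = np.cumsum(w)
        k = min(int(np.searchsorted(c, self.state.rng.random() * tot)),
                len(ids) - 1)
        i = ids[k]
        if not self.state.a_alive[i]:
            self.rejected += 1
            return None
        s = self.state
        nb = int(s.a_next[i]) if int(s.a_prev[i]) == -1 else int(s.a_prev[i])
        survivors = gr.apply_retraction(s, i, self.p,
                                        clamp_pools=self.config.clamp_pools)
        self.refresh_node(i)
        self.refresh_node(nb)
        self._post_event(survivors if survivors else [])
        return f"{kind}_retraction"

    def _fire_barbed_retr(self):
        return self._fire_retr("barbed")

    def _fire_pointed_retr(self):
        return self._fire_retr("pointed")

    def _fire_cap(self):
        if not len(self.cappable) or self.state.pools["cap"] < 1:
            return None
        i = self.cappable.sample(self.state.rng)
        if not (self.state.a_alive[i] and gr.cappable(self.state, i)):
            self.refresh_node(i)
            self.rejected += 1
            return None
        gr.apply_capping(self.state, i, self.p,
                         clamp_pools=self.config.clamp_pools)
        self._post_event([i])
        return "capping"

    def _fire_uncap(self):
        if not len(self.capped):
            return None
        i = self.capped.sample(self.state.rng)
        gr.apply_uncapping(self.state, i, self.p,
                           clamp_pools=self.config.clamp_pools)
        self._post_event([i])
        return "uncapping"

    def _fire_branch(self):
        s, p = self.state, self.p
        if not len(self.branchable) or s.pools["arp_active"] < 1:
            return None
        if self._chem_dirty:
            self._recompute_chem()
        interior = (s.a_sub[self._ids] == st.INTERIOR)
        w = np.where(interior, p.n_cg - s.a_arpin[self._ids], 0).astype(float)
        if w.sum() <= 0:
            return None
        i = self._pick_weighted(w)
        if not gr.branchable(s, i, p):
            self.rejected += 1
            return None
        if self.config.membrane_on and not mb.point_in_polygon(
                s.membrane_coords(), s.a_pos[i]):
            self.rejected += 1
            return None
        seed = gr.apply_branching(s, i, p)
        self._post_event([i, seed])
        return "branching"

    def _fire_unbranch(self):
        if not len(self.bare_junctions):
            return None
        j = self.bare_junctions.sample(self.state.rng)
        touched = gr.apply_unbranching(self.state, j, self.p)
        self._post_event(touched)
        return "unbranching"

    def _fire_arpin_bind(self):
        s, p = self.state, self.p
        if s.pools["arp_inactive"] < 1:
            return None
        if self._chem_dirty:
            self._recompute_chem()
        interior = (s.a_sub[self._ids] == st.INTERIOR)
        w = np.where(interior, p.n_cg - s.a_arpin[self._ids], 0).astype(float)
        if w.sum() <= 0:
            return None
        i = self._pick_weighted(w)
        s.a_arpin[i] += 1
        s.pools["arp_inactive"] -= 1
        self._post_event([i])
        return "arp_inactive_bind"

    def _fire_arpin_unbind(self):
        s = self.state
        if self._chem_dirty:
            self._recompute_chem()
        w = s.a_arpin[self._ids].astype(float)
        if w.sum() <= 0:
            return None
        i = self._pick_weighted(w)
        s.a_arpin[i] -= 1
        s.pools["arp_inactive"] += 1
        self._post_event([i])
        return "arp_inactive_unbind"

    def _fire_cof_bind(self):
        s = self.state
        if s.pools["cofilin"] < 1:
            return None
        if self._chem_dirty:
            self._recompute_chem()
        if self._chem["cof"] <= 0:
            return None
        i = self._pick_weighted(self._w_cof)
        if int(s.a_adp[i]) + int(s.a_adppi[i]) == 0:
            self.rejected += 1
            return None
        gr.apply_cofilin_bind(s, i, self.p,
                              clamp_pools=self.config.clamp_pools)
        self._post_event([i])
        return "cofilin_bind"

    def _fire_cof_unbind(self):
        s = self.state
        if self._chem_dirty:
            self._recompute_chem()
        if self._chem["cofoff"] <= 0:
            return None
        i = self._pick_weighted(self._w_cofoff)
        if int(s.a_cof[i]) == 0:
            self.rejected += 1
            return None
        gr.apply_cofilin_unbind(s, i, self.p,
                                clamp_pools=self.config.clamp_pools)
        self._post_event([i])
        return "cofilin_unbind"

    def _fire_hyd(self):
        s = self.state
        if self._chem_dirty:
            self._recompute_chem()
        if self._chem["hyd"] <= 0:
            return None
        i = self._pick_weighted(self._w_hyd)
        if int(s.a_atp[i]) == 0:
            self.rejected += 1
            return None
        gr.apply_hydrolysis(s, i)
        self._chem_dirty = True
        return "atp_hydrolysis"

    def _fire_pi(self):
        s = self.state
        if self._chem_dirty:
            self._recompute_chem()
        if self._chem["pi"] <= 0:
            return None
        i = self._pick_weighted(self._w_pi)
        if int(s.a_adppi[i]) == 0:
            self.rejected += 1
            return None
        gr.apply_pi_release(s, i)
        self._chem_dirty = True
        return "pi_release"

    def _fire_bundle(self):
        s = self.state
        if not self.eligible_pairs or s.pools["cam"] < 1:
            return None
        k = int(s.rng.integers(len(self.eligible_pairs)))
        a, b = self.eligible_pairs[k]
        if not (s.a_alive[a] and s.a_alive[b]):
            self.rejected += 1
            return None
        try:
            ok = gr.bundling_eligibility(s, a, b, self.p)
        except ValueError:
            ok = False
        if not ok:
            self.rejected += 1
            return None
        gr.apply_bundle(s, a, b, self.p, clamp_pools=self.config.clamp_pools)
        self.eligible_pairs.pop(k)
        self._post_event([a, b])
        return "bundling"

    def _fire_unbundle(self):
        s = self.state
        if not s.bundles:
            return None
        bids = sorted(s.bundles)
        bid = bids[int(s.rng.integers(len(bids)))]
        a, b = gr.apply_unbundle(s, bid, self.p,
                                 clamp_pools=self.config.clamp_pools)
        self._post_event([a, b])
        return "unbundling"

    def _move_constraint(self, i: int):
        """Membrane impenetrability for actin node moves (with a cheap
        deep-interior bypass: small steps far from the boundary cannot
        cross it)."""
        if not self.config.membrane_on:
            return None
        s = self.state
        r = math.hypot(*(s.a_pos[i] - self._mem_centroid))
        if r < self._mem_rmin - 1.0:
            return None
        return lambda x0, x1: not mb.crosses_membrane(s, x0, x1)

    def _fire_diss(self):
        if not len(self.all_actin):
            return None
        i = self.all_actin.sample(self.state.rng)
        mech.dissipative_step(self.state, i, self.p,
                              constraint=self._move_constraint(i))
        self._after_move(i)
        return "dissipative"

    def _fire_thermal(self):
        if not len(self.all_actin):
            return None
        i = self.all_actin.sample(self.state.rng)
        moved = mech.thermal_step(self.state, i, self.p,
                                  constraint=self._move_constraint(i))
        if moved is not None:
            self._after_move(i)
        return "thermal"

    def _after_move(self, i: int) -> None:
        if "breaks" in self.groups:
            extra = gr.check_local_breaks(self.state, [i], self.p)
            if extra:
                self.refresh_around([i] + extra)
        if "attach" in self.groups and self.config.membrane_on:
            self._try_attach(i)

    def _fire_mem(self):
        if not len(self.mem_verts):
            return None
        v = self.mem_verts.sample(self.state.rng)
        mb.membrane_step(self.state, v, self.p)
        return "membrane"

    # -- SSA ------------------------------------------------------------

    def ssa_step(self, max_dt: float = math.inf):
        """Draw dt ~ Exp(total rate) and fire one event ∝ its propensity.

        Returns ``(event_name, dt)``.  If the total rate is zero the result
        is ``(None, inf)``; if the drawn waiting time reaches ``max_dt`` the
        event is *not* fired and ``(None, dt)`` is returned so the caller
        can advance to its checkpoint boundary.  A stale match consumes the
        step and returns ``("rejected", dt)``.
        """
        ch = self._channels()
        totals = np.array([c[0] for c in ch]) if ch else np.zeros(0)
        big_r = float(totals.sum())
        if big_r <= 0:
            return None, math.inf
        rng = self.state.rng
        dt = rng.exponential(1.0 / big_r)
        if dt >= max_dt:
            return None, dt
        u = rng.random() * big_r
        k = int(np.searchsorted(np.cumsum(totals), u))
        k = min(k, len(ch) - 1)
        name = ch[k][1]()
        if name is None:
            return "rejected", dt
        self._count(name)
        return name, dt

    # -- checkpoints ------------------------------------------------------

    def hybrid_advance(self, dt: float) -> None:
        """Deterministic inter-event update: pools, remesh, pair scan,
        ratchet release, attachment sweep, propensity refresh."""
        s, p = self.state, self.p
        self.area = mb.polygon_area(s.membrane_coords())
        self._update_mem_bounds()
        if "ode" in self.groups and not self.config.clamp_pools and dt > 0:
            gr.species_ode_step(s.pools, dt, p, self.area)
        self._cp_count += 1
        if self.config.membrane_on:
            if "attach" in self.groups:
                for e in sorted(s.attach_end2vert):
                    if mb.ratchet_detach(s, e, p):
                        self._count("ratchet_detach")
                        self._try_attach(e)
                for i in list(self.ends.items):
                    self._try_attach(i)
            if self._cp_count % self.config.remesh_every == 0:
                mb.remesh(s, p, self.l0)
                self.mem_verts = ListSet()
                for v in s.membrane_cycle():
                    self.mem_verts.add(int(v))
        if self._cp_count % self.config.bundle_scan_every == 0:
            self._scan_pairs()
        self._chem_dirty = True

    # -- main loop --------------------------------------------------------

    def run(self, observer=None):
        """Advance to t_end; call ``observer(state, engine)`` at each sample
        time (including t = 0 and t_end)."""
        cfg = self.config
        s = self.state
        t_end = s.t + cfg.t_end if s.t > 0 else cfg.t_end
        if observer is not None:
            observer(s, self)
        last_obs = s.t
        next_sample = s.t + cfg.sample_interval
        next_cp = s.t + cfg.dt_ode
        last_cp = s.t
        while s.t < t_end - 1e-15:
            boundary = min(next_cp, next_sample, t_end)
            ev, dt = self.ssa_step(max_dt=boundary - s.t)
            if ev is None:
                s.t = boundary
                self.hybrid_advance(s.t - last_cp)
                last_cp = s.t
                if boundary >= next_cp - 1e-15:
                    next_cp += cfg.dt_ode
                if boundary >= next_sample - 1e-15:
                    if observer is not None:
                        observer(s, self)
                    last_obs = s.t
                    next_sample += cfg.sample_interval
            else:
                s.t += dt
        if observer is not None and s.t > last_obs + 1e-15:
            observer(s, self)
        return s


@dataclass
class RunResult:
    trajectory: "object"          # pandas.DataFrame of observable rows
    state: SimState
    rule_counts: dict


def run(config: RunConfig) -> RunResult:
    """Build the initial state, run to t_end, return trajectory + final state."""
    from . import analysis
    eng = Engine(config)
    rows = []
    writer = None
    if config.trajectory_path:
        writer = analysis.TrajectoryWriter(config.trajectory_path)

    def observer(state, engine):
        row = analysis.record_observables(state, engine.p)
        rows.append(row)
        if writer is not None:
            writer.write(row)

    eng.run(observer=observer)
    if writer is not None:
        writer.close()
    import pandas as pd
    return RunResult(trajectory=pd.DataFrame(rows), state=eng.state,
                     rule_counts=dict(eng.rule_counts))
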