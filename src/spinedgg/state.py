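"""Typed graph state: actin network, membrane polygon, bonds, species pools.

The actin network is a directed graph of coarse-grained segment objects.
Each object stores its position (in unit lengths), pointers to the previous
and next object along its filament, an optional branch pointer (junctions
point at their Arp2/3 daughter seed), an optional bundle-bond id, a subtype,
and the per-monomer occupancy counts of its ``n_cg`` sub-sites
(ATP / ADP / ADP+Pi / cofilin-bound).  The membrane is a single
counterclockwise polygon of vertices.  Storage is struct-of-arrays (numpy)
with ids equal to row indices; ids are monotone and never reused, so
trajectories are replayable.

Conventions
-----------
* ``prev -> next`` runs pointed-to-barbed: the barbed end of a filament is
  the node with ``next == -1``, the pointed end has ``prev == -1``.
* A junction's two outgoing links are ``next`` (mother filament) and ``arp``
  (daughter seed); the daughter seed's ``prev`` is the junction.
* Signed angles are counterclockwise-positive (two-argument arctangent of
  cross over dot).
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

# actin subtypes
INTERIOR = 0       # ◯ interior filament segment
END = 1            # ⬤ uncapped filament end (barbed or pointed)
CAPPED = 2         # ▶ capped barbed end
JUNCTION = 3       # Δ branch-point segment
ARP_END = 4        # ■ Arp2/3 seed at the tip of a daughter filament
ARP_INTERIOR = 5   # □ Arp2/3 within a grown daughter filament

ACTIN_SUBTYPES = (INTERIOR, END, CAPPED, JUNCTION)
ARP_SUBTYPES = (ARP_END, ARP_INTERIOR)

SUBTYPE_NAMES = {
    INTERIOR: "interior", END: "end", CAPPED: "capped",
    JUNCTION: "junction", ARP_END: "arp_end", ARP_INTERIOR: "arp_interior",
}

POOL_NAMES = ("actin", "arp_active", "arp_inactive", "cofilin", "cam", "cap")


# ----------------------------------------------------------------------
# geometric primitives
# ----------------------------------------------------------------------

def bend_angle(x1, x2, x3) -> float:
    """Signed turning angle at ``x2`` between (x2-x1) and (x3-x2), radians.

    Counterclockwise turns are positive; antisymmetric under traversal
    reversal: ``bend_angle(x3, x2, x1) == -bend_angle(x1, x2, x3)``.
    """
    u = (x2[0] - x1[0], x2[1] - x1[1])
    v = (x3[0] - x2[0], x3[1] - x2[1])
    if (u[0] == 0.0 and u[1] == 0.0) or (v[0] == 0.0 and v[1] == 0.0):
        raise ValueError("bend_angle: coincident points")
    return math.atan2(u[0] * v[1] - u[1] * v[0], u[0] * v[0] + u[1] * v[1])


def segment_intersection(p1, p2, q1, q2) -> Optional[np.ndarray]:
    """Intersection point of segments [p1,p2] and [q1,q2], or None.

    Endpoint contact counts as an intersection.  Parallel (including
    collinear-overlapping) segments return None: there is no unique point.
    """
    r = (p2[0] - p1[0], p2[1] - p1[1])
    s = (q2[0] - q1[0], q2[1] - q1[1])
    denom = r[0] * s[1] - r[1] * s[0]
    if denom == 0.0:
        return None
    w = (q1[0] - p1[0], q1[1] - p1[1])
    t = (w[0] * s[1] - w[1] * s[0]) / denom
    u = (w[0] * r[1] - w[1] * r[0]) / denom
    if -1e-12 <= t <= 1 + 1e-12 and -1e-12 <= u <= 1 + 1e-12:
        return np.array([p1[0] + t * r[0], p1[1] + t * r[1]])
    return None


# ----------------------------------------------------------------------
# state container
# ----------------------------------------------------------------------

class SimState:
    """Full simulation state: typed graph + pools + clock + RNG stream."""

    def __init__(self, seed: int = 0, actin_capacity: int = 64,
                 mem_capacity: int = 64):
        cap = actin_capacity
        self.a_pos = np.zeros((cap, 2))
        self.a_prev = np.full(cap, -1, dtype=np.int32)
        self.a_next = np.full(cap, -1, dtype=np.int32)
        self.a_arp = np.full(cap, -1, dtype=np.int32)
        self.a_bundle = np.full(cap, -1, dtype=np.int32)
        self.a_sub = np.zeros(cap, dtype=np.int8)
        self.a_atp = np.zeros(cap, dtype=np.int32)
        self.a_adp = np.zeros(cap, dtype=np.int32)
        self.a_adppi = np.zeros(cap, dtype=np.int32)
        self.a_cof = np.zeros(cap, dtype=np.int32)
        self.a_arpin = np.zeros(cap, dtype=np.int32)  # inactive-Arp2/3 sub-sites bound
        self.a_alive = np.zeros(cap, dtype=bool)
        self.n_actin_rows = 0

        mcap = mem_capacity
        self.m_pos = np.zeros((mcap, 2))
        self.m_prev = np.full(mcap, -1, dtype=np.int32)
        self.m_next = np.full(mcap, -1, dtype=np.int32)
        self.m_alive = np.zeros(mcap, dtype=bool)
        self.n_mem_rows = 0

        self.attach_end2vert: dict[int, int] = {}
        self.attach_vert2end: dict[int, int] = {}
        self.attach_rest: dict[int, float] = {}  # spring rest length per end
        self.attach_elongated: set[int] = set()  # end ids elongated since attach

        self.bundles: dict[int, tuple[int, int, float]] = {}  # id -> (a, b, rest)
        self._next_bundle_id = 0

        self.pools: dict[str, float] = {k: 0.0 for k in POOL_NAMES}
        self._mem_version = 0
        self._mem_cycle_cache: tuple[int, np.ndarray] | None = None
        self.t = 0.0
        self.seed = int(seed)
        self.rng = np.random.default_rng(int(seed))

    # -- actin bookkeeping ------------------------------------------------

    def _grow_actin(self) -> None:
        cap = len(self.a_sub)
        new = 2 * cap
        for name in ("a_prev", "a_next", "a_arp", "a_bundle"):
            arr = np.full(new, -1, dtype=np.int32)
            arr[:cap] = getattr(self, name)
            setattr(self, name, arr)
        for name, dt in (("a_sub", np.int8), ("a_atp", np.int32),
                         ("a_adp", np.int32), ("a_adppi", np.int32),
                         ("a_cof", np.int32), ("a_arpin", np.int32)):
            arr = np.zeros(new, dtype=dt)
            arr[:cap] = getattr(self, name)
            setattr(self, name, arr)
        pos = np.zeros((new, 2))
        pos[:cap] = self.a_pos
        self.a_pos = pos
        alive = np.zeros(new, dtype=bool)
        alive[:cap] = self.a_alive
        self.a_alive = alive

    def add_actin(self, pos, sub: int, prev: int = -1, nxt: int = -1,
                  atp: int = 0, adp: int = 0, adppi: int = 0,
                  cof: int = 0) -> int:
        if self.n_actin_rows >= len(self.a_sub):
            self._grow_actin()
        i = self.n_actin_rows
        self.n_actin_rows += 1
        self.a_pos[i] = pos
        self.a_prev[i] = prev
        self.a_next[i] = nxt
        self.a_arp[i] = -1
        self.a_bundle[i] = -1
        self.a_sub[i] = sub
        self.a_atp[i] = atp
        self.a_adp[i] = adp
        self.a_adppi[i] = adppi
        self.a_cof[i] = cof
        self.a_arpin[i] = 0
        self.a_alive[i] = True
        return i

    def kill_actin(self, i: int) -> None:
        """Mark node dead; the caller is responsible for pointer surgery."""
        self.a_alive[i] = False
        self.a_prev[i] = self.a_next[i] = self.a_arp[i] = -1
        if self.a_bundle[i] >= 0:
            self.remove_bundle(int(self.a_bundle[i]))
        if i in self.attach_end2vert:
            self.detach(i)

    def actin_ids(self) -> np.ndarray:
        return np.flatnonzero(self.a_alive[: self.n_actin_rows])

    @property
    def n_actin(self) -> int:
        return int(self.a_alive[: self.n_actin_rows].sum())

    def filament_neighbors(self, i: int) -> list[int]:
        """Graph-connected partners of node i along filaments and branches."""
        out = []
        for j in (self.a_prev[i], self.a_next[i], self.a_arp[i]):
            if j >= 0:
                out.append(int(j))
        # a daughter seed's prev is the junction (covered); the junction's
        # arp covers the reverse edge, so nothing more is needed here.
        return out

    def is_barbed_end(self, i: int) -> bool:
        return self.a_sub[i] in (END, CAPPED, ARP_END) and self.a_next[i] == -1

    def is_pointed_end(self, i: int) -> bool:
        return self.a_sub[i] == END and self.a_prev[i] == -1

    # -- bundles ----------------------------------------------------------

    def add_bundle(self, a: int, b: int, rest: float) -> int:
        if a == b:
            raise ValueError("self-bundling is not allowed")
        bid = self._next_bundle_id
        self._next_bundle_id += 1
        self.bundles[bid] = (int(a), int(b), float(rest))
        self.a_bundle[a] = bid
        self.a_bundle[b] = bid
        return bid

    def remove_bundle(self, bid: int) -> None:
        a, b, _ = self.bundles.pop(bid)
        if self.a_bundle[a] == bid:
            self.a_bundle[a] = -1
        if self.a_bundle[b] == bid:
            self.a_bundle[b] = -1

    # -- attachments ------------------------------------------------------

    def attach(self, end_id: int, vert_id: int, rest: float = 0.0) -> None:
        if end_id in self.attach_end2vert:
            raise ValueError(f"actin end {end_id} already attached")
        if vert_id in self.attach_vert2end:
            raise ValueError(f"membrane vertex {vert_id} already attached")
        self.attach_end2vert[end_id] = vert_id
        self.attach_vert2end[vert_id] = end_id
        self.attach_rest[end_id] = float(rest)

    def detach(self, end_id: int) -> None:
        vid = self.attach_end2vert.pop(end_id)
        self.attach_vert2end.pop(vid)
        self.attach_rest.pop(end_id, None)
        self.attach_elongated.discard(end_id)

    # -- membrane bookkeeping ---------------------------------------------

    def _grow_mem(self) -> None:
        cap = len(self.m_prev)
        new = 2 * cap
        for name in ("m_prev", "m_next"):
            arr = np.full(new, -1, dtype=np.int32)
            arr[:cap] = getattr(self, name)
            setattr(self, name, arr)
        pos = np.zeros((new, 2))
        pos[:cap] = self.m_pos
        self.m_pos = pos
        alive = np.zeros(new, dtype=bool)
        alive[:cap] = self.m_alive
        self.m_alive = alive

    def set_membrane_polygon(self, positions: np.ndarray) -> list[int]:
        """Initialize the membrane as one CCW cycle from (N,2) positions."""
        ids = []
        for p in positions:
            if self.n_mem_rows >= len(self.m_prev):
                self._grow_mem()
            i = self.n_mem_rows
            self.n_mem_rows += 1
            self.m_pos[i] = p
            self.m_alive[i] = True
            ids.append(i)
        n = len(ids)
        for k, i in enumerate(ids):
            self.m_prev[i] = ids[(k - 1) % n]
            self.m_next[i] = ids[(k + 1) % n]
        self._mem_version += 1
        return ids

    def insert_vertex_after(self, vid: int, pos) -> int:
        if self.n_mem_rows >= len(self.m_prev):
            self._grow_mem()
        i = self.n_mem_rows
        self.n_mem_rows += 1
        nxt = int(self.m_next[vid])
        self.m_pos[i] = pos
        self.m_prev[i] = vid
        self.m_next[i] = nxt
        self.m_alive[i] = True
        self.m_next[vid] = i
        self.m_prev[nxt] = i
        self._mem_version += 1
        return i

    def remove_vertex(self, vid: int) -> None:
        if vid in self.attach_vert2end:
            raise ValueError(f"vertex {vid} is attached; detach first")
        p, n = int(self.m_prev[vid]), int(self.m_next[vid])
        self.m_next[p] = n
        self.m_prev[n] = p
        self.m_alive[vid] = False
        self.m_prev[vid] = self.m_next[vid] = -1
        self._mem_version += 1

    def membrane_cycle(self, use_cache: bool = True) -> np.ndarray:
        """Vertex ids in cycle order, starting from the lowest alive id.

        The pointer walk is cached and invalidated on topology changes
        (vertex insertion/removal), since it sits on the engine's hot path;
        validators pass ``use_cache=False`` to re-walk the pointers.
        """
        if (use_cache and self._mem_cycle_cache is not None
                and self._mem_cycle_cache[0] == self._mem_version):
            return self._mem_cycle_cache[1]
        alive = np.flatnonzero(self.m_alive[: self.n_mem_rows])
        if len(alive) == 0:
            return alive.astype(np.int32)
        start = int(alive[0])
        out = [start]
        j = int(self.m_next[start])
        while j != start:
            out.append(j)
            j = int(self.m_next[j])
            if len(out) > len(alive):
                raise RuntimeError("membrane pointers do not form a single cycle")
        arr = np.asarray(out, dtype=np.int32)
        if len(arr) == len(alive):
            self._mem_cycle_cache = (self._mem_version, arr)
        return arr

    def membrane_coords(self) -> np.ndarray:
        return self.m_pos[self.membrane_cycle()]

    @property
    def n_mem(self) -> int:
        return int(self.m_alive[: self.n_mem_rows].sum())

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        nodes = []
        for i in self.actin_ids():
            nodes.append({
                "id": int(i), "pos": [float(self.a_pos[i, 0]), float(self.a_pos[i, 1])],
                "prev": int(self.a_prev[i]), "next": int(self.a_next[i]),
                "arp": int(self.a_arp[i]), "bundle": int(self.a_bundle[i]),
                "subtype": SUBTYPE_NAMES[int(self.a_sub[i])],
                "n_atp": int(self.a_atp[i]), "n_adp": int(self.a_adp[i]),
                "n_adppi": int(self.a_adppi[i]), "n_cofilin": int(self.a_cof[i]),
                "n_arp_inactive": int(self.a_arpin[i]),
            })
        verts = []
        for i in self.membrane_cycle():
            verts.append({
                "id": int(i), "pos": [float(self.m_pos[i, 0]), float(self.m_pos[i, 1])],
                "prev": int(self.m_prev[i]), "next": int(self.m_next[i]),
            })
        return {
            "clock": self.t,
            "seed": self.seed,
            "n_actin_rows": self.n_actin_rows,
            "n_mem_rows": self.n_mem_rows,
            "next_bundle_id": self._next_bundle_id,
            "actin": nodes,
            "membrane": verts,
            "attachments": [
                {"end": int(e), "vertex": int(v),
                 "rest": float(self.attach_rest.get(e, 0.0)),
                 "elongated": bool(e in self.attach_elongated)}
                for e, v in sorted(self.attach_end2vert.items())
            ],
            "bundles": [
                {"id": int(b), "a": int(a), "b2": int(c), "rest": float(r)}
                for b, (a, c, r) in sorted(self.bundles.items())
            ],
            "pools": {k: float(v) for k, v in self.pools.items()},
            "rng_state": _encode_rng(self.rng),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimState":
        st = cls(seed=d.get("seed", 0),
                 actin_capacity=max(16, int(d["n_actin_rows"])),
                 mem_capacity=max(16, int(d["n_mem_rows"])))
        st.t = float(d["clock"])
        st.n_actin_rows = int(d["n_actin_rows"])
        st.n_mem_rows = int(d["n_mem_rows"])
        st._next_bundle_id = int(d.get("next_bundle_id", 0))
        name2sub = {v: k for k, v in SUBTYPE_NAMES.items()}
        for nd in d["actin"]:
            i = nd["id"]
            st.a_pos[i] = nd["pos"]
            st.a_prev[i] = nd["prev"]
            st.a_next[i] = nd["next"]
            st.a_arp[i] = nd["arp"]
            st.a_bundle[i] = nd["bundle"]
            st.a_sub[i] = name2sub[nd["subtype"]]
            st.a_atp[i] = nd["n_atp"]
            st.a_adp[i] = nd["n_adp"]
            st.a_adppi[i] = nd["n_adppi"]
            st.a_cof[i] = nd["n_cofilin"]
            st.a_arpin[i] = nd.get("n_arp_inactive", 0)
            st.a_alive[i] = True
        for vd in d["membrane"]:
            i = vd["id"]
            st.m_pos[i] = vd["pos"]
            st.m_prev[i] = vd["prev"]
            st.m_next[i] = vd["next"]
            st.m_alive[i] = True
        for at in d.get("attachments", []):
            st.attach_end2vert[at["end"]] = at["vertex"]
            st.attach_vert2end[at["vertex"]] = at["end"]
            st.attach_rest[at["end"]] = float(at.get("rest", 0.0))
            if at.get("elongated"):
                st.attach_elongated.add(at["end"])
        for bd in d.get("bundles", []):
            st.bundles[bd["id"]] = (bd["a"], bd["b2"], bd["rest"])
        for k, v in d.get("pools", {}).items():
            st.pools[k] = float(v)
        if "rng_state" in d:
            _decode_rng(st.rng, d["rng_state"])
        return st


def _encode_rng(rng: np.random.Generator) -> dict:
    s = rng.bit_generator.state
    return {"bit_generator": s["bit_generator"],
            "state": int(s["state"]["state"]),
            "inc": int(s["state"]["inc"]),
            "has_uint32": int(s["has_uint32"]),
            "uinteger": int(s["uinteger"])}


def _decode_rng(rng: np.random.Generator, d: dict) -> None:
    rng.bit_generator.state = {
        "bit_generator": d["bit_generator"],
        "state": {"state": int(d["state"]), "inc": int(d["inc"])},
        "has_uint32": int(d["has_uint32"]),
        "uinteger": int(d["uinteger"]),
    }


def states_equal(s1: SimState, s2: SimState) -> bool:
    """Structural equality of two states (used by snapshot round-trip tests)."""
    d1, d2 = s1.to_dict(), s2.to_dict()
    return d1 == d2


# ----------------------------------------------------------------------
# validation
# ----------------------------------------------------------------------

def validate_state(state: SimState, n_cg: int = 50) -> list[str]:
    """Return a list of invariant violations (empty iff the state is valid)."""
    v: list[str] = []
    s = state
    ids = s.actin_ids()
    idset = set(int(i) for i in ids)
    for i in ids:
        i = int(i)
        sub = int(s.a_sub[i])
        p, n, ar = int(s.a_prev[i]), int(s.a_next[i]), int(s.a_arp[i])
        for tag, j in (("prev", p), ("next", n), ("arp", ar)):
            if j >= 0 and j not in idset:
                v.append(f"actin {i}: {tag} pointer {j} does not resolve")
        # mutual consistency: a.next == b implies b.prev == a; the branch edge
        # J.arp == d implies d.prev == J.
        if n >= 0 and n in idset and int(s.a_prev[n]) != i:
            v.append(f"actin {i}: next {n} has prev {int(s.a_prev[n])}")
        if ar >= 0 and ar in idset:
            if sub != JUNCTION:
                v.append(f"actin {i}: non-junction with arp pointer")
            if int(s.a_prev[ar]) != i:
                v.append(f"actin {i}: arp child {ar} has prev {int(s.a_prev[ar])}")
        if p >= 0 and p in idset:
            # the reverse of prev is either prev.next or prev.arp (junctions)
            if int(s.a_next[p]) != i and int(s.a_arp[p]) != i:
                v.append(f"actin {i}: prev {p} does not point back")
        total = int(s.a_atp[i] + s.a_adp[i] + s.a_adppi[i] + s.a_cof[i])
        if sub in ACTIN_SUBTYPES and total != n_cg:
            v.append(f"actin {i}: monomer counts sum to {total}, expected {n_cg}")
        if sub in ARP_SUBTYPES and total != 0:
            v.append(f"actin {i}: Arp2/3 object with monomer counts {total}")
        ndeg = (p >= 0) + (n >= 0) + (ar >= 0)
        if sub in (END, CAPPED, ARP_END) and ndeg != 1:
            v.append(f"actin {i}: end-type node with {ndeg} filament neighbors")
        if sub in (INTERIOR, ARP_INTERIOR) and ndeg != 2:
            v.append(f"actin {i}: interior-type node with {ndeg} filament neighbors")
        if sub == JUNCTION and ndeg != 3:
            v.append(f"actin {i}: junction with {ndeg} filament neighbors")
        if sub == CAPPED and n != -1:
            v.append(f"actin {i}: capped node is not a barbed end")
        bid = int(s.a_bundle[i])
        if bid >= 0 and bid not in s.bundles:
            v.append(f"actin {i}: bundle id {bid} does not resolve")

    for bid, (a, b, rest) in s.bundles.items():
        if a == b:
            v.append(f"bundle {bid}: self-bundling")
        for j in (a, b):
            if j not in idset:
                v.append(f"bundle {bid}: actin {j} does not resolve")
        if a in idset and b in idset:
            if b in s.filament_neighbors(a):
                v.append(f"bundle {bid}: partners are filament-adjacent")
        if rest <= 0:
            v.append(f"bundle {bid}: rest length {rest} <= 0")

    # membrane: one simple CCW cycle
    try:
        cyc = s.membrane_cycle(use_cache=False)
    except RuntimeError as e:
        v.append(f"membrane: {e}")
        cyc = None
    if cyc is not None and len(cyc) >= 3:
        pts = s.m_pos[cyc]
        nxt = np.roll(pts, -1, axis=0)
        area2 = float((pts[:, 0] * nxt[:, 1] - nxt[:, 0] * pts[:, 1]).sum())
        if area2 <= 0:
            v.append("membrane: polygon is not counterclockwise")
        if _polygon_self_intersects(pts):
            v.append("membrane: polygon self-intersects")
    elif cyc is not None and 0 < len(cyc) < 3:
        v.append("membrane: fewer than 3 vertices")

    mem_ids = set(int(i) for i in (cyc if cyc is not None else []))
    for e, vid in s.attach_end2vert.items():
        if e not in idset:
            v.append(f"attachment: actin end {e} does not resolve")
        elif not (s.is_barbed_end(e) or s.is_pointed_end(e)):
            v.append(f"attachment: actin {e} is not a filament end")
        if vid not in mem_ids:
            v.append(f"attachment: membrane vertex {vid} not in cycle")

    for k, val in s.pools.items():
        if val < 0:
            v.append(f"pool {k}: negative count {val}")
    return v


def _polygon_self_intersects(pts: np.ndarray) -> bool:
    n = len(pts)
    segs = [(pts[i], pts[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent around the cycle
            if segment_intersection(segs[i][0], segs[i][1],
                                    segs[j][0], segs[j][1]) is not None:
                return True
    return False
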