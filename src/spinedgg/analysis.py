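"""Observables, parameter sweeps and deterministic test fixtures."""

from __future__ import annotations

import csv
import math
from dataclasses import replace

import numpy as np

from . import mechanics as mech
from . import membrane as mb
from . import state as st
from .params import ModelParams
from .state import SimState

TRAJECTORY_FIELDS = [
    "t", "area_um2", "perimeter_um", "circularity",
    "n_actin", "n_filaments", "bound_cofilin", "bound_cam", "bound_arp",
    "capped_ends", "n_attachments", "pool_actin",
    "energy_radial", "energy_angular", "energy_bundle", "energy_membrane",
    "energy_total",
]


def record_observables(state: SimState, p: ModelParams) -> dict:
    """One trajectory row: membrane geometry, bound-protein counts, energies."""
    coords = state.membrane_coords()
    u_um = p.unit_m * 1e6
    area_u = mb.polygon_area(coords)
    per_u = mb.polygon_perimeter(coords)
    ids = state.actin_ids()
    subs = state.a_sub[ids] if len(ids) else np.zeros(0, dtype=np.int8)
    n_filaments = int((state.a_prev[ids] == -1).sum()) if len(ids) else 0
    n_filaments += int((state.a_arp[ids] >= 0).sum()) if len(ids) else 0
    bound_arp = int((subs == st.ARP_END).sum() + (subs == st.ARP_INTERIOR).sum())
    bound_arp += int(state.a_arpin[ids].sum()) if len(ids) else 0
    e = mech.energy_breakdown(
        state, p, membrane=mb.membrane_energy_state(state, p).total
        + mb.attachment_energy(state, p))
    return {
        "t": state.t,
        "area_um2": area_u * u_um**2,
        "perimeter_um": per_u * u_um,
        "circularity": mb.circularity(area_u, per_u),
        "n_actin": int(len(ids)),
        "n_filaments": n_filaments,
        "bound_cofilin": int(state.a_cof[ids].sum()) if len(ids) else 0,
        "bound_cam": len(state.bundles),
        "bound_arp": bound_arp,
        "capped_ends": int((subs == st.CAPPED).sum()),
        "n_attachments": len(state.attach_end2vert),
        "pool_actin": state.pools["actin"],
        "energy_radial": e.radial,
        "energy_angular": e.angular,
        "energy_bundle": e.bundle,
        "energy_membrane": e.membrane,
        "energy_total": e.total,
    }


class TrajectoryWriter:
    """Append-only CSV trajectory with a fixed header; flushed per row so a
    crashed run leaves a parseable file."""

    def __init__(self, path: str):
        self.path = path
        self._fh = open(path, "w", newline="")
        self._writer = csv.DictWriter(self._fh, fieldnames=TRAJECTORY_FIELDS)
        self._writer.writeheader()
        self._fh.flush()

    def write(self, row: dict) -> None:
        self._writer.writerow({k: row.get(k, "") for k in TRAJECTORY_FIELDS})
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()


def write_trajectory(rows, path: str) -> None:
    w = TrajectoryWriter(path)
    for r in rows:
        w.write(r)
    w.close()


def read_trajectory(path: str):
    import pandas as pd
    return pd.read_csv(path)


# ----------------------------------------------------------------------
# parameter sweeps
# ----------------------------------------------------------------------

def sweep(config, param_name: str, values, reps: int,
          observables=("area_um2", "circularity", "bound_cofilin",
                       "bound_cam", "bound_arp")):
    """End-point statistics over ``reps`` independent seeds per value.

    Each replicate runs the full simulation with ``param_name`` overridden;
    reported are the mean and the Bessel-corrected standard error
    (s / sqrt(n), variance divisor n-1) of each end-point observable.
    """
    if reps < 2:
        raise ValueError("sweep needs reps >= 2 for a standard error")
    from . import engine as eng
    import pandas as pd
    base = config.params.to_dict()
    if param_name not in base:
        raise KeyError(f"unknown parameter {param_name!r}")
    rows = []
    for vi, value in enumerate(values):
        pd_dict = dict(base)
        pd_dict[param_name] = value
        finals = []
        for rep in range(reps):
            cfg = replace(config,
                          params=ModelParams.from_dict(pd_dict),
                          seed=int(config.seed + 7919 * vi + rep),
                          trajectory_path=None)
            res = eng.run(cfg)
            finals.append(res.trajectory.iloc[-1])
        row = {"param": param_name, "value": value, "n": reps}
        for ob in observables:
            xs = np.array([float(f[ob]) for f in finals])
            row[f"{ob}_mean"] = xs.mean()
            row[f"{ob}_se"] = (xs.std(ddof=1) / math.sqrt(reps)) if reps > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# fixtures
# ----------------------------------------------------------------------

def _square_membrane(state: SimState, half: float, n_side: int = 8) -> None:
    """CCW square polygon of half-width ``half`` with n_side points per side."""
    ts = np.linspace(-half, half, n_side, endpoint=False)
    pts = ([(x, -half) for x in ts] + [(half, y) for y in ts]
           + [(-x, half) for x in ts] + [(-half, -y) for y in ts])
    state.set_membrane_polygon(np.asarray(pts, dtype=float))


def fixture(name: str, n: int = 5, theta: float = 0.3, n_vertices: int = 32,
            radius: float = 2.0, n_cg: int = 50, seed: int = 0) -> SimState:
    """Deterministic small states for tests and examples.

    Names: ``straight_filament`` (n nodes on the x-axis),
    ``bent_filament`` (constant turning angle theta),
    ``branched_Y`` (the four-object seed network: one Δ, one ■),
    ``bundled_pair`` (two parallel filaments crosslinked at midspan),
    ``polygon_only`` (membrane only, regular n_vertices-gon),
    ``default_spine`` (the engine's default initial state).
    """
    p = ModelParams(n_cg=n_cg)
    if name == "default_spine":
        from . import engine as eng
        return eng.build_initial_state(eng.RunConfig(params=p, seed=seed))
    s = SimState(seed=seed)
    if name == "straight_filament":
        if n < 2:
            raise ValueError("straight_filament needs n >= 2")
        ids = [s.add_actin((float(k), 0.0),
                           st.END if k in (0, n - 1) else st.INTERIOR,
                           atp=n_cg) for k in range(n)]
        for a, b in zip(ids, ids[1:]):
            s.a_next[a] = b
            s.a_prev[b] = a
        _square_membrane(s, half=n + 2.0)
    elif name == "bent_filament":
        pos = np.zeros(2)
        d = np.array([1.0, 0.0])
        ids = []
        for k in range(n):
            ids.append(s.add_actin(pos.copy(),
                                   st.END if k in (0, n - 1) else st.INTERIOR,
                                   atp=n_cg))
            c, sn = math.cos(theta), math.sin(theta)
            d = np.array([c * d[0] - sn * d[1], sn * d[0] + c * d[1]])
            pos = pos + d
        for a, b in zip(ids, ids[1:]):
            s.a_next[a] = b
            s.a_prev[b] = a
        _square_membrane(s, half=n + 2.0)
    elif name == "branched_Y":
        n1 = s.add_actin((-1.0, 0.0), st.END, atp=n_cg)
        n2 = s.add_actin((0.0, 0.0), st.JUNCTION, atp=n_cg)
        n3 = s.add_actin((1.0, 0.0), st.END, atp=n_cg)
        th = 70.0 * math.pi / 180.0
        sd = s.add_actin((math.cos(th), math.sin(th)), st.ARP_END)
        s.a_next[n1] = n2
        s.a_prev[n2] = n1
        s.a_next[n2] = n3
        s.a_prev[n3] = n2
        s.a_arp[n2] = sd
        s.a_prev[sd] = n2
        _square_membrane(s, half=4.0)
    elif name == "bundled_pair":
        sep = 0.9
        a_ids = [s.add_actin((float(k), 0.0),
                             st.END if k in (0, 2) else st.INTERIOR,
                             atp=n_cg) for k in range(3)]
        b_ids = [s.add_actin((float(k), sep),
                             st.END if k in (0, 2) else st.INTERIOR,
                             atp=n_cg) for k in range(3)]
        for ids in (a_ids, b_ids):
            for a, b in zip(ids, ids[1:]):
                s.a_next[a] = b
                s.a_prev[b] = a
        s.add_bundle(a_ids[1], b_ids[1], sep)
        _square_membrane(s, half=6.0)
    elif name == "polygon_only":
        ang = 2 * np.pi * np.arange(n_vertices) / n_vertices
        s.set_membrane_polygon(
            radius * np.stack([np.cos(ang), np.sin(ang)], axis=1))
    else:
        raise ValueError(f"unknown fixture {name!r}")
    errs = st.validate_state(s, n_cg)
    if errs:
        raise RuntimeError(f"fixture {name} invalid: {errs}")
    return s
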