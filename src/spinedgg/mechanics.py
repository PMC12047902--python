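"""Filament mechanics: energies, gradients, Hessians, kinetic update rules.

Two energy sectors act on the actin graph:

* a *radial* (separation) sector — every filament edge, branch edge and
  CaMKIIβ bundle bond carries a Morse potential, linearized below a clipping
  radius so the repulsive core cannot destabilize the explicit update;
* an *angular* (bending) sector — every connected triple carries a harmonic
  bending energy ``k_b/2 (θ - θ_t)²`` with target 0 along filaments and the
  Arp2/3 branching angle at junctions.  Cofilin occupancy softens bending.

Forces are internal (pairwise / triple-wise), so they conserve total
momentum by construction.  Dissipative rules implement one stochastic
forward-Euler step of the overdamped force balance ``ζ dx/dt = -∇U``; the
thermal rule proposes a Gaussian displacement from the local (regularized)
buckling Hessian and accepts it with a heat-bath probability satisfying
detailed balance against the Boltzmann distribution of the separation
energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import state as st
from .params import ModelParams

# ----------------------------------------------------------------------
# scalar potentials
# ----------------------------------------------------------------------

def morse_potential(r: float, de: float, alpha: float, rmin: float) -> float:
    """Morse bond energy: ``De (1 - exp(-α(r - rmin)))²``; 0 at rmin, → De."""
    e = math.exp(-alpha * (r - rmin))
    return de * (1.0 - e) ** 2


def morse_d1(r: float, de: float, alpha: float, rmin: float) -> float:
    e = math.exp(-alpha * (r - rmin))
    return 2.0 * de * alpha * e * (1.0 - e)


def morse_d2(r: float, de: float, alpha: float, rmin: float) -> float:
    e = math.exp(-alpha * (r - rmin))
    return 2.0 * de * alpha**2 * (2.0 * e * e - e)


def clipped_potential(r: float, eps: float, base, dbase) -> float:
    """Piecewise potential: ``base`` for r >= eps, linear extension below.

    The extension matches value and slope at r = eps, so the potential is C¹
    and the force is bounded near coincident points.
    """
    if eps <= 0:
        raise ValueError("clipping radius must be positive")
    if r >= eps:
        return base(r)
    return base(eps) + dbase(eps) * (r - eps)


def clipped_gradient(r: float, eps: float, dbase) -> float:
    if eps <= 0:
        raise ValueError("clipping radius must be positive")
    return dbase(r) if r >= eps else dbase(eps)


# -- specialized clipped-Morse bond (the hot path) ----------------------

def bond_energy(r: float, de: float, alpha: float, rmin: float,
                eps_clip: float) -> float:
    eps = eps_clip * rmin
    if r >= eps:
        return morse_potential(r, de, alpha, rmin)
    return (morse_potential(eps, de, alpha, rmin)
            + morse_d1(eps, de, alpha, rmin) * (r - eps))


def bond_d1(r: float, de: float, alpha: float, rmin: float,
            eps_clip: float) -> float:
    eps = eps_clip * rmin
    return morse_d1(max(r, eps), de, alpha, rmin)


def bond_d2(r: float, de: float, alpha: float, rmin: float,
            eps_clip: float) -> float:
    eps = eps_clip * rmin
    return 0.0 if r < eps else morse_d2(r, de, alpha, rmin)


def bond_psi(r: float, de: float, alpha: float, rmin: float,
             eps_clip: float) -> float:
    """ψ(r) = U'(r)/r for the clipped bond (finite at r → 0)."""
    return bond_d1(r, de, alpha, rmin, eps_clip) / max(r, 1e-300)


# ----------------------------------------------------------------------
# bond enumeration
# ----------------------------------------------------------------------

def bonds_of(state: st.SimState, i: int, p: ModelParams):
    """(j, de, alpha_u, rmin, eps_clip) for every bond incident to node i."""
    out = []
    for j in state.filament_neighbors(i):
        out.append((j, p.d_e, p.alpha_u, 1.0, p.eps_clip))
    bid = int(state.a_bundle[i])
    if bid >= 0:
        a, b, rest = state.bundles[bid]
        j = b if a == i else a
        out.append((j, p.d_e_cam, p.alpha_cam_u, rest, p.eps_clip))
    return out


def all_edges(state: st.SimState):
    """Filament + branch edges as (i, j) pairs, each once (i -> next/arp)."""
    edges = []
    for i in state.actin_ids():
        i = int(i)
        j = int(state.a_next[i])
        if j >= 0:
            edges.append((i, j))
        j = int(state.a_arp[i])
        if j >= 0:
            edges.append((i, j))
    return edges


def triples_at_center(state: st.SimState, j: int, p: ModelParams):
    """Bending triples centered on node j: (i, j, k, theta_target, k_bend).

    Chain triples (prev, j, next) have target 0; a junction adds the branch
    triple (prev, J, daughter) with the Arp2/3 target angle and the stiffer
    branch rigidity.  Cofilin occupancy of the center softens chain triples
    linearly, reaching the five-fold reduction at full occupancy.
    """
    out = []
    pv, nx, d = int(state.a_prev[j]), int(state.a_next[j]), int(state.a_arp[j])
    sub = int(state.a_sub[j])
    if pv >= 0 and nx >= 0:
        if sub == st.JUNCTION or sub in st.ARP_SUBTYPES:
            kb = p.k_bend_arp
        else:
            f = state.a_cof[j] / p.n_cg
            kb = p.k_bend * (1.0 - p.cofilin_softening * f)
        out.append((pv, j, nx, 0.0, kb))
    if d >= 0 and pv >= 0:
        out.append((pv, j, d, p.theta_arp, p.k_bend_arp))
    return out


def triples_containing(state: st.SimState, i: int, p: ModelParams):
    """All bending triples in which node i participates, with i's role."""
    centers = {i}
    centers.update(state.filament_neighbors(i))
    out = []
    for c in centers:
        for (a, j, k, tt, kb) in triples_at_center(state, int(c), p):
            if i in (a, j, k):
                out.append((a, j, k, tt, kb))
    return out


# ----------------------------------------------------------------------
# angle geometry
# ----------------------------------------------------------------------

def angle_terms(x1, x2, x3):
    """Scalar/vector quantities of the bending energy at the triple.

    Returns ``(a, b, c, L, Ltilde, K)`` where ``a = cos θ``,
    ``b = |x3-x2|/|x2-x1|``, ``c = |x2-x1||x3-x2|``, ``L = x1 - 2 x2 + x3``,
    ``Ltilde = b x1 - (b + 1/b) x2 + x3/b`` and
    ``K = (x2 - x3) - a b (x1 - x2)``.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x3 = np.asarray(x3, dtype=float)
    u = x2 - x1
    v = x3 - x2
    nu = math.hypot(*u)
    nv = math.hypot(*v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("angle_terms: zero-length edge")
    c = nu * nv
    a = float(np.dot(u, v)) / c
    a = max(-1.0, min(1.0, a))
    b = nv / nu
    L = x1 - 2.0 * x2 + x3
    Lt = b * x1 - (b + 1.0 / b) * x2 + x3 / b
    K = (x2 - x3) - a * b * (x1 - x2)
    return a, b, c, L, Lt, K


def angle_theta_grads(x1, x2, x3):
    """θ = acos(a) plus its gradients wrt the three points.

    Near-collinear triples (sin θ → 0) switch to the transverse-direction
    limit, which keeps the bending machinery finite for straight fibers.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x3 = np.asarray(x3, dtype=float)
    u = x2 - x1
    v = x3 - x2
    nu = math.hypot(*u)
    nv = math.hypot(*v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("degenerate triple: coincident points")
    c = nu * nv
    dot = float(u[0] * v[0] + u[1] * v[1])
    cross = float(u[0] * v[1] - u[1] * v[0])
    theta = math.atan2(abs(cross), dot)
    sin = abs(cross) / c
    a = max(-1.0, min(1.0, dot / c))
    if sin > 1e-9:
        b = nv / nu
        k1 = -v + a * b * u
        k3 = u - (a / b) * v
        d1 = -k1 / (c * sin)
        d3 = -k3 / (c * sin)
    else:
        e = u / nu
        n = np.array([-e[1], e[0]])
        d1 = n / nu
        d3 = n / nv
    d2 = -(d1 + d3)
    return theta, d1, d2, d3


def angle_gradient(x1, x2, x3, theta_target: float, k_bend: float,
                   which_node: int):
    """Analytic ∇ of ``k_b/2 (θ - θ_t)²`` wrt point 1, 2 or 3."""
    theta, d1, d2, d3 = angle_theta_grads(x1, x2, x3)
    g = k_bend * (theta - theta_target)
    return g * (d1, d2, d3)[which_node - 1]


# ----------------------------------------------------------------------
# forces on graph nodes
# ----------------------------------------------------------------------

def radial_gradient(state: st.SimState, i: int, p: ModelParams) -> np.ndarray:
    """∇_{x_i} of the separation energy: Σ_j ψ(r_ij) (x_i - x_j).

    Includes filament, branch and bundle bonds of node i.
    """
    xi = state.a_pos[i]
    g = np.zeros(2)
    for (j, de, al, rmin, ec) in bonds_of(state, i, p):
        d = xi - state.a_pos[j]
        r = math.hypot(*d)
        g += bond_psi(r, de, al, rmin, ec) * d
    return g


def angular_gradient(state: st.SimState, i: int, p: ModelParams) -> np.ndarray:
    g = np.zeros(2)
    for (a, j, k, tt, kb) in triples_containing(state, i, p):
        theta, d1, d2, d3 = angle_theta_grads(
            state.a_pos[a], state.a_pos[j], state.a_pos[k])
        pref = kb * (theta - tt)
        if i == a:
            g += pref * d1
        if i == j:
            g += pref * d2
        if i == k:
            g += pref * d3
    return g


def internal_force(state: st.SimState, i: int, p: ModelParams) -> np.ndarray:
    """-∇U_i over the radial + angular + bundle sectors (no membrane terms)."""
    return -(radial_gradient(state, i, p) + angular_gradient(state, i, p))


def total_force_sum(state: st.SimState, p: ModelParams) -> np.ndarray:
    """Σ_l internal forces; zero to floating tolerance (momentum conservation)."""
    f = np.zeros(2)
    for i in state.actin_ids():
        f += internal_force(state, int(i), p)
    return f


# ----------------------------------------------------------------------
# energies
# ----------------------------------------------------------------------

def radial_energy(state: st.SimState, p: ModelParams) -> float:
    e = 0.0
    for (i, j) in all_edges(state):
        r = math.hypot(*(state.a_pos[i] - state.a_pos[j]))
        e += bond_energy(r, p.d_e, p.alpha_u, 1.0, p.eps_clip)
    return e


def bundle_energy(state: st.SimState, p: ModelParams) -> float:
    e = 0.0
    for (a, b, rest) in state.bundles.values():
        r = math.hypot(*(state.a_pos[a] - state.a_pos[b]))
        e += bond_energy(r, p.d_e_cam, p.alpha_cam_u, rest, p.eps_clip)
    return e


def angular_energy(state: st.SimState, p: ModelParams) -> float:
    e = 0.0
    for i in state.actin_ids():
        for (a, j, k, tt, kb) in triples_at_center(state, int(i), p):
            theta, *_ = angle_theta_grads(
                state.a_pos[a], state.a_pos[j], state.a_pos[k])
            e += 0.5 * kb * (theta - tt) ** 2
    return e


@dataclass
class EnergyBreakdown:
    radial: float
    angular: float
    bundle: float
    membrane: float

    @property
    def total(self) -> float:
        return self.radial + self.angular + self.bundle + self.membrane


def energy_breakdown(state: st.SimState, p: ModelParams,
                     membrane: float = 0.0) -> EnergyBreakdown:
    return EnergyBreakdown(radial=radial_energy(state, p),
                           angular=angular_energy(state, p),
                           bundle=bundle_energy(state, p),
                           membrane=membrane)


# ----------------------------------------------------------------------
# Hessians
# ----------------------------------------------------------------------

@dataclass
class LocalHessian:
    node_id: int
    matrix: np.ndarray  # 2x2 symmetric, J/unit-length²
    epsilon_sq: float   # regularizer added to the diagonal


def radial_hessian_scalar(state: st.SimState, i: int, p: ModelParams,
                          clamp: bool = True) -> float:
    """Isotropic diagonal of the radial Hessian: Σ_j U''(r_ij) (+ ε²).

    Negative curvature sums (bonds past the Morse inflection) are clamped to
    zero before regularization so the thermal Gaussian stays proper.
    """
    s = 0.0
    xi = state.a_pos[i]
    for (j, de, al, rmin, ec) in bonds_of(state, i, p):
        r = math.hypot(*(xi - state.a_pos[j]))
        s += bond_d2(r, de, al, rmin, ec)
    if clamp and s < 0.0:
        s = 0.0
    return s + p.eps_sep_sq


def radial_hessian_diag(state: st.SimState, i: int, p: ModelParams) -> LocalHessian:
    h = radial_hessian_scalar(state, i, p)
    return LocalHessian(node_id=i, matrix=h * np.eye(2),
                        epsilon_sq=p.eps_sep_sq)


def radial_hessian_full(state: st.SimState, p: ModelParams) -> np.ndarray:
    """Unregularized 2n×2n radial Hessian in the isotropic-scalar form.

    Weighted graph Laplacian: diagonal blocks Σ_j U''(r_ij)·I, off-diagonal
    blocks -U''(r_lm)·I.  Rows sum to zero by construction.
    """
    ids = [int(i) for i in state.actin_ids()]
    pos = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    H = np.zeros((2 * n, 2 * n))
    for (i, j) in all_edges(state):
        r = math.hypot(*(state.a_pos[i] - state.a_pos[j]))
        w = bond_d2(r, p.d_e, p.alpha_u, 1.0, p.eps_clip)
        a, b = pos[i], pos[j]
        for d in (0, 1):
            H[2 * a + d, 2 * a + d] += w
            H[2 * b + d, 2 * b + d] += w
            H[2 * a + d, 2 * b + d] -= w
            H[2 * b + d, 2 * a + d] -= w
    for (a2, b2, rest) in state.bundles.values():
        r = math.hypot(*(state.a_pos[a2] - state.a_pos[b2]))
        w = bond_d2(r, p.d_e_cam, p.alpha_cam_u, rest, p.eps_clip)
        a, b = pos[a2], pos[b2]
        for d in (0, 1):
            H[2 * a + d, 2 * a + d] += w
            H[2 * b + d, 2 * b + d] += w
            H[2 * a + d, 2 * b + d] -= w
            H[2 * b + d, 2 * a + d] -= w
    return H


def angle_hessian_diag(state: st.SimState, i: int, p: ModelParams) -> LocalHessian:
    """Gauss-Newton bending Hessian at node i: Σ k_b (dθ_i)(dθ_i)ᵀ.

    Terms of order (θ - θ_t) are dropped, leaving a positive-semidefinite sum
    of rank-one outer products.  Rank-deficient sums fall back to the
    Frobenius norm times the identity, and ε_ang²·I makes the result
    positive definite.
    """
    H = np.zeros((2, 2))
    for (a, j, k, tt, kb) in triples_containing(state, i, p):
        theta, d1, d2, d3 = angle_theta_grads(
            state.a_pos[a], state.a_pos[j], state.a_pos[k])
        d = np.zeros(2)
        if i == a:
            d = d + d1
        if i == j:
            d = d + d2
        if i == k:
            d = d + d3
        H += kb * np.outer(d, d)
    tr = H[0, 0] + H[1, 1]
    det = H[0, 0] * H[1, 1] - H[0, 1] * H[1, 0]
    if tr > 0 and det < 1e-12 * (0.5 * tr) ** 2:
        H = float(np.linalg.norm(H)) * np.eye(2)
    H += p.eps_ang_sq * np.eye(2)
    return LocalHessian(node_id=i, matrix=H, epsilon_sq=p.eps_ang_sq)


# ----------------------------------------------------------------------
# local separation energy (thermal-rule bookkeeping)
# ----------------------------------------------------------------------

def local_sep_energy(state: st.SimState, i: int, p: ModelParams,
                     pos_i=None, k_att: float | None = None) -> float:
    """Separation energy of bonds incident to i, with optional trial position.

    Includes the attachment spring when the node is membrane-attached
    (``k_att`` defaults to the model's attachment stiffness).
    """
    xi = state.a_pos[i] if pos_i is None else np.asarray(pos_i, dtype=float)
    e = 0.0
    for (j, de, al, rmin, ec) in bonds_of(state, i, p):
        r = math.hypot(*(xi - state.a_pos[j]))
        e += bond_energy(r, de, al, rmin, ec)
    if i in state.attach_end2vert:
        ka = p.k_att_u if k_att is None else k_att
        vid = state.attach_end2vert[i]
        gap = math.hypot(*(xi - state.m_pos[vid]))
        e += 0.5 * ka * (gap - state.attach_rest.get(i, 0.0)) ** 2
    return e


def attachment_force_on_end(state: st.SimState, i: int, p: ModelParams) -> np.ndarray:
    """Spring force on an attached filament end (harmonic about its rest gap)."""
    vid = state.attach_end2vert.get(i)
    if vid is None:
        return np.zeros(2)
    d = state.m_pos[vid] - state.a_pos[i]
    gap = math.hypot(*d)
    if gap < 1e-12:
        return np.zeros(2)
    rest = state.attach_rest.get(i, 0.0)
    return p.k_att_u * (gap - rest) * (d / gap)


# ----------------------------------------------------------------------
# kinetic rules
# ----------------------------------------------------------------------

def node_drag(state: st.SimState, i: int, p: ModelParams) -> float:
    """Stokes drag (N·s/m): parallel form at working ends, else perpendicular."""
    if int(state.a_sub[i]) in (st.END, st.CAPPED, st.ARP_END):
        return p.zeta_par
    return p.zeta_perp


def dissipative_step(state: st.SimState, i: int, p: ModelParams,
                     apply: bool = True, constraint=None) -> np.ndarray:
    """One viscous gradient-descent displacement Δx = -∇U / (ζ k_kinetic).

    The displacement norm is capped at ``p.step_cap`` unit lengths (the
    Table-rate update frequency under-resolves the stiff Morse bond; see the
    methods note).  Includes the membrane-attachment spring so the membrane
    reaction force enters the actin update.  ``constraint(x_old, x_new)``
    may veto the move (used for membrane impenetrability); a vetoed move
    returns the zero vector.
    """
    f = internal_force(state, i, p) + attachment_force_on_end(state, i, p)
    zeta = node_drag(state, i, p)
    dx = f / (zeta * p.k_kinetic * p.unit_m**2)
    norm = math.hypot(*dx)
    if norm > p.step_cap:
        dx *= p.step_cap / norm
    x_new = state.a_pos[i] + dx
    if constraint is not None and not constraint(state.a_pos[i], x_new):
        return np.zeros(2)
    if apply:
        state.a_pos[i] = x_new
    return dx


def heat_bath_acceptance(du: float, duq: float, det_sqrt_ratio: float,
                         kbt: float) -> float:
    """A = e·s / (1 + e·s), e = exp(-(ΔU-ΔUq)/kBT), s = √(|H(x)|/|H(x')|)."""
    z = -(du - duq) / kbt
    # guard overflow: for large |z| the ratio saturates at 0 or 1
    if z > 500:
        return 1.0
    es = math.exp(z) * det_sqrt_ratio
    return es / (1.0 + es)


def thermal_step(state: st.SimState, i: int, p: ModelParams, constraint=None):
    """Hessian thermal-noise rule: propose u ~ N(0, kBT·H⁻¹), heat-bath accept.

    Only the buckling (separation) Hessian and energy enter, per the model's
    separation of thermal noise from the bending drive.  Returns the applied
    displacement, or None on rejection.  ``constraint`` may veto proposals
    (membrane impenetrability); vetoed proposals count as rejections.
    """
    h = radial_hessian_scalar(state, i, p)
    sigma = math.sqrt(p.kbt / h)
    u = sigma * state.rng.standard_normal(2)
    x_old = state.a_pos[i].copy()
    x_new = x_old + u
    if constraint is not None and not constraint(x_old, x_new):
        return None
    e_old = local_sep_energy(state, i, p)
    e_new = local_sep_energy(state, i, p, pos_i=x_new)
    du = e_new - e_old
    # trial Hessian at the proposed point
    state.a_pos[i] = x_new
    h_new = radial_hessian_scalar(state, i, p)
    state.a_pos[i] = x_old
    uu = float(u @ u)
    duq = 0.5 * uu * h - 0.5 * uu * h_new
    # √(|H(x')|/|H(x)|): the reverse-proposal normalization carries the
    # trial-point Hessian; this order is what satisfies detailed balance
    a = heat_bath_acceptance(du, duq, h_new / h, p.kbt)
    if state.rng.random() < a:
        state.a_pos[i] = x_new
        return u
    return None
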