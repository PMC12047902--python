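"""Model parameters for the spine-head actin/membrane simulator.

All kinetic and mechanical constants live in :class:`ModelParams`, by their
literature names and SI units (rates in 1/s or 1/(M·s), energies in J,
lengths in m, membrane moduli in pN/μm powers).  Internally the simulator
works in *unit lengths* — one coarse-grained segment rest length,
``unit_m = n_cg · r_actin`` (50 × 2.76 nm = 138 nm) — with energies in
joules.  The derived, unit-converted quantities the engine actually consumes
(``alpha_u``, ``sigma_theta``, ``pressure_u`` ...) are computed once in
``__post_init__`` and treated as read-only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

AVOGADRO = 6.02214076e23

DEG = math.pi / 180.0


@dataclass
class ModelParams:
    # --- global / numerical ---
    k_kinetic: float = 175.0            # 1/s, relative rate of biophysical updates
    n_cg: int = 50                      # actin monomers per coarse-grained object
    temperature: float = 310.0          # K
    boltzmann: float = 1.38e-23         # J/K
    eps_clip: float = 0.9               # clipping factor (× rmin) for Morse core

    # --- mechanics ---
    theta_arp: float = 70.0 * DEG       # Arp2/3 branching angle, rad
    k_s: float = 0.00725                # N/m, spring constant of adjacent monomers
    k_bend_flex: float = 5.0e-26        # N·m², flexural rigidity of F-actin
    k_bend_arp_factor: float = 2.0      # branch bending rigidity multiplier
    d_e: float = 4.81e-20               # J, Morse dissociation energy (F-actin bond)
    alpha_morse: float = 7.39e7         # 1/m, Morse spring constant (F-actin)
    d_u: float = 1.0                    # unit lengths, CaMKIIβ binding distance cap
    theta_bundle: float = 15.0 * DEG    # rad, CaMKIIβ bundling angle cap
    d_break: float = 1.5                # unit lengths, rod distance-breaking threshold
    k_bend_cam_mult: float = 160.0      # kB,Cam multiplier (unused by energy; see docs)
    k_s_cam_mult: float = 0.25          # ks,Cam multiplier (unused by energy; see docs)
    d_e_cam: float = 9.36e-20           # J, CaMKIIβ bond dissociation energy
    alpha_cam: float = 3.69e7           # 1/m, Morse spring constant (CaMKIIβ bond)
    sigma_actin: float = 8.0e-9         # m, actin molecule diameter
    sigma_cam: float = 26.0e-9          # m, CaMKIIβ diameter
    viscosity: float = 3.17             # kg/(s·m), medium viscosity
    r_actin: float = 2.76e-9            # m, rise of the actin helix
    l_p: float = 17.7e-6                # m, persistence length of F-actin

    # --- breaking angles ---
    theta_break_arp: float = 25.0 * DEG
    theta_break_actin: float = 57.0 * DEG
    theta_break_cofilactin: float = 73.0 * DEG
    theta_break_boundary: float = 31.0 * DEG

    # --- end kinetics, 1/(M·s) and 1/s ---
    k_barbed_on_atp: float = 11.6e6
    k_barbed_off_atp: float = 1.4
    k_pointed_on_atp: float = 1.3e6
    k_pointed_off_atp: float = 0.81
    k_barbed_on_adp: float = 3.8e6
    k_barbed_off_adp: float = 7.2
    k_pointed_on_adp: float = 0.16e6
    k_pointed_off_adp: float = 0.27

    # --- Arp2/3 ---
    k_branch: float = 3200.0            # 1/(M·s), keq·k2 nucleation
    k_arp_inactive_on: float = 19.0     # 1/(M·s), deactivated Arp2/3 sub-site binding
    k_arp_inactive_off: float = 0.07    # 1/s
    k_unbranch: float = 0.47            # 1/s, unbinding of activated Arp2/3 (k-2)

    # --- capping ---
    k_cap_on: float = 2.3e6             # 1/(M·s)
    k_cap_off: float = 9.5e-4           # 1/s

    # --- CaMKIIβ bundling ---
    k_cam_on: float = 0.5e6             # 1/(M·s)
    k_cam_off: float = 0.23             # 1/s

    # --- nucleotide state ---
    k_atp_hydrolysis: float = 0.35      # 1/s per ATP monomer
    k_pi_cof: float = 0.035             # 1/s per ADP+Pi monomer, cofilin nearby
    k_pi: float = 0.006                 # 1/s per ADP+Pi monomer

    # --- cofilin ---
    k_cof_edge_adp: float = 17.0e6      # 1/(M·s), accelerated, ADP substrate
    k_cof_edge_adppi: float = 0.45e6    # 1/(M·s), accelerated, ADP+Pi substrate
    k_cof_off: float = 0.7              # 1/s per bound cofilin
    k_cof_single: float = 1.0e4         # 1/(M·s), isolated binding
    cofilin_softening: float = 0.8      # full occupancy weakens bending 5×

    # --- synthesis / degradation (Eq-of-motion pools), M/s and 1/s ---
    i_actin: float = 24.4284e-6
    k_deg_actin: float = 0.0081
    i_arp: float = 0.0255e-6
    k_deg_arp: float = 0.0013
    i_cof: float = 0.0237e-6
    k_deg_cof: float = 0.0006
    i_cam: float = 3.49e-6
    k_deg_cam: float = 0.013
    i_cap: float = 0.238e-6
    k_deg_cap: float = 0.004

    # --- membrane ---
    pressure_strength: float = 85.7143  # pN/μm², compresses the polygon inward
    tension_strength: float = 15.0      # pN/μm, line tension
    curvature_strength: float = 0.18    # pN·μm², contour Helfrich modulus
    zeta_mem: float = 0.002             # m²/(N·s), per-arclength membrane mobility
    curvature_arclength_weighted: bool = True

    # --- artifact choices (documented in docs/methods.md) ---
    h_eff: float = 100e-9               # m, slab thickness for 2D number<->M conversion
    attachment_stiffness: float = 1000.0  # pN/μm, end-to-vertex spring
    overgrowth: float = 0.5             # unit lengths, ratchet attach/detach length
    step_cap: float = 0.02              # unit lengths, dissipative step cap
    mem_step_cap: float = 0.005         # unit lengths, membrane vertex step cap
    eps_reg_rel: float = 0.1            # relative Hessian regularization
    adp_fraction: float = 0.0           # ADP share of the free actin pool

    # --- derived (filled in __post_init__) ---
    unit_m: float = field(init=False, repr=False, default=0.0)
    sigma_theta: float = field(init=False, repr=False, default=0.0)
    kbt: float = field(init=False, repr=False, default=0.0)
    alpha_u: float = field(init=False, repr=False, default=0.0)
    alpha_cam_u: float = field(init=False, repr=False, default=0.0)
    k_bend: float = field(init=False, repr=False, default=0.0)      # J/rad², actin triple
    k_bend_arp: float = field(init=False, repr=False, default=0.0)  # J/rad², branch triple
    zeta_perp: float = field(init=False, repr=False, default=0.0)   # N·s/m
    zeta_par: float = field(init=False, repr=False, default=0.0)    # N·s/m
    pressure_u: float = field(init=False, repr=False, default=0.0)  # J/unit²
    tension_u: float = field(init=False, repr=False, default=0.0)   # J/unit
    kappa_u: float = field(init=False, repr=False, default=0.0)     # J·unit
    k_att_u: float = field(init=False, repr=False, default=0.0)     # J/unit²
    eps_sep_sq: float = field(init=False, repr=False, default=0.0)  # J/unit²
    eps_ang_sq: float = field(init=False, repr=False, default=0.0)  # J/unit²
    mem_step_coeff: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        self._validate()
        u = self.n_cg * self.r_actin
        self.unit_m = u
        lp_units = self.l_p / u
        self.sigma_theta = math.sqrt(2.0 / lp_units)
        self.kbt = self.boltzmann * self.temperature
        self.alpha_u = self.alpha_morse * u
        self.alpha_cam_u = self.alpha_cam * u
        # bending constant = flexural rigidity / equilibrium rod length
        self.k_bend = self.k_bend_flex / u
        self.k_bend_arp = self.k_bend_arp_factor * self.k_bend
        # Stokes drag for a rod of length one unit, radius sigma_actin/2
        ratio = u / self.sigma_actin  # L / 2R with R = sigma_actin / 2
        self.zeta_perp = 4 * math.pi * self.viscosity * u / (math.log(ratio) + 0.886)
        self.zeta_par = 2 * math.pi * self.viscosity * u / (math.log(ratio) + 0.114)
        # membrane moduli: pN/μm^k → J/unit^k  (1 pN·μm = 1e-18 J)
        u_um = u * 1e6
        self.pressure_u = self.pressure_strength * 1e-18 * u_um**2
        self.tension_u = self.tension_strength * 1e-18 * u_um
        self.kappa_u = self.curvature_strength * 1e-18 / u_um
        self.k_att_u = self.attachment_stiffness * 1e-18 * u_um**2
        bond_k = 2.0 * self.d_e * self.alpha_u**2
        self.eps_sep_sq = self.eps_reg_rel * bond_k
        self.eps_ang_sq = self.eps_reg_rel * self.k_bend
        # membrane vertex step: Δx_units = mem_step_coeff · F[J/unit] / (z[unit] · k_kinetic)
        self.mem_step_coeff = self.zeta_mem / u**3

    def _validate(self) -> None:
        for f in fields(self):
            if f.init and f.name.startswith(("k_", "i_")) and f.name not in (
                "k_bend_cam_mult", "k_s_cam_mult", "k_bend_arp_factor",
            ):
                v = getattr(self, f.name)
                if isinstance(v, (int, float)) and v < 0:
                    raise ValueError(f"rate {f.name} must be >= 0, got {v}")
        if not 0.0 < self.eps_clip < 1.0:
            raise ValueError(f"eps_clip must be in (0, 1), got {self.eps_clip}")
        for name in ("theta_arp", "theta_bundle", "theta_break_arp",
                     "theta_break_actin", "theta_break_cofilactin",
                     "theta_break_boundary"):
            v = getattr(self, name)
            if not 0.0 < v < math.pi:
                raise ValueError(f"{name} must be in (0, pi) rad, got {v}")
        if self.n_cg < 2:
            raise ValueError("n_cg must be >= 2")
        if not 0.0 <= self.adp_fraction <= 1.0:
            raise ValueError("adp_fraction must be in [0, 1]")

    # ------------------------------------------------------------------
    def volume_liters(self, area_u: float) -> float:
        """Slab volume (L) under a membrane of area ``area_u`` unit-lengths²."""
        if area_u <= 0:
            raise ValueError(f"membrane area must be positive, got {area_u}")
        return area_u * self.unit_m**2 * self.h_eff * 1e3

    def number_rate(self, k_molar: float, area_u: float) -> float:
        """Convert a bimolecular rate constant to a per-molecule-pair rate.

        ``k_molar`` [1/(M·s)] acting in the 2D slab of volume A·h_eff gives a
        propensity ``number_rate(k, A) * N_a * N_b`` that reproduces
        mass-action kinetics; see the grammar module.
        """
        return k_molar / (AVOGADRO * self.volume_liters(area_u))

    def concentration(self, count: float, area_u: float) -> float:
        """Molar concentration of ``count`` molecules in the slab volume."""
        return count / (AVOGADRO * self.volume_liters(area_u))

    def count_from_molar(self, molar: float, area_u: float) -> float:
        return molar * AVOGADRO * self.volume_liters(area_u)

    def steady_state_molar(self) -> dict[str, float]:
        """Closed-form synthesis/degradation steady states, in M."""
        return {
            "actin": self.i_actin / self.k_deg_actin,
            "arp": self.i_arp / self.k_deg_arp,
            "cofilin": self.i_cof / self.k_deg_cof,
            "cam": self.i_cam / self.k_deg_cam,
            "cap": self.i_cap / self.k_deg_cap,
        }

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.init}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        valid = {f.name for f in fields(cls) if f.init}
        unknown = set(d) - valid
        if unknown:
            import warnings
            warnings.warn(f"ignoring unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in d.items() if k in valid})
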