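"""Filament mechanics in isolation: buckling, bending, force balance.

A short filament is perturbed and relaxed by the dissipative rules alone
(no remodeling).  Printed: the Morse + bending energy before and after
relaxation, the total internal force (zero by Newton's third law), and a
compressed three-node fiber buckling sideways — the transverse instability
that severs filaments at the breaking angles when it grows large.
"""

import numpy as np

import spinedgg.mechanics as mech
from spinedgg import ModelParams, analysis

p = ModelParams(k_kinetic=5e4)  # large update rate = small stable steps

s = analysis.fixture("bent_filament", n=6, theta=0.25, seed=3)
ids = [int(i) for i in s.actin_ids()]
rng = np.random.default_rng(3)
for i in ids:
    s.a_pos[i] += rng.uniform(-0.05, 0.05, 2)

e0 = mech.radial_energy(s, p) + mech.angular_energy(s, p)
for _ in range(4000):
    mech.dissipative_step(s, ids[int(rng.integers(len(ids)))], p)
e1 = mech.radial_energy(s, p) + mech.angular_energy(s, p)
f = mech.total_force_sum(s, p)
print(f"energy before relaxation: {e0:.3e} J, after: {e1:.3e} J "
      f"(descent: {100 * (1 - e1 / e0):.1f}% released)")
print(f"total internal force: |F| = {np.hypot(*f):.3e} J/unit "
      f"(momentum conserved)")

# compression buckles a colinear triple
s2 = analysis.fixture("straight_filament", n=3)
j = [int(i) for i in s2.actin_ids()]
s2.a_pos[j[0]] = (0.2, 0.0)
s2.a_pos[j[2]] = (1.8, 0.0)
s2.a_pos[j[1]] = (1.0, 1e-3)
p2 = ModelParams(k_kinetic=1e4, k_bend_flex=0.0)
for _ in range(4000):
    mech.dissipative_step(s2, j[1], p2)
print(f"compressed triple: middle node deflects transversally to "
      f"y = {s2.a_pos[j[1], 1]:+.3f} unit lengths (buckling)")
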