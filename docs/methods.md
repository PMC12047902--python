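# Methods

`spinedgg` simulates a two-dimensional coarse-grained model of the
dendritic spine head: a dynamic actin filament network, rewritten by
stochastic rules, mechanically coupled to an enclosing membrane polygon.
This note records the model, its assumptions, the numerical choices, and
what the synthetic scenarios do and do not establish.

## State representation

One graph node represents `n_cg` consecutive actin monomers (default 50),
with the coarse-grained resting length `u = n_cg · r_actin = 138 nm` used
as the internal unit length.  A node stores its 2D position, previous/next
pointers along the filament (pointed → barbed), an optional branch pointer
(junctions point at their Arp2/3 daughter), an optional CaMKIIβ bundle
bond, a subtype (interior ◯, uncapped end ⬤, capped end ▶, junction Δ,
Arp2/3 seed ■, Arp2/3 interior □), and integer occupancies of its `n_cg`
monomer sub-sites: ATP, ADP, ADP+Pi, and cofilin-bound.  The sub-site
counts of an actin node always sum to `n_cg`; the two Arp2/3 node types
represent the branching complex itself and carry no monomer counts.  The
membrane is a single counterclockwise polygon of vertices.  Ids are
monotone row indices and never reused, so trajectories replay exactly
from a seed.

## Remodeling rules

Bimolecular rate constants k (1/(M·s)) are converted to per-molecule-pair
propensities through the slab volume `A·h_eff` (`h_eff` = 100 nm is the
effective thickness that maps 2D membrane area to a cytosolic volume);
pool concentrations are therefore `N/(N_A·A·h_eff)` and mass-action
kinetics is recovered exactly.  Species pools (free actin monomers,
active/inactive Arp2/3, cofilin, CaMKIIβ, capping protein) follow
`dM/dt = I − k·M`, advanced between stochastic events by the exact
exponential solution; initial pools sit at the closed-form steady states
`I/k`.

* **Elongation** adds one segment at an uncapped end at
  `k_on·[A]/n_cg` per end (the coarse-grained segment takes `n_cg`
  monomer additions); the growth direction is the terminal rod rotated by
  `θ ~ N(0, σθ)` with `σθ = √(2/Lp)` in unit lengths (≈ 0.125 rad), the
  small-angle statistics of a semiflexible polymer.  New segments are
  all-ATP by default (`adp_fraction` exposes an ADP split of the pool).
* **Retraction** removes the end segment at the weighted harmonic mean of
  its per-monomer off rates, `1/(N_ATP/k_ATP + (N_ADP+N_ADPPi)/k_ADP)` —
  the inverse of the expected time to strip the segment sequentially.
  Cofilin-decorated monomers use the ADP rate.  A two-node filament whose
  end retracts dissolves entirely.
* **Branching**: activated Arp2/3 binding to *any one* of a segment's
  `n_cg` sub-sites nucleates a daughter, so the per-mother propensity is
  `keq·k2·[Arp] · (free sub-sites)`.  The seed is placed one unit length
  from the mother at ±70° (plus the elongation jitter) off the mother
  axis and grows barbed-only through the seed rule (■ → □ → ⬤).
  Inactive Arp2/3 occupancy of sub-sites (capacity `n_cg`) blocks
  branching when saturated; under default conditions the inactive pool
  starts empty, so this pathway is present but dormant.
* **Capping/uncapping** toggles ⬤ ↔ ▶ at `k_cap,on·[Cap]` and the
  first-order `k_cap,off`; capped ends are excluded from growth and from
  forming new membrane attachments.
* **Cofilin** binds ADP and ADP+Pi monomers (the table lists accelerated
  rates for both substrates); binding is slow on bare nodes and
  accelerated once the node carries cofilin or a neighbor is fully
  decorated.  Bound cofilin softens the node's bending stiffness linearly
  down to five-fold at full occupancy, accelerates neighboring phosphate
  release, and feeds the severing clauses.
* **Phosphate release** proceeds ATP → ADP+Pi (`k_hyd` per ATP monomer)
  → ADP (`k_Pi`, or `k_cof,Pi` when cofilin is on the node or a filament
  neighbor).
* **CaMKIIβ bundling** crosslinks two non-adjacent nodes within `D_U` and
  15° of axis alignment at `k_on·[CaM]` per eligible pair (pairs are
  rescanned on a spatial tree every 10 checkpoints and re-validated at
  firing); the bond keeps its formation separation as the rest length of
  a Morse term with the CaMKIIβ well depth and stiffness.  The printed
  bundle bending stiffness is not used: the model never defines which
  angle triple a two-node crosslink bends.
* **Severing** is instantaneous when a disjunction of threshold clauses
  holds on an interior edge: bare-actin angle (57°, cofilin-free node),
  cofilactin angle (73°, majority-cofilin node), boundary angle (31°,
  unequal cofilin across the edge), or rod distance ≥ 1.5 u.  Thresholds
  fire at equality.  Over-stretched edges of any type disconnect (the
  Morse bond is flat there); a segment orphaned by a cut dissolves into
  the pools.  Junctions release their branch when its angle strays 25°
  from 70° or the branch rod over-stretches.

Severing and junction breaking are checked locally after every event that
moves or rebinds the involved nodes, which realizes their "instantaneous
rate" semantics without propensity bookkeeping.

## Mechanics

All forces derive from one global energy: clipped Morse potentials on
every filament, branch and bundle edge (well depth `De`, exponent `α`
taken directly from the parameter table, rest length 1 u; linearized
below `0.9·rmin` so the repulsive core stays numerically benign), plus
harmonic bending energies `k_b/2 (θ−θ_t)²` on every connected triple
(`k_b` = flexural rigidity / unit length ≈ 3.6e-19 J, doubled at
branches; target 0° along filaments and 70° for the branch triple).
Gradients are analytic, including the l'Hôpital-safe near-collinear form;
forces are strictly pairwise/triple-wise, so total momentum is conserved
to round-off.

* **Dissipative rule** (per node, rate `k_kinetic`): a forward-Euler step
  of the overdamped balance, `Δx = −∇U/(ζ·k_kinetic)`, with the Stokes
  rod drag (perpendicular form for interiors, parallel at working ends).
  The table-rate update frequency under-resolves the bond stiffness
  (`2De α²` ≈ 0.5 N/m), so steps are capped at 0.02 u (≈ 3 nm); the
  energy-descent property is exact in the small-step (large `k_kinetic`)
  limit and is tested there.
* **Thermal rule** (per node, rate `k_kinetic`): a Gaussian proposal with
  covariance `kBT·H⁻¹` from the local buckling Hessian (the isotropic
  diagonal `ΣU''·I`, clamped at zero and regularized by
  `ε² = 0.1·2De α²`; the regularizer bounds proposals to the thermal
  scale where the clipped Morse curvature vanishes), accepted with the
  heat-bath probability `A = e·s/(1+e·s)`,
  `e = exp(−(ΔU−ΔUq)/kBT)`, `s = √(|H(x')|/|H(x)|)`.  The determinant
  order is fixed by detailed balance (the reverse-proposal normalization
  carries the trial-point Hessian); the sampler reproduces the exact
  Boltzmann distribution of a single bond (KS test).  Note the bond is
  strongly anharmonic at 310 K — its Boltzmann variance is ≈1.47× the
  harmonic `kBT/U''(rmin)` — so harmonic equipartition is *not* the
  right reference for this potential.
* The bending-angle Hessian uses the positive-semidefinite Gauss–Newton
  form (rank-one outer products of the angle gradient), with a
  Frobenius-norm×identity fallback for rank-deficient interiors; only
  the buckling Hessian drives thermal proposals.

## Membrane

Energy `U = −P·Ω + τ·S + 2κ Σ H_i² z_i` on the polygon: positive `P`
(the absolute pressure difference) inflates the compartment, `τ` is line
tension, and the Helfrich term uses a discrete mean curvature — the
average over a three-vertex window of the tangent-turn estimates
`|ΔT|/z` (exactly `1/R` on a regular polygon; an unweighted-sum variant
is switchable).  The printed curvature strength is read as a contour
modulus in pN·μm² and the membrane mobility as a per-arclength mobility
(`v = ζ_mem · force-per-length`), the dimensionally consistent readings.
Vertices update at `k_kinetic` per vertex by
`Δx = ζ_mem·(F/z)/k_kinetic`.  The Helfrich term is stiff at this update
rate (explicit-Euler overshoot ≈ 300×), so its force contribution is
clipped at a fine step cap (0.005 u) while the soft pressure/tension/
spring forces use the generic 0.02 u cap; without the split the ring
roughens at the cap amplitude and spuriously shrinks.  Moves that would
self-intersect the polygon or sweep an edge across an actin node are
rejected; symmetrically, actin moves whose path crosses a membrane edge
are rejected.  This bilateral impenetrability is what makes the polygon a
compartment boundary: without it the network drifts through the membrane
and all growth happens outside.  Edges longer than 2× or shorter than ¼
of the initial spacing are split/merged (attachment vertices are kept).

### Filament–membrane coupling (Brownian ratchet)

An uncapped end whose terminal rod, extended by the overgrowth length
(0.5 u), crosses a membrane edge is attached: a new vertex is inserted at
the crossing and bonded to the end by a harmonic spring whose rest length
is the gap at attachment (default stiffness 1000 pN/μm — stiff enough to
hold a vertex's share of the membrane load within a fraction of a unit
length, i.e. the attachment acts as a constraint, not a soft tether).
Growth at a membrane-proximal end is clamped at the boundary: the new
node is placed just inside the first membrane crossing of the growth rod,
and the resulting compressed bond is the force transducer — it pushes the
tip (and through the spring, the membrane) outward while the pressurized
membrane opens gaps for the next step.  Growth steps always attempt one
full rest length of advance (the pure geometry rule preserves rod length;
compounding compressed rods would stall).  An attachment transfers to the
new end on elongation and releases when the end-to-vertex gap exceeds
twice the overgrowth length (the factor gives the bond a working range;
releasing exactly at the maximum possible rest gap makes attachments
churn every checkpoint).  Spring forces appear equal-and-opposite in the
end's and the vertex's updates (Newtonian reaction pair).

## Engine

A single exact-SSA clock (direct method) spans all channels: remodeling
events, per-node dissipative and thermal updates, and membrane vertex
updates (each mechanics channel at `k_kinetic` per eligible object).
Propensities are maintained through eligibility sets refreshed around
every rewrite plus cached per-node weight vectors recomputed when
chemistry or topology changes; matches are re-validated at firing, and an
invalidated match consumes the time step without rewriting.  Pools,
propensity refreshes, ratchet release, the attachment sweep, remeshing
and the bundling pair rescan happen at fixed checkpoints (1 ms; pair scan
and remesh every 10).  All randomness flows from one seeded generator, so
a seed fixes the trajectory byte-for-byte.

## Default scenario and study conditions

The default initial condition is the canonical seed: a three-node
mother filament (pointed end, junction, barbed end, 1 u spacing) with its
Arp2/3 seed at 70°, inside a regular 32-gon of circumradius 0.18 μm — a
snug polygon around the seed network (the initial radius is a modeling
choice, config-exposed; 0.18 μm leaves ≈ 0.3 u margin
over the seed tips, so the first attachments form immediately).  At the
table parameters the membrane's tension–pressure balance radius is
`Ω/P = 0.175 μm`; growth beyond it is driven by the network: branching
and severing keep nucleating uncapped tips whose clamped polymerization
ratchets the pinned membrane outward.  Under these defaults the
membrane-enclosed area grows by ≈ 21% ± 6% (mean ± sd over ten seeds)
in 0.6 s of biological time, with the membrane developing the
characteristic low-circularity protrusions.

The acceptance sweeps vary one synthesis rate over `{0.1×, 1×, 10×}`
(the table value centered, log-spaced) with ten
replicate seeds per point at a shortened horizon (0.3 s; 0.25 s for
Arp2/3, whose high-rate networks grow large) — sizes chosen so the full
suite completes in a routine test run.  At these horizons the three
qualitative trends (area down with cofilin, circularity down with
CaMKIIβ, area up with Arp2/3) are weak relative to seed-to-seed noise in
this implementation; the sweep tests assert the trends and report
honestly.

## What the scenarios do and do not show

The default scenario emulates the model's study conditions, not a
validated biological spine: concentrations derive from fluorescence-fit
synthesis/degradation rates (the implied 3 mM G-actin and 60 μM capping
protein are far above cytosolic values, which makes barbed ends cap
within ~10 ms and elongation very fast), there is no excluded volume
between non-bonded filaments, no filament annealing, no formin/profilin
pathway, and the geometry is strictly 2D.  Passing tests therefore
establish internal correctness — conservation laws, oracle agreement of
energies/forces/statistics, rate-law fidelity, geometric closed forms
and reproducibility — not quantitative agreement with real spine
morphodynamics.

## Known limitations

* The dissipative update at the table `k_kinetic` is step-capped rather
  than resolved; effective node speeds saturate at ≈ 3.5 u/s.
* Severing at the printed thresholds combined with sub-site-accelerated
  cofilin binding shreds confined filaments into many short fragments
  and inert two-node pieces; these persist as membrane anchors and
  dominate late-time network composition.
* The Arp2/3 inactivation pathway is dormant by default (nothing feeds
  the inactive pool).
* Membrane–filament contact is vertex/edge-resolution impenetrability
  plus end attachments; filament bodies do not repel each other.
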