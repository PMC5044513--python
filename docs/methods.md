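# Methods

## Scope and dimensionality

The package models three perfusion hepatocyte-culture devices as planar 2D
mid-plane sections. Full 3D CFD is out of scope: published 3D field values
for these devices (shear ranges, 3D oxygen minima, 3D equilibration times)
are treated as ordering and monotonicity targets only, because a 2D section
cannot reproduce them quantitatively — the published 2D and 3D inlet peak
velocities for the same devices already differ by a factor of ~5, which
shows how strongly such numbers depend on the 2D normalization. The one
genuinely axisymmetric element, fully developed flow in a circular inlet
port, is solved with a dedicated radial finite-volume solver, for which the
continuum peak velocity is exactly 2Q/A.

### 2D normalization

Each planar geometry carries an explicit extrusion depth, chosen as
depth = V_device / A_section so the section area times the depth reproduces
the device's stated total volume exactly (7.0, 4.8 and 4.0 mL). A 3D
volumetric flow rate Q maps to the per-depth 2D rate q = Q/depth. This keeps
the 2D residence volume V/Q equal to the device's, which is the quantity
that controls distribution times. It does not preserve port cross-sections
(a circular port becomes a slot), hence 2D near-port velocities are not
comparable to 3D values; inlet Reynolds numbers are therefore computed from
the true circular port area.

## Geometry defaults

Published dimensions: total volumes (7.0/4.8/4.0 mL), port internal
diameters (RB four 1-mm ports; FB 1.5-mm inlet, 3-mm outlet; QV 1-mm inlet,
2-mm outlet), the 1-mm scaffold, the 100-μm filter layers with 100-μm pores,
the 100-μm scaffold pore size, the bed porosity factor 0.3, and the three FB
widths (27.3/22.2/16.7 mm). Everything else is a documented, overridable
default chosen to satisfy those constraints:

| device | default section | rationale |
|---|---|---|
| RB | two 3-mm media channels × 40 mm, 1-mm scaffold between; depth 25 mm | channel heights/length free; membranes on outer walls |
| FB | funnel (4 mm) → filter → 2.5-mm bed → filter → funnel; width per variant; depth ≈ 24 mm | smoothly expanding/contracting profile matches the device's parabolic cross-section and, at creeping Reynolds numbers, avoids artificial stagnant corner wedges a flat-roofed box would create |
| QV | 20-mm-wide chamber, roof slanting 11 → 9 mm, inlet high on the left wall, 2-mm outlet lower on the right wall, 0.5-mm bead layer on the floor (x = 4–16 mm); depth 20 mm | slanted roof and offset outlet per the device description |

Port staggering in the RB (top channel's outlet at 60% length on the top
wall, bottom channel's inlet at 40% length on the bottom wall) is the 2D
stand-in for the device's angled ports, which are there to drive a gentle
cross-flow through the scaffold; with co-axial ports a 2D section would
develop no cross-flow at all. The resulting scaffold through-flow is
~1e−5 m/s, inside the published 3D scaffold-velocity range (1–8e−5 m/s).

Porosities: scaffold ε = 0.9 (woven polycarbonate; only its 100-μm pore
size is published), FB bed ε = 0.3 (published), FB filters ε = 0.35, QV
floor bed ε = 0.7 (a sparse single layer of 500-μm beads: 1.5e6 cells at
50% v/v occupy ~12.6 μL of beads scattered over the floor). Permeabilities
are Kozeny–Carman estimates κ = d²ε³/(180(1−ε)²). The physically 100-μm
filter layers are represented as one 250-μm mesh layer with permeability
scaled ×2.5 so the Darcy resistance t/κ is preserved.

## Flow solver

Staggered marker-and-cell finite volumes on a masked Cartesian grid
(cells whose centers fall inside the section polygons are fluid). The
stationary momentum/continuity system with Brinkman drag μ/κ in porous
regions is assembled as one sparse saddle-point system and solved directly
(SuperLU); the convective term ρ(u·∇)u is first-order upwind, lagged, and
converged by under-relaxed Picard iteration (relative update < 1e−8,
typically ~15 iterations at the chamber Reynolds numbers of 10–15). Rates
implying inlet Re > 2000 are refused as outside the laminar model.

Boundary conditions: prescribed parabolic (optionally plug) inflow
distributed over the inlet faces; no-slip walls and gas membranes with a
quadratic ghost treatment that makes the viscous term exact for a parabola
vanishing at the wall (the discrete Poiseuille profile is then nodally
exact, and wall shear from the one-sided quadratic fit is second order);
outlets carry zero normal velocity gradient at reference pressure 0, which
also pins the pressure level. Discrete continuity makes global mass
conservation exact to solver precision; the channel-flow oracle shows
L2 velocity error ~0.1% and wall-shear error ~0.1% at default resolution.

Shear reported "at the cells" inside a homogenized porous compartment uses
the standard pore-scale estimate τ = μ (|u|/ε)/(d_pore/2), because resolved
macroscopic gradients inside a homogenized region understate what cells
experience. With it, the FB bed median (~1700 μPa) and RB scaffold median
(~64 μPa) fall inside the published 3D ranges (1070–4260 and 34.6–484 μPa),
and the ordering FB > RB > QV is robust; only the ordering is asserted.

## Transport solver

Cell-centered finite volumes on the same grid; advective face fluxes are
exactly the flow solver's (so the advection operator conserves mass
discretely), first-order upwind, two-point diffusion. In porous regions the
solute occupies the pore space: storage is ε·V_cell and effective
diffusivity ε·D (tortuosity beyond that is neglected). Time stepping is
implicit Euler (dt = 1–2 s), one sparse factorization reused for all steps.
Recirculation couples the outlet flux to a well-mixed external reservoir
(default 2 mL loop dead volume — the experimental loop volume is
unreported) feeding the inlet; the discrete closed-loop total mass is
conserved to machine precision by construction.

The steady oxygen balance uses the same operator plus the sink
R(c) = V_max c/(c+k_m) δ(c), linearized per Picard sweep as
R = [V_max δ(c_old)/(c_old+k_m)]·c, which keeps the system an M-matrix and
the iterates non-negative; under-relaxation 0.7, convergence 1e−10.
V_max is per compartment (bulk) volume, per the cell-count recipe, so the
sink uses the full cell area. Oxygen enters at the inlet at C₀ (scaled by
gas_fraction/0.21 via Henry linearity) and, in the RB and FB, through
gas-membrane boundaries held at the same concentration (Dirichlet). The QV
has no membrane: oxygen arrives only with the medium, which is why it is
the device whose bead-level oxygen responds strongly to flow rate and gas
fraction.

### Uniformity criterion

The study's "time to establish a uniform distribution" is not given an
operational definition in the source material. Two facts constrain the
choice: the reported FB value (6 min) is close to the chamber residence
time, and distribution times were reported insensitive to the diffusion
coefficient across 1e−6–1e−10 m²/s. A strict minimum-over-all-cells
criterion violates both in any no-slip domain: the last cells to fill are
vanishing-measure wall layers whose filling time diverges as D decreases
(measured here: ~32% spread across that D range, and a time well above the
bulk's). The default criterion is therefore volume coverage: the first
output time at which ≥95% of the fluid volume (pore-space weighted) is at
≥95% of the inlet concentration, sustained for the rest of the run. With it
the FB distributes in 6.5 min at default resolution and the D-spread drops
to ~12%. `coverage=1.0` recovers the strict minimum. The RB and QV sections
distribute much more slowly than the published 2D figures (54 and 34 min vs
18 and 6 min); those figures could not be reproduced under any criterion
tried with these section geometries and are not asserted — consistent with
the unrecoverable 2D normalization noted above.

### Equilibration estimator

Outlet washout series are max-normalized; equilibration is the first sample
at or above 0.95 of a plateau reference, sustained (median of the
subsequent samples within 0.05 of the level). The reference is the median
of the trailing quarter of samples rather than the raw maximum: the maximum
of a noisy series overstates the plateau by ~2 noise standard deviations,
and thresholding 0.95 against it makes the estimator diverge at 5% CV. If
the trailing median sits below 85% of the maximum the series has either not
plateaued (sentinel: not reached) or is an overshoot-then-decline series —
detected first, as a post-peak median more than 0.2 below the peak — which
reports the first peak time with an overshoot flag, matching the
interpretation caveat that an early outlet peak in a recirculating loop
underestimates system equilibration.

## Bead model

Steady diffusion–consumption in a sphere (or cylinder):
(1/r^s) d/dr (r^s D dc/dr) = R(c), dc/dr(0) = 0, c(R) = 214 μM, with the
same Michaelis–Menten + step-down sink at V_max = 4.77e−2 mol/m³/s (50% v/v
packing). Conservative radial finite volumes (the r = 0 singularity closes
naturally through the vanishing face area), damped Newton with analytic
Jacobian, 400 cells by default (center value changes <0.5% on refinement;
surface flux balances integrated consumption to ~1e−7 relative). The
zero-order oracle C_s − V_max R²/(6D) (sphere; 4D for cylinder, floored at
zero in the dead-core regime) agrees with the full solve within 3% whenever
the center concentration is far above k_m. Both symmetries are exposed
because the source's own 2D and 3D bead values disagree at 500 μm (25 vs
150 μM) and only the 250-μm sphere value (175 μM; computed here 174.2 μM)
is quantitative. An optional external film-resistance surface condition
exists but is off by default.

## Synthetic washout data

The generator emulates the cell-free validation experiments: a tracer
(7-ethoxycoumarin read by fluorescence or trypan blue by absorbance —
wavelengths are metadata; both instruments are modeled as linear in
concentration) dosed into a recirculating loop, the outlet sampled at 1-min
cadence up to 30 min (60 min for RB-like runs) and normalized to the
maximum. The loop is a reservoir (2 mL) feeding a chain of stirred tanks
(default 3) holding the chamber volume; a bypass fraction short-circuits
the chain and reproduces the overshoot-then-decline shape. The linear
system is evaluated exactly by matrix exponential; noise is multiplicative
Gaussian at CV 5% (seeded, deterministic). The noiseless truth
equilibration time is recorded for recovery testing; across 100 seeds the
estimator's median bias is well under one sampling interval.

What the generator does not emulate: tracer adsorption to tubing, bubble
artifacts, instrument drift, or spatial concentration structure inside the
chamber (the tank chain is zero-dimensional). Passing recovery tests
therefore validate the estimator against mixing-topology and noise effects,
not against spatial CFD detail — the CFD side is exercised separately by
the transport solver.

## Problem sizes and determinism

Default meshes: RB 80×28, FB 91×53, QV 50×44 cells (2000–3700 fluid cells;
sub-millimeter resolution, 0.1 mm across the scaffold and bead layers).
These sizes put every flow solve under a second and the full transient
transport runs under a few seconds while leaving the verification oracles
(Poiseuille, pipe peak, bead center) converged to well under their
tolerances; halving the resolution changes the reported FB distribution
time by one output interval. All solvers are deterministic; the only
randomness in the package is the seeded measurement noise of the synthetic
generator.

## Known limitations

- 2D sections cannot reproduce 3D port velocities, 3D shear magnitudes or
  3D oxygen minima; these are covered as orderings and monotonicities.
- RB/QV distribution times depend strongly on unpublished chamber
  dimensions; only the FB value is asserted quantitatively.
- First-order upwinding adds numerical diffusion ~u·dx/2; at the default
  resolutions this is below the test compound's D in the bulk and vanishes
  near walls, but sharp-front details are smeared.
- The fluidized bed is modeled as a static homogenized porous region (as in
  the source study); bead motion and bead–bead shading are not represented.
- Oxygen membranes are ideal Dirichlet surfaces; membrane mass-transfer
  resistance is neglected.
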