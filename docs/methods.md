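# Methods

## Problem and model

The package simulates steady blood flow through a rigid, straight model
inferior vena cava (IVC) — a circular tube of diameter D = 20 mm — with an
eight-arm convertible wire filter deployed on its axis, and computes the
hemodynamic metrics used to judge such a device: wall shear stress (WSS) on
the filter wires, velocity profiles along and off the axis, the extent of
the low-speed stagnation zone trailing the filter, and the relative flow
resistance the filter adds to the vessel.

Governing equations are the incompressible steady Navier–Stokes equations
with a generalized-Newtonian stress, tau = mu(gamma) [grad V + (grad V)^T].
Blood shear thinning is modelled with the four-parameter Carreau law

    mu(gamma) = mu_inf + (mu_0 - mu_inf) [1 + (lambda gamma)^2]^((n-1)/2)

with the standard blood fit mu_inf = 3.45 mPa s (plasma), mu_0 = 56 mPa s,
lambda = 3.313 s, n = 0.3568, and density rho = 1060 kg/m^3.  The operating
point is a constant volumetric rate Q = 1.134 L/min, i.e. a mean speed
V_m = 0.0602 m/s; with a spatially averaged viscosity near 0.01 Pa s the
Reynolds number is O(120–130), firmly laminar.  Pulsatility, vessel
compliance, side branches and trapped clots are outside the model's scope.

## Modelled assumptions

* The IVC is rigid and circular; the filter sits exactly on the axis with
  its lateral stabilizers ignored.
* The filter is a set of straight wire capsules: eight arms (radius
  0.2 mm) plus, in the unconverted states, a cylindrical head (radius
  1.5 mm, length 3 mm) at the cone apex.  The real device's dimensions are
  not published; cone length 40 mm and the radii above are declared
  assumptions consistent with the device's size class, are configurable,
  and travel with every output (config hash in each manifest).
* Deployment states: "normal" (cone opening upstream, head downstream),
  "reverse" (the exact axial mirror image through the apex plane) and
  three converted states in which the head is removed and each arm pivots
  about its wall-contact point until it makes an inclined angle alpha with
  the wall: small open 14°, moderate open 10°, large open 5°.  Arm length
  is preserved by the pivot, so the radial penetration of the cone,
  L sin(alpha), shrinks monotonically as the filter opens — the
  monotonicity the geometry tests assert.

## Semi-analytic pipe-flow reference (the oracle)

In fully developed tube flow the shear stress is exactly linear in radius,
tau(r) = tau_w r/R.  Because tau = mu(gamma) gamma is strictly increasing
for 0 < n <= 1, it inverts uniquely (bracketed Brent iteration, relative
tolerance 1e-12); integrating -du/dr = gamma(r) from the no-slip wall gives
the profile, and a one-dimensional Brent search on tau_w matches the
integrated flow rate to Q (quadrature: composite Simpson on 401 uniform
radial stations; the Newtonian Poiseuille bounds bracket the root).  At the
study operating point this yields tau_w = 0.172 Pa — the filter-free wall
shear scale WSS_0 ≈ 0.17 Pa — and a blunted profile with centreline speed
1.76 V_m.  The oracle is independent of the finite-volume solvers and
serves as their quantitative reference.

## Finite-volume solvers

Two staggered-grid SIMPLE-type solvers share the rheology:

**Axisymmetric (r, z)** — used for the quantitative empty-tube checks.
Implicit under-relaxed momentum solves (sparse direct), a direct pressure-
correction solve, SIMPLEC correction coefficients (alpha_u = 0.95,
alpha_p = 1.0), first-order upwind convection (immaterial for the parallel
flows this topology is used for), Picard viscosity updates.  At 64 radial
cells the outlet profile matches the oracle to 0.01% (L2) and the
developed pressure gradient to 0.01%.

**Cartesian 3D immersed boundary** — used for the filter cases.  The tube
cross-section is embedded in an nx × ny box; per-cell solid fractions are
computed by deterministic midpoint subsampling of the capsule signed
distance field.  Three solid treatments, by resolvability:

* cells/faces more than half solid are hard no-slip (velocity pinned);
* partially solid *wall and head* cells get a strong Brinkman penalization
  (coefficient 1e3 × the local diffusion scale), since these surfaces are
  at or above the cell scale;
* partially solid *arm* cells carry a thin-wire drag: the Lamb–Oseen drag
  per unit length of a cylinder in cross-flow, F/L = 4 pi mu U /
  ln(7.4/Re_a) with Re_a = rho U a / mu (log factor floored at 0.5),
  multiplied by the wire length contained in the cell
  (fraction × cell volume / (pi a^2)).  This makes the obstruction scale
  with the true 0.2 mm wire radius instead of the grid spacing — at desk
  resolutions a wire is thinner than a cell, and pinning whole cells would
  model a rod 2–5× too thick.  The fidelity limit remains: quantitative
  wire-surface fields require >= 2 cells across the wire diameter.

Discretization: first-order upwind convection made second-order by a
deferred upwind correction (slopes clamped at array ends), central
diffusion with the transpose-stress term omitted from the implicit
operator (its effect vanishes in parallel shear and is absorbed by the
Picard loop elsewhere), variable axial spacing with a refined window
around the filter (factor 2 by default).  Momentum systems are solved
with warm-started Jacobi-preconditioned BiCGSTAB whose absolute inner
tolerance is tied to the outer residual target (divided by sqrt(n),
because the outer norm is an L1 sum), with a sparse-direct fallback; the
pure-Neumann pressure correction uses conjugate gradients on the
mean-projected right-hand side.  The inlet imposes the analytic fully
developed oracle profile (rescaled to the exact discrete flux), which
replaces the 20-diameter uniform-inlet development length at equal
fidelity and far lower cost; a uniform inlet remains available by
configuration.  The outlet is a zero-gradient copy rescaled to the target
flow rate, making the discrete flux through every cross-section exact by
construction.  Residuals are normalized by inlet-flux scales (rho Q for
continuity, rho Q V_m for momentum) so tolerances are grid-independent.
There is no random initialization: the initial state is the extruded
inlet profile plus the developed pressure ramp, so repeated runs are
bit-identical.

## Post-processing

* **Filter WSS.**  Each wire is sampled at 40 arclength stations × 8
  azimuths (azimuth 0 facing upstream).  The tangential speed U at a probe
  1.5 cells off the surface is converted to a wall shear rate with the
  creeping-flow log profile around a cylinder, gamma_w = U / (a ln(d/a)),
  then to stress via the Carreau law.  Patch areas are exact surface
  elements, so the area-averaged filter WSS is a proper surface integral.
  Stresses are reported normalized by WSS_0.
* **Pressure drop / relative flow resistance.**  Sectional pressures are
  open-area-weighted means, interpolated linearly between cell layers;
  RF = 100 (dP - dP0)/dP0 with dP0 from the *same grid's* filter-free
  solve, so stair-step wall bias cancels in the ratio.  Default segment
  z = -50 mm to +10 mm about the apex (configurable; the printed reference
  dP0 = 0.0249 mmHg is itself inconsistent with a 60 mm fully developed
  segment, which would give ≈ 0.015 mmHg, so only RF ratios are compared).
* **Profiles and stagnation.**  Speed along the axis ("centric") and along
  a parallel line at 0.5 R, azimuth 22.5° (midway between arms — both
  offsets are declared conventions, the source figures give no numbers).
  For the reverse state the plotted profile is shifted by the head length
  so the heads of the normal and reverse cases coincide; wake metrics use
  unshifted stations.  The stagnation length is the first contiguous run of
  stations downstream of the filter's trailing edge where the speed falls
  below 0.9× the filter-free reference at the same station; the threshold
  is configurable and always reported, since "stagnation" has no published
  quantitative definition.

## Verification calculus

For three meshes coarse→fine with differences eps21, eps32, the observed
order is p = ln(eps21/eps32)/ln(r) with r the *fine-pair total-node-count
ratio* — the convention under which the reference six-mesh series
reproduces its published orders (3.41 on the finest WSS triplet) and GCI
cells (0.46%, 3.39% with safety factor 1.25).  A Celik-style fixed-point
correction for unequal successive ratios is available (`ratio_correction`)
but is not the default, because the published values evidently use the
plain formula.  GCI = 125 |phi_f - phi_c| / |phi_f| / (r^p - 1) in
percent; Richardson extrapolation gives the infinite-mesh estimate.  The
package's own empty-tube study refines the radial direction only, so the
node-count ratio equals the per-dimension ratio and the observed order
lands at the scheme order (~2).

## Study problem sizes

The reduced-resolution suite solves all six cases on a 20 × 20 × 110 grid
(1 mm transverse cells, 2 mm axial cells in a refined window around the
filter, 4 mm outside; domain z ∈ [-140, +190] mm about the apex) to scaled
residuals of 2e-4, about 160 s total on one core.  A coarser preset
(16 × 16 × 84, 4e-4) runs in under a minute and preserves all qualitative
orderings.  The axisymmetric verification grid is 64 × 100 at residuals of
1e-6.

## What the synthetic conditions do and do not show

The geometry generator emulates the published deployment states of the
real device, but its wire dimensions are declared assumptions, and the
immersed-boundary grids are two orders of magnitude smaller than the
2.4-million-node body-fitted meshes a fully resolved study uses.
Consequently the suite is expected to reproduce — and its tests assert —
the *structure* of the reference results: RF(normal) > RF(large open) > 0
with RF decreasing monotonically as the filter opens and the reverse state
below the normal one; a finite centreline wake behind the normal, reverse
and small-open filters that vanishes for the moderate/large-open states;
peak upstream-side arm WSS several times WSS_0; and a viscous-block
acceleration of the core flow.  Absolute wake lengths (~8 D at full
resolution), the ~20× peak WSS multiplier and absolute RF percentages are
resolution-limited here and are reported, not asserted.  Quantitative
agreement is demonstrated where an exact reference exists: the
axisymmetric solver against the semi-analytic oracle, and the
verification calculus against the published mesh series.

## Known limitations

* Stair-step tube wall in the 3D solver (no cut cells); absolute dP is
  grid-biased, which the RF ratio removes.
* The thin-wire drag model assumes locally uniform cross-flow per cell and
  ignores wire-wake interaction between neighbouring arms near the apex.
* First-order upwinding (plus deferred correction) still diffuses the far
  wake at 2–4 mm axial spacing; measured stagnation lengths at desk
  resolution are roughly a third of the fully resolved values.
* The scalar shear-rate magnitude uses centered differences of
  interpolated cell-centre velocities; near masked cells it is first-order
  accurate.
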