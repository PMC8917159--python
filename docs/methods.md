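# Methods

## Model overview

`hemonet` models blood in capillary-scale vessels as a suspension of
deformable red cells in plasma at zero Reynolds number. The package has
three layers: (i) synthetic geometry — planar networks of winding
vessels (5.5–24 μm diameter) joined at bifurcations and mergers, with a
closed lumen boundary built from the union of constant-width strips
along the centerlines plus blending disks at junctions; (ii) cell
mechanics — Skalak shear/dilation elasticity and Helfrich bending on a
triangulated biconcave surface (3D, statically validated) and on a
closed contour (2D, advected by the flow core); (iii) an
immersed-boundary Stokes solver coupling the two, followed by the
statistics stages (per-vessel hematocrit/flow/resistance, bifurcation
partitioning, lingering, wall shear stress) and the paired
normal-vs-stiffer experiment driver.

Units: lengths in μm, times in ms, pressures in Pa; velocities are then
mm/s and 2D fluxes μm²/ms per unit depth. Material parameters are
stored in the units the literature quotes (N/m, J, Pa·s) and converted
once (see `hemonet.units`).

## Membrane mechanics

**Resting shape.** The Evans–Fung biconcave profile with the classic
coefficients (0.207161, 2.002558, −1.122762), scaled so the maximum
pairwise vertex distance equals 7.8 μm. The 3D surface is a subdivided
icosahedron mapped onto the profile (20·4ⁿ triangles; n = 4 gives the
5120-element default); the 2D cell is the cross-section contour with
equal reference arc spacing.

**Skalak elasticity (3D).** Per-triangle membrane FEM with linear
elements: the in-plane deformation gradient F maps the reference
triangle to the current one, C = FᵀF gives the invariants
I₁ = trC − 2 and I₂ = detC − 1, and the energy density is
W = (G_s/4)(I₁² + 2I₁ − 2I₂) + (C_d·G_s/4)I₂². The dilation ratio
defaults to C_d = 100 (a nearly area-incompressible membrane; the
choice only needs to be large). Nodal forces are the exact analytic
gradient; finite differences confirm them to ~10⁻⁸ relative.

**Helfrich bending (3D).** E = 2κ_b Σ_v H_v² A_v with the
cotangent-Laplacian mean curvature (H_v = |m_v|/2A_v, m_v the
integrated mean-curvature vector) and barycentric vertex areas;
κ_b = 2×10⁻¹⁹ J. The force is the exact analytic gradient of this
discrete energy (chain rule through the cotangents and areas), checked
against finite differences and against the sphere closed form
E → 8πκ_b under refinement.

**2D analogs.** Contour elements carry the strain-hardening tension
T(λ) = G_s(λ − λ⁻³) — an analog chosen to mimic the Skalak law's
stiffening, not a literal reduction — and the bending energy
(κ_b/2)∮k² ds discretized by turning angles (the circle closed form
πκ_b/R is reproduced). Both forces are exact gradients, so net force
and torque vanish identically for every evaluation.

## Flow core

**Equations.** Continuity and unsteady Stokes with a spatially varying
viscosity: plasma 0.0012 Pa·s outside cells, hemoglobin 0.006 Pa·s
inside (ratio 5), blended over ~2 grid cells by a smoothed indicator of
each cell polygon. Advection is absent (capillary Reynolds numbers are
≪ 1); the unsteady term is retained but is numerically negligible
against viscosity at these scales.

**Discretization.** Uniform staggered (MAC) grid, default 8–10 points
per cell diameter. The viscous stress div(μ(∇u + ∇uᵀ)) is discretized
with cell-center viscosities on compressive links and corner-averaged
viscosities on shear links.

**Coupled solve.** Each backward-Euler step solves the full
velocity–pressure saddle system at once. This is a deliberate departure
from split projection schemes: in the viscous-dominated regime
(ρ/Δt ≪ μ/h²) the pressure Schur complement behaves like a
lubrication operator whose long-channel modes defeat both mass-matrix
and Poisson-type preconditioners, so pressure converges impractically
slowly under splitting; the monolithic solve is exact per step. The
factored sparse matrix is reused across steps as a preconditioner in a
defect-correction loop (refactored every 20 steps, on cell insertion,
or when the loop stalls), so each step is still solved exactly for the
current viscosity field. An exact projection operator (Poisson solve +
gradient correction) is kept as a utility for initializing and cleaning
externally supplied fields.

**Walls.** Sharp-interface ghost nodes: every exterior velocity node
adjacent to the lumen gets its value from a quadratic no-slip closure —
the parabola through the wall zero and two probes at h and 2h along the
inward normal, evaluated at the ghost. The closure is linear in the
unknowns and is eliminated directly into the system matrix. This
reproduces plane Poiseuille flow to <1% at 32 points across the channel
and converges at second order in the interior-resistance metric.

**Conservative continuity.** Faces cut by a wall carry zero flux in the
discrete divergence (a cut-cell aperture closure). Without it the ghost
values leak ~0.3% of mass through walls; with it, prescribed inflow is
conserved to machine precision and junction flux balance holds
discretely.

**Boundary conditions.** Port segments are extended through the domain
boundary ("stubs") so ports open onto the box edge. Pressure ports pin
the pressure in the boundary layer of lumen cells (values in Pa or
mmHg); flow-rate ports prescribe a parabolic normal-velocity profile on
the opening, normalized so the discrete flux equals the prescribed
value (axis-aligned openings only; pressure BCs cover arbitrary
orientations). The physiological per-vessel flow scale of roughly a
nanoliter per second maps to per-depth fluxes of order 10 μm²/ms here
(2D fluxes are per unit depth throughout).

**Membrane coupling.** Forces spread to the grid and velocities
interpolated back with the 4-point cosine kernel (partition of unity;
spreading conserves total force; the pair is adjoint). Membranes move
by forward Euler at the interpolated velocity. The time step is set by
the membrane-stiffness limit Δt = 0.12·h·μ/(G_s + κ/h²) — about
0.027 ms for normal cells at 8 points per cell, ten times smaller for
the stiffer cells (empirically, a safety factor of 0.25 is unstable;
0.12 is robust).

**Area maintenance.** The interpolated velocity field is not exactly
divergence-free at the membrane, so each cell's enclosed area is
restored every step by a uniform offset along the outward normal
(offset = deficit/perimeter, capped at 0.02h so the correction never
drives the dynamics). Typical per-step corrections are ~10⁻⁵ relative;
a leak exceeding 5% within one output interval aborts the run as an
instability.

**Inlet seeding.** Cells are inserted at the inlet entry gate with
lateral offsets drawn with probability proportional to the local speed
u(y) — a uniform-concentration core delivers number flux ∝ velocity —
over the band that keeps the membrane at least ~1.5 grid cells off the
wall (the cell-free layer). The arrival rate r = H·w/(A_cell·E[1/u])
makes the expected tube hematocrit equal the target H; arrival times
are stratified around regular spacing. The calibration measurement
(acceptance target) advects the scheduled cells kinematically with the
steady plasma profile and averages the cell-area fraction in a 60-μm
inlet window over 2 s; full simulations insert the same schedules into
the two-way-coupled solver, delaying any insertion that would overlap
an existing cell.

## Statistics

Per-vessel tube hematocrit is the instantaneous cell-area fraction
inside the segment lumen (junction blend disks belong to no segment —
the gate rule — so nothing is double counted); discharge hematocrit is
not used. Flow series are gate fluxes (Simpson quadrature at
grid-spaced samples plus quadratic no-slip wall panels); resistance is
the mean entry–exit pressure drop over the mean flux. Coefficients of
variation use the population standard deviation. Partitioning windows
are non-overlapping, 0.1 s at model scale; cell counts are net centroid
gate crossings (a backward re-crossing decrements), and a crossing is
attributed to the gate whose segment owns the crossing midpoint
(nearest centerline), which prevents double counting where daughter
gate planes overlap near an apex. N\* counts number flux. The WSS
normal derivative uses the interior-only three-point stencil
(−5u₁ + 8u₂ − 3u₃)/2h at probes h, 2h, 3h — exact for parabolic
profiles and zero for plug flow — with the plasma viscosity, since the
cell-free layer keeps membranes off the wall.

**Lingering.** The criterion is qualitative in the field ("longer than
a freely flowing cell"), so the operational definition is the module's
central judgment call: an event is a maximal run of samples with the
centroid within d_th of the apex and speed below α times the cell's own
upstream mean speed (measured over the 3-feeder-radii approach band),
lasting at least T_th. Defaults: d_th = one feeder radius, α = 0.5,
T_th = 5× the apex transit time 2·d_th/u of a centerline tracer. All
three thresholds are configurable; the detector achieves recall 1 and
zero false positives on planted synthetic stalls.

## The synthetic-data generator

`synthesize_event_stream` emits mother/daughter gate crossings with a
prescribed routing probability, straight-line trajectories through an
idealized junction, and planted apex stalls of prescribed duration,
returning the ground truth alongside — every analysis stage is testable
against exact truth without the solver. `synthesize_velocity_field`
samples plane-Poiseuille/plug/skewed profiles on the staggered grid.
What these do *not* emulate: cell–cell interactions, deformation, the
feedback of cells on the flow, or correlated arrivals; passing the
statistics tests therefore validates the bookkeeping and formulas, not
the flow physics (the solver runs do that).

## Desk-scale study conditions and their limits

The reference systems in this field are 3D networks traced from in-vivo
images, simulated on ~10⁸-point grids with ~10³ cells — cluster scale.
This package's study conditions are deliberately desk scale: a 2D flow
core, single fixtures or small generated networks, 8–10 grid points per
cell diameter, run durations of 12–320 ms, and 10–30 cells per
mechanism run (stated here as the package's problem sizes; the paired
experiment accepts a global time-scale factor). Three consequences
matter when interpreting results:

1. **Resistance exaggeration.** A 2D cell spans the full channel depth,
   so a single cell raises a vessel's resistance far more than in 3D.
   With pressure-driven ports, a few cells can visibly shift a
   bifurcation's flow split. Where a fixed split is the study
   condition (the imposed-Q\* partitioning check), outlet flow-rate
   conditions pin the split exactly.
2. **Blocking artifact at narrow daughters.** When the cell is as large
   as a daughter mouth, every transit partially occludes the nearer
   (higher-flow) branch and the measured partitioning turns reverse —
   a 2D-exaggerated version of the real blocking mechanism. The
   Zweifach–Fung (regular-partitioning) regime appears cleanly when
   daughters are clearly wider than the cell (cell/daughter ≲ 0.7) and
   cells arrive near the feeder axis one at a time, which is how the
   low-hematocrit partitioning condition is realized (single-cell
   probes at −1, 0, +1 μm offsets all route to the higher-flow branch).
3. **Small samples.** Mechanism runs count 10–30 cell passages;
   fractions like N\* carry binomial noise of ±0.1. Tests assert
   orderings and inequalities, not tight values.

## Numerical choices, degenerate inputs, tie-breaks

- Gate placement: entry gates one local radius downstream of the
  junction blend; a cell within the blend disk belongs to the junction
  region, not to any vessel.
- Windows with zero mother crossings are excluded from f and σ_N,Q
  (counted separately), never NaN-propagated.
- Δ metrics use the normal run's higher-flow daughter so paired
  comparisons stay aligned if the split flips; vessels with near-zero
  normal-run denominators are suppressed (reported as missing).
- Δτ is floored: wall points with |τ_normal| below 1% of the network
  median report the absolute difference instead of a relative blow-up.
- Empty vessels report H = 0 with an undefined (missing) CV; empty
  event logs produce all-missing reports, not exceptions.
- Determinism: all randomness flows from a single integer seed through
  named generators; identical configs and seeds give identical records,
  which is also how the null experiment (stiffness multiplier 1) yields
  exactly zero deltas.

## Known limitations

- The 2D core cannot reproduce 3D magnitudes (resistance and WSS
  changes, absolute partitioning curves); it reproduces mechanisms and
  orderings.
- Membrane viscosity, thermal fluctuations, spontaneous curvature and
  cytoskeletal remodeling are out of scope; vessel walls are rigid.
- Flow-rate ports require axis-aligned openings.
- The lingering thresholds are an operational definition; γ values
  depend on them (they are configurable and sensitivity lives in the
  tests, which vary T_th).
- At 8 points per cell, lubrication films thinner than ~1.5 grid cells
  are under-resolved; cells squeezed into vessels narrower than
  themselves need 10+ points per cell to keep area leakage small.
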