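# Methods

`tortuflow` studies how coronary tortuosity affects the pressure a vessel
loses between its inlet and outlet. It builds idealized 2D tortuous
vessels parameterized by the tortuosity angle (CTA, the interior angle at
each bend apex) and the tortuosity count (CTN, the number of repeated
serpentine units), solves steady and pulsatile incompressible laminar flow
through them with a finite-volume SIMPLE solver, and tabulates the
inlet-to-outlet pressure drop over the CTA x CTN design grid.

## Vessel geometry

A vessel is a planar channel of constant lumen diameter d = 3 mm whose
centerline runs a total axial length L = 130 mm: straight entry, a
centered train of n tortuous units, straight exit. One unit is a
tangent-continuous bump of four circular arcs with centerline radii
R = 6.318 mm, r = 6 mm, r, R, each subtending (180 - CTA) degrees, so the
interior angle at every bend apex is exactly the CTA; successive units
alternate orientation (up, down, ...), which keeps the inlet and outlet
collinear and makes the train a serpentine. A straight run is inserted at
each bump crest whenever the four arcs alone would span less than the unit
width w = 20 mm axially. Two properties motivated this crest rule over a
pure four-arc unit:

* at CTA = 30 deg the four bare arcs span only 2(R + r) sin 30 = 12.3 mm
  axially, less than the 2R + d clearance the two base arcs need, so the
  offset lumen self-intersects; with the crest straight the unit spans
  exactly w = 20 mm and the lumen is simple;
* w is then reproduced exactly at the reference model (30 deg, 1 unit) and
  treated as descriptive elsewhere (w, R, r and CTA cannot all be held
  fixed simultaneously).

The centerline length follows in closed form,
S = L + 2 n (R + r) (phi - sin phi) with phi = pi (180 - CTA)/180, giving
the expected trends: S grows with CTN and shrinks with CTA. Walls are
exact normal offsets of the centerline by +/- d/2 (arc offsets stay arcs,
radius -/+ d/2); every design point is verified non-self-intersecting.

The exact arc arrangement of the source's drawings is not recoverable from
its text, and this choice is the main caveat when comparing sharp-angle
results with the published table (see Limitations).

## Mesh

A structured body-fitted quad mesh is swept along the centerline:
`round(d/interval)` cells across and `ceil(S/interval)` cells along, at the
nominal 1 mm interval that is 3 cells across the lumen — the same coarse
resolution as the published unstructured paved meshes (total counts differ;
the straight vessel gives 390 cells against the published 429 paved cells).
Because the walls are normal offsets of a G1 curve, the (s, n) grid is
orthogonal everywhere, including inside bends. Uniform spacing, no wall
refinement.

## Flow solver

Incompressible Newtonian laminar Navier-Stokes (mu = 0.0035 Pa s,
rho = 1050 kg/m^3; Newtonian rheology is retained by design even though
d = 3 mm is below the usual large-artery threshold for that assumption).
Discretization: cell-centered collocated finite volumes; first-order
upwind convection; two-point central diffusion (the swept grid is
orthogonal, so no non-orthogonal correction is applied); linear pressure
interpolation; Rhie-Chow momentum-weighted face fluxes against pressure
checkerboarding; SIMPLE coupling with implicit under-relaxation 0.7
(momentum) and 0.3 (pressure). Boundary conditions: uniform (plug) or
parabolic inlet velocity, fixed outlet gauge pressure, no-slip rigid
walls. Convergence is declared when every equation's residual, scaled by
the largest residual over its first five iterations, falls below 1e-3
(raw residuals below 1e-12 count as converged — the rest state). Steady
runs start from zero velocity and uniform outlet pressure, making every
run deterministic; two runs of one config agree bitwise.

Linear algebra: momentum and pressure-correction systems are solved with
sparse LU below 8000 cells and Jacobi-preconditioned BiCGSTAB above; the
pressure-correction matrix is refactorized every 25 SIMPLE iterations with
its coefficients lagged in between — flux corrections use the same lagged
coefficients, so discrete continuity holds exactly regardless (measured
global mass imbalance ~1e-16).

Pulsatile mode uses first-order implicit (backward Euler) stepping at
dt = 0.01 s, which hits the cardiac landmark times (0.26, 0.36, 0.8 s)
exactly; each step runs SIMPLE sub-iterations to the same 1e-3 scaled
tolerance. Runs start from the steady solution at the t = 0 waveform
values, simulate three cycles, and the analysis reads the second cycle
(cycle 2 vs cycle 3 velocity fields differ by ~1e-7 relative L2, so
periodicity is established).

## Cardiac waveform

Only three anchor points of the inlet-velocity / outlet-pressure cycle are
known: t1 = 0.26 s (peak diastole, 0.51 m/s, 17850 Pa), t2 = 0.36 s
(pressure maximum, 0.42 m/s, 20206 Pa), t3 = 0.8 s (late systole,
0.318 m/s, 10869 Pa). The period is taken as T = 1.0 s (resting heart
rate; the largest anchor time is 0.8 s). The default reconstruction is a
*periodic shape-preserving cubic* (PCHIP) through the anchors: it passes
each anchor exactly, cannot overshoot, and places the velocity maximum at
t1 and the pressure maximum at t2 — matching how those landmarks are
defined. A plain periodic cubic spline (`kind="cubic"`) is also available
but moves the extrema off the landmarks and puts a steep accelerating
flank at t3, which inverts the expected t2/t3 pressure-drop ordering; it
is kept for sensitivity checks. Between-anchor shape remains uncertain
either way, so pulsatile magnitudes carry waveform-shape uncertainty and
only orderings and magnitudes are treated as meaningful.

## Verification oracles

Two independent oracles verify the solver on the straight channel:

* plane-Poiseuille closed form, dp = 12 mu U L / h^2 = 94.64 Pa at the
  study conditions; the solver matches it within 2% on a 0.1 mm mesh with
  a parabolic inlet, and approaches it monotonically under refinement at
  observed order >= 1;
* the fully developed *discrete* momentum system at n cells across (solved
  directly as a small linear system, with half-cell wall fluxes). At
  n = 3 it gives 9/11 of the continuum gradient (77.43 Pa over 130 mm);
  the solver's mid-vessel gradient on the 1 mm mesh matches it within 5%.

The second oracle quantifies what the 3-cells-across working resolution
can and cannot resolve: the coarse mesh underestimates the viscous
gradient by ~18%, which is intrinsic to the published mesh interval, not a
solver defect.

## What the synthetic conditions do and do not show

All inputs are the published ones: geometry parameters, fluid properties,
0.156 m/s steady inlet with zero outlet gauge, and the three-anchor
cardiac cycle. The models are rigid-walled, 2D planar and Newtonian; no
fluid-structure interaction, no patient-specific shape, no out-of-plane
secondary flow (2D bends produce no Dean vortices). Passing tests
therefore demonstrate the tortuosity-severity trends under these idealized
conditions, not patient-level pressure predictions.

## Problem sizes and defaults

Design sweep: 4 angles x 6 counts = 24 steady runs of 390-1173 cells,
~2 s total. Pulsatile sweep: 20 design points x 3 cycles x 100 steps,
~10 s per point. Fine-mesh verification: 39000 cells, ~7 s. Defaults
throughout reproduce the reference model: CTA 30 deg, CTN 1, 1 mm
interval, tolerance 1e-3.

## Known limitations

* The sharp-angle (30 and 60 deg) steady drops exceed the published table
  by up to ~25% while the straight, 90 and 120 deg models agree within a
  few percent. Grid refinement *raises* our sharp-angle drops (the coarse
  mesh under-resolves bend losses), so the discrepancy is not a resolution
  artifact of this implementation; it is consistent with the published
  sharp-angle geometries having shorter tortuous paths than the
  (180 - CTA)-subtending four-arc unit reconstructed here. All published
  monotone trends (drop increasing with CTN, decreasing with CTA,
  near-linear in centerline length, R^2 = 0.97) are reproduced.
* First-order upwind is diffusive; it was chosen to match the published
  scheme, not for accuracy.
* The waveform between anchors is a reconstruction; pulsatile tables are
  compared as orderings/magnitudes only.
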