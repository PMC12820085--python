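# Methods

This package models how a polarly flagellated bacterium negotiates a
micrometre-scale passage by wrapping its flagellar filament around the cell
body, and implements the statistics pipeline used to quantify quasi-1D
motility. Four computational components share one set of geometric
presets: a Stokes mobility solver for the confined swimmer, a discrete
elastic rod simulator for the wrapping transformation, an equipartition
estimator for hook bending stiffness, and a trajectory-statistics pipeline
with matching synthetic-data generators.

## Geometry and presets

The cell body is a capsule (cylinder with hemispherical caps) of
pole-to-pole length H = 2.5 um and radius a = 0.40 um. The flagellar
filament is a helix in one of two polymorphic forms: the *normal* form
(pitch 2 um, radius 0.3 um, 3 turns; the trailing run configuration) and
the *coiled* form (pitch 1 um, radius 0.5 um, 2.5 turns; the form adopted
on wrapping). Both have contour length ~8.25 um. The filament is meshed
as a slender tube of radius 0.02 um; a taper over the first 10% of contour
length avoids a singular attachment.

In the wrapped configuration the filament winds around the body like a
screw thread at radius a + delta with delta = 0.05 um clearance and the
coiled pitch, starting on the axis just above the attachment pole,
spiralling over the offset spherical cap, and continuing at the same
radius beyond the far pole with whatever contour length remains. Because
the wound curve *descends* the body axis, a left-handed filament winds
with the opposite azimuthal sense to an ascending left-handed helix; the
centerline builder accounts for this.

The body radius follows from the paper-level constraint that a tube of
1 um diameter leaves a normalized gap DeltaR/(H/2) of about 0.025, where
DeltaR is measured from the *widest* swimmer surface. In wrapped mode the
widest surface is the wound filament (a + delta + filament radius =
0.47 um), giving DeltaR = 0.03 um and a normalized gap of 0.024. A body
radius of 0.47 um, sometimes convenient for unwrapped-only geometry, would
make the wound filament overlap a 0.5 um tube and is not used.

Confining channels are circular tubes, meshed as open-ended sections
truncated at 10 H (end effects checked by doubling the truncation length),
with axial grading: fine elements near the swimmer, geometric coarsening
toward the ends.

Meshes are triangle surfaces of revolution (capsule, tube wall) or swept
tubes with parallel-transported frames (filament). Panel areas are
rescaled so each labeled component integrates to its analytic area; the
mesh thereby acts as an exact-area quadrature rule for the boundary
integral solver, and the flat-triangle area stays within 1% of the
analytic value at the default resolutions.

## Mobility solver (regularized Stokeslets)

The zero-Reynolds-number mobility problem is discretized with one
regularized Stokeslet per surface element, collocated at element
centroids. The blob width is eps_i = 0.42 sqrt(A_i); the constant 0.42
was calibrated once against the closed-form Stokes drag (6 pi mu a U) and
torque (8 pi mu a^3 Omega) of a translating/rotating sphere, where it
yields better than 0.5% accuracy at both of the two coarsest ladder
resolutions, and is not adjusted per geometry. Pair interactions use the
symmetrized width eps_ij^2 = (eps_i^2 + eps_j^2)/2, which keeps
one-component resistance matrices symmetric.

The swimming solve treats the swimmer as rigid: the filament rotates as a
rigid helix about the body axis at the signed motor rate relative to the
body (the time-averaged description of steady swimming; no beat-cycle
resolution). Unknowns are the surface point forces plus the rigid body
velocities (U, Omega); the linear system couples the no-slip conditions on
body, filament, and wall (zero velocity) with the constraints of zero net
force and torque on the swimmer. Force/torque residuals of the solutions
are at machine precision relative to the traction scale. Inside a tube
the swimmer is held coaxial; lateral equilibrium positions are not
explored.

Defaults: motor rate 100 Hz CW, viscosity 1 mPa s. In the Stokes limit U
is linear in the motor rate and independent of viscosity, so absolute
speeds scale trivially with the (experimentally uncertain) motor
frequency; normalized curves U/U0 do not depend on it at all. The
confinement sweep sets, per mode, the tube radius from the requested
normalized gap and that mode's widest radial extent, and normalizes speeds
by the free-space unwrapped speed U0.

Resolution ladder (elements per um^2 for body/filament/wall): sweep
(45/110/34), coarse (60/150/45), medium (120/300/90), fine (240/600/180).
Many-solve gap sweeps use the sweep rung (~800-2300 elements per solve),
single solves the coarse or medium rung (~4000 elements at medium); the
wrapped tube speed changes by ~10% per rung, so sweep/coarse numbers are
read as indicative, medium-rung numbers as the reported values. The
narrowest gap (0.03 um clearance) is below the element size, so wall
lubrication there is under-resolved; monotone speed collapse survives
this, but absolute speeds in the tightest tubes carry discretization error
of order 10-20%.

## Elastic rod model of wrapping

The filament is a discrete elastic (Kirchhoff) rod: N = 36 segments, node
positions plus one material-frame angle per edge, with stretching
(penalty, stiffness 1000 in units of A/L^2 keeping strain below ~1%),
bending (discrete curvature binormal, material curvatures against
time-parallel reference frames), and twisting energy. Nodal forces are
exact analytic gradients of the discrete energy, including the reference
twist holonomy (verified against finite differences to 1e-9 relative).

Everything is nondimensional: lengths by the filament contour length L =
8.28 um, time by xi_perp L^4 / A, energies by A/L. Physical inputs are
the stiffness ratios A_hook/A and C/A, the scaled body/helix geometry, the
scaled motor rate, and the contact parameters.

The rest (intrinsic) shape is the coiled polymorphic form - the form the
filament takes while wrapping - attached through a straight hook edge
emerging axially from the pole; the helix is rotated so its starting
tangent continues the hook, making the built state exactly stress-free.
The hook is the proximal joint, with bending stiffness A_hook * l_joint /
L_hook so that one discrete joint reproduces the compliance of a 60 nm
flexible element; its twist stiffness is the filament's C.

Overdamped dynamics: anisotropic resistive-force drag (xi_perp/xi_par =
2) for positions; twist is quasi-static (the physical limit - rotational
drag of a 20 nm filament is negligible), solved per step by one Newton
iteration on the tridiagonal twist Hessian augmented with the
Gauss-Newton bending terms and a 0.3 rad trust region. The motor imposes
the clamp angle theta_0(t) = theta_0 + omega t (CW negative); on arrest
the clamp angle is frozen at its current value. Explicit Euler with dt
at 40% of the stability bound estimated from the discrete bending,
stretch, and contact-stiffness rates.

Filament-body contact is a short-range attractive well between nodes and
the capsule surface: a 2-4 Lennard-Jones-like profile (minimum -epsilon
at clearance h0 = 0.05 um, truncated at 2.5 h0, force-capped below
0.75 h0). The 2-4 exponents keep the contact stiffness comparable to the
bending stiffness at the segment scale; a 6-12 profile would force a ~100x
smaller time step for no change in the physics of interest. Filament
self-contact is not modeled.

With the body held fixed (the morphology, not net swimming, is the
observable), a wound rotating filament generates axial thrust that slowly
screws it back off the pole, so sustained drive produces wrap/detach
cycles rather than a steady rotating wrap; the wrapped state *without*
drive is a genuine local minimum (a pre-wound filament stays wrapped
indefinitely). The simulation protocol therefore drives the motor (scaled
rate -500, well depth 0.35 A/L - calibrated so that the flexible-hook
parameter set wraps reliably) until the wrapped morphology is expressed
(winding >= 1 turn with half-body contact sustained over two consecutive
checks 0.02 time units apart) or a cap of 0.5 time units, then arrests
the motor (clamp angle frozen), relaxes for 0.06, and classifies the
arrested steady shape.

Under this protocol the flexible-hook point (A_hook/A = 0.02, C/A = 0.75)
wraps on every replicate and relaxes to one and the same wrapped attractor
(winding 1.87 turns, contact over 2/3 of the body).  Stiffening the hook
to 0.14 suppresses reliable wrapping - the central experimental claim -
but the finer morphology distinctions are only partly reproduced: the
transformation attempts are chaotic whirl cycles, occasional chance
captures can wrap even the stiff hook, and non-wrapped runs usually relax
back to the free coil rather than to a persistent incomplete wrap or a
proximal ring.  Likely missing ingredients relative to the source model:
filament self-contact, tangential surface friction, and finite rotational
drag (with quasi-static twist the free end spins freely, so twist cannot
accumulate to fold the coil into a ring).

Classification thresholds (recorded in every outcome): wrapped =
|winding| >= 1 turn about the body axis with filament-body contact over
at least half the body length; ring = at least 60% of the filament within
0.5 um of the attachment pole without such coverage; incomplete = partial
winding (>= 0.5 turn) hugging the body near a pole without half-length
coverage; otherwise other.

## Hook stiffness from thermal fluctuations

For an immobilized, de-energized cell the filament wobbles about its mean
orientation through the hook's bending compliance; equipartition gives EI
= k_B T L_hook / sigma^2 with sigma the *standard deviation* (rad) of the
orientation angle - the formula divides by sigma squared, so sigma must
be the SD even where source wording says "variance"; this interpretation
is recorded in the output metadata. Defaults: L_hook = 60 nm, T = 298 K,
and per-hook stiffness A_hook = EI/3 for a three-filament bundle. The
point estimate uses all samples (equipartition is distribution-level);
confidence intervals use a block bootstrap (0.1 s blocks) because
consecutive samples are correlated. The generator counterpart is an
Ornstein-Uhlenbeck process with the matching stationary variance and a
20 ms relaxation time; round-trip recovery is within 5% at 1e5 samples.

## Trajectory statistics

Tracks are uniform-dt tables (default 0.1 s frames); 2-D chamber tracks
are projected onto their principal axis before 1-D analysis. Run
segmentation uses hysteresis: a direction change is accepted only when the
cumulative counter-displacement exceeds a threshold (default 0.2 um),
with the reversal placed at the preceding extremum; first/last runs are
censored and excluded from duration fits.

Hysteresis has a detection floor: counter-runs shorter than about
threshold/speed merge into their neighbours and inflate observed
durations. The exponential time constants are therefore fit with an
alternating-renewal merge correction (see
`fit_alternating_time_constants`): observed mean durations are inverted
through a model in which a reversal is detected only when the new run
outlasts the floor. The floor is threshold/speed plus a quarter frame;
the quarter frame absorbs frame quantization and the second-order
displacement deficit left at the running extremum by missed runs, and was
validated on generated tracks at parameter sets other than the one used
to choose it. Recovery is within ~10% for time constants of 0.45-0.9 s
at the default frame rate; the threshold-sensitivity table produced by
the analysis scripts shows how the uncorrected means would drift.

MSD analysis: time-averaged per track, cohort-averaged, fit over lags up
to 25% of track length by weighted least squares to MSD = v^2 tau^2 + 2 d
D tau. Net displacement per minute averages |x(t+60 s) - x(t)| over all
windows, treating both directions as positive. The competitive index is
the ratio of output/input ratios of the two strains.

## Synthetic data

Generators are deterministic given a seed, return ground truth alongside
data, and write the same CSV dialects the pipeline reads. Run-and-reverse
tracks: piecewise-constant velocity, per-direction exponential durations,
optional duration-dependent forward bias (logistic in run duration,
defaults rising 0.5 -> 0.9 around 1 s), Gaussian localization noise of
0.05 um SD. Species archetypes reproduce the observed net-displacement
bands (wrapper 40-130 um/min at ~3-10% of free-swimming speed;
non-wrapper 0-6 um/min) by rejection through the pipeline's own
net-displacement measure. Bead tracks are pure Brownian motion; the
confined cohort uses a 60x smaller diffusion coefficient. What the
generators do not emulate: camera photophysics, anisotropic localization
error, track linking errors, cell-cell interactions, or any 3-D
confinement geometry - so passing recovery tests validates the estimators
under the stated statistical model, not tracking robustness on real
imagery.

## Problem sizes in routine testing

The test suite and the reproduction script use reduced but documented
sizes: the gap ladder runs at the sweep mesh rung over six gaps; the
single confined wrapped-mode solve uses the medium rung; wrapping
simulations run three replicate seeds at the flexible-hook point and one
seed at the stiffer points; estimator-recovery checks use 1e5 angle
samples, ~1000 segmented runs, and 120-240 bead tracks.

## Known limitations

- The absolute confined swimming speed scales linearly with the motor
  frequency, for which only a conventional default (100 Hz) is set; the
  normalized confinement curves are the robust output.
- Lubrication in the tightest gaps (0.03 um) is below mesh resolution.
- The rod model omits filament self-contact and motor torque dependence;
  the body is rigid and fixed.
- Wrapping outcomes are classified at motor arrest; sustained-drive
  steady rotation of the wrapped filament is not a stable state of the
  fixed-body model.
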