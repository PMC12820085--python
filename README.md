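# flagwrap

Tools for studying how polarly flagellated bacteria move through
micrometre-scale passages by **flagellar wrapping** — winding the flagellar
filament around the cell body like a screw thread — together with the
statistics pipeline for quasi-one-dimensional (Q-1D) single-cell tracks.

The package has four scientific components over one set of geometric
presets (capsule body, H = 2.5 um, a = 0.40 um; normal-form helix 2 um
pitch / 0.3 um radius; coiled form 1 um / 0.5 um):

- **`flagwrap.hydrodynamics`** — a regularized-Stokeslet mobility solver
  for the swimmer in free space and inside circular tubes.  It solves for
  the rigid-body velocities (U, Omega) under zero net force and torque
  while the filament rotates at the motor rate omega_m relative to the
  body, and produces the confinement curves U(DeltaR)/U_0 for the
  unwrapped and wrapped modes (DeltaR = radial clearance between the
  widest swimmer surface and the wall, normalized by H/2).
- **`flagwrap.elastic_rod`** — a discrete Kirchhoff rod simulation of the
  motor-driven filament (stretch + bend + twist, exact discrete energy
  gradients, resistive-force drag, short-range filament-body attraction)
  that classifies the terminal morphology — wrapped / incomplete / ring —
  as a function of the hook/filament bending ratio A_hook/A and the
  twist/bend ratio C/A.
- **`flagwrap.hook_stiffness`** — the equipartition estimate of hook
  bending stiffness from thermal orientation-angle fluctuations,
  EI = k_B T L_hook / sigma^2 (L_hook = 60 nm), with per-hook stiffness
  A_hook = EI / n_filaments.
- **`flagwrap.trajectory`** + **`flagwrap.synthetic`** — run segmentation
  with hysteresis, merge-corrected exponential run-duration fits,
  duration-binned forward bias, windowed net displacement, MSD
  decomposition MSD(tau) = v^2 tau^2 + 2 d D tau, diffusion-confinement
  ratios, the competitive index, and seeded generators for every input
  the pipeline consumes.

## Worked example

Estimate hook stiffness from the measured orientation-angle spreads of a
wrapping and a non-wrapping species, and validate the estimator on a
generated trace:

```python
>>> from flagwrap.hook_stiffness import hook_stiffness_from_sigma, compare_species
>>> soft = hook_stiffness_from_sigma(0.038, label="wrapper")
>>> stiff = hook_stiffness_from_sigma(0.018, label="nonwrapper")
>>> print(f"EI = {soft.EI:.3e} N m^2, A_hook = {soft.A_hook:.3e} N m^2")
EI = 1.710e-25 N m^2, A_hook = 5.699e-26 N m^2
>>> compare_species([soft, stiff]).loc[0, "EI_ratio"]
4.45679012345679
```

The wrapper's hook is ~4.5x softer.  Solve the confined swimming problem
for the wrapped swimmer in a 1-um tube at the default 100 Hz CW drive:

```sh
flagwrap swim --mode wrapped --tube-diameter 1.0 --resolution coarse --out sol.json
```

prints ``U = 516.5 um/min -> sol.json`` and records the normalized gap
0.024 (~0.025 for H = 2.5 um).  Across the gap ladder the wrapped mode
keeps ~0.6 of the free-space unwrapped speed U_0 at every confinement,
while the unwrapped mode collapses monotonically to ~0.3 U_0 in the
tightest tube (`flagwrap sweep-gap`), so the wrapped swimmer is the
faster one exactly where the passage is narrowest.  Because Stokes flow
is linear, absolute speeds scale 1:1 with the motor frequency.

The `analysis/` scripts run the full study end to end (confinement sweep,
wrapping phase scan, hook stiffness, trajectory statistics), printing what
they find and writing tables under `results/`.

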