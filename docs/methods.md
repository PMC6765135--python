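# Methods

## The measurement

A fluorescent repressor operator system (FROS) strain carries a chromosomal
array of operator repeats (32–288 copies) bound by a GFP-tagged dimeric
repressor; each repeat binds one dimer, i.e. two labeled molecules at full
occupancy.  In a fluorescence z-stack the bound pool appears as a single
diffraction-limited dot and the free pool as diffuse background.  The
apparent K_d is the free concentration at half occupancy of the array, and
it is read off a binding curve assembled from single cells that differ
naturally in expression level.

The per-cell measurement follows the dot/background bookkeeping

    dot_total / background_total = N_bound / N_free
                                 = N_bound / (C x area x DOF)

where `area` is the area of a ring enclosing the dot and DOF is the depth
of field: the effective axial extent over which diffuse fluorophores
contribute to one in-focus slice.  A strain imaged far above K_d fixes the
intensity-per-molecule scale (`mean dot_total / (2 x repeats)`), after
which dot intensities convert to bound molecules, ring intensities to free
molecules in the ring's collection volume `area x DOF`, and the number
density to nM via 0.6022 molecules/um^3 per nM.  The "free" concentration
measured this way deliberately includes transiently, non-specifically
DNA-bound molecules — they exchange fast and contribute to the diffuse
background — so the fitted constant is an apparent K_d against that pool.

## Forward model (`froskd.simulate`)

Each synthetic cell is an elliptical mask (semi-axes 1.3–1.9 um, yeast
scale) in its own 40x40 px tile, 9 z-slices of 0.4 um at 0.1 um/px.  Its
stack is the sum of three terms:

1. **Dot.** A separable 3D Gaussian (sigma_xy 0.12 um, sigma_z 0.35 um),
   pixel-integrated and renormalized so the voxel sum is exactly
   `photons_per_molecule x n_bound`, with
   `n_bound = round(2 x repeats x theta(C))`.  The PSF widths are typical
   for a 1.4-NA widefield setup; any localized kernel with the right photon
   total would do, and the Gaussian is chosen because its integrals are
   analytic in tests.
2. **Free background.** Widefield optics collect light from out-of-focus
   planes, so each slice sees the diffuse pool over an effective
   DOF = 1.6 um slab: per-pixel rate
   `photons_per_molecule x 0.6022 C x pixel^2 x DOF`.  This is the same
   relation the quantifier inverts, which makes concentration recovery an
   internal-consistency property rather than a fit.
3. **Autofluorescence.** A flat per-pixel rate inside every mask, also
   rendered alone into a matched unlabeled control stack, mirroring the
   side-by-side imaging of unlabeled cells.

Poisson noise is applied per voxel (camera units are treated as photon
counts; `photons_per_molecule = 100` keeps per-cell shot noise on the dot
at the percent level, and its absolute value cancels from every reported
ratio).  A configurable fraction of cells (default 10%) carries a
replicated, co-localized array pair rendered as two full-brightness dots
2 px apart — the ~2x "extra-bright dots" the discard filter targets.

Defaults are the study conditions: 268 cells, 256x array, generating truth
K_d = 592 nM with n = 2.93, free concentrations log-uniform over
10–1500 nM (covering both flanks of the half-maximum), 9 z-slices,
DOF 1.6 um.

What the simulator does **not** emulate: segmentation errors (masks are
ground truth), vacuole/organelle intensity heterogeneity, photobleaching,
cell-cycle stage, camera read noise and gain, or focal drift.  Passing
recovery tests therefore validate the estimator chain under the stated
optical model, not robustness to every nuisance of real microscopy — the
local-ring background measurement is the pipeline's main defense against
intracellular heterogeneity, and only its geometry, not its motivation, is
exercised here.

## Quantification (`froskd.quantify`)

* **Localization.** A max-intensity composite over z inside the mask; the
  dot is the brightest local maximum whose prominence over the in-mask
  median exceeds 5 robust (MAD-based) noise sigmas.  Below that (the
  dim-dot regime at low concentration) the cell still contributes: the
  measurement falls back to the brightest pixel with ring clearance, and
  the resulting near-zero dot intensity anchors the bottom of the binding
  curve.  Multiple comparably prominent maxima are counted and reported.
* **Dot integration.** At each z, the sum over a disc of radius 3.7 px
  minus the annulus-mean background times the disc area, after subtracting
  the autofluorescence floor; `dot_total` is the per-z profile summed over
  all slices ("the volume under the peak") and the best-focus slice is the
  profile's argmax.  The 3.7 px aperture captures ~98.6% of a
  sigma = 1.2 px Gaussian dot; the small loss cancels in occupancy (the
  calibration shares it) and biases concentrations by ~+1.5%.
* **Ring background.** The annulus between 4 and 8 px at the best-focus
  slice (no standard geometry exists for this measurement; these defaults
  fit inside the simulated cells with margin and are configurable).  If the ring
  leaves the mask its outer radius shrinks in 0.5 px steps; if fewer than
  8 pixels remain the cell is unusable.  A raw-intensity outlier in the
  ring (e.g. a second, separated dot) marks the measurement contaminated.
* **Bright-dot discard.** Records with `dot_total > 1.8 x median` of their
  comparison population are flagged, in a single pass; the median is used
  as the "average level" because it barely moves when the bright minority
  is removed, making the filter idempotent.  On a mixed-concentration
  binding curve the comparison population is the cell's own 100-nM bin,
  and the cut is applied only in bins whose median occupancy is >= 0.5:
  there a doubled dot provably exceeds the single-array ceiling, whereas
  lower down it is indistinguishable from the bin's own legitimate spread
  (one bin in the steep region of an n ~ 3 curve spans more than 1.8x) or
  from shot noise around a near-zero median.  Estimated occupancies above
  1.05 (impossible for a single array, tolerant of noise overshoot) are
  additionally excluded from the curve.
* **Negative corrected intensities** are clipped to zero and flagged.
  Coordinates are 0-based `(z, y, x)` at pixel centers.

Known limitation: replicated cells *below* half saturation survive every
filter (as they would in a real dataset) and drag small-sample bin medians
upward; at the default 268 cells the median-based bins absorb this
(sub-percent K_d bias), but noise-free runs with ~100 cells show it at the
several-percent level.

## Binding fit (`froskd.binding`)

Cells are binned into half-open 100-nM windows of estimated free
concentration; each bin contributes its median normalized intensity
(5th–95th percentiles reported) at its median concentration, weighted by
its cell count.  `I(C) = I_max C^n/(K_d^n + C^n)` is fit by bounded
trust-region least squares (`scipy.optimize.curve_fit`), initialized at
`I_max = max(y)`, `K_d` at the half-maximum crossing, `n = 2`, with bounds
K_d in (1e-3, 1e5) nM and n in (0.2, 10) and tolerances of 1e-12 on cost,
step and gradient.  Medians rather than means are fit because the discard
filter leaves a right-skewed residue.  Standard errors are the square
roots of the covariance diagonal with residual scaling; the reported
uncertainty is therefore a fit SE, not a bootstrap.  When the data never
reach half of the fitted I_max the fit warns that K_d is only a lower
bound (the regime of a near-saturated system).  Non-convergence raises
with diagnostics rather than returning silently.

## Kinetic models (`froskd.kinetics`)

Degradation of the bound complex extends the single-site reaction to
`d(theta)/dt = kon C (1-theta) - (koff + kdeg) theta`, whose steady state
is half-occupied at `(koff + kdeg)/kon` — a fold increase of
`1 + kdeg/koff` over the equilibrium K_d.  With the CLN2-degron rate
(half-life 12 min, kdeg = ln2/720 s = 9.6e-4 s^-1) and koff in the
diffusion-limited range 1e-4–1e-3 s^-1, the fold is 1.96–10.6, i.e. up to
about ten-fold.  The scheme treats the measured free concentration as the
externally fixed steady-state value and lets degradation act on the bound
complex; whether turnover also depletes the free pool (balanced by
synthesis) is a modeling choice that does not change the half-occupancy
result under a fixed free concentration, which is the quantity the imaging
measurement actually controls for.  Tests verify the closed form against
an independent ODE-integration + bisection oracle to 1e-6 relative error.

Non-specific competition uses `K_d,app = K_d,s (1 + [gDNA]/K_d,n)` with the
ratio `K_d,s/K_d,n` (2.5e-7 for LacI) and each competitive base pair
counted as one site.  `[gDNA]` defaults to 12.1 Mbp x 50% in a 3.0 um^3
nucleus ≈ 3.3 mM; the genome size and nuclear volume are stated
assumptions exposed as parameters (only their resulting molarity is
constrained), giving a competition floor of ratio x [gDNA] ≈ 0.8 nM below
which no apparent K_d can fall.  The inverse transform errors out below
that floor instead of returning a negative specific constant.

## Numerical and design choices

- Concentration/density conversion: 1 nM = 0.6022 molecules/um^3, defined
  once in `froskd.constants`.
- z-spacing 0.4 um (9 slices span 3.2 um, comfortably covering a yeast
  nucleus); dot z-positions sampled away from the stack ends so the axial
  profile peaks inside the stack.
- Saturation calibration simulates expression at 10–30x K_d, where Hill
  occupancy with n ~ 3 rounds to exactly 2 molecules per repeat; the
  calibration warns if dot and background intensities correlate (Pearson
  |R| > 0.5 with a meaningful dot-intensity spread), the signature of an
  unsaturated population.
- Problem sizes used by the acceptance script — twenty 268-cell
  populations for the K_d/n recovery and 24 cells per array size for the
  linearity check — give standard errors a few times smaller than the
  effects being checked while keeping the whole run under a minute.
- Determinism: a single `numpy` Generator per simulation seeded from the
  config; identical seeds give bit-identical stacks, and all stochastic
  entry points take explicit seeds.

## Known limitations

- The dot integration reproduces the intent of the original "volume under
  the peak" scan; the original Matlab implementation is not public, so
  aperture conventions may differ in detail.
- The per-slice DOF slab is a first-order model of widefield defocus; real
  axial collection efficiency varies smoothly and the effective DOF would
  be calibrated per instrument.
- Fit standard errors assume independent bin medians; with few sparse top
  bins they can understate the uncertainty, which is why multi-seed checks
  compare medians across replicates.
- The apparent K_d measured against the diffusive-plus-nonspecific pool is
  the operationally relevant quantity for recruitment design but is not
  the microscopic specific-site constant; the competition model relates
  the two under stated assumptions.
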