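# froskd

Apparent in-vivo dissociation constants from fluorescent repressor operator
system (FROS) imaging.

A transcription factor's dissociation constant measured in vitro can be
orders of magnitude lower than its *apparent K_d* inside a cell — the free
concentration at which half its binding sites are actually occupied.  FROS
makes this measurable: a chromosomal array of operator repeats (e.g. LacO)
recruits a GFP-tagged repressor (GFP-LacI) into a single diffraction-limited
"chromosome dot", so one fluorescence z-stack yields, per cell, both the
bound amount (dot intensity) and the free concentration (diffuse
background).  Exploiting cell-to-cell expression variability, the dot
intensity vs free concentration cloud traces the binding curve

    theta(C) = C^n / (K_d^n + C^n)

whose midpoint is the apparent K_d and whose steepness is the Hill
coefficient n.

`froskd` is aimed at people building or analyzing such recruitment systems.
It provides:

- **`froskd.simulate`** — a forward model rendering synthetic z-stacks
  (Gaussian-PSF dots with 2 molecules per operator repeat, widefield
  diffuse background, autofluorescence, Poisson noise, matched unlabeled
  controls, a minority of replicated co-localized double dots) with full
  ground truth.
- **`froskd.quantify`** — the measurement: max-intensity composite for dot
  localization, per-z disc integration with local annulus background,
  ring-based free-protein quantification, the 1.8x extra-bright-dot
  discard, and conversion to molecules and nM via a saturated-array
  calibration and the depth-of-field relation
  `N_free = background / (intensity-per-molecule)`, `C = N_free / (area x DOF)`.
- **`froskd.binding`** — 100-nM binning, weighted Hill fits with standard
  errors, and the repeat-number linearity check.
- **`froskd.kinetics`** — closed-form models for how degradation
  (`K_d,app = (k_off + k_deg)/k_on`) and non-specific genomic DNA
  (`K_d,app = K_d,s (1 + [gDNA]/K_d,n)`) raise the apparent K_d.

## Worked example

Measure the apparent K_d of a simulated experiment: 268 cells, a 256x
operator array, free concentrations log-uniform over 10–1500 nM, generating
truth K_d = 592 nM and n = 2.93:

```python
from froskd import SimulationConfig, measure_apparent_kd

res = measure_apparent_kd(SimulationConfig(seed=1))
f = res.fit
print(f"apparent Kd = {f.kd:.0f} +/- {f.se_kd:.0f} nM")
print(f"Hill n      = {f.hill_n:.2f} +/- {f.se_n:.2f}")
print(f"I_max       = {f.i_max:.3f} +/- {f.se_imax:.3f}")
print(f"cells used  = {f.n_cells} in {f.n_bins} bins of {f.bin_width:.0f} nM")
```

prints

```
apparent Kd = 590 +/- 14 nM
Hill n      = 2.84 +/- 0.13
I_max       = 1.002 +/- 0.024
cells used  = 256 in 16 bins of 100 nM
```

The fitted K_d agrees with the generating 592 nM within one standard error,
the Hill coefficient with 2.93, and the saturation level is 1 because dot
intensities are normalized by the saturated-array calibration.  `res.cells`
holds the per-cell table (dot and ring intensities, estimated molecules,
free concentration, discard flags); `res.binned` the binned curve.

The same steps are available from the shell on TIFF stacks:

```sh
froskd simulate --out sim/ --seed 1
froskd quantify --stacks sim/ --saturated-reference 98.6 --out cells.csv
froskd fit --cells cells.csv --bin 100 --out fit.json
```

and the closed-form models as, e.g.

```sh
froskd model degradation --kon 1e-4 --koff 1e-4 --kdeg 9.6e-4
```

```
{
 "equilibrium_kd_nM": 1.0,
 "apparent_kd_nM": 10.6,
 "fold_increase": 10.6,
 ...
}
```

— a protein degraded with k_deg = 9.6e-4 s^-1 (12-minute half-life, the
CLN2-degron rate) and k_off = 1e-4 s^-1 has a ~10.6-fold larger apparent
K_d than its stable counterpart.

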