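# condensekit

Quantitative analysis tools for in-vitro studies of biomolecular
condensates — protein droplets formed by liquid–liquid phase separation
(LLPS). The package covers the measurement pipelines such studies run
around a scaffold protein and its domain deletion series:

- **`xlmap`** — crosslinking mass spectrometry (XL-MS) structure mapping.
  Identified residue pairs are tested against monomer and dimer structure
  models by Cα–Cα distance (compatible when d ≤ 30 Å, the span of the
  DSBU crosslinker), classified into five compatibility categories,
  screened for *homodimer* crosslinks (same residue on
  sequence-overlapping peptides — necessarily intermolecular), and
  aggregated into domain-by-domain spectrum-count (XSM) crosstabs with
  between-condition frequency differences.
- **`rheo`** — passive microrheology. Embedded-bead trajectories are
  pooled into an ensemble time-averaged mean-squared displacement,
  fit to MSD(t) = 4Dt^α, and converted to viscosity with the
  Stokes–Einstein–Sutherland relation η = k_B·T/(6πDr). Includes Tukey
  outlier fences and rank-sum group comparisons with
  Benjamini–Hochberg adjustment.
- **`imaging`** — condensate image quantification. Segmentation on a
  reference channel, per-condensate partition coefficients
  PC = median(dense)/median(dilute annulus), size distributions,
  two-phase/one-phase scoring, and double normalization of FRAP
  recovery curves (prebleach mean = 1, first post-bleach ratio = 0).
- **`binding`** — biolayer interferometry. Global 1:1 Langmuir kinetic
  fits across analyte concentrations yielding k_on, k_off and
  K_D = k_off/k_on.
- **`condense`** — phase-behavior utilities: the c_dil regime test
  (two-phase iff the dilute-phase concentration is independent of input
  concentration), saturation-concentration estimates with 95% CIs,
  pellet fractions p/(p+s), the in-vivo protein:RNA stoichiometry
  conversion, and phase-diagram assembly.
- **`synthgen`** — synthetic data with known ground truth for every
  stage: deterministic toy structures, crosslink tables with realistic
  tryptic peptide fields, 2D Brownian bead tracks, two-channel
  condensate images, single-exponential FRAP traces and 1:1
  sensorgrams, plus CSV/TIFF/PDB writers.

## Worked example

Recover the viscosity of a condensate whose beads diffuse at the rate
implied by η = 3.30 Pa·s (T = 292.15 K, bead radius 0.1 µm), then measure
a partition coefficient on a synthetic two-channel field built at a true
dense:dilute ratio of 1.30:

```python
import numpy as np
from condensekit import imaging, rheo, synthgen

# microrheology round trip
D = rheo.diffusion_from_viscosity(3.30)           # 6.485e-4 µm²/s
ts = synthgen.simulate_trajectories(D, dt=0.15, n_frames=100,
                                    n_particles=25, seed=42)
est = rheo.estimate_viscosity(ts)
print(f"D = {est.D*1e12:.3e} um2/s, alpha = {est.alpha:.3f}, "
      f"eta = {est.eta:.2f} Pa.s")

# partition coefficients from image segmentation
field, _ = synthgen.simulate_condensate_field(
    n_condensates=50, pc_true=1.30, noise_sd=4.0, blur_sigma=1.0, seed=42)
masks = imaging.segment_condensates(field.channels["reference"], min_area=20)
pcs = [r.pc for r in imaging.partition_coefficient(field, masks, "probe")
       if r.pc is not None]
print(f"{len(pcs)} condensates, median PC = {np.median(pcs):.3f}")
```

Output:

```
D = 6.461e-04 um2/s, alpha = 1.003, eta = 3.31 Pa.s
50 condensates, median PC = 1.279
```

The fitted diffusion coefficient matches the simulation input to ~0.4%,
the exponent α ≈ 1 confirms free diffusion, and the recovered viscosity
is within 1% of the 3.30 Pa·s ground truth. The imaged partition
coefficient sits within 0.03 of the true ratio 1.30 — the small downward
bias comes from optical blur mixing dense and dilute intensities at
condensate rims.

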