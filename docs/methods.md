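# Methods

This note documents the models behind each analysis module, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Crosslink structure mapping (`xlmap`)

**Model.** A crosslink between residues i and j is *compatible* with a
structure model when the Cα–Cα distance is at or below a cutoff set by
the crosslinker span; for DSBU (reactive toward K/S/T/Y) the default is
30 Å, and a distance of exactly 30.000 Å counts as compatible. Distances
are measured twice: *intra-chain* on a monomer model, and *inter-chain*
on a dimer model as the minimum over the two cross-chain pairings
d(i@A, j@B) and d(i@B, j@A), which makes classification invariant under
chain relabeling. The two booleans map to five classes: compatible only
intra-chain, only inter-chain, with both, with neither, or
`no_structure` when neither model resolves the pair.

**One-sided missing data.** If exactly one of the two distances is
unmeasurable (residue unresolved, or one model absent), classification
falls back on the available distance rather than discarding the record;
such records carry a `one_sided` audit flag in `classify_records`
output. This maximizes the information extracted from partial models; a
stricter both-or-nothing rule can be recovered by filtering the flag.

**Homodimer rule.** Tryptic fragments of a single-protein digest are
unique in sequence, so a crosslink joining peptides that *overlap in
sequence* cannot come from one molecule and marks a homodimer contact.
The implemented classifier is interval overlap of the two peptides; a
link between the same residue on both sides is the canonical case and
always implies overlap. Overlap is deliberately the broader criterion —
residue identity alone would miss contacts between distinct residues on
overlapping peptides.

**Domain crosstabs.** Records aggregate into a square domain-by-domain
table by summing crosslink spectrum matches (`n_xsm`) per unordered
domain pair; the upper triangle (including the diagonal) is canonical
and the matrix is mirrored for display. Frequencies divide by the total
XSM count; condition comparison is the entrywise frequency difference,
whose upper-triangle entries sum to zero by construction. A
`unique_pairs` mode counts each residue pair once instead, and
`merge_domains` re-bins a table into super-domains (e.g. the folded
D1-D2 half versus the disordered IDR-RGG half) while conserving totals.

**Default domain map.** The bundled map for full-length PGL-3
(693 residues) is D1 = 1–212, D2 = 213–447, IDR = 448–622,
RGG = 623–693. The D1/D2 split point resolves the small overlap between
the crystallized constructs of the homologous protein (1–212 and
205–447) by a hard cut at 212/213. These boundaries are a reconstruction
from the domain architecture, not an authoritative annotation, so the
map is fully user-overridable and all crosstab code takes an explicit
`DomainMap`; counts near domain borders shift if different boundaries
are supplied.

## Passive microrheology (`rheo`)

**Model.** Beads of radius r in a condensate at temperature T perform
2D Brownian motion. All trajectories from one condensate are pooled into
a single ensemble time-averaged MSD — the mean squared displacement over
every particle and every start time at each lag — and fit to
MSD(t) = 4Dt^α. For α ≈ 1 the Stokes–Einstein–Sutherland relation
η = k_B·T/(6πDr) converts D to viscosity.

**Fitting.** The default fit is linear regression of log MSD on log t
over lags 1–10 (short lags carry the smallest statistical error in
time-averaged MSD; the window is configurable); a direct nonlinear fit
is available and agrees exactly on power-law data. Non-positive MSD
values are excluded with a warning. For the viscosity conversion, when
|α − 1| < 0.15 the pipeline refits D with α pinned to 1 over the same
window, since the Stokes–Einstein relation presumes free diffusion;
otherwise the estimate keeps the free-fit D and is flagged anomalous.
The 0.15 band is a declared operating choice, not a physical constant.

**Defaults.** T = 292.15 K (≈19 °C ambient), bead radius 0.1 µm (0.2 µm
diameter microspheres), frame interval 0.15 s. All overridable.

**Outliers and comparisons.** Per-condensate viscosities pass through
Tukey fences (outliers outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]; quartiles
by linear interpolation between order statistics — the convention is
fixed so the fences are reproducible). Fewer than four values skips the
filter with a warning. Group comparisons use two-sided Wilcoxon
rank-sum tests with Benjamini–Hochberg adjustment across all pairs.
Manual exclusions applied upstream in bead-tracking experiments
(beads near interfaces, aggregates, fusion events) are assumed already
applied to the input tracks.

## Image quantification (`imaging`)

**Segmentation.** Condensates are segmented on the reference channel by
Otsu's global threshold, connected-component labeling, an area filter
(default min 20 px) and exclusion of border-touching regions. A flat
image yields zero regions. This deterministic scheme replaces
trained pixel classifiers sometimes used for this task: it needs no
training data and is exactly reproducible. Externally computed masks
(including classifier outputs) can be injected through
`masks_from_labels`, which converts any label image into analysis-ready
masks, so segmentation and quantification are decoupled. An optional
contrast heuristic (`focus_contrast_quantile`) drops regions whose
boundary-gradient contrast falls in the low tail, standing in for
out-of-focus rejection; it is off by default.

**Partition coefficient.** PC = median probe intensity in the dense
mask / median in a dilute annulus starting 2 px outside the dense
contour and extending 5 px, minus every dense pixel of any region. The
annulus geometry is a declared default (recorded in the mask `params`),
configurable where the periphery definition should differ. Using the
local periphery rather than the global background makes PC robust to
uneven illumination; medians are used throughout, never means. A zero
dilute median leaves PC undefined (`None`) rather than infinite.

**Sizes and phase scoring.** Condensate sizes are equivalent-circle
diameters 2·√(area/π)·pixel_size. An image scores `two_phase` when
segmentation finds at least `min_condensates` regions (default 1).

**FRAP.** The bleached/reference intensity ratio (which cancels
acquisition photobleaching common to both areas) is affinely rescaled
so the prebleach mean equals 1 and the ratio at the first post-bleach
frame equals 0. "Right after photobleaching" is implemented as the
single first post-bleach frame, not a short average. No kinetic model
is fit: curves are summarized pointwise (mean ± sample SD across
condensates, single curve → SD 0).

## Binding kinetics (`binding`)

**Model.** 1:1 Langmuir kinetics: association
R(t) = R_eq·(1 − e^{−(k_on·C + k_off)t}) with
R_eq = R_max·C/(C + K_D), dissociation R(t) = R₀·e^{−k_off·t},
continuous at the phase boundary; K_D = k_off/k_on by definition.

**Fitting.** One (k_on, k_off, R_max) triple is fit globally across all
concentrations — per-curve 1:1 fits are poorly identifiable, the global
fit is not. Parameters are optimized in log10 space (positive,
spanning orders of magnitude) within bounds of 10⁰–10⁸ M⁻¹s⁻¹ for k_on,
10⁻⁶–10² s⁻¹ for k_off and 10⁻³–10⁴ response units for R_max, with
multi-start initialization (one central start plus seeded random draws
inside the bounds; the seed makes fits reproducible). Baseline handling
is limited to subtracting the pre-association mean
(`subtract_baseline`); inputs are assumed reference-subtracted. No
mass-transport-limited or heterogeneous-ligand models are offered.

## Phase behavior (`condense`)

**Regime test.** In a two-phase regime the dilute-phase concentration
c_dil equals the saturation concentration c_sat independent of input
concentration; in a one-phase regime c_dil tracks the input. The test
regresses c_dil on input concentration and requires, for a two-phase
call, failing to reject slope = 0 *and* rejecting slope = 1, both at
α = 0.05 (configurable). This dual-hypothesis framing is this package's
operationalization of a judgment usually made visually; a single input
level leaves the regime indeterminate. One-phase tables with slope
< 0.9 trigger a warning, since depressed slopes can reflect adsorption
losses to tube walls rather than condensation. c_sat is the pooled mean
of c_dil with a t-based 95% CI (undefined for n < 2).

**Pelleting and stoichiometry.** Pellet fraction = p/(p+s), optionally
normalized to a buffer-control fraction. The RNA stoichiometry
conversion scales a reference point of 0.68 µM protein : 50 ng/µl mRNA
linearly to the working protein concentration, reported to one decimal
(4 µM → 294.1 ng/µl). Phase-diagram assembly grids (protein, salt,
state) points; replicate conflicts need an explicit majority rule, ties
resolve to two-phase and are flagged. Turbidity values are carried as
annotations only — no binodal or Flory–Huggins fitting.

## Synthetic data (`synthgen`)

Every generator is a pure function of (parameters, seed); identical
calls reproduce identical outputs.

- **Toy structures** are deterministic: chain A residues on a straight
  line at a given Cα spacing (default 3.8 Å), chain B a rigid copy
  translated 20 Å along y. Every distance is closed-form, so
  compatibility classes are hand-checkable. A consequence of the
  translated-copy geometry is that the inter-chain distance never
  undercuts the intra-chain one, so `inter_only` records are
  infeasible on toy structures and requesting them raises an error.
- **Crosslink tables** draw residue pairs of a requested compatibility
  class from K/S/T/Y positions of a repeating-block sequence
  ("SAGTAYAK") whose tryptic digest gives uniform 8-residue peptides
  containing all four reactive residue types. Homodimer records use the
  same residue and peptide on both sides. The digest follows fully
  specific trypsin (cleave after K/R unless before P), up to 3 missed
  cleavages, peptide length 6–60; peptide *mass* filtering is omitted
  as irrelevant to the downstream logic.
- **Bead tracks** draw per-axis Gaussian steps with variance 2·D·dt;
  optional Gaussian localization noise on positions adds the known
  4σ² MSD offset (default 0).
- **Condensate fields** place disk condensates on a jittered grid (one
  per cell, clear of borders and of each other with room for the dilute
  annuli), with the probe channel at exactly pc_true × dilute level
  inside disks before blur and noise. Grid placement makes feasibility
  deterministic; a request that cannot fit in the maximum image size
  fails immediately.
- **FRAP traces** recover single-exponentially toward the plateau
  implied by the recovery fraction. This is a test-harness model chosen
  for its closed form — the analysis code never fits it, and no claim
  is made that real recovery curves are single-exponential.
- **Sensorgrams** evaluate the 1:1 model exactly, plus optional
  Gaussian noise.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: bead tracking errors other than Gaussian
localization noise (no blinking, linking errors or drift), confinement
by finite condensate size, hydrodynamic coupling near interfaces;
non-disk condensate shapes, out-of-focus light, uneven illumination,
camera offsets; crosslink false identifications or FDR structure;
reaction-dominant vs diffusion-dominant FRAP physics; mass-transport
limitation or sensor drift in BLI. Recovery tests demonstrate that the
pipelines are unbiased under their stated models at realistic noise,
not that those models exhaust real-data behavior.

## Problem sizes and tolerances

Simulation-based checks use 20 condensates of 25 beads × 100 frames for
viscosity recovery (median within 15% of truth) and 50-condensate
fields with 2% noise and 1 px blur for partition-coefficient recovery
(median within ±0.05) — sizes comparable to the per-condition scale of
the corresponding experiments, kept small enough that the whole suite
runs in seconds. Noiseless BLI round-trips recover rates to ≤0.1%
relative error; FRAP normalization anchors and crosstab conservation
identities are exact. The regime-test operating characteristics are
checked over 200 seeds (≥95% correct classification on flat and
proportional tables with 3% noise, n = 6).

## Known limitations

- Compatibility classification consumes whatever structure models it is
  given; model quality (homology-model error, unresolved loops) is not
  assessed.
- The XSM crosstab totals depend on the domain map; the bundled PGL-3
  boundaries are reconstructed, not authoritative, and counts for
  residues near boundaries move with the map. Published aggregate
  counts can be reproduced only with the corresponding deposited
  identification table, which is not bundled here.
- The viscosity conversion assumes a Newtonian medium; for clearly
  anomalous transport (|α − 1| ≥ 0.15) the reported η is a nominal
  value carrying an explicit flag, not a rheological measurement.
- Segmentation is intensity-threshold based; dim or overlapping
  condensates that defeat Otsu thresholding require externally supplied
  masks via `masks_from_labels`.
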