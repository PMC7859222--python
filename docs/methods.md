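# Methods

This note documents the models, parameter choices and numerical details
behind `mircoloc`, and what the synthetic-data tests do and do not show
about real microscopy data.

## The measurement problem

Fluorescently labelled miRNA introduced into resealed cells accumulates
in punctate structures; a fraction of those puncta sit on CD63-positive
multivesicular endosomes (MVEs). The quantity of interest is the
per-cell fraction of miRNA puncta co-localized with MVEs (and its
converse, the fraction of MVEs carrying miRNA), measured object-wise on
maximum-intensity projections of confocal z-stacks, at the single-cell
level. Pixel-intensity correlation (Pearson *r*) is a complementary,
object-free readout.

## Synthetic-microscopy model

The simulator is the test bed for the whole pipeline; its defaults are
the study conditions under which the package's accuracy claims hold.

* **Geometry.** Cells are random non-overlapping ellipses (semi-major
  axis 7–9 µm, axis ratio 0.7–1, random orientation), each with one
  concentric elliptical nucleus (2.5–3.5 µm). Ellipses keep
  inside/outside tests exact for truth generation. Geometry is 2D and
  constant across z: analysis happens after projection, so per-slice
  cell outlines would only add cost. Cell centres are sampled so cells
  lie fully inside the field; packing failures raise an error naming the
  count achieved. Per-cell random substreams are spawned in cell order,
  so adding cells never perturbs earlier ones.
* **Puncta.** MVE centres are uniform over each cell's cytoplasm with a
  Poisson(12) count per cell; miRNA spots (Poisson(15) per strand per
  cell) are placed at a uniformly chosen MVE (centre offset < ¼ MVE
  diameter) with probability `coloc_fraction`, otherwise uniformly in
  the cytoplasm. A spot placed at an MVE inherits the MVE's z plane —
  physically it sits in/on that organelle, and this matters: if stacked
  spots were given independent z, the maximum projection would silently
  swallow them (max is lossy), and no 2D analysis could recover the true
  fraction. A configurable fraction of guide spots can instead be placed
  in the nucleus, emulating early-time-point nuclear accumulation.
  "Co-localized" in the truth tables means placed at an MVE; the ¼-diameter
  offset bound guarantees pixel-level mask overlap after rendering.
* **Optics and noise.** Spots render as isotropic Gaussians with
  σ = diameter/(2√(2 ln 2)) combined in quadrature with a 100 nm PSF σ;
  nucleus/cytoplasm channels render as filled, PSF-blurred regions.
  Per-pixel Poisson shot noise is followed by additive Gaussian read
  noise (SD 2), clipped at zero. Default amplitudes (300 photons over a
  background of 10) give peak SNR ≈ 17. Pixel size defaults to 80 nm
  (not dictated by the imaging protocol being emulated; exposed in the
  config), field 1024×1024 px, 9 z-slices, 8 cells per field.
  Sub-resolution sizes floor at 1 px after nm→px conversion.

What the simulator does **not** model: realistic PSFs (Airy rings,
z-dependent blur, astigmatism), spectral bleed-through, photobleaching,
z-attenuation, autofluorescence texture, or irregular cell shapes.
Passing recovery tests therefore demonstrates correctness of the
algorithmic chain under controlled optics, not robustness to every
artefact of real data.

## Segmentation

Nuclei: Gaussian smoothing (σ 2 px) → global threshold (Otsu default;
fixed and percentile available) → hole filling → distance-transform
watershed. Watershed markers are h-maxima (depth 4 px) of the *smoothed*
(σ 1 px) distance map, dilated before labelling: raw EDT plateaus of a
noisy ellipse fragment into multiple same-height maxima and would
oversplit single nuclei, while genuinely touching nuclei keep saddles
far deeper than 4 px and still split. Components below `min_area_px`
(default 100) are dropped; a constant image yields zero nuclei with a
warning.

Because a global Otsu threshold on a signal-free (pure noise) image
splits the noise distribution in half, segmentation additionally
requires foreground/background contrast: mean separation greater than 4
background SDs, else the channel is treated as empty. On bimodal images
with real structures the separation is orders of magnitude larger, so
the guard only triggers on empty fields.

Cells: the smoothed cytoplasm channel is thresholded, union-ed with the
nucleus masks, and partitioned by a watershed seeded at the nuclei.
Nuclei without surrounding cytoplasm are dropped; cells touching the
image border are flagged and excluded from all per-cell statistics
(truncated cells bias counts). Coordinates are 0-based (row, col);
areas are in pixels with nm conversion via the pixel size.

## Puncta detection

The LoG response is −σ²·∇²G∗I with σ = d/(2√2·pixel size), which puts
the filter's zero-crossing at the expected blob radius. The discrete
truncated kernel has a small non-zero DC gain (~10⁻⁴ per unit
intensity); it is measured once per σ and subtracted so constant images
map to exactly zero and the operator stays strictly linear. Thresholding
(Otsu over positive response values, `>=` comparison so ties resolve to
the lower threshold) is followed by 8-connected labelling, an area
filter (default min 2 px), and intensity measurements on the original
image. Spots are assigned to cells by the label under their
intensity-weighted centroid, keeping each spot in exactly one cell.

## Object co-localization

An object is co-localized when at least `min_overlap_px` (default 1) of
its pixels survive the AND gate of the two binary masks. Two estimator
corrections matter at realistic densities:

* **Multiplicity.** Puncta closer than the optical resolution merge into
  one connected component — common when several miRNA spots accumulate
  on the same MVE. Integrated intensity is additive, so each object is
  weighted by `max(1, round(flux / unit))`, the unit being the median
  object flux (robust while most objects are single). Without this the
  object-level rate underestimates the true spot fraction by ~0.05–0.08
  at intermediate fractions.
* **Chance overlap.** A punctum dropped at random in the cytoplasm
  already hits the MVE mask with probability *p* ≈ the MVE mask dilated
  by the punctum radius, as an area fraction of the cytoplasm (~0.04 at
  default densities). The headline rate is the excess over chance,
  (raw − p)/(1 − p) clipped to [0, 1] — the object-level analogue of
  randomisation controls in pixel co-localization. The raw rate is
  reported alongside.

With both corrections the pipeline recovers true fractions
{0, 0.25, 0.5, 0.75, 1} with ≤ ~0.03 absolute error over ≥ 50 cells at
default SNR (the acceptance script recomputes this). Cells with zero
objects get a missing rate, never zero, and are excluded from means.

MVE classification samples up to 20 MVEs per cell without replacement
(seeded, in spot-label order, so draws are reproducible) and assigns
each to exactly one of {single, guide-only, passenger-only, both}. How a
both-positive MVE should enter a 3-way single/guide+/passenger+ tally is
genuinely ambiguous, so the 4 exclusive counts are reported together
with the projection guide+ = guide-only + both (and likewise for
passenger), flagged in the table metadata.

Nuclear accumulation is operationalized as mean nuclear / mean
cytoplasmic intensity ≥ 1.5 (visual judgement in the original workflow;
the threshold is a config parameter). Pearson *r* is computed without
Costes thresholding over the union of retained cell masks by default.

## Quantification and statistics

* **Copies per cell**: c·N_A·V with V in litres (µm³ × 10⁻¹⁵); linear in
  both arguments. 1.5 µM in 2.6×10³ µm³ gives 2.35×10⁶ copies, ~23.5×
  the 10⁵ cpc endogenous upper bound.
* **ΔΔCt**: ΔCt = Ct(target) − Ct(reference); ΔΔCt subtracts the mean
  control-group ΔCt within the same (target, compartment) stratum;
  log₂FC = −ΔΔCt. The control-group mean is used as baseline because
  control groups have n > 1. Outliers: single pass, per (target,
  compartment, group), flag |log₂FC − group median| > 2 × (1.4826·MAD).
  The robust centre/scale is deliberate: the naive centred form
  |x − x̄| > 2s can never fire for n ≤ 6 (max |x − x̄|/s = (n−1)/√n < 2),
  while the MAD form tracks it on clean Gaussian groups at n ≈ 10–14 and
  retains power in small panels. The literal centred rule is available
  via `outlier_policy="group"`. Flagged samples are excluded from group
  means/SDs but kept (marked) in the per-sample table.
* **Standard curve**: least squares of Ct on log₁₀(amount); unknowns by
  inversion; efficiency 10^(−1/slope) − 1.
* **Welch's t / Cohen's d**: scipy's unequal-variance t with
  Welch–Satterthwaite df; d pooled by df weights.
* **Dunnett**: scipy's multivariate-t implementation; the quantile
  integration is seeded and the method recorded in the output.
* **Steel–Dwass**: implemented here (no suitable installed
  implementation): for each pair, the Wilcoxon rank-sum statistic on the
  two groups' pooled midranks with tie-corrected variance, standardised
  and referred to the studentized-range distribution with k groups at
  df = ∞, p = P(Q_k ≥ √2·|z|). The range CDF is evaluated by direct
  quadrature of k·∫φ(z)[Φ(z) − Φ(z−q)]^(k−1)dz (the df = ∞ form of
  scipy's studentized range, which is numerically fragile there). Null
  familywise error at k = 3, n = 10 is ~0.04 at α = 0.05 — slightly
  conservative, as expected for a rank test at this n.
* **Regression band**: OLS with the pointwise t-based CI for the mean
  response (statsmodels); the band is narrowest at x̄ and covers the true
  mean at x̄ at the nominal rate.

## Problem sizes

Unit tests run on 512×512 fields with 4 cells; end-to-end recovery uses
seven 1024×1024 fields (56 cells) per co-localization fraction, and the
statistical calibrations use 1000 null replicates — sizes chosen so the
whole suite completes in a few minutes while keeping binomial/Monte-Carlo
error well inside the tested tolerances.

## Known limitations

* Object counting after projection cannot resolve puncta merged beyond
  what intensity quantisation can disambiguate; at very high spot
  densities the multiplicity unit (median flux) itself becomes biased.
* The chance-overlap correction assumes puncta are placed uniformly in
  the cytoplasm; strong spatial clustering of miRNA away from MVEs would
  make it an overcorrection.
* Segmentation assumes one nucleus per cell and roughly convex cells;
  deeply lobed or overlapping cells are out of scope.
* TIFF I/O targets the package's own layout (C×Z×H×W with a JSON
  description); arbitrary microscope vendor formats should be converted
  upstream.
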