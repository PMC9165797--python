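# Methods

## The problem

*Leptospermum scoparium* s.l. (mānuka) and *Kunzea* spp. (kānuka) pollen are
morphologically similar oblate, tricolporate, angulaperturate Myrtaceae
grains. Published light-microscope measurements give equatorial diameters
(E) of 19.08 ± 1.28 μm (*Leptospermum*, n = 490) and 16.30 ± 0.95 μm
(*Kunzea*, n = 318) and polar diameters (P) of 12.98 ± 1.66 and
11.28 ± 2.33 μm; the amb (polar outline) is concave-sided in *Leptospermum*
and straight-to-slightly-convex in *Kunzea*; the exine is scabrate
(flecked) in *Leptospermum* and psilate in *Kunzea*. This package simulates
grains with exactly that statistical structure, measures them the way an
automated dark-field imaging system and a human palynologist would, and
reproduces the discrimination analyses (QC, ordination, repeated
random-split SVM, size rule, mixture estimation).

Everything below is either a published measurement (marked *published*) or a
calibration choice of this package (marked *calibrated*) — light microscopy
does not quantify curvature, texture contrast or outline irregularity, so
those values were chosen once so that the simulated cohorts land in the
qualitative and quantitative bands the published analyses report
(compactness filter removing ~4.8%, MFD exceeding protocol E by 0.5–1 μm,
first two PCs ≥ 85% of core-feature variance, SVM accuracy ~95–97%).

## Grain geometry

**Polar view (the amb).** A k-fold-symmetric rounded polygon (k = aperture
count; 3 for tricolporate grains, rarely 2 or 4) with circumradius 1:

- each side is a circular arc whose sagitta is `curvature × side length`
  (negative = concave, positive = convex);
- each apex is a circular fillet of radius `apex_rounding × circumradius`
  constructed tangent to both adjacent side arcs (the tangency condition is
  solved in closed form; combinations where the fillet cannot be placed —
  e.g. |curvature| ≳ 0.1 at apex_rounding 0.3 — raise an error, and sampled
  curvatures are clipped to the feasible interval found by bisection);
- optional apex enlargement multiplies the radius by a smooth bump centred
  on each apex.

**Equatorial view.** A flattened oval with width E and height P (scaled
exactly after noise is applied). Colpi converge on the poles, so the first
aperture angle records the polar-axis direction.

**Boundary irregularity.** Real grain walls are not perfect arcs. A smooth
random radial field (Fourier harmonics 2–8, amplitude ∝ 1/h, total relative
s.d. = `irregularity`) models wall-level variation; equatorial-view grains
receive additional pose noise (0.05, added in quadrature, identical for all
taxa) because side-lying grains roll into oblique positions. Degraded
(poor-focus) grains get a high-frequency ragged field (harmonics 16–40,
relative s.d. 0.055) that inflates the perimeter and collapses compactness
below the QC threshold.

**Anchoring.** Polar contours are scaled so that the measurement-protocol E
of the final noisy outline equals the sampled `e_true` exactly; equatorial
contours are scaled to width `e_true` and height `p_true`. The published E/P
statistics are human measurements, so the simulator anchors the human
protocol, and instrument-style measures (maximum Feret diameter) then
inherit realistic positive offsets.

## Measurement protocol (E, P)

E is the maximum dimension along a line at right angles to the line from the
grain centre through the midpoint of one aperture. The default
(`aperture_rule="first"`) reads against a single (randomly oriented)
aperture, as a palynologist measuring one visible colpus would; the maximum
over all apertures is available (`"max"`). This choice matters: against the
best of three apertures, the maximum Feret diameter exceeds E only to second
order in any outline perturbation, whereas the single-aperture protocol
makes the offset first-order, which is what produces the observed
"instrument reads 0.5–1 μm larger" behaviour at realistic (~3–6%)
irregularity. P is the extent along the polar axis of an equatorial-view
grain (read from the recorded aperture direction; minimum Feret extent as a
fallback). Graticule rounding quantizes readings to the nearest 0.3125 μm
(half of one 0.625 μm eyepiece division).

## Features

The 7 core features are computed from the polygon (sub-pixel exact): area
(shoelace), maximum Feret diameter (= maximum pairwise convex-hull vertex
distance), minimum Feret (flush-edge rotating-caliper minimum),
elongation = maxF/minF, compactness = 4πA/P², solidity = A/A_hull, Heywood
circularity = P/(2√(πA)) (so compactness × heywood² ≡ 1), hydraulic radius
= A/P. The instrument whose output these mirror does not publish its 43
remaining parameter definitions, so this package freezes its own
rotation-invariant set of 43 (intensity moments, gradient energy, histogram
entropy, angle-averaged GLCM statistics at offsets 1 and 3 px, radial
Fourier boundary descriptors, multi-scale Laplacian-of-Gaussian response,
rotation-invariant uniform LBP histogram, log-scaled Hu moments; order
frozen in `texture.TEXTURE_FEATURE_NAMES`, published in CSVs as
`texture_01..texture_43`).

## Rendering

Dark field: background ≈ 0 (sensor noise s.d. 0.01), interior at 0.55, a
2 px bright rim. The exine speckle is a unit-variance random-Fourier
Gaussian field (128 cosine components, correlation length `texture_scale`,
default 0.8 μm — below the ~1 μm optical resolution, hence "obscurely
flecked") evaluated in grain-local coordinates so the texture rotates with
the grain; it is scaled by the per-grain `texture_amplitude`. Equatorial
views multiply the amplitude by a random focus factor in [0.35, 1] (the
curved flank of a side-lying grain is never uniformly in focus).
Parasyncolpate grains receive a small bright apocolpium ring (radius
~0.7 μm) at the pole; degraded grains are Gaussian-blurred (σ = 1 μm). No
further optics (PSF stack, depth of field) are simulated. Default pixel
size 0.25 μm/px, 2 μm canvas margin.

## Genus presets (calibrated values)

| parameter | leptospermum | kunzea | basis |
|---|---|---|---|
| E mean ± sd (μm) | 19.08 ± 1.28 | 16.30 ± 0.95 | published |
| P mean ± sd (μm) | 12.98 ± 1.66 | 11.28 ± 2.33 | published |
| curvature mean ± sd | −0.055 ± 0.014 | +0.012 ± 0.014 | calibrated (concave vs straight/convex) |
| apex rounding | 0.30 | 0.30 | calibrated |
| aperture probabilities | {2: 0.005, 3: 0.99, 4: 0.005} | same | "very rarely di-/tetracolporate" |
| parasyncolpate prob. | 0.02 | 0.50 | qualitative descriptions |
| texture amplitude ± sd | 0.120 ± 0.042 | 0.040 ± 0.032 | calibrated (scabrate vs psilate) |
| irregularity | 0.036 | 0.058 | calibrated |
| degraded fraction | 0.048 | 0.048 | published discard rate (1190/24892) |

Morphotype/species presets use each taxon's published E/P average, with the
s.d. approximated as range/4, and inherit the genus shape/texture values.

Calibration notes: an earlier draft used curvature −0.12 for
*Leptospermum*; under the sagitta convention above that outline has
compactness ≈ 0.25–0.35, i.e. *below* the 0.55 QC threshold, so every
healthy grain would be discarded — the milder −0.055 keeps healthy
compactness near 0.85–0.93 while preserving a clear concave-vs-convex
contrast. *Kunzea*'s higher irregularity reflects the tabulated variability
of its amb appearance and gives it the larger MFD−E offset.

## Statistics

- `summarize`: sample mean, s.d. (n−1), 1-s.d. and 2-s.d. ranges (the size
  rule's reference intervals).
- `pca`: columns centred and (by default) scaled to unit variance —
  correlation PCA, the defensible choice for features in mixed units (μm²,
  μm, dimensionless); SVD-based; axis sign fixed so the largest-magnitude
  loading is positive; zero-variance columns are an error naming the column.
- `hpd_region_2d`: binned Gaussian KDE (2-D histogram on a 201×201 grid
  smoothed with Scott's-rule bandwidth per axis, overridable), then the
  smallest density super-level set holding the requested mass, returned as
  contour polygons. Binned KDE keeps the n = 10⁵ sanity check (95% region
  of a standard bivariate normal ≈ π·χ²₂(0.95) ≈ 18.8 score-units²) in
  seconds; the KDE bandwidth inflates the area by ~(1+h²), well inside the
  10% check tolerance.
- `svm_cv`: per iteration, a simple (unstratified) random 80:20 split —
  matching a "randomised" split; a stratified mode exists but is off by
  default — standardization fit on the training split only, RBF SVM with
  C = 1 and gamma = "scale" (the reference instrument's hyperparameters are
  unpublished; these are fixed and overridable). Iteration i is seeded
  seed + i. Reports per-iteration accuracies, their mean ± sd (the headline
  statistic), pooled-prediction accuracy (computed but secondary), per-class
  recall and the majority-class baseline (~75% at the study's 3:1
  imbalance).
- `estimate_mixture`: `fixed_components` maximizes the likelihood over the
  mixing weight only (bounded 1-D optimization; component parameters fixed
  at the genus references) — the right tool when the reference populations
  are trusted; `em` refits weight and components by EM (scikit-learn
  GaussianMixture, initialized at the references, spherical covariance,
  max 500 iterations; non-convergence is reported via `converged=False`
  with the best estimate returned). 95% CIs are nonparametric bootstrap
  percentile intervals, default 500 resamples, widened if needed to include
  the point estimate.

## Problem sizes

The test suite and the acceptance script run desk-scale versions of the
study design: two-genus cohorts of 4000 grains (3000:1000, the study's ~3:1
imbalance; the study itself analysed 23 702), 99-iteration cross-validation,
n = 490/318 measurement calibrations, 10⁵-point KDE checks and 200-replicate
mixture-recovery experiments. At these sizes the whole suite completes in
roughly 15 minutes on one CPU; all quantities scale with √n sampling error
and were verified stable across seeds.

## What passing tests do and do not show

The generator reproduces the *statistical contrasts* the published analyses
rely on — size distributions, concave/convex amb shape, texture contrast,
degraded-capture rate, view mix — not real optics: there is no PSF,
focus stack, debris, clumping, or hybrid morphology, and the 43 texture
features are this package's own definitions, not the instrument's
unpublished ones. Passing tests therefore demonstrate that the analysis
chain is implemented correctly and behaves as published *under the stated
morphological model*; they do not certify instrument-level accuracy on real
slides. The published real-data counts (17 835 / 5 867 grains, 1 190
discarded) are used only as calibration constants (class imbalance, view
mix, degraded fraction), never as test assertions.

## Known limitations

- The amb model cannot represent |curvature| beyond the fillet-feasibility
  bound (≈ −0.10..0.26 at apex_rounding 0.30); sampled curvatures are
  clipped there.
- Degraded grains are modelled as ragged-plus-blurred; real poor-focus
  captures vary more (halos, partial grains).
- The mixture estimator assumes acetolysed, polar/oblique-view E
  measurements from exactly two genera; contaminant taxa would bias the
  weight.
- Heuristic view sorting (elongation cut at 1.25) is a convenience with
  ~95% agreement to truth labels on calibrated cohorts; the reference
  workflow sorts views manually, and truth-label mode is the default.
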