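# Methods

This document describes the statistical and geometric model implemented by
`atriashape`: how cohorts are represented, how the shape comparison is run,
how deformation features are extracted, and how the outcome models are
evaluated. Default parameter values and the reasoning behind them are stated
inline.

## Overview

The pipeline asks a single question: *do patients whose atrial fibrillation
recurs after ablation have a systematically different left-atrial shape than
patients who stay in rhythm, and is that difference predictive per patient?*
It answers it in four stages:

1. **Cohort** — binary left-atrium segmentation masks with outcome labels
   (1 = recurrence, 0 = no recurrence), plus a clinical covariate table.
   The package ships a synthetic generator that plants a known shape effect,
   so every downstream stage can be validated against ground truth.
2. **SOI** — align the cohort to a template, run a voxelwise permutation
   test on signed-distance values, and project the significant voxels onto
   the template surface as the *surface of interest* (SOI); the remaining
   surface is the *complement SOI* (cSOI).
3. **Features** — register the template to each patient non-rigidly and
   summarize the resulting deformation field over the SOI and cSOI
   (16 descriptors per region, 32 per patient).
4. **Evaluate** — screen features with rank-sum tests, train a
   gradient-boosted classifier under repeated stratified cross-validation,
   and compare AUCs of shape, clinical, and combined models.

## Shape representation: signed distance

Each binary mask is converted to a signed Euclidean distance map `d(x)`
(negative inside, positive outside, zero on the surface), computed on the
mask's own grid via exact Euclidean distance transforms of the foreground
and background. The signed distance is the working representation
throughout because:

* it is continuous across the surface, so voxelwise group differences in
  `d` measure *local surface displacement in millimetres* directly;
* it satisfies the eikonal property `|∇d| = 1` away from the medial axis,
  which the test suite checks (median deviation ≤ 0.05 in a 2–5 mm band);
* statistics can be restricted to a **narrow band** `|d| ≤ 5 mm` around the
  template surface, where the displacement interpretation is valid and the
  multiple-testing burden is smallest.

## Alignment and atlas construction

One cohort member is chosen as the template: the member of the majority
(no-recurrence) group whose foreground volume is the cohort median
(`select_template`). All other members are registered to it and resampled
onto its grid (`build_atlas`).

Three alignment modes are implemented:

* `similarity` (default for the statistical comparison): rigid rotation +
  translation + one isotropic scale, 7 parameters.
* `affine`: full 12-parameter linear map.
* `affine+nonrigid`: affine followed by a B-spline free-form deformation.

**Why similarity is the default for the group comparison.** The comparison
must remove nuisance pose and size while *preserving* the shape difference
it is trying to detect. A full affine has enough freedom (anisotropic
scales + shears) to absorb a large part of a localized protrusion — in
synthetic experiments a planted 3 mm cap lost most of its t-statistic
under affine pre-alignment — and a non-rigid alignment would erase it
entirely. Similarity alignment is the standard Procrustes-style
normalisation in statistical shape analysis and keeps localized effects
intact. The affine and non-rigid modes remain available for atlas uses
where residual shape is *not* the signal.

### Registration backend

Registration optimizes a mean-squared-difference metric between the fixed
and warped-moving signed-distance maps, evaluated only inside a ±8 mm band
around the fixed surface (SDF values far from both surfaces carry no
correspondence information and only flatten the metric). Optimization is
quasi-Newton (L-BFGS-B) with analytic gradients.

* **Affine / similarity** start from a moments-based initializer (centroid
  and second-moment scale matching). The affine adds a small quadratic
  penalty (weight 1e-3) on the deviation of the matrix from the identity
  and of the translation from the initializer — a minimal-deformation
  prior that resolves the gauge freedom of near-flat metric directions
  without measurably constraining the fit.
* **B-spline free-form deformation** places a cubic B-spline control
  lattice with 10 mm knot spacing over the fixed grid; the total transform
  is `y(x) = Ax + t + FFD(x)` with the affine part frozen. A bending
  penalty — the mean squared second-order difference of the control
  lattice, weight 0.01 — keeps the field smooth and invertible in
  practice. 60 L-BFGS iterations suffice on banded SDFs.

**Quality gates.** Every registration is scored by the Dice overlap of the
warped moving mask against the fixed mask. Affine/similarity registrations
must reach Dice ≥ 0.85 (hard failure, the exception carries the achieved
Dice); B-spline results carry a `gate_passed` flag at Dice ≥ 0.9. Atlas
construction excludes gate failures and records them rather than silently
degrading the cohort.

## Voxelwise statistics: permutation maxT

On the atlas grid, each narrow-band voxel gets a pooled two-sample
t-statistic of signed-distance values (recurrence minus no-recurrence;
zero-variance voxels get t = 0). Familywise error is controlled with the
Westfall–Young **maxT** procedure: group labels are permuted, the maximum
absolute t over the band is recorded per permutation, and each voxel's
corrected p-value is the fraction of permutations whose max-|t| reaches its
observed |t|.

* When the number of distinct relabellings `C(n, n1)` is at most `n_perm`,
  the test enumerates all of them and is **exact** (the smallest achievable
  p is `2 / C(n, n1)` by the mirror-pair symmetry of |t|).
* Otherwise it draws `n_perm` random relabellings — a seed is then
  mandatory — and uses the add-one convention
  `p = (1 + #{exceedances}) / (n_perm + 1)`, so sampled p-values are never
  zero and the test remains valid.

The implementation is vectorized over permutations via the sufficient
statistics `G·X` and `G·X²` (permutation-by-voxel matrix products), which
makes 1000 permutations on a ~50k-voxel band a seconds-scale operation.

## SOI extraction

The template surface is extracted by marching cubes on the template mask
(vertices in world millimetres). A vertex belongs to the **SOI** if any
significant voxel (corrected p < α, default 0.05) lies within `band_mm`
(default 3 mm) of it; all other vertices form the **cSOI**. The two sets
are disjoint by construction and together cover the surface. An empty SOI
is a legitimate outcome (no significant shape difference) and downstream
stages refuse to fabricate features from it.

## Deformation-field features

For feature extraction the template is registered to each patient with the
full `affine + B-spline` model, and the field analyzed is the **total**
displacement (affine plus FFD) unless `nonrigid_only` is requested. At
each surface vertex the displacement `u` and the curl `∇×u` (central
differences on the field grid) are sampled. Per region (SOI and cSOI), 16
descriptors:

* `norm_min, norm_mean, norm_max, norm_std` — statistics of ‖u‖,
* `mean_ux, mean_uy, mean_uz` — mean displacement components,
* `curl_{x,y,z}_{min,mean,max}` — nine curl-component statistics.

The magnitude block captures how much the template must move to become the
patient; the curl block captures local rotational/twisting character that
magnitudes miss. 2 regions × 16 = 32 features per patient
(`soi_*` and `csoi_*` columns). The curl operator is validated against
analytic linear fields, for which `∇×(Mx + b)` is constant and known.

## Outcome models and evaluation

* **Screening.** Each shape feature is tested with a two-sided
  Wilcoxon rank-sum test (exact enumeration for group sizes ≤ 10 without
  ties, normal approximation otherwise); features with p < 0.05 are kept.
  If none pass, the model falls back to the full block rather than
  fabricating a selection.
* **Classifier.** Gradient-boosted trees (XGBoost; 100 trees, depth 3,
  learning rate 0.1, single-threaded for determinism) under **repeated
  stratified 5-fold cross-validation** (25 repetitions by default). Each
  patient is held out 25 times; their out-of-fold probabilities are
  averaged before computing metrics, which stabilizes the estimate on
  small cohorts.
* **Metrics.** AUC uses the rank (Mann–Whitney) definition with ties
  counted one half — validated against brute-force pairwise counting up to
  n = 1000. Accuracy/precision/recall are reported at the 0.5 threshold.
* **Model comparison.** Correlated AUCs (same patients, two probability
  vectors) are compared with DeLong's covariance-adjusted z-test.
* **Clinical table.** Continuous covariates get pooled or Welch t-tests
  (also computable directly from published group summaries, mean/SD/n);
  categorical covariates get Fisher's exact test; a Spearman correlation
  map relates shape features to clinical covariates.

## Synthetic cohort generator

The generator exists so that every claim above is testable against known
ground truth. Each member is a star-shaped surface on a shared grid:

```
r(θ, φ) = s · r_ell(θ, φ) · (1 + f(θ, φ)/R) + g · A · bump(θ, φ)
```

* `r_ell`: an ellipsoidal base (radius 30 mm, axis ratios 1 : 0.85 : 0.7)
  — an atrium-scale, clearly non-spherical blob.
* `f`: a random smooth spherical-harmonic field (RMS-calibrated to
  `variability_mm`, default 1 mm) giving each member individual shape.
* `s`: per-member volume jitter (default 5 % coefficient of variation).
* `bump`: the planted effect — a **plateau cap** (constant amplitude over
  the inner 85 % of a 30° cap, smooth roll-off outside) of amplitude
  `effect_mm` (default 3 mm) applied only to recurrence members (`g`).
  A plateau rather than a peaked bump makes "the deformed region" well
  defined for recovery scoring: the effect is at full strength across the
  cap instead of only at its centre.

Defaults were fixed a priori by a power argument: a 3 mm planted effect
against ~1 mm inter-patient variability gives the voxel test roughly a 3:1
signal-to-noise ratio at n = 15 + 15, large enough to be detectable and
small enough that failures of alignment or statistics would be visible.
The generator validates its output (closed single-component surface, ≥2
voxel margin to the grid edge) and records ground truth: the cap axis and
angular extent, exposed as a per-vertex indicator on any mesh for
sensitivity/precision scoring of a detected SOI.

Clinical covariates are drawn to match published group summaries of an
ablation cohort (age, BMI, LVEF, LA volume as Gaussians per group; sex,
rhythm, AF type, ablation technology as Bernoulli counts), so the clinical
arm of the model and the characteristics table can be exercised
realistically.

Because all members of a synthetic cohort share one grid, null-calibration
experiments (no planted effect) can legitimately run the statistics chain
without registration; this isolates the false-positive behaviour of the
permutation test itself from registration noise.

## Problem sizes

Defaults target cohorts of tens of members on 1–3 mm isotropic grids —
30 + 30 members at 2 mm runs the full pipeline in minutes on one CPU, and
15 + 15 at 1 mm resolves a 3 mm planted effect cleanly. The banded metric,
analytic gradients, and vectorized permutations are what keep registration
at ~1 s per pair and 1000 permutations at seconds-scale; nothing in the
design caps cohort size beyond memory for the SDF stack.

## Limitations

* The generator's shapes are star-shaped smooth blobs: adequate for
  validating alignment, statistics and features, but without pulmonary
  veins, appendage, or topology variation of real atria.
* Similarity alignment preserves localized effects but leaves global
  anisotropic size differences in the data; if those are nuisance rather
  than signal for a given question, the affine mode exists.
* The permutation test assumes exchangeability of members under the null;
  registration to a template chosen from one group can in principle break
  this, which is why the template is taken from the majority group and the
  null calibration is part of the test suite.
* DeLong's test compares AUCs on the same sample; cross-validated
  probabilities violate its independence assumptions mildly, a standard
  and accepted approximation.
* Curl is computed on the displacement (not velocity) field; it is a
  descriptor of local rotational character, not a diffeomorphic quantity.
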