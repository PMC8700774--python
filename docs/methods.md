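# Methods

This note records the models, defaults and numerical choices behind `visqc`,
and what the synthetic validation does and does not demonstrate.

## Scene model and synthetic cohorts

A scene is a black field (nominal RGB 8, SD 2) holding a circular sample
disc, a white reflectance patch (nominal `white_level`, default 245, SD 1.5),
and a mid-gray dimensional indicator (128, SD 2). The default layout is a
512×512 frame with the disc, white patch and indicator in fixed, disjoint
positions; `SceneLayout.scaled(n)` shrinks the geometry proportionally and is
used throughout the test suite at 96–160 px for speed. Feature extraction is
resolution-configurable, so frame size is a free choice.

The disc interior is `base_color` (default carrot-orange (225, 120, 35))
plus:

* a **texture field**: Gaussian white noise smoothed to a configurable
  correlation length (default 6 px), normalized to unit SD and scaled by
  `texture_amplitude` (default 10 intensity units), added as a shared
  luminance perturbation;
* independent per-channel pixel noise (`color_noise_sd`, default 6);
* **whitening blotches**: a second smooth random field is thresholded at the
  quantile that makes exactly `whitening_fraction` of the disc area blend
  fully to the white-reference color. This emulates the surface whitening
  (dehydration/lignification) seen on stored cut vegetables, with exact,
  deterministic area coverage so severity is a usable ground truth.

The whole frame is finally scaled by `illumination_gain` and shifted by
`illumination_offset`, clipped to [0, 255] and rounded half-up to 8 bits.
All randomness flows from a single integer seed.

**Cohorts.** The study design enumerates packages (atmosphere × treatment
run × control time × replicate; the default design is the 2³⁻¹ fractional
factorial with a triplicated center point, 3 atmospheres, control times
0/3/7/14 days, 2 replicates → 168 treated packages) and untreated controls
(one per atmosphere per non-zero control time → 9). Every package holds two
slices imaged at two events. Treated packages contribute a fresh-state and a
treated-state image per slice (336 + 336); all four images of a control
package are counted as control-state (36), the only reading consistent with
the overall inventory of 708. Per-package appearance is drawn from a
`FreshPopulation` (channel-wise SD (6, 5, 4) around the base color, texture
amplitude SD 1.5, per-image illumination gain SD 0.02 — values chosen as a
plausible biological-plus-fixture spread); degradation effects are looked up
by (condition, storage day) and clipped to valid ranges with a warning.
Per-image random streams are derived from the cohort seed and the record
index, so cohorts are reproducible and order-independent.

**What the generator does not emulate:** real carrot reflectance and
translucency, specular highlights, packaging-film optics, camera optics and
nonlinear response, and spatially *non*-stationary degradation (real
whitening concentrates at cut edges). Passing tests demonstrate that the
pipeline recovers known structure under controlled conditions, not that it
matches any particular instrument.

## Standardization

The correction is the minimal model that uses both references exactly: a
per-channel affine map sending the measured white/black reference means to
nominal 255/0, applied pixel-wise, clipped and rounded half-up. Reference
colors are central-80% trimmed means of the reference patches (robust to
specular pixels). Without a layout hint, the white patch is found by
scanning tiles (side = min(H, W)/16, ≥ 8 px) for the brightest one with
within-tile SD below 8 intensity units, then growing the surrounding uniform
region; the black estimate is the darkest such tile. The correction is exact
only while nothing relevant clips; the renderer's `white_level` exists
precisely so invariance can be exercised at gains up to 1.3 on non-clipping
scenes.

## Segmentation

k-means (scikit-learn, k-means++ seeding, 4 restarts, fitted on at most
50,000 sampled pixels and applied to all) clusters standardized RGB pixels
with k = 4 (background, sample, white reference, indicator). The darkest and
brightest clusters are excluded; among the rest the sample cluster must lie
within 0.12 of the configured sample hue (default 24°/360°) and have mean
saturation ≥ 0.2 — the saturation gate is what rejects the gray indicator
when no sample is present. After opening/closing, the ROI is the **convex
hull** of the cluster's non-trivial connected patches (≥ 5% of the largest).
On intact samples this equals the largest connected component; on severely
whitened samples, whose surface largely co-clusters with the white
reference, the surviving hue islands still span the slice and the hull
recovers it. The convexity assumption is appropriate for cut slices and is
the deliberate trade-off here: a non-convex sample would be over-segmented.

The largest axis-aligned rectangle inscribed in the mask is found by the
histogram-stack dynamic program (O(HW)); ties on area break to the smallest
(top, left). Coordinates are 0-based, half-open.

## Features

All statistics use population (biased) moments; zero-variance inputs return
skewness = kurtosis = 0 so constant crops stay finite. Grayscale uses ITU-R
BT.601 weights. Wavelet features use Daubechies-4, 4 levels, periodization
mode (orthonormal, perfect reconstruction), four moments of each of the
three detail subbands per level per RGB channel (4·3·4·3 = 144); the
per-channel (rather than grayscale) reading is what yields the 144-feature
block consistent with the rest of the descriptor. GLCM features are the raw
entries of the symmetric, sum-normalized co-occurrence matrices of the
11-level equal-width-quantized gray crop at distances 1–5 px and angles
0°/45°/90°/135° (11²·5·4 = 2420); displacements are rounded polar offsets,
matching scikit-image. Feature order and names are fixed; extraction is
bit-deterministic.

## Conformance monitoring

Calibration autoscales features (mean 0, variance 1, sample SD with ddof 1);
zero-variance columns are dropped and recorded in the model's column map.
Loadings are the top-A right singular vectors; score variances λₐ are the
calibration score variances. T² uses the calibration-form F limit
A(O−1)/(O−A)·F; the new-observation form A(O²−1)/(O(O−A))·F is available by
flag (difference ≈ 0.3% at O = 336). The Q limit is the Box two-moment
chi-square match g·χ²ₕ with g = ν/2μ, h = 2μ²/ν, where μ and ν are the mean
and **variance** of the calibration Q residuals; that is the reading under
which the formula is the established moment match (a standard-deviation
reading is selectable via `nu_convention="sd"`). If calibration residuals
vanish (data exactly in the component span), Q_lim is 0 and any nonzero
residual is out of control. Verdicts use strict inequalities; a sample
exactly on a limit does not conform. Calibration points falling outside
their own limits (≈5% by construction) are kept, not trimmed.

**Small-sample behaviour worth knowing.** With many more features than
calibration samples (M ≫ O), in-sample Q residuals underestimate held-out Q
by a factor of roughly 1 + (A + 2)/O, so held-out false alarms stay near α
only when O is large against A relative to the spread of Q — a condition the
full design (O = 336, A = 7) satisfies but tiny cohorts do not. The
Monte-Carlo validation (20 variables, rank-7 signal with score variances
10…4, isotropic noise SD 0.5, O = 336, A = 7) shows T² held-out coverage of
95% ± ~0.4 across calibrations, while Q coverage averages ≈ 93.5–94% with a
between-calibration SD of ≈ 1.4% — the moment-estimated Box limit inherits
the sampling noise of ν and a small overfitting bias. The test suite
therefore checks T² coverage at 95 ± 1 on a single 10,000-draw experiment
and the replicate-averaged Q coverage at 95 ± 3.

## Pipeline and scales

`run_study` renders the cohort lazily, pushes every image through
standardization (layout-hint references), segmentation (per-image seeds
derived from the cohort seed) and feature extraction, calibrates on
fresh-state images only, projects everything else, and reports per
(condition, storage day) rejection fractions. Outputs are byte-reproducible
given the seed. Tests run reduced designs (1 atmosphere, 2–4 conditions,
24–152 calibration images) at 128–160 px frames — sizes chosen so each
statistical check has the sample size its tolerance needs; the full design
remains the default for library users.

The microbial utility computes log₁₀(N/N₀); survivor counts below the assay
detection limit return the censored upper bound log₁₀(limit/N₀) with a
`censored` flag.

## Known limitations

* The renderer's whitening blends to the exact white-reference color; real
  whitened tissue is off-white, so real scenes are easier to segment at high
  severity than synthetic ones.
* Q-limit coverage is approximate by construction (Box two-moment match,
  moments estimated in-sample); see above for the quantified behaviour.
* The severity model treats replicate slices as independent samples; any
  within-package correlation in real data would make rejection summaries
  slightly optimistic.
* Auto-location of references assumes the white patch is the brightest
  uniform region; a heavily whitened sample can defeat it, which is why the
  pipeline passes layout hints.
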