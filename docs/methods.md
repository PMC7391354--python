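# Methods

## Problem setting

The package measures how reproducible radiomic features are when the only
thing that changes between measurements is the lesion contour. One
"measurement" is: take a CT slice, take one rater's binary mask of the
lesion, run the fixed extraction protocol, obtain a feature vector. With k
raters per lesion and n lesions, each feature yields an n × k table whose
intraclass correlation quantifies robustness to contour disagreement.

Real multi-rater cohorts are replaced by a synthetic test bed with two
simulated rater populations per lesion: a small "expert panel" (k = 4) and
a large sampled population (k = 25), the sizes used when comparing human
readers to probabilistic-segmentation samples on lung CT.

## Synthetic lesions

`make_lesion` renders a star-convex lesion on a noisy background:

- Boundary: radius r(θ) = r₀ · (1 + ε·f(θ)), with f a band-limited
  periodic field (harmonics 2–7, 1/m amplitude decay, normalised to
  max |f| = 1) and ε ∈ [0, 1) the irregularity. ε = 0 gives a disc.
- Intensity: background HU + white noise; lesion HU + a correlated
  Gaussian texture field (white noise smoothed over `texture_corr_len`,
  rescaled to `texture_sd`); the lesion/background transition is blended
  through a Gaussian-blurred mask (σ = `edge_blur_sigma`) to mimic the
  partial-volume effect.

Two presets bracket the contrast regimes that matter for feature
stability: `LUNG_PRESET` (lesion ≈ 40 HU on ≈ −800 HU aerated lung,
contrast ~840 HU) and `ABDOMEN_PRESET` (≈ 90 HU on ≈ 45 HU soft tissue,
contrast ~45 HU). Cohort heterogeneity comes from `default_spec_sampler`:
radius uniform on 4–15 mm (small nodules to large tumours; the lower end
stays above the 30 mm³ eligibility floor), irregularity uniform on
0.05–0.45, lesion attenuation jittered with SD 60 HU (ground-glass to
solid range), texture strength scaled uniformly on 0.4–1.8×. These are
fixed, documented study conditions, not tuning knobs.

## Simulated raters

`perturb_mask` produces one plausible alternative contour: the signed
Euclidean distance field of the mask (positive inside, with a half-pixel
offset so boundary-adjacent pixels sit at ±0.5 px and sub-pixel
displacements can move the rasterised contour) plus a smooth random field
(white noise smoothed over `corr_len` = 4 mm, rescaled so its standard
deviation equals the `amplitude` in mm), re-thresholded at zero. The
largest connected component is kept, so a rater's contour is always a
single body. Amplitude 0 returns the input bit-identically.

`sample_rater_set` applies rejection sampling: a draw is accepted only if
its Dice with at least one reference mask strictly exceeds 0.3 (references
are the ground truth, or the simulated expert panel for the sampled
population — the any-expert variant used with multi-rater datasets) and
its one-voxel-extruded volume stays ≥ 30 mm³, so every emitted mask is
eligible for feature extraction.

`calibrate_amplitude` bisects the amplitude until the median pairwise Dice
of a 20-draw rater set matches a target within ±0.02. The objective is
evaluated with a fixed seed and averaged over three independent draw sets,
making it a deterministic, monotone function of amplitude. Targets: 0.87
for the expert panel, 0.85 for the sampled population — the median
agreement levels reported between human readers and between network
samples and readers on lung-nodule CT. On the 10 mm reference lesion these
calibrate to ≈1.1 mm and ≈1.5 mm displacement fields respectively.

## Extraction protocol

1. Resample image (bilinear) and mask (nearest-neighbour) to isotropic
   1 mm spacing. 2. Crop a fixed window (128 px default, 192 px for
   abdominal fields of view; capped at the image size) centred on the
   midpoint of the minimal rectangle covering the lesion, ties toward the
   lower index, padding with the image minimum. 3. Eligibility: reject
   masks with more than one 8-connected component or volume < 30 mm³
   (area × 1 mm slice extrusion); the floor corresponds to a 1.92 mm
   sphere radius. 4. Discretize in-mask intensities with a fixed 25 HU bin
   width anchored at the ROI minimum: level = floor((x − min)/25) + 1.
   Min-anchoring makes all downstream texture features invariant to a
   constant HU shift. 5. Extract 89 features; raw values, no scaling.

Feature conventions (matching the common open-source defaults): GLCM at
distance 1 over the four unique 2D directions, symmetric matrices,
features computed per direction then averaged; GLRLM likewise; GLSZM and
NGTDM direction-free with 8-connected zones/neighbourhoods; entropies in
log base 2 with 0·log 0 = 0; percentiles by linear interpolation;
population variance; non-excess kurtosis (and skewness/kurtosis of a
constant ROI defined as 0). Degenerate single-level ROIs use limit values:
GLCM Correlation = 1, Imc1 = Imc2 = InverseVariance = 0; NGTDM Coarseness
is capped at 10⁶ when its denominator vanishes.

The slice is analysed in 2D but given volume semantics by a one-voxel
(1 mm) extrusion, consistent with the isotropic resampling: VoxelVolume =
area × 1 mm, MeshVolume from the marching-squares contour area,
SurfaceArea = 2·A_mesh + perimeter·t. The 12 shape features are a 2D
adaptation of the standard 3D set under this extrusion; axis lengths use
the 4·√eigenvalue convention on the pixel-coordinate covariance, and
Maximum2DDiameterSlice is the largest distance between boundary pixel
centres (computed on the convex hull). A signature of 89 = 18 + 12 + 22 +
16 + 16 + 5 features is the complete set under these category definitions.

## Reliability analysis

ICC(1,1) = (MSB − MSW)/(MSB + (k−1)·MSW) from the one-way random-effects
ANOVA. Conventions: negative estimates are reported as-is (not floored);
MSW = 0 with between-lesion signal gives exactly 1; a table with zero
total variance has no defined ICC and is reported as such rather than
dropped. Confidence intervals are 95% percentile bootstrap over lesions
(rows), 1000 replicates by default; undefined replicates are dropped and
counted, and more than 50% undefined is an error. Lesions missing any
rater are dropped whole before analysis.

Aggregation reports the mean defined ICC per category and the fraction of
features above 0.75 / 0.8 / 0.9 — the three stability cut-offs in common
use; `classify_stability` labels a feature under both the 0.75-excellent
and the stricter 0.90-excellent convention side by side, since the field
has not settled on one. Two rater populations are compared by the Pearson
correlation of their per-feature ICC vectors.

## What the phantom does and does not show

The generator reproduces the *mechanism* under study — plausible, smooth,
Dice-calibrated contour disagreement around heterogeneous lesions — and
the qualitative findings follow: shape features are the most robust
category, texture features the least, and a k = 4 panel and a k = 25
sampled population rank feature robustness nearly identically (Pearson
r ≈ 0.95 on a 20-lesion cohort, > 0.9 at 100 lesions).

Absolute ICC levels are *not* transferable to real cohorts. The phantom is
deliberately punishing for intensity and texture features: the lung preset
has ~840 HU lesion/background contrast, so a rater mask that strays into
background admixes air-like voxels (the known driver of non-shape
instability on lung CT), and the intratumoral texture is statistically
homogeneous, so between-lesion texture variance — which inflates ICC in
real data — is modest. Consequently mean non-shape ICCs on the synthetic
cohort (≈0.4–0.6) sit well below the ≈0.9 reported for real lung-lesion
cohorts, while shape ICCs (≈0.86–0.91) are comparable. Fractions of
features above 0.8 behave accordingly. The phantom also omits scanner and
reconstruction effects, anatomy, 3D structure (a single principal slice is
analysed, as in 2D slicewise practice) and rater biases (the perturbation
is centred on the truth; ICC(1,1) assumes no systematic rater effect,
which the simulator satisfies by construction).

## Numerical and design choices

- Signed distance with half-pixel boundary offset (see above); without it
  sub-pixel perturbations cannot change the rasterised mask.
- Rejection sampling truncates the perturbation distribution at large
  amplitudes (Dice floor + volume floor), so median feature ICC saturates
  rather than decreasing strictly; trend checks therefore use a one-sided
  trend test across amplitudes instead of strict adjacent ordering.
- Organ masking fills with −1000 HU (air) by default.
- Crop/principal-slice ties break toward the lower index.
- Both-empty Dice is undefined (NaN) and excluded from summaries with a
  count; the volume floor prevents it in the pipeline.
- Bootstrap resamples lesions, not raters: lesions are the exchangeable
  sampling unit; rater labels are arbitrary under the one-way model.

## Problem sizes

Default study sizes were chosen so each stage is interactive on one CPU:
20-lesion cohorts (4 + 25 raters) for the worked example, 40 lesions for
the headline recomputation in `scripts/acceptance.py`, 50-lesion cohorts
for amplitude-trend checks and a 100-lesion cohort for the
cross-population consistency check; coverage simulations use 200 trials of
n = 100, k = 4 with 500-replicate bootstraps. Larger cohorts sharpen the
estimates but do not change the qualitative picture.
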