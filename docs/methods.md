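# Methods

## Problem and data model

A leaf is observed as a hyperspectral cube: H×W pixels × B reflectance
bands. The instrument model is a 231-channel VNIR imager covering
400–1000 nm. The true band-center table of such imagers is
device-specific; the packaged fixture grid is constructed to satisfy the
four facts the pipeline depends on — 231 strictly increasing centers from
400 to 1000 nm, the three RGB synthesis centers 700.37 / 545.64 /
439.75 nm present exactly, and exactly 210 centers inside the closed
analysis window [437, 998] nm. No claim of fidelity to any particular
sensor is made beyond those constraints.

Cubes are persisted as ENVI-style pairs (text header + raw BSQ float32),
the de-facto exchange format of push-broom exporters. Reading validates
the declared geometry against the binary size and requires the
`wavelength` key.

## Segmentation and spectra

The leaf lies on near-black cloth, so a single near-infrared band
(default: nearest to 800 nm, where the vegetation plateau maximizes
contrast) is thresholded with Otsu's method; only the largest connected
component is kept and holes are filled. The band and the threshold rule
are configurable (`method="fixed"` with an explicit level). The whole-leaf
silhouette is the ROI; its per-band arithmetic mean is the sample
spectrum, cropped to the closed window [437, 998] nm (210 bands on the
fixture grid) because band edges outside it are noise-dominated.

## The 53-variable image battery

All texture statistics operate on a 16-level quantization (min–max over
the foreground) of the Rec.601 luminance of the synthesized RGB preview;
16 levels keeps co-occurrence matrices dense on leaf-sized regions while
preserving contrast structure. Choices that the classical definitions
leave open:

- **GLCM (16)** — contrast, correlation, energy, homogeneity at distance 1
  and angles 0°/45°/90°/135°, symmetric accumulation, *mask-aware*: pixel
  pairs touching background are excluded so the irregular outline does not
  contaminate counts. Correlation of a constant region is defined as 0
  (the σ=0 limit must not produce NaN in feature vectors).
- **GGCM (15)** — joint distribution of gray level and Sobel gradient
  magnitude (3×3 kernels, magnitude quantized to 16 levels over [0, max]);
  only pixels whose 3×3 window lies inside the foreground contribute. The
  15 statistics are the canonical set: small/large-gradient dominance,
  gray/gradient nonuniformity, energy, gray and gradient means and
  standard deviations, correlation, gray/gradient/mixing entropies
  (natural log, 0·log 0 = 0), inertia, inverse difference moment.
- **GLDM (4)** — mean, contrast, angular second moment and entropy of the
  absolute gray-difference histogram at a single displacement (0, 1);
  a single displacement keeps the block at exactly 4 features.
- **Tamura (5)** — coarseness (best 2^k averaging window per pixel,
  k ≤ 5, via integral images), contrast (σ/kurtosis^¼), directionality
  (single-peak sharpness of a 16-bin Prewitt direction histogram with a
  magnitude floor of 12/255 of the dynamic range), linearity (direction
  co-occurrence concentration along the diagonal at distance 4), and
  roughness = coarseness + contrast by definition.
- **Hu moments (7)** — computed on the binary silhouette (they are shape,
  not texture, features), via central → scale-normalized moments.

Fusion vectors are spectral-first: [210 spectral | 6 color | 16 GLCM |
15 GGCM | 4 GLDM | 5 Tamura | 7 Hu] = 263 features, with a named block
map so downstream stages can slice blocks without magic offsets.

## Classifiers

- **LDA** — pooled full-covariance linear discriminant
  (scikit-learn, SVD solver). The SVD path handles rank-deficient pooled
  scatter — routine here, since 210–263 features can exceed per-period
  sample counts — without forming the covariance explicitly, so no
  explicit ridge jitter is needed.
- **Quadratic SVM** — polynomial kernel (γ⟨x, z⟩ + 1)², C = 1, one-vs-one.
  "Automatic kernel scale" is implemented as γ = 1/(d · Var(X)), recorded
  in the model so fits are reproducible and auditable.
- **SDA** — a random-subspace ensemble of 30 linear discriminants, each on
  a uniformly drawn feature subset of size ⌊d/2⌋ (without replacement,
  from a stored seed: fits are bit-reproducible). Aggregation is majority
  vote with the mean posterior breaking ties. With one learner on the full
  space it reduces exactly to LDA.

Features are not standardized by default (LDA is affine-invariant and the
SVM's γ heuristic adapts to scale); an opt-in z-score switch using
training statistics exists for mixed-unit fusion vectors.

## Two-stage period-predetermined classification

Stage 1 classifies the phenological period (green vs yellow leaf stage)
with an LDA on the spectral block only — the stage difference dwarfs the
sex difference, so this stage is essentially perfect, and using spectra
even in fusion mode avoids coupling the gate to texture features. Stage 2
routes to a per-period sex bank. Named presets:

| preset            | mode     | green bank                  | yellow bank                 |
|-------------------|----------|-----------------------------|-----------------------------|
| `spectral_pp`     | spectral | SDA-s                       | LDA-s                       |
| `spectral_pp_vote`| spectral | SVM-s, SDA-s, LDA-d         | LDA-s, SDA-s, SDA-d         |
| `fusion_pp`       | fusion   | SDA-s                       | SDA-s                       |
| `fusion_pp_vote`  | fusion   | SDA-s, LDA-s, LDA-d         | SDA-s, LDA-s, LDA-d         |

(`-s` = trained on single-period data, `-d` = trained on both periods.)
Banks of even size > 1 are rejected at construction: majority voting is
only defined for odd committees here, avoiding silent tie policies.
Custom banks are accepted alongside the presets.

## Synthetic leaf generator

The generator emulates the statistical structure the analysis assumes; it
is the test bed, not a radiative-transfer model (no PROSPECT-style leaf
optics, illumination or BRDF effects).

- **Geometry** — a fan-shaped circular sector (apex angle 120–160°,
  radius 21–27 px in a 64×64 frame, random orientation, optional central
  notch), area ≥ 400 px. The frame size is chosen so a full study
  (hundreds of cubes) generates in seconds while leaving every texture
  window well-populated.
- **Stage curves** — green: blue/red chlorophyll troughs, green peak at
  550 nm, logistic red edge at 715 nm to an NIR plateau (~0.45); yellow:
  elevated 505–700 nm carotenoid-like plateau (~0.36) with an NIR step.
- **Sex effect** — an additive reflectance offset for males: δ_green =
  0.01 on the 437–500 and 520–640 nm windows; δ_yellow = 0.03 on the full
  437–998 nm window.
- **Per-leaf biology (sex-independent)** — (i) individual variation of the
  sex-linked trait itself, drawn along the same window pattern with σ =
  0.0035: this is what makes the green stage genuinely harder, because the
  class difference and the individual variation occupy the same subspace.
  The value is calibrated so the green-stage Bayes accuracy
  Φ(δ_green/2σ) ≈ 92% while the yellow stage sits at ≈ 100%, reproducing
  the stage ordering the method exploits. (ii) A smooth spectral deviation
  (σ = 0.005, ~8-band correlation length) and a ±0.5% amplitude jitter.
- **Noise** — i.i.d. pixel noise σ = 0.01, plus per-capture band
  calibration noise σ = 0.002 (constant over the frame, i.i.d. across
  bands) which, unlike pixel noise, does not average out in the mean
  spectrum — realistic for push-broom captures and essential for a
  well-conditioned within-class covariance at desk-scale sample sizes.
- **Texture** — a Gaussian-smoothed spatial field (σ = 3 px) with
  amplitude 0.02, demeaned over the leaf so it is pure spatial pattern
  with no radiometric shift; males get 1.5× the amplitude
  (`texture_sex_contrast = 0.5`) so the image-feature battery also carries
  sex signal. This is a synthetic assumption that makes image features
  informative, not a biological claim.
- **Determinism** — every cube is a pure function of (period, sex, params,
  seed); datasets derive child seeds from a master SeedSequence.

`GeneratorParams.null_sex_effect()` zeroes *all* sex-linked parameters
(both spectral offsets and the texture contrast); under it, male and female
cubes with the same seed are byte-identical, so any above-chance sex
accuracy under the null would indicate leakage in the pipeline.

What passing tests on this generator do show: the pipeline recovers
planted class structure of realistic magnitude through segmentation,
feature extraction, fusion and routed classification, and reports chance
under the null. What they do not show: performance on real leaves, whose
variability (venation, disease, specular effects, instrument drift) is far
richer than this model.

## Splitting and evaluation

The 3:1:1 calibration:validation:prediction ratio is realized inside a
4-fold routine: a fixed 20% prediction hold-out shared by all folds, with
the remaining 80% rotated through 4 validation folds (each rotation is
3:1 cal:val). This is the only reading that satisfies both the ratio and
the fold count. Splits are group-aware (all observations of one leaf/tree
stay in one part; a group larger than a part is an error). Model-selection
accuracy is the mean over the 4 folds' validation accuracy; prediction
accuracy comes from a model refit on the full 80%.

`evaluate_pp` reports the joint 4-class confusion matrix over
G-M / G-F / Y-M / Y-F (rows true, columns predicted), overall accuracy =
100 · trace/total, the period-stage accuracy, and per-period sex accuracy.

## Numerical conventions and degenerate inputs

Empty masks, empty test sets, single-class training data, and dimension
mismatches raise `ValueError` with the offending quantity named. Constant
images yield contrast 0, energy 1, correlation 0 (not NaN). Co-occurrence
angles with no valid pairs contribute zeros with a warning. Nearest-band
ties break toward the lower index. Window endpoints are inclusive.
`scale_pad`/`pad_only` center content with the extra pixel going to
bottom/right; padding is exactly zero; resizing is bilinear.

## Problem sizes

Default study sizes: 100 leaves per period × sex cell (400 cubes) for the
recovery experiment, 200 training + 400 evaluation cubes for the null
calibration, 64×64×231 cubes throughout. These sizes put per-period
training sets (~160) below the fusion dimension (263), which is the
regime the SVD-based LDA and the subspace ensemble are built to tolerate;
accuracies at these sizes are accordingly a few points below their
asymptotic (Bayes) levels, most visibly in the green stage.

## Known limitations

- The generator's sex-texture contrast and trait-variability magnitudes
  are modeling choices, not measurements; only the qualitative structure
  (male ≥ female reflectance; green harder than yellow) is grounded.
- Tamura directionality/linearity constants (16 bins, magnitude floor
  12/255, distance 4) follow common practice but other conventions exist.
- One leaf per cube is assumed; multi-leaf scenes and petiole removal are
  out of scope.
- No feature selection or dimensionality reduction is performed anywhere
  in the pipeline.
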