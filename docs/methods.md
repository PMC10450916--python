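# Methods

## Co-occurrence matrices

`compute_glcm` counts, for every pixel whose offset-neighbor lies inside
the image, the pair (reference level, neighbor level). There is no padding:
pairs straddling the border are dropped, so an image smaller than the
offset is an error (`"ROI too small for offset"`). Angle 0° places the
neighbor `distance` pixels to the right; 45°, 90° and 135° rotate
counter-clockwise in the conventional mathematical sense (45° = up-right).
Diagonal offsets step the unit diagonal `distance` times, i.e. a distance-5
45° offset is (−5, +5) pixels. This differs from scikit-image's
`graycomatrix`, which rounds `distance·sin θ` per axis (its distance-3
diagonal offset is (2, 2)); the two agree at distance 1 and on axis-aligned
angles, which is what the cross-check tests use. With `symmetric=True`
every pair is also counted in reversed order (the matrix equals its
transpose exactly); with `normalized=True` counts are divided by the total
pair count so entries sum to 1.

The default parameters — distance 5 px, 256 gray levels, symmetric,
normalized — are the settings used in the clinical texture-analysis
workflow this package supports. The angle is not part of that published
protocol; the package defaults to 0° (the default of the scikit-image
function family) and optionally averages features over the four angles
(`average_angles=True`, off by default). Averaging is over features, not
matrices.

## Texture features

The seven features are the standard Haralick-style statistics of the
normalized matrix (formulas in the README). Numerical conventions:

* entropy uses the natural logarithm and `0·ln 0 = 0`; its range is
  `[0, 2 ln L]`, maximized by the uniform matrix;
* `energy = sqrt(ASM)` identically, so the two features are monotone
  transforms of each other and their PCA loadings nearly superimpose;
* correlation is defined as 1 when a marginal standard deviation vanishes
  (a constant image is perfectly self-similar — the convention of common
  implementations);
* `dissimilarity ≤ sqrt(contrast)` always (Cauchy–Schwarz on `|i−j|`), a
  relation the property tests enforce on random matrices.

Features are invariant to adding a constant to all pixels (the matrix just
translates along the diagonal) — checked by tests, and the reason overall
echogenicity/gain shifts matter far less than texture for these
descriptors.

## Quantization and image loading

`quantize_image` passes through inputs that are already integers inside
`[0, levels−1]` (8-bit images are never re-stretched) and otherwise
rescales `[min, max]` linearly onto `[0, levels−1]`, rounding halves toward
zero; a constant image maps to zeros. PNG and TIFF load through imageio;
channel-equal RGB collapses losslessly to one channel, true color is
converted with the Rec. 601 luminance before quantization, 16-bit inputs
are rescaled, and unsupported sample types raise rather than truncate.
Single-frame monochrome DICOM is available behind the optional `pydicom`
extra; the supported contract is PNG/TIFF.

## ROI handling and the CSV schema

ROIs are axis-aligned rectangles in 0-based, half-open coordinates with
x = column and y = row, supplied as a CSV table rather than selected
interactively — reproducibility over interactivity. The feature CSV has a
fixed column order (`image_id, x0, y0, x1, y1, plane, side, mineralization,
nodule, lesion_label`, then the seven features, then any extra metadata
columns), UTF-8 with comma delimiter and `.` decimals. Floats are written
with `%.17g` and parsed with pandas' round-trip parser, so the CSV
round-trip is bit-exact. Lesion labels are `normal`, `microlith`
(requires the mineralization flag) and `other` (requires the nodule flag);
duplicate `(image_id, roi)` keys are rejected with the offending row
number.

## PCA

Features are standardized to zero mean and unit variance (sample std,
ddof=1) before the decomposition, i.e. PCA of the correlation matrix. The
choice is forced by the feature scales (contrast ~10², ASM ~10⁻³);
covariance PCA would be a contrast/entropy analysis in disguise. A
zero-variance feature cannot be standardized and raises an error naming
the feature. Components are ordered by decreasing variance with a
deterministic sign convention — the largest-magnitude entry of each loading
column is positive — because PC signs are otherwise arbitrary and
reproducible plots and tests need a fixed orientation. `scores =
standardized data × loadings` holds as an identity, scores are centered,
and loading columns are orthonormal. When a table has fewer records than
features the component count is capped by the rank bound
`min(n_records, n_features)`.

Biplots group scores by any label column (lesion class, plane, age group,
treatment flag) and draw loading arrows scaled by the component standard
deviation (`sqrt(variance_fraction × n_features)` in standardized units);
the raw orthonormal loadings stay in the data structure. Feature
correlation matrices report zero-variance features as NaN, never as 0.

Sagittal and transverse ROIs are pooled as independent observations by
default; the `plane` tag is carried through the table so users can
stratify.

## The synthetic phantom generator

The generator emulates the *texture statistics* of B-mode parenchyma, not
acoustic physics. Homogeneous parenchyma is an i.i.d. Rayleigh envelope
(the classical fully-developed-speckle amplitude model), Gaussian-smoothed
with sigma = `smoothing_radius` to set the speckle correlation length, then
rescaled to a target mean gray level and quantized to 8 bits. Log
compression, beam geometry, attenuation and shadowing are deliberately
omitted — the GLCM features respond to relative local structure, and
adding acquisition physics would add parameters without making the tests
more informative. Defaults: 128 × 128 px, mean gray level 120, Rayleigh
scale 1 (only the distribution shape matters after rescaling), smoothing
sigma 1.5 px.

Lesions:

* **microliths** — non-overlapping bright disks, radius 1–3 px, additive
  gain +120 gray levels clipped at 255, no shadow artifact; per-image count
  drawn from 5–20 in cohorts. Chosen to echo pinpoint-to-small hyperechoic
  foci.
* **septated cyst** — an ellipse whose interior is attenuated to ~12 % of
  the local speckle (near-anechoic) crossed by 0–3 one-pixel bright septa
  through the center.
* **heterogeneous parenchyma** — a smooth multiplicative gain field
  (Gaussian-filtered noise, patch scale 8–16 px, gain 0.55–1.45).

Cohorts default to 245 normal / 16 microlith / 19 other images with mild
per-image jitter of mean level (±8 %) and smoothing radius (±15 %), the
"other" group alternating deterministically between cysts and
heterogeneous fields. Every generator is a pure function of its spec and
seed (per-image seeds are drawn from the master seed), so cohorts —
including the written PNGs and CSV — regenerate byte-identically.

What passing tests on phantoms do and do not show: they verify the
pipeline's *directional* behavior (lesions raise entropy, contrast and
dissimilarity, lower ASM and energy, and separate along PC1 on the
entropy/contrast side) and its determinism. They do not calibrate feature
magnitudes or variance fractions against clinical images — real speckle is
log-compressed, spatially anisotropic and scanner-dependent, and real
lesions are far more varied — so numeric results on phantoms characterize
the phantoms, not tissue.

## Problem sizes

Tests run cohorts of 40 + 40 phantoms at 128 × 128 px for the qualitative
cohort checks and toy cohorts (≈10 images, 64 × 64) for the CLI round
trips; the acceptance script runs the full 280-image cohort at 128 × 128.
These sizes give stable group statistics for directional assertions while
keeping a full run in the order of seconds.

## Known limitations

* Single rectangular ROI per row; no masks or polygonal ROIs.
* One offset per GLCM call (angle averaging aside); no multi-distance
  feature fusion.
* The phantom generator is a texture stand-in, not an ultrasound
  simulator (no shadowing, enhancement, or depth-dependent resolution).
* PCA is exploratory only; no supervised classification or significance
  testing of group separation is provided.
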