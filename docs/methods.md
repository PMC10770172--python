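# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `lesionfuse`, and what the synthetic experiments do and do
not demonstrate.

## Pipeline model

The pipeline assumes a single pigmented lesion per RGB dermoscopic image and
a binary benign/malignant label. It proceeds in two "decks": a baseline CNN
that handles confidently classified samples, and a second, feature-oriented
path for the hard remainder.

The confidence factor of a sample is `|p_benign − p_malignant|` from the
softmax head. The triage threshold defaults to j = 0.999995 with upper bound
k = 1: samples with confidence strictly below j form the Baseline Separated
Channel (BSC); a confidence of exactly j is retained. The threshold encodes a
tolerated 0.05 error ratio among retained samples — the error ratio of a
confidence band is the misclassified fraction of the records inside it, and
`error_ratio_curve` reports it per band, flagging empty bands as undefined
rather than zero. The headline report merges the two ledgers: retained
samples keep the deck-one prediction, BSC samples take the fused-feature
prediction of the configured final classifier (default XGBoost). This merge
convention is a design choice of this package.

## CNN decks

No deep-learning framework is required: `lesionfuse.nn` is a small
self-contained NumPy engine (valid 3×3 convolution, batch normalisation,
2×2 max pooling, inverted dropout, dense layers, softmax/sigmoid heads with
cross-entropy, Adam and Adamax, full backpropagation, all seeded through
`numpy.random.Generator`). Backprop is verified against central finite
differences in the test suite.

Deck one: conv(15)-BN ×2, pool, dropout 0.2, conv(15)-BN, pool, dropout,
conv(15)-BN, pool, flatten, dense(100)-ReLU, dropout, dense(2)-softmax;
Adam, lr 0.001, batch 40, binary cross-entropy. Deck two: conv 32, 64, pool,
128, pool, 256, pool, then dense 256-128-64-32-2 with a 2-unit sigmoid head
(prediction = argmax of the two sigmoids), Adamax. The 64-unit dense layer's
post-ReLU activations are the bottleneck features (length 64, non-negative).

The textbook pooling-size expression `(n − f + 1)/L` is non-integral for a
2×2/stride-2 pool; the layer stack uses the standard `⌊(n − f)/L⌋ + 1`, and
`pool_output_size(literal=True)` exposes the literal form for reference.
Default training budgets in this package are desk-scale (tens of epochs at
32×32 inputs); the architecture, not the budget, is the fixed part.

## Hair removal

Detection: BT.601 luma → morphological black-hat (17×17 square closing minus
image) → threshold 10 on the 0–255 response. The black-hat transform also
responds at any dark feature narrower than its kernel — tapering lesion
tips, thin dark pigment regions pinched between colour tones — so the raw
mask is refined by a hair-shape filter: a connected component is kept only
if its bounding-box extent is ≥ 20 px (hairs are long strokes), and regions
wider than 2×4 px (found by a disk-opening and dilated back to their rim)
are excluded pixel-wise, so a hair crossing a wide dark blob keeps its thin
run while the blob is left untouched. Without the width exclusion, dark
pigment structures get "repaired" into their surroundings, which *increases*
the reconstruction error on variegated lesions.

Inpainting: the image is tiled into ⌊N/p⌋×⌊M/p⌋ patches (p = 16, row-major,
the last patch absorbing the remainder); a patch with no hairy pixel
terminates immediately. Each masked pixel becomes the weight-normalised sum
of the *unmasked* pixels within radius 5, with Gaussian weights
(scale 2.5 px) decreasing in Euclidean distance; if no clean neighbour
exists the radius is doubled up to 4× before an error is raised. Every
filled value is therefore a convex combination of clean neighbours (no new
extremes), and unmasked pixels are returned bit-identical. The Gaussian
weight function and row-major patch traversal are this package's choices;
only the normalised distance-weighted principle and the patch tiling are
fixed by the method.

## Clinical scores

Segmentation: grayscale → Otsu threshold (`skimage.filters.threshold_otsu`;
equivalent to the exhaustive 256-bin inter-class-variance maximiser, which
the tests check independently) → lesion = darker class → 3×3 binary dilation
then erosion → largest connected component → crop to the occupancy region
with a 20% margin. The crop defines the affected/unaffected frame for A, so
A is invariant to image padding. A as implemented is an area ratio
(`a_aff/a_non_aff`, ×100/10), not a left/right reflection asymmetry — that
is the score's printed form and is kept literally.

Perimeter: arc length of the marching-squares 0.5-level contour after
Douglas–Peucker simplification with tolerance 1 px. The simplification is
load-bearing: the raw staircase contour overestimates a disc's perimeter by
~5% (inflating B = p²/(4πa)/10 by ~10%), while Crofton-style estimators
undercount square corners by a similar margin. With DP simplification,
rasterised discs of radius 30–100 give B = 0.100–0.101 and squares
0.1252–0.1265 against the 0.4/π ≈ 0.1273 closed form. A pixel-count
perimeter remains available (`perimeter_method="pixel_count"`) but breaks
the isoperimetric identity by design. The mask is zero-padded by one pixel
before contour extraction so regions that touch or fill the frame still
close.

C pools all three HSV channels: channels are normalised to [0,1]
(hue = degrees/360), the pooled std is `sqrt(mean of the per-channel
variances)`, divided by 10. Pooling three channels (rather than one) is a
documented default; the score is unitless either way. E is the mean absolute
relative change of area and of B between the first and last frame of a
temporal series and defaults to 0 for the ordinary single-image pipeline.

## Flag features

Per-pixel features: F7 is the grey-blue indicator — hue ∈ [185°, 255°],
saturation ∈ [0.15, 0.65], value ∈ [0.25, 0.75]; F13 is the local
pigment-network response — variance of a σ = 1 Laplacian-of-Gaussian in a
5×5 window, normalised per image to [0,1]. These two definitions are this
package's defaults (the feature names refer to an external numbering whose
formulas are not public); both feed an optional depth-≤3 Gini decision tree
trainable on the generator's per-pixel veil labels, with the F7 rule as the
shipped fallback. The raw veil mask is smoothed by a 3×3 strict-majority
filter (window clipped at borders, tie → 0).

S_Flag2 uses the mean/std of centroid-to-boundary distances; an
all-equidistant boundary (relative std below 1e-9) returns a +infinity
sentinel rather than raising, and fusion caps the sentinel at 1e6. S_Flag3
folds the affine moment invariant `M = (μ20μ02 − μ11²)/μ00⁴` through
`16π²M` / its reciprocal, so any ellipse scores 1 and every value lies in
[0,1]. A literal third/fourth-order variant `(μ30μ03 − μ11²)/μ04⁴` is kept
behind `literal=True`; it is ≤ 0 for every centrally symmetric shape and
therefore cannot grade ellipticity — it exists for comparison only, and the
second-order invariant is the default.

## Augmentation and balancing

Rotations default to the lossless fixed set {180°, 270°, 360°} (90°
multiples, no interpolation); a `uniform_range` mode draws continuous angles
in ±45° by default. Noise is zero-mean Gaussian with variance 0.05 on
[0,1]-scaled intensities, clipped. Balancing only ever augments the minority
group to parity (originals are never dropped) and tags every synthetic
sample with its source id and transform string; the balancing axis is the
class label by default, with a `hairy` option.

## Classifiers and evaluation

Defaults: gradient boosting 20 estimators / lr 0.1 / log-loss; bagging over
10 seeded decision trees; XGBoost 100 estimators with η = 0.1; Gini decision
tree; sigmoid-kernel SVM; logistic regression; MLP with hidden stack
512-256 (the preset `prose` swaps in three 64-unit layers). Malignant is the
positive class throughout; specificity is recall on benign. Zero-denominator
metrics are reported as undefined flags, never coerced to 0. AUC comes from
a threshold sweep over unique scores with trapezoidal integration, which
equals Mann–Whitney pair counting with ties at ½ (checked to 1e-12).
Cross-validation is stratified k-fold; when k exceeds the minority-class
count (e.g. leave-one-out) it falls back to plain shuffled k-fold, since
stratification is impossible there.

Before classification, the clinical columns are min–max scaled with
parameters fit on the training split only; bottleneck activations are left
unscaled. The flag ablation trains every classifier twice on one identical
stratified 70:30 split — full features vs flag columns dropped — and
reports per-classifier Spec_with − Spec_without in percentage points.

## Synthetic data: what it emulates, what it does not

The generator renders elliptical lesions (waved borders, half-plane
asymmetry removal, 1–5 brown/black tones by nearest-seed regions) on a flat
skin tone with σ = 2.5 Gaussian texture, an optional contiguous grey-blue
veil patch covering an exact pixel fraction of the lesion (hue 185–255°,
saturation 0.2–0.6, value 0.3–0.7 — inside the F7 band by construction), and
dark quadratic-Bézier hair strokes 1–3 px wide with intensity ≤ 60. Each
sample carries exact lesion/veil/hair masks plus the hair-free render. All
randomness flows through one seeded generator per call.

Dataset-level defaults encode the class signal the clinical features
measure: malignant draws are larger, more asymmetric (bias 0.2–0.5), wavier
(amplitude 2.5–5 px), more variegated (3–5 tones) and veiled (fraction
0.15–0.5); benign draws are smaller, smoother, and veil-free. The
`bwv_only` mode instead matches the shape/size/colour distributions between
classes and carries the label exclusively in a *subtle* veil (fraction
0.05–0.18 of the lesion). The subtlety is deliberate: a veil covering half
the lesion is trivially absorbed by any image model, whereas the regime in
which a dedicated veil feature adds information over a briefly trained CNN
bottleneck — the regime the ablation study probes — is a small patch that
per-pixel colour rules resolve cleanly.

What passing tests show: each stage satisfies its stated contract on inputs
whose ground truth is known exactly, the shape scores reproduce their
closed forms, and the flag features carry recoverable information end to
end. What they do not show: performance on real dermoscopy — the generator
has no specular highlights, gel bubbles, ruler marks, vignetting, skin
lines, or the gradual pigment transitions of real lesions, and its veil is
colourimetrically ideal. Benchmarks on clinical archives require the real
datasets and full-scale training, which are outside this package's scope.

## Study sizes

The shipped experiments run at desk scale, chosen so the whole suite and the
acceptance script complete in minutes on one CPU: hair-removal efficacy over
100 lesions at 128², veil recovery over 50 lesions, and the flag ablation
over 600 samples at 64² with the deck-two CNN trained 3 epochs at 32² input
(well under the architecture's nominal budgets). Larger runs only sharpen
the same statistics.

## Known limitations

- The baseline deck needs ≥ 32 px inputs to survive its three pooling
  stages; smaller images must be upsampled.
- Hair detection assumes hairs darker than their background and ≥ 20 px
  long; light (blonde) hair and short stubble are not modelled.
- `ClinicalScaler` min–max scaling is sensitive to train-split outliers in
  S_Flag2 (capped at 1e6 for degenerate circles).
- The per-pixel veil rule is colourimetric only; a veil outside the F7 band
  (or heavy colour casts) requires retraining the decision tree.
- Ensemble learners consume feature-count-dependent RNG streams, so adding
  even constant columns can perturb their fitted trees; exact
  ablation-neutrality of constant flags holds for the plain decision tree
  and XGBoost.
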