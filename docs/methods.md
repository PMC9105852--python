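# Methods

`roitone` implements a family of grey-level tone-curve corrections for small
B-mode ultrasound regions of interest (ROIs), together with the complete
experimental machinery needed to measure whether such corrections help a
classifier distinguish normal from cirrhotic liver tissue: a shallow
convolutional network, classical baseline classifiers, a repeated
stratified-holdout error estimator, parameter sweeps and cross-validated
parameter selection, and a synthetic speckle ROI generator that stands in
for clinical data.

## Tone-curve operators

Eight pixel-wise transfer functions map an input grey level `f ∈ [0, fmax]`
to an output `g` in the same range (`fmax = 2^b − 1`; 255 for 8-bit, 4095
for 12-bit):

| type | g(f) | parameter |
|------|------|-----------|
| 0 | `f` | — |
| I | `0 if f < t else f` | `t ∈ [0, fmax]` |
| II | `0 if f < t else fmax·(f−t)/(fmax−t)` | `t ∈ [0, fmax−1]` |
| III | `fmax·(f/fmax)^(1/γ)` | `γ > 0` |
| IV | `fmax − f` | — |
| V | `fmax − f if f < t else 0` | `t ∈ [0, fmax]` |
| VI | `fmax·(1 − f/t) if f < t else 0` | `t ∈ [1, fmax]` |
| VII | `fmax·((fmax−f)/fmax)^(1/γ)` | `γ > 0` |

Types I–III enhance contrast by suppressing or stretching the dark end;
IV–VII are their intensity-inverted counterparts, which highlight dark
structure instead.  Useful algebra, all enforced by tests: type 0, I(t=0),
II(t=0) and III(γ=1) are the identity; IV is an involution; V(t=fmax) and
VII(γ=1) equal IV.

Numerical choices, made here because the transfer formulas alone do not fix
them:

- **Quantisation.** Formulas are evaluated in real arithmetic, rounded
  *half away from zero*, then clipped to `[0, fmax]`.  Round-half-away is
  symmetric and keeps golden values stable across platforms (numpy's
  default round-half-even would differ at e.g. type VI, t=200, f=100).
- **Threshold strictness.** All threshold branches are strict `f < t`; the
  boundary `f == t` falls in the "otherwise" branch.
- **Degenerate parameters.** Type II rejects `t = fmax` (zero denominator)
  and type VI rejects `t = 0` (zero divisor) at construction instead of
  defining a limit; the standard parameter grids never touch these values.
- **Gamma at the endpoint.** `0^(1/γ)` is taken as 0 for all `γ > 0`
  (continuity of the power function).

Each operator is compiled once into a lookup table (LUT) of `fmax + 1`
entries and applied to images by indexing, which is exactly equivalent to
per-pixel formula evaluation and much cheaper; the equivalence is asserted
exhaustively (every type, every grid parameter, both bit depths, every
input level) against an independent scalar oracle.

## Shallow CNN

The classifier is the small network appropriate to a few hundred training
images: `conv(32 filters, 3×3, same padding) → ReLU → 2×2 max-pool`, twice,
taking a 32×32 single-channel input to 32 maps of 8×8; then
`flatten(2048) → dense(100) → ReLU → dropout(0.5) → dense(2) → softmax`.
Training minimises softmax cross-entropy with Adam (learning rate 0.001,
β₁ = 0.9, β₂ = 0.999) for 100 epochs at batch size 400 — with 400 training
images that is full-batch descent.  Inputs are scaled to `[0, 1]` by
division by `fmax` and nothing else, so tone-curve effects reach the
network undiluted (per-image standardisation would cancel much of what the
corrections do; this interaction is why the scaling rule is fixed here).

The network is implemented directly in numpy: shift-accumulate convolution
(nine small matmuls against slices of the padded input), argmax max-pooling
with first-index tie-breaking, inverted dropout, and standard
bias-corrected Adam.  Everything is float32 and bit-deterministic under the
config seed; analytic gradients are verified against central differences in
float64.  Design points the architecture description leaves open, fixed
here: same-size convolution padding (forced by the 32→16→8 shape
sequence), dropout placed between the hidden and output layers, and He
initialisation from the seeded generator.

**Scaled-down protocol.** Synthetic end-to-end runs (tests, acceptance
script, examples) use 3–5 trials and 30 epochs at minibatch 50 instead of
10 trials × 100 full-batch epochs.  Minibatching is what makes a 30-epoch
budget meaningful: 30 full-batch steps barely move Adam at lr 0.001,
whereas 30 × 8 minibatch steps train the net to its plateau on these
synthetic tasks.  Parameter selection inside the acceptance script uses a
further-reduced 10-epoch schedule.

## Synthetic ROI generator

No clinical ROI data is distributable, so the generator emulates the
documented structure of such a dataset: 200 normal + 300 cirrhosis patches,
32×32 at 8 bits, cirrhosis slightly lighter than normal, both covered in
multiplicative speckle.  A pixel is

    clip(round(class_mean · G · S), 0, fmax)

where

- `S` is the pixel-scale speckle field: a standard Rayleigh field
  standardised to mean 1 and standard deviation `speckle_scale`
  (default 0.3), then smoothed with a Gaussian kernel of width
  `correlation_sigma` pixels (default 1.0) so speckle grains have finite
  extent.  Standardising the Rayleigh draw is deliberate: a Rayleigh field
  rescaled only to unit mean has a fixed coefficient of variation
  (~0.52), leaving no dispersion knob.
- `G` is a per-image gain factor, Rayleigh-derived the same way with
  dispersion `gain_scale` (default 0.15).  It is the zero-frequency
  component of the speckle and emulates patient-to-patient and depth/gain
  brightness variability.  It is also what keeps the default task honest:
  without it, the mean over ~1000 pixels concentrates so sharply that a
  20-grey-level class gap is trivially separable and every classifier
  scores ~0%.  With it, default per-image mean brightness spreads ±13–17
  grey levels around class means of 90 (normal) and 110 (cirrhosis), and
  the CNN's holdout error on the default dataset sits near 30% — hard but
  clearly better than the 40% majority-class rate.
- Class means default to `mu_normal = 90`, `mu_cirrhosis = 110`; the
  magnitude of "slightly lighter" is not documented anywhere, so the gap is
  a fixture parameter, not an estimate.  An optional per-class
  `correlation_sigma_cirrhosis` adds a texture difference; it is off by
  default so the minimal mean-only structure is the baseline.

What the generator does *not* model: point-spread functions, attenuation,
depth-dependent focus, scan conversion, or any pathology-specific texture
signature.  Passing tests on this data show the pipeline measures what it
claims to measure (and that the CNN can exploit a planted contrast); they
say nothing about clinical error rates.

## Holdout protocol and statistics

Each trial splits the dataset per class without replacement — 160/240
train, 40/60 test for the default 200/300 dataset — applies the tone curve
under study to both halves, trains a fresh classifier on the corrected
training images, and scores the percentage of misclassified corrected test
images.  The summary over `n` trials (default 10) is the arithmetic mean
and the Student-t 95% half-width `t_{0.975, n−1} · sd / √n`.

- **Paired design.** All methods in an experiment run on byte-identical
  splits, enforced by a SHA-256 split hash; method comparison is a paired
  two-sided t-test on per-trial error differences.  (Whether the original
  protocol shared splits across methods is not documented; pairing is the
  stronger design and is enforced here.)  Zero-variance differences are
  reported as p = 1 (all zero) or p = 0 (constant nonzero — below any
  representable tail probability) rather than NaN.  An unpaired Welch
  fallback exists behind an explicit flag.
- **Seeding.** The base seed drives per-trial split generation through
  spawned seed sequences, and per-trial classifier seeds through a separate
  stream, so adding a method to an experiment never perturbs existing
  splits or results.
- **Parameter selection** follows the deployment recipe: candidates for
  `t` or `γ` are scored by stratified 3- or 5-fold cross-validated mean
  error and the argmin is returned, ties to the smaller parameter value.

## Baselines

k-NN (k = 1, 3, 5, Euclidean), linear SVM (C = 1), LDA and a 100-tree
random forest consume the identical row-major 1024-vector flattening,
scaled by `1/fmax` like the CNN input, so error differences are
attributable to the classifier.  LDA uses the SVD pooled-covariance
solver, which remains well-defined when 1024 features exceed the sample
count and the pooled covariance is singular.  SVM and k-NN hyperparameters
beyond those listed are the library defaults.

## Known limitations

- Clinical error rates cannot be reproduced here; all reported numbers are
  properties of synthetic data and of the machinery itself.
- The CNN is CPU-bound numpy; it is sized for 32×32 patches and a few
  hundred images, not for larger studies.
- The speckle model is first-order (multiplicative, spatially smoothed);
  classes differing only in texture statistics of higher order would not be
  represented by the default generator.
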