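# Methods

This note documents the models implemented in `bcdnet`, their assumptions,
the tunable parameters that matter, and the design choices made where the
problem was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Phantom generator

The generator emulates single 2-D breast-MRI-like slices:

* **Background**: seeded white noise blurred with a Gaussian
  (`background_smoothness`, default σ = 6 px) and min-max rescaled to
  [40, 160] — a smooth, featureless "anatomy" on the 0–255 scale.
* **Lesion**: one filled ellipse per lesion-bearing slice, semi-axes drawn
  uniformly from `lesion_axis_range` (default 8–18 % of the image side),
  random center (constrained fully inside the frame) and orientation. The
  lesion adds an intensity offset plus a sinusoidal texture. Benign
  lesions get offset `benign_offset` (20) at `texture_frequency` (0.15
  cycles/px); malignant lesions add `class_contrast` (60) on top and double
  the texture frequency. With the default `benign_lesion=True` both
  classes carry lesions (so shape, texture and intensity all carry class
  signal); `benign_lesion=False` models a sick-vs-healthy screening task.
* **Noise**: additive Gaussian (default σ = 5) or Rician, implemented as
  the magnitude of (signal + n₁) + i·n₂ with iid Gaussian components, the
  standard model for MRI magnitude images. Noise is added last; values are
  clipped to [0, 255].

What the phantom does **not** model: 3-D structure, DCE time series,
realistic fibroglandular anatomy, partial-volume effects, intensity
inhomogeneity fields, or the texture families of real tumors. Passing
tests on phantoms demonstrates that each mechanism works and that the
composed pipeline can recover a known signal; it says nothing about
clinical performance on real MRI.

## Adaptive Kalman filter

Per scanline, a scalar random-walk Kalman filter (state = true intensity,
measurement = pixel) whose measurement variance is re-estimated every
pixel as `max(mean of last λ squared innovations − predicted state
variance, ς_min)`. The window warms up with however many innovations
exist; negative estimates (possible on quiet stretches) are clamped at
`ς_min = 1e−6`, which keeps the gain in [0, 1]. Initialization:
state = first pixel of the line, state variance = global image variance.
Default `passes="bidirectional"` averages a forward and backward pass per
row, cancelling the causal lag; `"single"` keeps the plain recursion for
exact hand-checking.

The process variance `q` is the one consequential tunable. It is the
squared intensity step the true image is allowed per pixel: too small and
the filter cannot follow anatomical gradients (the lag bias exceeds the
noise removed), too large and it passes noise through. The default
(q = 50, i.e. ≈ 7 intensity units per pixel on the 0–255 scale) tracks
both the smooth background and lesion edges of phantom-like images.

## Jellyfish search optimizer

Box-constrained minimization with a population of candidate vectors.
Per iteration and candidate, a time-control value
ξ = |(1 − t/N)(2r − 1)| decides the move: ξ ≥ x₀ (0.5) → ocean-current
drift `J + r₂ (J* − η r₁ ℓ)` toward the incumbent J* (ℓ = population
mean, η = 3); otherwise a swarm move — passive (`J + χ r (U − L)`,
χ = 0.1) early, active (a step toward a better random peer) increasingly
often as t → N. Initial positions come from a per-dimension logistic map
(β = 4) seeded away from its degenerate points {0, ¼, ½, ¾, 1}; all moves
are hard-clipped to the box.

A candidate move is **accepted only if it improves that candidate's
fitness** (greedy replacement, as in the algorithm's original
formulation). This is essential, not cosmetic: without it the swarm
collapses onto the incumbent and freezes, and the late-phase passive
jitter — which under greedy acceptance acts as a per-candidate local
refinement search — only burns evaluations. The incumbent best is tracked
separately, so the per-iteration history is non-increasing by
construction and the final best equals the minimum over all evaluations.

## Pyramid-pooling segmenter

A deliberately small network: 3×3 conv stages (default channels 6→8 in
the tiny preset, 8→16 in the default) with ReLU and a per-channel affine
scale/shift in place of batch normalization — the optimizer is
gradient-free and population statistics are unavailable, so only the
learnable affine terms are kept — and 2× average pooling between stages.
The pyramid module pools the final feature map to s×s bins for each scale
(adaptive averaging over an equal partition), applies a 1×1 conv + ReLU
per branch, upsamples bilinearly and concatenates with the pre-pooling
map; a 1×1 conv + sigmoid head, bilinearly upsampled to the input size,
emits the probability map. With all parameters zero the output is exactly
sigmoid(0) = 0.5 everywhere, a useful algebraic anchor for tests.

All parameters form one flat vector (a documented fixed layout:
per-stage conv weight/bias then affine scale/shift, then pyramid convs by
scale, then the head) bounded to [−B, B] with B = 2; training minimizes
the mean per-pixel squared mask error by jellyfish search. A parameter
cap (5000) guards against architectures too large for gradient-free
training; the tiny preset has 597 parameters. Training cost is dominated
by forward passes, which vectorize over the image batch.

## Augmentation

Rotation (2-D rotation about the image center; bilinear for intensities,
nearest for masks, zero fill; right-angle multiples are exact index
permutations), one random square erase per copy (side a fraction of the
image side, fully in-frame; fill zero/mean/random), and exact flips
(vertical / horizontal / both, the latter ≡ 180° rotation). Geometric
operators transform image and mask identically; erasing leaves the mask
untouched because it models occlusion of appearance, not anatomy. Labels
are always preserved, and the evaluation harness augments training folds
only, after splitting.

## Feature bank

* **Gabor**: complex kernels
  `(f²/πωℵ) exp(−(f²/ω²)x′² − (f²/ℵ²)y′²) exp(j2πfx′)` with the standard
  rotated frame x′ = x cos θ + y sin θ, y′ = −x sin θ + y cos θ (the
  degenerate printed form of y′ lacking an x term is treated as a typo);
  magnitude responses under reflect padding, kernel size covering three
  envelope standard deviations. Defaults: f ∈ {0.1, 0.2, 0.3, 0.4},
  θ ∈ {0°, 45°, 90°, 135°}, ω = ℵ = 1.
* **LBP**: 8-bit sign codes against the center pixel, neighbor order
  starting East and proceeding counter-clockwise, sign(0) = 1, borders 0.
* **LVP**: per direction ħ, first-order derivative fields along ħ and
  ħ+45°, combined through the comparative-space ratio transform (slope
  defined as 0 where the ħ-derivative vanishes) into 8-bit codes; radius
  1, 8 neighbors.
* **Shape** (largest connected component): compactness P/A with P the
  crack (inter-pixel edge) perimeter — the ratio is kept as P/A, not the
  conventional P²/A; eccentricity as moment-ellipse major/minor axis
  ratio (degenerate 1-px-thin regions floor the minor axis at one pixel);
  rectangularity A/eccentricity; solidity A/convex-hull-area.
* **Statistics**: each texture map is min-max scaled to integer levels
  0..E−1 (E = 256) and histogrammed; mean, variance, SD and
  skewness/kurtosis normalized by the 3rd/4th power of the **mean** — the
  source formulas are kept even where unconventional (the usual
  normalization is by powers of the SD), with both defined as 0 when the
  mean is 0. A constant map is a degenerate histogram at its value:
  (c, 0, 0, 0, 0).

Fidelity to the source formulas over field conventions is deliberate
throughout and documented here so the independent histogram oracle in the
tests is exact. The assembled vector is 5 statistics × (16 Gabor + 1 LBP
+ 4 LVP) maps + 4 shape features = 109 entries, in a fixed order; a
7-channel stacked feature image (original, LBP, 4×LVP, mean Gabor
magnitude) is kept for the classifier's convolutional branch.

## Classifier and loss

Dual-branch input: a small conv stack (two 3×3 conv + ReLU + 2× avg-pool
stages, global average pooling) over the stacked feature image, and/or a
one-hidden-layer dense branch over the z-scored 109-vector; features
concatenate (plus a bias unit) into the softmax output layer G. Either
branch can be disabled; the end-to-end pipeline uses the dense branch
only, since at phantom scale the scalar features carry the signal and the
conv branch adds cost without benefit (it is exercised separately by its
own tests).

The loss is cross-entropy weighted by the ambiguity (t_max − t_ε), the
weight treated as a detached constant during differentiation so that
∇ = t(t_max − t_ε) − (t_max − t)·t̃ = (t_max − t_ε)(t − t̃) is the exact
gradient (verified against central finite differences). Two consequences
shape training:

1. the loss has a second zero at the *uniform* prediction, and
2. gradient magnitudes carry the vanishing ambiguity weight, so samples
   approaching the decision boundary from the wrong side take
   geometrically shrinking steps.

Step sizes must therefore be generous for samples to actually cross the
boundary; the default learning rate is 3 (30 on low-dimensional toy
problems), far larger than typical for plain cross-entropy.

Output-layer update: one step per epoch from the epoch-mean loss e_i and
epoch-mean gradient. With at least two recorded past errors the CAViaR
recursion blends the two lagged weight matrices and their gradients with
coefficients φ₁ = e_i/e_{i−1}, φ₂ = e_i/e_{i−2}, each clamped to
[0, φ_max = 10] (a zero lagged error makes the ratio φ_max — similarity
undefined means maximal weight) and normalized to sum to 1; a constant
φ₀ (default 0) is added. The recursion as printed in its source defines
g^{i−1} in terms of itself and never defines F(·); the forward reading
implemented here — a convex blend of the two lags minus the blended
lagged gradients, F = lagged gradient — is the stable interpretation, and
the raw unnormalized variant remains available behind
`normalize_ratios=False`. With fewer than two past errors the update is a
plain gradient step. Interior layers take a plain SGD step per minibatch
through the same loss. e_i is the epoch-mean training loss.

## Evaluation

Accuracy (TP+TN)/N, sensitivity TP/(TP+FN), specificity TN/(TN+FP), with
explicit errors on empty or one-class evaluations. The K-fold harness
shuffles with a fixed seed, stratifies whenever each class has at least K
members (plain shuffled folds beyond that, e.g. leave-one-out), and
applies augmentation inside the training folds only.

## Pipeline and problem sizes

`run_pipeline` chains: AKF → stratified train/test split (default ⅓
test) → segmenter training by jellyfish search on a 16-image subsample of
the training split (population 15, 80 iterations by default) → mask
prediction for every sample → augmentation of the training split (1 copy
per image) → feature extraction (texture maps from the filtered image,
shape from the predicted mask; an empty predicted mask contributes zero
shape features) → classifier training → confusion-matrix metrics on the
held-out split. One global seed fans out to per-stage child seeds by
fixed offsets, so each stage is independently reproducible.

The study-scale experiment used throughout (tests and acceptance script)
is 300 default phantoms — 200 train / 100 test; the segmenter quality
benchmark trains the 597-parameter tiny preset on 8 32×32 phantoms with
population 20 for 300 iterations. These sizes were chosen so that every
mechanism is exercised at a scale where its effect is measurable while a
full verification run stays in the minutes range on one CPU.

## Known limitations

* Scanline (1-D) Kalman filtering is directional; the bidirectional
  average removes lag but not the row-wise anisotropy of residual noise.
* Gradient-free training limits the segmenter to a few thousand
  parameters; the architecture is a faithful miniature of the
  pyramid-pooling design, not a competitive segmentation model.
* The ambiguity-weighted loss never builds confident margins (correct
  samples stop contributing immediately), so predicted probabilities
  hover near 0.5 even when labels are right; calibration is out of scope.
* Phantom realism limits (above) apply to every quantitative claim.
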