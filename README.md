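# bcdnet

A desk-scale, fully tested implementation of a breast-MRI lesion detection
pipeline: **adaptive Kalman denoising → jellyfish-search-trained
pyramid-pooling segmentation → geometric augmentation → a five-family
feature bank → a compact classifier trained with an adaptive
error-similarity loss**. Every stage runs on synthetic breast-MRI-like
phantom slices with known ground truth, so the whole chain is verifiable
on a laptop CPU without downloading any clinical dataset.

It is aimed at researchers who want to study the individual mechanisms of
such pipelines — innovation-adaptive Kalman filtering, gradient-free
metaheuristic training of a segmentation network, hand-crafted texture
descriptors, and ambiguity-weighted loss design — in isolation and in
composition, with reproducible seeds and quantitative checks.

## The methods in brief

**Adaptive Kalman filter (AKF).** Each scanline is a scalar random-walk
state x observed through identity measurements z (the pixels). The
measurement-noise variance is re-estimated at every pixel from the last
λ innovations ν:

    ς = max( (1/λ) Σ ν²  −  P ,  ς_min )

where P is the predicted state variance. Pixels inconsistent with the
local model inflate ς and are down-weighted by the Kalman gain
K = P/(P+ς) instead of corrupting the estimate.

**Pyramid segmenter + jellyfish search (JSO).** A small encoder feeds a
pyramid module that adaptively average-pools the feature map at bin counts
{1, 2, 3, 6}, reduces each branch with a 1×1 convolution, upsamples and
concatenates with the pre-pooling features, then a sigmoid head emits a
lesion probability map P_b. All parameters Ψ live in one flat vector
trained by jellyfish search — a population metaheuristic alternating
ocean-current moves toward the incumbent best with passive/active swarm
moves under a decaying stochastic time control — minimizing the mean
squared mask error F = (1/o) Σ_b mean[(T_b − P_b)²].

**Feature bank.** Gabor magnitude maps at 4 frequencies × 4 orientations,
local binary patterns (LBP), and local vector patterns (LVP) at
0°/45°/90°/135°; 5 histogram statistics (mean, variance, SD, skewness,
kurtosis) per texture map; and 4 mask shape features (compactness P/A,
moment-ellipse eccentricity, rectangularity, solidity) — a 109-entry
vector per sample.

**Classifier.** Softmax probabilities t; the loss weights cross-entropy by
the ambiguity of a sample,

    loss = −(t_max − t_ε) · log t_ε ,     ∇ = (t_max − t_ε)(t − t̃),

so confidently-correct samples contribute exactly nothing and hard
samples dominate. The output-layer weights follow a CAViaR-style
recursion blending two lagged weight copies with coefficients derived
from ratios of the last three epoch errors; interior layers use plain SGD.

## Worked example

```python
from bcdnet import PhantomSpec, generate_dataset
from bcdnet.pipeline import PipelineConfig, run_pipeline

samples = generate_dataset(PhantomSpec(seed=0), 150)   # 300 slices, balanced
report = run_pipeline(PipelineConfig(seed=0), samples=samples)
print(f"accuracy    {report.accuracy:.3f}")
print(f"sensitivity {report.sensitivity:.3f}")
print(f"specificity {report.specificity:.3f}")
```

prints

```
accuracy    0.930
sensitivity 0.960
specificity 0.900
```

i.e. on 100 held-out phantoms (50 benign / 50 malignant) the full chain —
denoising, segmenter trained by jellyfish search on 16 training images,
augmentation of the 200 training slices, feature extraction and
classification — recovers 93% of labels, detecting 96% of malignant
lesions at a 10% false-positive rate.

The same flow is available from the shell:

```bash
bcdnet simulate --out data --n-per-class 150 --seed 0
bcdnet run --manifest data/manifest.csv --seed 0 --out results/
```

with `preprocess`, `segment`, `augment`, `featurize`, `train` and
`evaluate` subcommands exposing the individual stages.

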