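"""Pyramid-pooling lesion segmenter trained by jellyfish search.

A deliberately small pyramid-scene-parsing network: a 2-stage convolutional
encoder feeds a pyramid module that adaptively average-pools the feature
map at several bin resolutions (default 1, 2, 3, 6), reduces each pooled
map with a 1x1 convolution, upsamples it bilinearly back to the feature-map
size and concatenates all branches with the pre-pooling features — mixing
local detail with global context — before a 1x1 sigmoid head produces a
per-pixel lesion probability map at the input resolution.

All learnable parameters (conv weights/biases and per-channel affine
scale/shift "batch-norm" terms) live in one flat vector, which is exactly
the solution encoding the jellyfish search optimizer tunes: training
minimizes the mean squared error between the probability map and the
ground-truth mask over the training samples. Because the optimizer is
gradient-free, normalization layers carry no running batch statistics —
only the learnable affine terms.

Everything is plain numpy; the forward pass vectorizes over a batch of
images and over a population of candidate parameter vectors evaluated one
at a time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator

from .imageio import GrayImage
from .jellyfish import JsoConfig, JsoResult, optimize
from .phantom import LabeledSample

__all__ = [
    "SegArchitecture",
    "parameter_count",
    "forward",
    "fitness",
    "train_with_jso",
    "binarize",
    "dice_coefficient",
    "PyramidSegmenter",
    "TINY_ARCH",
    "SMALL_ARCH",
]


@dataclass
class SegArchitecture:
    """Architecture descriptor; fully determines the parameter layout.

    encoder_channels: channels of the 3x3 conv stages (2x average pooling
    between stages). pyramid_scales: strictly increasing bin counts of the
    adaptive pooling branches. reduction_channels: output channels of each
    branch's 1x1 conv. input_size: square input resolution in pixels.
    """

    encoder_channels: tuple[int, ...] = (8, 16)
    pyramid_scales: tuple[int, ...] = (1, 2, 3, 6)
    reduction_channels: int = 4
    input_size: int = 64

    def __post_init__(self) -> None:
        self.encoder_channels = tuple(int(c) for c in self.encoder_channels)
        self.pyramid_scales = tuple(int(s) for s in self.pyramid_scales)
        if any(c < 1 for c in self.encoder_channels) or not self.encoder_channels:
            raise ValueError("encoder_channels must be a nonempty list of positive ints")
        if any(s < 1 for s in self.pyramid_scales) or not self.pyramid_scales:
            raise ValueError("pyramid_scales must be positive")
        if list(self.pyramid_scales) != sorted(set(self.pyramid_scales)):
            raise ValueError("pyramid_scales must be strictly increasing")
        if self.reduction_channels < 1:
            raise ValueError("reduction_channels must be >= 1")

    @property
    def concat_channels(self) -> int:
        return self.encoder_channels[-1] + len(self.pyramid_scales) * self.reduction_channels


# ~600-parameter preset used for desk-scale gradient-free training.
TINY_ARCH = SegArchitecture(encoder_channels=(6, 8), pyramid_scales=(1, 2, 3),
                            reduction_channels=2, input_size=32)
SMALL_ARCH = SegArchitecture()


def _layout(arch: SegArchitecture) -> list[tuple[str, tuple[int, ...]]]:
    """Documented fixed ordering of the flat parameter vector."""
    shapes: list[tuple[str, tuple[int, ...]]] = []
    in_ch = 1
    for i, out_ch in enumerate(arch.encoder_channels):
        shapes.append((f"enc{i}.weight", (out_ch, in_ch, 3, 3)))
        shapes.append((f"enc{i}.bias", (out_ch,)))
        shapes.append((f"enc{i}.bn_scale", (out_ch,)))
        shapes.append((f"enc{i}.bn_shift", (out_ch,)))
        in_ch = out_ch
    for s in arch.pyramid_scales:
        shapes.append((f"pyr{s}.weight", (arch.reduction_channels, in_ch)))
        shapes.append((f"pyr{s}.bias", (arch.reduction_channels,)))
    shapes.append(("head.weight", (1, arch.concat_channels)))
    shapes.append(("head.bias", (1,)))
    return shapes


def parameter_count(arch: SegArchitecture) -> int:
    return int(sum(np.prod(shape) for _, shape in _layout(arch)))


def _unpack(theta: np.ndarray, arch: SegArchitecture) -> dict[str, np.ndarray]:
    theta = np.asarray(theta, dtype=np.float64).ravel()
    expected = parameter_count(arch)
    if theta.size != expected:
        raise ValueError(f"parameter vector length mismatch: expected {expected}, got {theta.size}")
    params = {}
    pos = 0
    for name, shape in _layout(arch):
        n = int(np.prod(shape))
        params[name] = theta[pos:pos + n].reshape(shape)
        pos += n
    return params


def _conv3x3(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution; x is (B, C, H, W), weight (O, C, 3, 3)."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    windows = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (B, C, H, W, 3, 3)
    return np.einsum("bchwij,ocij->bohw", windows, weight, optimize=True) + bias[None, :, None, None]


def _avgpool2(x: np.ndarray) -> np.ndarray:
    b, c, h, w = x.shape
    return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _pool_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Adaptive average pooling as a (n_out, n_in) row-stochastic matrix."""
    m = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo = (i * n_in) // n_out
        hi = -(-(i + 1) * n_in // n_out)  # ceil
        m[i, lo:hi] = 1.0 / (hi - lo)
    return m


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Separable bilinear upsampling matrix (n_out, n_in), half-pixel centers."""
    if n_in == 1:
        return np.ones((n_out, 1))
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    w = src - lo
    m = np.zeros((n_out, n_in))
    m[np.arange(n_out), lo] += 1 - w
    m[np.arange(n_out), hi] += w
    return m


def adaptive_avg_pool(x: np.ndarray, bins: int) -> np.ndarray:
    """Adaptive average pooling of (..., H, W) to (..., bins, bins)."""
    h, w = x.shape[-2:]
    pr, pc = _pool_matrix(bins, h), _pool_matrix(bins, w)
    return np.einsum("ih,...hw,jw->...ij", pr, x, pc, optimize=True)


def _upsample(x: np.ndarray, size: int) -> np.ndarray:
    h, w = x.shape[-2:]
    mr, mc = _interp_matrix(size, h), _interp_matrix(size, w)
    return np.einsum("ih,...hw,jw->...ij", mr, x, mc, optimize=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _prepare_batch(images: Sequence[GrayImage | np.ndarray], arch: SegArchitecture) -> np.ndarray:
    """Stack images as (B, 1, S, S) in [0, 1], resizing if needed."""
    from skimage.transform import resize

    out = np.empty((len(images), 1, arch.input_size, arch.input_size))
    for i, img in enumerate(images):
        if isinstance(img, GrayImage):
            arr = img.normalized()
        else:
            arr = np.asarray(img, dtype=np.float64)
            if arr.max(initial=0.0) > 1.0:
                arr = arr / 255.0
        if arr.shape != (arch.input_size, arch.input_size):
            arr = resize(arr, (arch.input_size, arch.input_size), order=1,
                         mode="edge", anti_aliasing=False, preserve_range=True)
        out[i, 0] = arr
    return out


def forward_batch(batch: np.ndarray, theta: np.ndarray, arch: SegArchitecture) -> np.ndarray:
    """Forward pass on a prepared (B, 1, S, S) batch -> (B, S, S) probabilities."""
    p = _unpack(theta, arch)
    x = batch
    for i in range(len(arch.encoder_channels)):
        x = _conv3x3(x, p[f"enc{i}.weight"], p[f"enc{i}.bias"])
        x = x * p[f"enc{i}.bn_scale"][None, :, None, None] + p[f"enc{i}.bn_shift"][None, :, None, None]
        x = np.maximum(x, 0.0)
        if i < len(arch.encoder_channels) - 1:
            x = _avgpool2(x)
    feat_size = x.shape[-1]
    branches = [x]
    for s in arch.pyramid_scales:
        pooled = adaptive_avg_pool(x, s)  # (B, C, s, s)
        reduced = np.einsum("oc,bcij->boij", p[f"pyr{s}.weight"], pooled) \
            + p[f"pyr{s}.bias"][None, :, None, None]
        reduced = np.maximum(reduced, 0.0)
        branches.append(_upsample(reduced, feat_size))
    cat = np.concatenate(branches, axis=1)  # (B, concat_channels, h, w)
    logits = np.einsum("oc,bcij->boij", p["head.weight"], cat) + p["head.bias"][None, :, None, None]
    prob = _sigmoid(logits[:, 0])
    return _upsample(prob, arch.input_size)


def forward(image: GrayImage | np.ndarray, theta: np.ndarray, arch: SegArchitecture) -> np.ndarray:
    """Lesion probability map for one image; pure function of (image, theta)."""
    return forward_batch(_prepare_batch([image], arch), theta, arch)[0]


def _prepare_masks(samples: Sequence[LabeledSample], arch: SegArchitecture) -> np.ndarray:
    from skimage.transform import resize

    masks = np.empty((len(samples), arch.input_size, arch.input_size))
    for i, s in enumerate(samples):
        m = s.mask.astype(np.float64)
        if m.shape != (arch.input_size, arch.input_size):
            m = resize(m, (arch.input_size, arch.input_size), order=0,
                       mode="edge", anti_aliasing=False, preserve_range=True)
        masks[i] = m
    return masks


def fitness(theta: np.ndarray, arch: SegArchitecture, samples: Sequence[LabeledSample]) -> float:
    """Mean over samples of the per-pixel mean squared mask error."""
    batch = _prepare_batch([s.image for s in samples], arch)
    masks = _prepare_masks(samples, arch)
    prob = forward_batch(batch, theta, arch)
    return float(np.mean((masks - prob) ** 2))


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map into a binary mask (>= convention)."""
    return (np.asarray(prob_map) >= threshold).astype(np.uint8)


def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    """Overlap score 2|A∩B| / (|A| + |B|); defined as 1 for two empty masks."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, truth).sum() / denom)


def train_with_jso(samples: Sequence[LabeledSample], arch: SegArchitecture,
                   jso_config: JsoConfig | None = None, weight_bound: float = 2.0,
                   param_cap: int = 5000) -> tuple[np.ndarray, JsoResult]:
    """Train all parameters as one flat vector with jellyfish search.

    Minimizes :func:`fitness` over [-weight_bound, weight_bound]^dim.
    Returns (best theta, full optimizer result with training curve).
    """
    dim = parameter_count(arch)
    if dim > param_cap:
        raise ValueError(
            f"architecture has {dim} parameters, above the gradient-free training cap "
            f"of {param_cap}; choose a smaller architecture"
        )
    cfg = jso_config or JsoConfig(population=20, iterations=300, bounds=(-weight_bound, weight_bound))
    cfg = JsoConfig(population=cfg.population, iterations=cfg.iterations, beta=cfg.beta,
                    eta=cfg.eta, chi=cfg.chi, x0=cfg.x0,
                    bounds=(-weight_bound, weight_bound), seed=cfg.seed)
    batch = _prepare_batch([s.image for s in samples], arch)
    masks = _prepare_masks(samples, arch)

    def fit_one(theta: np.ndarray) -> float:
        prob = forward_batch(batch, theta, arch)
        return float(np.mean((masks - prob) ** 2))

    result = optimize(fit_one, dim, cfg)
    return result.best_position, result


class PyramidSegmenter(BaseEstimator):
    """scikit-learn-style estimator around the pyramid-pooling segmenter.

    ``fit(X, y)`` takes images and binary masks (or a list of
    :class:`LabeledSample`) and trains by jellyfish search;
    ``predict_proba`` returns probability maps, ``predict`` binary masks.
    """

    def __init__(self, encoder_channels=(6, 8), pyramid_scales=(1, 2, 3),
                 reduction_channels=2, input_size=32, population=20,
                 iterations=300, weight_bound=2.0, threshold=0.5, seed=0):
        self.encoder_channels = encoder_channels
        self.pyramid_scales = pyramid_scales
        self.reduction_channels = reduction_channels
        self.input_size = input_size
        self.population = population
        self.iterations = iterations
        self.weight_bound = weight_bound
        self.threshold = threshold
        self.seed = seed

    def _arch(self) -> SegArchitecture:
        return SegArchitecture(self.encoder_channels, self.pyramid_scales,
                               self.reduction_channels, self.input_size)

    def fit(self, X, y=None):
        if y is None:
            samples = list(X)
        else:
            samples = [
                LabeledSample(img if isinstance(img, GrayImage) else GrayImage(np.asarray(img, float)),
                              mask, 1 if np.any(mask) else 0)
                for img, mask in zip(X, y)
            ]
        arch = self._arch()
        cfg = JsoConfig(population=self.population, iterations=self.iterations,
                        bounds=(-self.weight_bound, self.weight_bound), seed=self.seed)
        self.theta_, result = train_with_jso(samples, arch, cfg, self.weight_bound)
        self.history_ = result.history
        self.fitness_ = result.best_fitness
        self.n_parameters_ = parameter_count(arch)
        return self

    def predict_proba(self, X):
        if not hasattr(self, "theta_"):
            raise RuntimeError("PyramidSegmenter is not fitted")
        arch = self._arch()
        imgs = [x.image if isinstance(x, LabeledSample) else x for x in X]
        return forward_batch(_prepare_batch(imgs, arch), self.theta_, arch)

    def predict(self, X):
        return binarize(self.predict_proba(X), self.threshold)
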