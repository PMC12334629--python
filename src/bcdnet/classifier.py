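"""Compact convolutional/dense classifier trained with an adaptive
error-similarity loss and a CAViaR-style output-layer update.

The loss reweights cross-entropy by how ambiguous a sample is: with
softmax probabilities t, true class eps, and t_max the largest probability,

    loss = -(t_max - t_eps) * log(t_eps)

The weight (t_max - t_eps) is treated as a constant (detached) during
differentiation, so the exact gradient with respect to the logits is

    grad_u = t_u * (t_max - t_eps) - (t_max - t_u) * [u == eps]
           = (t_max - t_eps) * (t_u - onehot_u)

Confidently correct samples (t_eps = t_max) contribute exactly zero loss
and zero gradient; the harder the sample, the larger its weight — a
built-in hard-example emphasis.

The output-layer weight matrix G is updated by a conditional
autoregressive (CAViaR-style) recursion over its two lagged copies, with
blending coefficients derived from ratios of the last three epoch errors:
phi_1 = e_i / e_{i-1}, phi_2 = e_i / e_{i-2} (clamped to [0, phi_max],
undefined ratios treated as maximal), normalized to sum to one:

    G_i = phi_0 + phi1~ * G_{i-1} + phi2~ * G_{i-2}
          - mu * (phi1~ * grad(G_{i-1}) + phi2~ * grad(G_{i-2}))

With fewer than two recorded past errors the update degrades to a plain
gradient step. Interior layers (the small conv stack over the stacked
feature image and/or the dense branch over the scalar feature vector) are
trained by ordinary SGD through the same loss. Everything is numpy; the
architecture is deliberately small and CPU-friendly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin

from .features import FeatureRecord

__all__ = [
    "TrainConfig",
    "ClassifierState",
    "softmax",
    "ces_loss",
    "ces_gradient",
    "caviar_update",
    "train",
    "predict",
    "BCDCNNClassifier",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Stable softmax along the last axis; outputs sum to 1."""
    a = np.asarray(logits, dtype=np.float64)
    a = a - a.max(axis=-1, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=-1, keepdims=True)


def ces_loss(t: np.ndarray, true_class: int) -> float:
    """Adaptive error-similarity loss -(t_max - t_eps) * log(t_eps) >= 0."""
    t = np.asarray(t, dtype=np.float64)
    t_eps = t[true_class]
    weight = t.max() - t_eps
    return float(-weight * np.log(max(t_eps, 1e-12)))


def ces_gradient(t: np.ndarray, true_class: int) -> np.ndarray:
    """Exact gradient of the (frozen-weight) loss with respect to the logits.

    Both printed forms are computed and asserted equal:
    t_u (t_max - t_eps) - (t_max - t_u) [u == eps]  ==  (t_max - t_eps)(t - onehot).
    """
    t = np.asarray(t, dtype=np.float64)
    onehot = np.zeros_like(t)
    onehot[true_class] = 1.0
    t_max = t.max()
    weight = t_max - t[true_class]
    grad = t * weight - (t_max - t) * onehot
    alt = weight * (t - onehot)
    assert np.allclose(grad, alt, atol=1e-12), "gradient forms diverged"
    return grad


@dataclass
class ClassifierState:
    """All learnable state plus the CAViaR lag registers."""

    conv_params: dict | None
    dense_params: dict | None
    output_weights: np.ndarray  # G, shape (n_classes, head_dim + 1); last column is the bias
    lag1_weights: np.ndarray | None = None  # G at the previous update
    prev_gradient: np.ndarray | None = None  # gradient evaluated at lag1_weights
    errors: list = field(default_factory=list)  # epoch-mean losses e_i
    phi0: float = 0.0
    learning_rate: float = 0.1
    phi_max: float = 10.0
    normalize_ratios: bool = True
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None
    loss_history: list = field(default_factory=list)
    n_classes: int = 2


def _ratio(num: float, den: float, phi_max: float) -> float:
    if den == 0.0:
        return phi_max  # similarity undefined -> maximal weight
    return float(np.clip(num / den, 0.0, phi_max))


def caviar_update(state: ClassifierState, gradient: np.ndarray) -> np.ndarray:
    """Update the output-layer weights from the current epoch gradient.

    ``state.errors`` must already contain the current epoch error as its
    last entry. Mutates the lag registers and returns the new weights.
    """
    g_prev = state.output_weights
    grad_prev = np.asarray(gradient, dtype=np.float64)
    if len(state.errors) < 3 or state.lag1_weights is None or state.prev_gradient is None:
        g_new = g_prev - state.learning_rate * grad_prev
    else:
        e_i, e_1, e_2 = state.errors[-1], state.errors[-2], state.errors[-3]
        phi1 = _ratio(e_i, e_1, state.phi_max)
        phi2 = _ratio(e_i, e_2, state.phi_max)
        if state.normalize_ratios:
            total = phi1 + phi2
            if total == 0.0:
                phi1n = phi2n = 0.5
            else:
                phi1n, phi2n = phi1 / total, phi2 / total
        else:
            phi1n, phi2n = phi1, phi2
        g_new = (state.phi0
                 + phi1n * g_prev + phi2n * state.lag1_weights
                 - state.learning_rate * (phi1n * grad_prev + phi2n * state.prev_gradient))
    state.lag1_weights = g_prev.copy()
    state.prev_gradient = grad_prev.copy()
    state.output_weights = g_new
    return g_new


# ---------------------------------------------------------------------------
# numpy layers


def _conv3x3(x, weight, bias):
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))
    return np.einsum("bchwij,ocij->bohw", win, weight, optimize=True) + bias[None, :, None, None]


def _conv3x3_backward(x, dz):
    """Gradient of _conv3x3 output ``dz`` with respect to the weights."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))
    dw = np.einsum("bohw,bchwij->ocij", dz, win, optimize=True)
    db = dz.sum(axis=(0, 2, 3))
    return dw, db


def _conv3x3_input_grad(dz, weight):
    flipped = weight.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
    return _conv3x3(dz, flipped, np.zeros(flipped.shape[0]))


def _avgpool2(x):
    b, c, h, w = x.shape
    return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _unpool2(d):
    return np.repeat(np.repeat(d, 2, axis=2), 2, axis=3) / 4.0


def _init_conv(rng, in_ch, channels):
    params = {}
    c_in = in_ch
    for i, c_out in enumerate(channels):
        params[f"w{i}"] = rng.uniform(-0.1, 0.1, (c_out, c_in, 3, 3))
        params[f"b{i}"] = np.zeros(c_out)
        c_in = c_out
    return params


def _conv_forward(x, params, n_stages):
    cache = {"x": x}
    cur = x
    for i in range(n_stages):
        z = _conv3x3(cur, params[f"w{i}"], params[f"b{i}"])
        a = np.maximum(z, 0.0)
        p = _avgpool2(a)
        cache[f"in{i}"], cache[f"z{i}"] = cur, z
        cur = p
    cache["spatial"] = cur.shape[2] * cur.shape[3]
    return cur.mean(axis=(2, 3)), cache


def _conv_backward(dout, params, cache, n_stages):
    grads = {}
    # distribute the global-average-pool gradient over the final pooled map
    last = cache[f"z{n_stages-1}"]
    pooled_shape = (last.shape[0], last.shape[1], last.shape[2] // 2, last.shape[3] // 2)
    d = np.broadcast_to(dout[:, :, None, None] / cache["spatial"], pooled_shape).copy()
    for i in reversed(range(n_stages)):
        da = _unpool2(d)
        dz = da * (cache[f"z{i}"] > 0)
        grads[f"w{i}"], grads[f"b{i}"] = _conv3x3_backward(cache[f"in{i}"], dz)
        if i > 0:
            # gradient with respect to the pooled activation of stage i-1
            d = _conv3x3_input_grad(dz, params[f"w{i}"])
    return grads


@dataclass
class TrainConfig:
    """Training tunables for the classifier."""

    epochs: int = 60
    learning_rate: float = 3.0
    batch_size: int = 16
    hidden_units: int = 16
    conv_channels: tuple[int, ...] = (4, 8)
    use_conv: bool = False
    use_dense: bool = True
    phi0: float = 0.0
    phi_max: float = 10.0
    use_caviar: bool = True
    normalize_ratios: bool = True
    seed: int = 0


def _split_inputs(samples, config: TrainConfig):
    """Extract (vectors, images) from FeatureRecords, arrays or tuples."""
    vectors, images = [], []
    for s in samples:
        if isinstance(s, FeatureRecord):
            vectors.append(s.vector)
            images.append(s.feature_image)
        elif isinstance(s, tuple):
            vectors.append(np.asarray(s[0], dtype=np.float64))
            images.append(np.asarray(s[1], dtype=np.float64))
        else:
            vectors.append(np.asarray(s, dtype=np.float64))
            images.append(None)
    vec = np.stack(vectors) if config.use_dense else None
    img = np.stack(images) if config.use_conv else None
    return vec, img


def _head_features(state, conv_params, dense_params, vec, img, config, caches=None):
    parts = []
    if config.use_conv:
        feats, cache = _conv_forward(img, conv_params, len(config.conv_channels))
        parts.append(feats)
        if caches is not None:
            caches["conv"] = cache
    if config.use_dense:
        z = vec @ dense_params["w"].T + dense_params["b"]
        a = np.maximum(z, 0.0)
        parts.append(a)
        if caches is not None:
            caches["dense_z"] = z
            caches["dense_in"] = vec
    h = np.concatenate(parts, axis=1)
    return np.concatenate([h, np.ones((h.shape[0], 1))], axis=1)  # bias column


def train(samples: Sequence, labels: Sequence[int], config: TrainConfig | None = None,
          n_classes: int = 2) -> ClassifierState:
    """Train the classifier; returns the fitted :class:`ClassifierState`.

    Interior layers take a plain SGD step per minibatch; the output layer
    takes one CAViaR-blended step per epoch, driven by the epoch-mean loss
    and epoch-mean output-layer gradient.
    """
    config = config or TrainConfig()
    if not (config.use_conv or config.use_dense):
        raise ValueError("at least one of use_conv/use_dense must be enabled")
    rng = np.random.default_rng(config.seed)
    y = np.asarray(labels, dtype=int)
    vec, img = _split_inputs(samples, config)

    feature_mean = feature_scale = None
    if config.use_dense:
        feature_mean = vec.mean(axis=0)
        feature_scale = np.maximum(vec.std(axis=0), 1e-9)
        vec = (vec - feature_mean) / feature_scale

    head_dim = 0
    conv_params = dense_params = None
    if config.use_conv:
        conv_params = _init_conv(rng, img.shape[1], config.conv_channels)
        head_dim += config.conv_channels[-1]
    if config.use_dense:
        dense_params = {
            "w": rng.uniform(-0.1, 0.1, (config.hidden_units, vec.shape[1])),
            "b": np.zeros(config.hidden_units),
        }
        head_dim += config.hidden_units

    state = ClassifierState(
        conv_params=conv_params,
        dense_params=dense_params,
        output_weights=rng.uniform(-0.1, 0.1, (n_classes, head_dim + 1)),
        phi0=config.phi0,
        learning_rate=config.learning_rate,
        phi_max=config.phi_max,
        normalize_ratios=config.normalize_ratios,
        feature_mean=feature_mean,
        feature_scale=feature_scale,
        n_classes=n_classes,
    )
    state._config = config  # retained for prediction-time architecture info

    n = y.size
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        g_accum = np.zeros_like(state.output_weights)
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            bvec = vec[idx] if config.use_dense else None
            bimg = img[idx] if config.use_conv else None
            caches: dict = {}
            h = _head_features(state, conv_params, dense_params, bvec, bimg, config, caches)
            logits = h @ state.output_weights.T
            t = softmax(logits)
            dlogits = np.empty_like(t)
            for j, cls in enumerate(y[idx]):
                epoch_loss += ces_loss(t[j], cls)
                dlogits[j] = ces_gradient(t[j], cls)
            if not np.isfinite(epoch_loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            # output-layer gradient accumulated over the epoch (per-sample mean)
            g_accum += dlogits.T @ h
            # interior layers: plain SGD through the frozen output layer
            dh = dlogits @ state.output_weights[:, :-1]
            offset = 0
            if config.use_conv:
                c_out = config.conv_channels[-1]
                dconv = dh[:, :c_out] / idx.size
                grads = _conv_backward(dconv, conv_params, caches["conv"], len(config.conv_channels))
                for k, gk in grads.items():
                    conv_params[k] -= config.learning_rate * gk
                offset = c_out
            if config.use_dense:
                dz = dh[:, offset:] * (caches["dense_z"] > 0) / idx.size
                dense_params["w"] -= config.learning_rate * (dz.T @ caches["dense_in"])
                dense_params["b"] -= config.learning_rate * dz.sum(axis=0)
        e_i = epoch_loss / n
        state.errors.append(e_i)
        state.loss_history.append(e_i)
        if config.use_caviar:
            caviar_update(state, g_accum / n)
        else:
            prev = state.output_weights
            state.output_weights = prev - config.learning_rate * (g_accum / n)
            state.lag1_weights = prev.copy()
            state.prev_gradient = (g_accum / n).copy()
    return state


def predict(state: ClassifierState, samples: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and softmax probabilities for a batch of samples.

    Ties in the probabilities resolve toward the lower class index.
    """
    config = state._config
    vec, img = _split_inputs(samples if isinstance(samples, (list, tuple)) else list(samples), config)
    if config.use_dense:
        vec = (vec - state.feature_mean) / state.feature_scale
    h = _head_features(state, state.conv_params, state.dense_params, vec, img, config)
    t = softmax(h @ state.output_weights.T)
    return np.argmax(t, axis=1), t


class BCDCNNClassifier(ClassifierMixin, BaseEstimator):
    """scikit-learn-style interface over :func:`train`/:func:`predict`.

    ``X`` may be a plain (n_samples, n_features) matrix (dense branch
    only) or a list of :class:`FeatureRecord` (enabling the conv branch
    over the stacked feature image when ``use_conv=True``).
    """

    def __init__(self, epochs=60, learning_rate=3.0, batch_size=16, hidden_units=16,
                 conv_channels=(4, 8), use_conv=False, use_dense=True, phi0=0.0,
                 phi_max=10.0, use_caviar=True, seed=0):
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.hidden_units = hidden_units
        self.conv_channels = conv_channels
        self.use_conv = use_conv
        self.use_dense = use_dense
        self.phi0 = phi0
        self.phi_max = phi_max
        self.use_caviar = use_caviar
        self.seed = seed

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs, learning_rate=self.learning_rate,
            batch_size=self.batch_size, hidden_units=self.hidden_units,
            conv_channels=tuple(self.conv_channels), use_conv=self.use_conv,
            use_dense=self.use_dense, phi0=self.phi0, phi_max=self.phi_max,
            use_caviar=self.use_caviar, seed=self.seed,
        )

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        self.state_ = train(list(X), y, self._train_config(), n_classes=max(2, self.classes_.size))
        self.loss_history_ = list(self.state_.loss_history)
        return self

    def predict(self, X):
        labels, _ = predict(self.state_, list(X))
        return labels

    def predict_proba(self, X):
        _, t = predict(self.state_, list(X))
        return t
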