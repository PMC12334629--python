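"""Synthetic breast-MRI-like phantom slices with ground-truth lesions.

Every downstream stage (denoising, segmentation, feature extraction,
classification) is validated on these phantoms, so the generator is
first-class, seeded and deterministic. Each slice is a smooth anatomical
background (blurred white noise rescaled to [40, 160]) with, for lesion
classes, one elliptical lesion carrying an additive intensity offset and a
sinusoidal texture whose spatial frequency depends on the class. Noise is
added last, Gaussian by default or Rician (magnitude of a complex Gaussian)
to mimic MRI magnitude images.

Class semantics follow the screening datasets the pipeline targets:
label 1 = malignant/sick, label 0 = benign/healthy. By default benign
images also carry a (fainter, lower-frequency) lesion so that all five
feature families see class signal; set ``benign_lesion=False`` for a
healthy-background negative class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .imageio import GrayImage

__all__ = ["PhantomSpec", "LabeledSample", "generate_dataset"]

_BG_LO, _BG_HI = 40.0, 160.0


@dataclass
class PhantomSpec:
    """Configuration of the phantom generator.

    Parameters
    ----------
    image_size : int
        Side of the square slice in pixels (>= 16).
    lesion_axis_range : (float, float)
        Ellipse semi-axes drawn uniformly from this range, expressed as a
        fraction of ``image_size``; must lie inside (0, 0.5).
    background_smoothness : float
        Gaussian blur sigma (pixels) applied to the white-noise background.
    noise_sigma : float
        Noise standard deviation on the 0-255 intensity scale.
    noise_model : {"gaussian", "rician"}
    class_contrast : float
        Additional intensity offset of malignant lesions over benign ones.
    texture_frequency : float
        Cycles/pixel of the benign lesion texture; malignant lesions use
        twice this frequency.
    texture_amplitude : float
        Amplitude of the sinusoidal lesion texture (intensity units).
    benign_offset : float
        Intensity offset of a benign lesion over the local background.
    benign_lesion : bool
        Whether benign (label 0) images contain a lesion at all.
    seed : int
        Seed for all randomness in the generator.
    """

    image_size: int = 64
    lesion_axis_range: tuple[float, float] = (0.08, 0.18)
    background_smoothness: float = 6.0
    noise_sigma: float = 5.0
    noise_model: str = "gaussian"
    class_contrast: float = 60.0
    texture_frequency: float = 0.15
    texture_amplitude: float = 10.0
    benign_offset: float = 20.0
    benign_lesion: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.image_size) < 16:
            raise ValueError(f"image_size must be >= 16, got {self.image_size}")
        lo, hi = self.lesion_axis_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError(
                f"lesion_axis_range must lie within (0, 0.5) with min <= max, got {self.lesion_axis_range}"
            )
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"noise_model must be 'gaussian' or 'rician', got {self.noise_model!r}")
        if self.background_smoothness < 0:
            raise ValueError(f"background_smoothness must be >= 0, got {self.background_smoothness}")
        if self.texture_frequency <= 0:
            raise ValueError(f"texture_frequency must be > 0, got {self.texture_frequency}")


@dataclass
class LabeledSample:
    """One phantom slice with its ground-truth mask and class label."""

    image: GrayImage
    mask: np.ndarray  # uint8, 1 inside the lesion
    label: int  # 0 = benign/healthy, 1 = malignant/sick

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.mask.shape != self.image.shape:
            raise ValueError("mask shape must match image shape")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


def _background(rng: np.random.Generator, size: int, smoothness: float) -> np.ndarray:
    field_ = rng.standard_normal((size, size))
    if smoothness > 0:
        field_ = gaussian_filter(field_, smoothness, mode="reflect")
    lo, hi = field_.min(), field_.max()
    if hi - lo < 1e-12:
        return np.full((size, size), 0.5 * (_BG_LO + _BG_HI))
    return _BG_LO + (field_ - lo) / (hi - lo) * (_BG_HI - _BG_LO)


def _lesion(rng: np.random.Generator, spec: PhantomSpec, malignant: bool) -> tuple[np.ndarray, np.ndarray]:
    """Return (mask, additive_texture) for one elliptical lesion fully inside the frame."""
    s = spec.image_size
    lo, hi = spec.lesion_axis_range
    a, b = rng.uniform(lo * s, hi * s, size=2)
    rmax = max(a, b)
    margin = rmax + 1.5
    cy, cx = rng.uniform(margin, s - margin, size=2)
    phi = rng.uniform(0.0, np.pi)
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    yr = (yy - cy) * np.cos(phi) + (xx - cx) * np.sin(phi)
    xr = -(yy - cy) * np.sin(phi) + (xx - cx) * np.cos(phi)
    mask = ((xr / a) ** 2 + (yr / b) ** 2) <= 1.0

    offset = spec.benign_offset + (spec.class_contrast if malignant else 0.0)
    freq = spec.texture_frequency * (2.0 if malignant else 1.0)
    ang = rng.uniform(0.0, np.pi)
    phase = rng.uniform(0.0, 2 * np.pi)
    wave = np.sin(2 * np.pi * freq * (np.cos(ang) * xx + np.sin(ang) * yy) + phase)
    texture = mask * (offset + spec.texture_amplitude * wave)
    return mask.astype(np.uint8), texture


def _add_noise(rng: np.random.Generator, image: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    if spec.noise_sigma == 0:
        return image
    if spec.noise_model == "gaussian":
        return image + rng.normal(0.0, spec.noise_sigma, image.shape)
    # Rician: magnitude of (signal + n1) + i*n2 with iid Gaussian components.
    n1 = rng.normal(0.0, spec.noise_sigma, image.shape)
    n2 = rng.normal(0.0, spec.noise_sigma, image.shape)
    return np.hypot(image + n1, n2)


def generate_dataset(spec: PhantomSpec, n_per_class: int) -> list[LabeledSample]:
    """Generate a balanced, seeded phantom dataset.

    Returns ``2 * n_per_class`` samples: first the benign (label 0) slices,
    then the malignant (label 1) ones. Identical specs (including seed)
    produce bit-identical datasets.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    rng = np.random.default_rng(spec.seed)
    samples: list[LabeledSample] = []
    for label in (0, 1):
        for _ in range(n_per_class):
            bg = _background(rng, spec.image_size, spec.background_smoothness)
            if label == 1 or spec.benign_lesion:
                mask, texture = _lesion(rng, spec, malignant=label == 1)
            else:
                mask = np.zeros_like(bg, dtype=np.uint8)
                texture = 0.0
            img = np.clip(_add_noise(rng, bg + texture, spec), 0.0, 255.0)
            samples.append(
                LabeledSample(
                    image=GrayImage(img, (0.0, 255.0), provenance="phantom"),
                    mask=mask,
                    label=label,
                )
            )
    return samples
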