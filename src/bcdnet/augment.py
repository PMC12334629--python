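"""Geometric training-set augmentation: rotation, random erasing, flips.

Rotation maps coordinates through the usual 2-D rotation matrix about the
image center (bilinear resampling for intensities, nearest-neighbor for
masks, zero fill outside the frame); right-angle multiples are applied as
exact index permutations. Random erasing blanks one axis-aligned square,
fully inside the frame, with a configurable fill — it models occlusion of
appearance, so masks are left untouched. Flips are exact row/column
reversals (vertical, horizontal, or both — the latter identical to a 180
degree rotation). Geometric operators are applied identically to image and
mask and labels are always preserved.

Augmentation must happen after any train/test split; the evaluation
harness enforces that by augmenting training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .imageio import GrayImage
from .phantom import LabeledSample

__all__ = ["AugmentSpec", "rotate", "random_erase", "flip", "augment_dataset"]

_FLIP_MODES = ("vertical", "horizontal", "both")


@dataclass
class AugmentSpec:
    """Augmentation configuration.

    rotation_angles: explicit list of angles in degrees, or None to draw
    uniformly from the integers 1..359. erase_fraction_range: square side
    as a fraction of the (shorter) image side. erase_fill: zero | mean |
    random. flips: enabled flip modes. copies_per_image: augmented variants
    generated per input sample.
    """

    rotation_angles: Sequence[float] | None = None
    erase_fraction_range: tuple[float, float] = (0.1, 0.3)
    erase_fill: str = "zero"
    flips: tuple[str, ...] = _FLIP_MODES
    copies_per_image: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_angles is not None:
            for a in self.rotation_angles:
                if not 1 <= a <= 359:
                    raise ValueError(f"rotation angles must lie in [1, 359], got {a}")
        lo, hi = self.erase_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"erase_fraction_range must lie in (0, 1), got {self.erase_fraction_range}")
        if self.erase_fill not in ("zero", "mean", "random"):
            raise ValueError(f"erase_fill must be zero|mean|random, got {self.erase_fill!r}")
        for f in self.flips:
            if f not in _FLIP_MODES:
                raise ValueError(f"unknown flip mode {f!r}")
        if self.copies_per_image < 0:
            raise ValueError("copies_per_image must be >= 0")


def _as_array(image) -> tuple[np.ndarray, GrayImage | None]:
    if isinstance(image, GrayImage):
        return image.pixels, image
    return np.asarray(image, dtype=np.float64), None


def _rewrap(arr: np.ndarray, template: GrayImage | None, tag: str):
    if template is None:
        return arr
    return template.with_pixels(arr, provenance=tag)


def rotate(image, mask: np.ndarray | None, angle_deg: float):
    """Rotate image (bilinear) and mask (nearest) about the image center.

    Multiples of 90 degrees are exact index permutations; other angles are
    resampled with zero fill outside the frame. Returns ``(image, mask)``.
    """
    arr, template = _as_array(image)
    angle = float(angle_deg) % 360.0
    if angle == 0.0:
        out_img, out_mask = arr.copy(), None if mask is None else np.asarray(mask).copy()
    elif angle % 90.0 == 0.0:
        k = int(angle // 90)
        out_img = np.rot90(arr, k).copy()
        out_mask = None if mask is None else np.rot90(np.asarray(mask), k).copy()
    else:
        out_img = _sk_rotate(arr, angle, resize=False, center=None, order=1,
                             mode="constant", cval=0.0, preserve_range=True)
        out_mask = None
        if mask is not None:
            out_mask = _sk_rotate(np.asarray(mask).astype(np.float64), angle, resize=False,
                                  order=0, mode="constant", cval=0.0,
                                  preserve_range=True).astype(np.asarray(mask).dtype)
    return _rewrap(out_img, template, "rotate"), out_mask


def random_erase(image, spec: AugmentSpec, rng: np.random.Generator):
    """Blank exactly one random square, fully inside the frame."""
    arr, template = _as_array(image)
    h, w = arr.shape
    lo, hi = spec.erase_fraction_range
    side = int(round(rng.uniform(lo, hi) * min(h, w)))
    side = max(1, min(side, min(h, w)))
    r0 = int(rng.integers(0, h - side + 1))
    c0 = int(rng.integers(0, w - side + 1))
    out = arr.copy()
    if spec.erase_fill == "zero":
        fill = 0.0
    elif spec.erase_fill == "mean":
        fill = arr.mean()
    else:
        lo_v = template.value_range[0] if template else 0.0
        hi_v = template.value_range[1] if template else 255.0
        fill = rng.uniform(lo_v, hi_v, (side, side))
    out[r0:r0 + side, c0:c0 + side] = fill
    return _rewrap(out, template, "erase")


def flip(image, mode: str):
    """Exact, lossless flip: vertical (row reversal), horizontal (column
    reversal) or both (equivalent to a 180 degree rotation)."""
    arr, template = _as_array(image)
    if mode == "vertical":
        out = arr[::-1].copy()
    elif mode == "horizontal":
        out = arr[:, ::-1].copy()
    elif mode == "both":
        out = arr[::-1, ::-1].copy()
    else:
        raise ValueError(f"unknown flip mode {mode!r}")
    return _rewrap(out, template, f"flip:{mode}")


def _augment_one(sample: LabeledSample, spec: AugmentSpec, rng: np.random.Generator) -> LabeledSample:
    families = ["rotation", "erase"] + (["flip"] if spec.flips else [])
    family = families[int(rng.integers(len(families)))]
    img, mask = sample.image, sample.mask
    if family == "rotation":
        if spec.rotation_angles is not None:
            angle = spec.rotation_angles[int(rng.integers(len(spec.rotation_angles)))]
        else:
            angle = int(rng.integers(1, 360))
        img, mask = rotate(img, mask, angle)
    elif family == "flip":
        mode = spec.flips[int(rng.integers(len(spec.flips)))]
        img = flip(img, mode)
        mask = flip(mask, mode)
    else:
        img = random_erase(img, spec, rng)
        mask = mask.copy()
    return LabeledSample(image=img, mask=mask, label=sample.label)


def augment_dataset(samples: Sequence[LabeledSample], spec: AugmentSpec) -> list[LabeledSample]:
    """Each sample yields itself plus ``copies_per_image`` augmented variants,
    the operator family drawn uniformly per copy. Seeded and deterministic."""
    rng = np.random.default_rng(spec.seed)
    out: list[LabeledSample] = []
    for sample in samples:
        out.append(sample)
        for _ in range(spec.copies_per_image):
            out.append(_augment_one(sample, spec, rng))
    return out
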