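"""Five-family feature bank: Gabor, LBP, LVP texture maps; shape features
from the segmentation mask; histogram statistics of every texture map.

Texture maps
------------
* Gabor: complex oriented filters g(x, y) = (f^2 / (pi * w * n)) *
  exp(-(f^2/w^2) x'^2 - (f^2/n^2) y'^2) * exp(j 2 pi f x') with the rotated
  frame x' = x cos(t) + y sin(t), y' = -x sin(t) + y cos(t); one magnitude
  map per (frequency, orientation) pair, reflect padding.
* LBP: per-pixel 8-bit code from sign comparisons of the 8 neighbors
  against the center, neighbor order starting East and proceeding
  counter-clockwise, with sign(0) counted as 1; border pixels get code 0.
* LVP: per direction (0, 45, 90, 135 degrees), first-order directional
  derivatives are compared through a ratio ("comparative space") transform
  against the derivative one octave (45 degrees) ahead, yielding another
  8-bit code per pixel.

Scalar features
---------------
* Shape (from the largest connected component of the mask): compactness
  P/A with the perimeter counted along inter-pixel cracks, eccentricity as
  the moment-ellipse major/minor axis ratio, rectangularity A/eccentricity
  and solidity A/convex-hull-area. These follow the source formulas even
  where they differ from the radiomics conventions (P/A rather than P^2/A;
  rectangularity over the eccentricity rather than the bounding box).
* Statistics (per texture map, from a normalized histogram over E gray
  levels after min-max scaling to [0, E-1]): mean, variance, standard
  deviation, and skewness/kurtosis normalized by powers of the *mean*
  (again the source's convention, not the usual SD powers); both are
  defined as 0 when the mean is 0. A constant map is treated as a
  degenerate histogram concentrated at its value.

The assembled vector concatenates the 5 statistics of every texture map in
a fixed documented order (Gabor maps by (frequency, orientation), then
LBP, then the 4 LVP directions), followed by the 4 shape features:
5 * (n_gabor + 1 + 4) + 4 entries (109 for the default 4x4 Gabor bank).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve
from skimage.measure import label as cc_label, regionprops
from sklearn.base import BaseEstimator, TransformerMixin

from .imageio import GrayImage

__all__ = [
    "GaborParams",
    "FeatureConfig",
    "FeatureRecord",
    "gabor_kernel",
    "gabor_bank",
    "lbp_map",
    "lvp_maps",
    "shape_features",
    "statistical_features",
    "assemble",
    "extract_features",
    "FeatureBank",
]

DEFAULT_FREQUENCIES = (0.1, 0.2, 0.3, 0.4)
DEFAULT_ORIENTATIONS = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
LVP_DIRECTIONS = (0, 45, 90, 135)

# (row, col) offsets of the 8 neighbors, starting East, counter-clockwise.
_NEIGHBORS = ((0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1))
# unit steps along the LVP directions (image rows grow downward)
_DIR_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1), 180: (0, -1)}


@dataclass
class GaborParams:
    """One Gabor filter: central frequency (cycles/pixel), Gaussian
    sharpness along the major/minor axes, orientation in radians."""

    frequency: float
    sharpness_major: float = 1.0
    sharpness_minor: float = 1.0
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"frequency must be > 0, got {self.frequency}")
        if self.sharpness_major <= 0 or self.sharpness_minor <= 0:
            raise ValueError("sharpness parameters must be > 0")


@dataclass
class FeatureConfig:
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS
    sharpness_major: float = 1.0
    sharpness_minor: float = 1.0
    levels: int = 256


@dataclass
class FeatureRecord:
    """All features for one sample: named texture maps, shape vector,
    per-map statistics, the assembled flat vector with its column names,
    and the stacked multi-channel feature image for the classifier."""

    texture_maps: dict[str, np.ndarray]
    shape: np.ndarray
    statistics: dict[str, np.ndarray]
    vector: np.ndarray
    names: list[str]
    feature_image: np.ndarray  # (channels, H, W)


def gabor_kernel(params: GaborParams, size: int) -> np.ndarray:
    """Complex Gabor kernel of odd ``size``, centered at the middle pixel."""
    if size % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {size}")
    f, w, n, theta = params.frequency, params.sharpness_major, params.sharpness_minor, params.orientation
    half = size // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float64)
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    envelope = np.exp(-((f ** 2 / w ** 2) * xr ** 2 + (f ** 2 / n ** 2) * yr ** 2))
    carrier = np.exp(1j * 2 * np.pi * f * xr)
    return (f ** 2 / (np.pi * w * n)) * envelope * carrier


def _kernel_size(params: GaborParams) -> int:
    # cover ~3 envelope standard deviations: sigma = w / (sqrt(2) f)
    sigma = max(params.sharpness_major, params.sharpness_minor) / (np.sqrt(2.0) * params.frequency)
    half = max(3, int(np.ceil(3.0 * sigma)))
    return 2 * half + 1


def _convolve_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    half = kernel.shape[0] // 2
    padded = np.pad(image, half, mode="reflect")
    real = fftconvolve(padded, kernel.real, mode="valid")
    imag = fftconvolve(padded, kernel.imag, mode="valid")
    return real + 1j * imag


def gabor_bank(image, frequencies=DEFAULT_FREQUENCIES, orientations=DEFAULT_ORIENTATIONS,
               sharpness_major: float = 1.0, sharpness_minor: float = 1.0) -> dict[str, np.ndarray]:
    """Magnitude responses for every (frequency, orientation) pair,
    reflect-padded, same shape as the input. Keys: ``gabor_f{f}_t{deg}``."""
    arr = image.pixels if isinstance(image, GrayImage) else np.asarray(image, dtype=np.float64)
    maps: dict[str, np.ndarray] = {}
    for f in frequencies:
        for theta in orientations:
            params = GaborParams(f, sharpness_major, sharpness_minor, theta)
            kern = gabor_kernel(params, _kernel_size(params))
            deg = int(round(np.degrees(theta))) % 180
            maps[f"gabor_f{f:g}_t{deg}"] = np.abs(_convolve_reflect(arr, kern))
    return maps


def lbp_map(image) -> np.ndarray:
    """8-bit local-binary-pattern code map; borders are 0."""
    arr = image.pixels if isinstance(image, GrayImage) else np.asarray(image, dtype=np.float64)
    codes = np.zeros(arr.shape, dtype=np.int32)
    center = arr[1:-1, 1:-1]
    interior = np.zeros_like(center, dtype=np.int32)
    for bit, (dr, dc) in enumerate(_NEIGHBORS):
        neigh = arr[1 + dr:arr.shape[0] - 1 + dr, 1 + dc:arr.shape[1] - 1 + dc]
        interior += ((neigh - center) >= 0).astype(np.int32) << bit
    codes[1:-1, 1:-1] = interior
    return codes


def _directional_diff(arr: np.ndarray, direction: int) -> np.ndarray:
    """First-order derivative I(p + u) - I(p) along ``direction`` (degrees);
    positions whose forward neighbor falls outside the frame get 0."""
    dr, dc = _DIR_STEPS[direction]
    out = np.zeros_like(arr)
    h, w = arr.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    out[r0:r1, c0:c1] = arr[r0 + dr:r1 + dr, c0 + dc:c1 + dc] - arr[r0:r1, c0:c1]
    return out


def lvp_maps(image) -> dict[str, np.ndarray]:
    """Local-vector-pattern code maps for directions 0/45/90/135 degrees.

    For each direction h, the first-order derivative field along h and
    along h+45 are combined through the comparative-space transform: at the
    reference pixel the ratio slope = D_{h+45} / D_h (0 when D_h = 0) is
    formed, and each of the 8 neighbors k contributes the sign bit of
    D_{h+45}(k) - slope * D_h(k) (sign(0) = 1). Borders are 0.
    """
    arr = image.pixels if isinstance(image, GrayImage) else np.asarray(image, dtype=np.float64)
    maps: dict[str, np.ndarray] = {}
    for h in LVP_DIRECTIONS:
        d1 = _directional_diff(arr, h)
        d2 = _directional_diff(arr, h + 45)
        d1c, d2c = d1[1:-1, 1:-1], d2[1:-1, 1:-1]
        slope = np.divide(d2c, d1c, out=np.zeros_like(d2c), where=d1c != 0)
        interior = np.zeros(slope.shape, dtype=np.int32)
        for bit, (dr, dc) in enumerate(_NEIGHBORS):
            n1 = d1[1 + dr:arr.shape[0] - 1 + dr, 1 + dc:arr.shape[1] - 1 + dc]
            n2 = d2[1 + dr:arr.shape[0] - 1 + dr, 1 + dc:arr.shape[1] - 1 + dc]
            interior += ((n2 - slope * n1) >= 0).astype(np.int32) << bit
        codes = np.zeros(arr.shape, dtype=np.int32)
        codes[1:-1, 1:-1] = interior
        maps[f"lvp_{h}"] = codes
    return maps


def crack_perimeter(mask: np.ndarray) -> int:
    """Boundary length counted along inter-pixel edges (4-connectivity)."""
    m = np.asarray(mask).astype(bool)
    padded = np.pad(m, 1)
    per = 0
    for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        per += int(np.sum(m & ~padded[1 + dr:padded.shape[0] - 1 + dr,
                                      1 + dc:padded.shape[1] - 1 + dc]))
    return per


def shape_features(mask: np.ndarray) -> np.ndarray:
    """(compactness, eccentricity, rectangularity, solidity) of the largest
    connected component of a binary mask."""
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("no region: mask has no foreground pixels")
    labels = cc_label(m)
    regions = regionprops(labels)
    region = max(regions, key=lambda r: r.area)
    component = labels == region.label

    area = float(region.area)
    perim = float(crack_perimeter(component))
    compactness = perim / area
    major, minor = region.axis_major_length, region.axis_minor_length
    minor = max(minor, 1.0)  # floor degenerate (1-pixel-thin) regions at one pixel
    major = max(major, 1.0)
    eccentricity = major / minor
    rectangularity = area / eccentricity
    solidity = float(region.solidity)
    return np.array([compactness, eccentricity, rectangularity, solidity])


def statistical_features(texture_map: np.ndarray, levels: int = 256) -> np.ndarray:
    """(mean, variance, SD, skewness, kurtosis) of the normalized histogram
    of a texture map after min-max scaling to integer levels 0..levels-1.

    Skewness and kurtosis are normalized by the 3rd/4th power of the mean
    (the source convention); both are 0 when the mean is 0. A constant map
    yields (value, 0, 0, 0, 0).
    """
    arr = np.asarray(texture_map, dtype=np.float64).ravel()
    lo, hi = arr.min(), arr.max()
    if hi - lo < 1e-300:
        return np.array([lo, 0.0, 0.0, 0.0, 0.0])
    levels = int(levels)
    quantized = np.rint((arr - lo) / (hi - lo) * (levels - 1)).astype(np.int64)
    hist = np.bincount(quantized, minlength=levels) / arr.size
    grey = np.arange(levels, dtype=np.float64)
    mean = float(np.sum(grey * hist))
    var = float(np.sum((grey - mean) ** 2 * hist))
    sd = float(np.sqrt(var))
    if mean == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(mean ** -3 * np.sum((grey - mean) ** 3 * hist))
        kurt = float(mean ** -4 * np.sum((grey - mean) ** 4 * hist))
    return np.array([mean, var, sd, skew, kurt])


_STAT_NAMES = ("mean", "var", "sd", "skew", "kurt")
_SHAPE_NAMES = ("shape_compactness", "shape_eccentricity", "shape_rectangularity", "shape_solidity")


def assemble(texture_maps: dict[str, np.ndarray], mask: np.ndarray,
             image: np.ndarray | None = None, levels: int = 256) -> FeatureRecord:
    """Assemble the flat feature vector T from texture maps and a mask.

    Statistics are computed per texture map and concatenated in the fixed
    map order (insertion order of ``texture_maps``: Gabor by (f, theta),
    then LBP, then LVP), the 4 shape features appended once. An empty mask
    contributes zero shape features (no region to describe).
    """
    stats: dict[str, np.ndarray] = {}
    values: list[float] = []
    names: list[str] = []
    for map_name, tmap in texture_maps.items():
        s = statistical_features(tmap, levels)
        stats[map_name] = s
        values.extend(s)
        names.extend(f"{map_name}_{st}" for st in _STAT_NAMES)
    mask = np.asarray(mask)
    shape = shape_features(mask) if mask.any() else np.zeros(4)
    values.extend(shape)
    names.extend(_SHAPE_NAMES)

    gabor_names = [k for k in texture_maps if k.startswith("gabor")]
    lvp_names = [k for k in texture_maps if k.startswith("lvp")]
    channels: list[np.ndarray] = []
    some_map = next(iter(texture_maps.values()))
    if image is not None:
        arr = np.asarray(image, dtype=np.float64)
        channels.append(arr / max(arr.max(), 1e-12))
    if "lbp" in texture_maps:
        channels.append(texture_maps["lbp"] / 255.0)
    channels.extend(texture_maps[k] / 255.0 for k in lvp_names)
    if gabor_names:
        gstack = np.stack([texture_maps[k] for k in gabor_names])
        gmean = gstack.mean(axis=0)
        channels.append(gmean / max(gmean.max(), 1e-12))
    feature_image = np.stack(channels) if channels else np.zeros((0,) + some_map.shape)

    return FeatureRecord(
        texture_maps=texture_maps,
        shape=shape,
        statistics=stats,
        vector=np.asarray(values, dtype=np.float64),
        names=names,
        feature_image=feature_image,
    )


def extract_features(image, mask: np.ndarray, config: FeatureConfig | None = None) -> FeatureRecord:
    """Full feature extraction for one (image, mask) pair."""
    cfg = config or FeatureConfig()
    arr = image.pixels if isinstance(image, GrayImage) else np.asarray(image, dtype=np.float64)
    maps: dict[str, np.ndarray] = {}
    maps.update(gabor_bank(arr, cfg.frequencies, cfg.orientations,
                           cfg.sharpness_major, cfg.sharpness_minor))
    maps["lbp"] = lbp_map(arr)
    maps.update(lvp_maps(arr))
    return assemble(maps, mask, image=arr, levels=cfg.levels)


class FeatureBank(TransformerMixin, BaseEstimator):
    """scikit-learn-style transformer producing the assembled feature matrix.

    ``transform(X)`` accepts a list of ``(image, mask)`` pairs or of
    objects with ``.image``/``.mask`` attributes and returns the stacked
    (n_samples, n_features) matrix; ``records_`` keeps the full
    :class:`FeatureRecord` list from the last transform and
    ``feature_names_`` the column names.
    """

    def __init__(self, frequencies=DEFAULT_FREQUENCIES, orientations=DEFAULT_ORIENTATIONS,
                 sharpness_major: float = 1.0, sharpness_minor: float = 1.0, levels: int = 256):
        self.frequencies = frequencies
        self.orientations = orientations
        self.sharpness_major = sharpness_major
        self.sharpness_minor = sharpness_minor
        self.levels = levels

    def _config(self) -> FeatureConfig:
        return FeatureConfig(tuple(self.frequencies), tuple(self.orientations),
                             self.sharpness_major, self.sharpness_minor, self.levels)

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        cfg = self._config()
        records = []
        for item in X:
            if hasattr(item, "image") and hasattr(item, "mask"):
                img, mask = item.image, item.mask
            else:
                img, mask = item
            records.append(extract_features(img, mask, cfg))
        self.records_ = records
        self.feature_names_ = records[0].names if records else []
        return np.stack([r.vector for r in records]) if records else np.empty((0, 0))
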