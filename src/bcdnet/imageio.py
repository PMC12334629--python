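"""Grayscale image container and file readers/writers.

Conventions shared by every stage of the pipeline: images are 2-D numpy
arrays indexed ``(row, col)``, 0-based, origin at the top-left corner.
Pixel values are floats on a declared ``value_range`` (``(0, 255)`` for
8-bit sources, ``(0, 65535)`` for 16-bit); quantization happens only on
file write.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["GrayImage", "read_image", "write_image", "read_manifest", "write_manifest"]

# Rec. 709 luminance weights (sum to 1, so gray RGB maps to its own value).
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclass
class GrayImage:
    """2-D intensity grid with value-range metadata.

    Parameters
    ----------
    pixels : ndarray of float, shape (rows, cols)
        Intensities. Must be finite and at least 3x3.
    value_range : tuple of float
        Declared (lo, hi) intensity scale.
    provenance : str
        Free-text tag naming the pipeline stage that produced the image.
    """

    pixels: np.ndarray
    value_range: tuple[float, float] = (0.0, 255.0)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 3:
            raise ValueError(f"image must be 2-D and at least 3x3, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")
        lo, hi = self.value_range
        if not lo < hi:
            raise ValueError(f"value_range must satisfy lo < hi, got {self.value_range}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def normalized(self) -> np.ndarray:
        """Pixels rescaled to [0, 1] by the declared value range."""
        lo, hi = self.value_range
        return (self.pixels - lo) / (hi - lo)

    def with_pixels(self, pixels: np.ndarray, provenance: str | None = None) -> "GrayImage":
        return replace(
            self,
            pixels=pixels,
            provenance=self.provenance if provenance is None else provenance,
        )


def read_image(path: str | os.PathLike) -> GrayImage:
    """Read a PNG/TIFF/JPEG file into a :class:`GrayImage`.

    RGB inputs are converted to luminance; 16-bit images are kept as floats
    on a (0, 65535) range.
    """
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except (OSError, SyntaxError) as exc:  # truncated/unreadable
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3].astype(np.float64) @ _LUMA
    arr = arr.astype(np.float64)
    hi = 65535.0 if arr.max(initial=0.0) > 255.0 else 255.0
    return GrayImage(arr, value_range=(0.0, hi), provenance=f"read:{os.fspath(path)}")


def write_image(image: GrayImage | np.ndarray, path: str | os.PathLike) -> None:
    """Write an image as 8-bit PNG (or whatever the extension implies),
    clipping and rounding to the declared range."""
    if isinstance(image, GrayImage):
        arr = image.normalized() * 255.0
    else:
        arr = np.asarray(image, dtype=np.float64)
    arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a dataset manifest CSV (columns: filename, mask_filename, label)."""
    df = pd.read_csv(path, dtype={"filename": str, "mask_filename": str})
    required = {"filename", "mask_filename", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path!r} is missing columns: {sorted(missing)}")
    return df


def write_manifest(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False)
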