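"""Raster image I/O and color-space conversions.

Everything downstream operates on 8-bit RGB rasters (``uint8`` arrays of
shape ``(H, W, 3)``).  Pixel clustering happens in CIELAB, where Euclidean
distance approximates perceptual color difference; this module provides the
round trip between the two representations plus a Rec. 601 luminance plane
used for entropy and thresholding.

Conventions: sRGB companding, D65 reference white, image origin at the
top-left, coordinates ``(x=column, y=row)``, 0-based.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from skimage import color as _skcolor

logger = logging.getLogger(__name__)

#: Rec. 601 luma weights for R, G, B.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


class ImageFormatError(ValueError):
    """Raised when a file cannot be decoded as a supported raster image."""


@dataclass(frozen=True)
class LabPixelSet:
    """Flat set of CIELAB pixels remembering the raster shape they came from.

    Attributes
    ----------
    values : ndarray, shape (n, 3)
        Per-pixel (L, a, b); L in [0, 100] for in-gamut 8-bit sources.
    shape : tuple of int
        ``(height, width)`` of the source raster, with ``n = height * width``.
    """

    values: np.ndarray
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError("values must have shape (n, 3)")
        if self.values.shape[0] != self.shape[0] * self.shape[1]:
            raise ValueError("n must equal height * width")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _as_raster(pixels: np.ndarray) -> np.ndarray:
    """Validate and return an (H, W, 3) uint8 raster."""
    arr = np.asarray(pixels)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB raster, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"expected uint8 raster, got dtype {arr.dtype}")
    return arr


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF image as an 8-bit RGB raster.

    Single-channel inputs are promoted by channel replication; an alpha
    channel is dropped; 16-bit inputs are linearly rescaled to 8-bit (with a
    warning, since downstream math assumes the [0, 255] color cube).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"image not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # decoder-specific exception types vary
        raise ImageFormatError(f"cannot decode {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.dtype == np.uint16:
        logger.warning("%s is 16-bit; rescaling to 8-bit", path)
        arr = np.round(arr.astype(np.float64) / 65535.0 * 255.0).astype(np.uint8)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    elif arr.dtype != np.uint8:
        raise ImageFormatError(f"unsupported pixel dtype {arr.dtype} in {path}")
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(f"unsupported channel layout {arr.shape} in {path}")
    return np.ascontiguousarray(arr)


def write_image(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write an RGB raster losslessly (PNG or TIFF chosen by extension)."""
    arr = _as_raster(image)
    parent = os.path.dirname(os.fspath(path)) or "."
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    try:
        iio.imwrite(path, arr)
    except PermissionError:
        raise
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def rgb_to_lab(image: np.ndarray) -> LabPixelSet:
    """Convert an 8-bit RGB raster to a flat CIELAB pixel set (sRGB, D65)."""
    arr = _as_raster(image)
    lab = _skcolor.rgb2lab(arr.astype(np.float64) / 255.0)
    return LabPixelSet(values=lab.reshape(-1, 3), shape=(arr.shape[0], arr.shape[1]))


def lab_to_rgb(labset: LabPixelSet) -> np.ndarray:
    """Invert :func:`rgb_to_lab`; out-of-gamut values are clamped to [0, 255]."""
    h, w = labset.shape
    rgb = _skcolor.lab2rgb(labset.values.reshape(h, w, 3))
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def luminance(image: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance plane ``0.299 R + 0.587 G + 0.114 B`` in [0, 255].

    Accepts uint8 rasters and real-valued (H, W, 3) arrays alike, since the
    entropy line search works on unquantized pixel values.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) raster, got shape {arr.shape}")
    return arr @ LUMA_WEIGHTS
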