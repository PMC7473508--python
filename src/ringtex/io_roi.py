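"""Image reading, resizing, 8-bit rescaling and ROI extraction.

All texture operators downstream work on small integer-valued patches
(:class:`QuantizedPatch`).  The conventions here are the contract for the
whole pipeline:

* ROI coordinates are 0-based, half-open ``[row, row+size) x [col, col+size)``.
* Intensity rescaling maps each image's own ``[min, max]`` linearly onto
  ``[0, 255]`` (per-image min-max); a fixed-range mode mapping
  ``[0, 2^bit_depth - 1]`` is available via ``mode="fixed"``.
* Quantization to ``L < 256`` levels is uniform re-binning of ``[0, 255]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from skimage.transform import resize as _sk_resize


class UnsupportedFormatError(ValueError):
    """Raised for multi-frame, colour or otherwise unsupported inputs."""


@dataclass
class GrayImage:
    """A 2-D non-negative grayscale intensity image.

    Attributes
    ----------
    pixels : ndarray
        2-D float array of non-negative intensities.
    bit_depth : int
        8 or 16; the nominal range is ``[0, 2**bit_depth - 1]``.
    source_id : str
        Provenance string (file path or synthetic id).
    """

    pixels: np.ndarray
    bit_depth: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise UnsupportedFormatError(
                f"expected a 2-D grayscale image, got shape {self.pixels.shape}"
            )
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("negative intensities after clipping are not allowed")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ROISpec:
    """A square ROI window: 0-based top-left corner, half-open bounds."""

    top_left: tuple[int, int]
    size: int = 10


@dataclass
class QuantizedPatch:
    """Small integer-valued patch with entries in ``[0, L-1]``."""

    levels: np.ndarray
    L: int = 256

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        if self.levels.ndim != 2:
            raise ValueError("patch must be 2-D")
        if self.L < 2:
            raise ValueError("need at least 2 gray levels")
        if self.levels.size:
            lo, hi = self.levels.min(), self.levels.max()
            if lo < 0 or hi >= self.L:
                raise ValueError(
                    f"levels outside [0, {self.L - 1}]: min={lo}, max={hi}"
                )
        if not np.issubdtype(self.levels.dtype, np.integer):
            if not np.allclose(self.levels, np.round(self.levels)):
                raise ValueError("levels must be integers")
            self.levels = self.levels.astype(np.int64)


def read_image(path: str | Path) -> GrayImage:
    """Read a single-frame DICOM MR object or an 8/16-bit grayscale PNG/TIFF.

    For DICOM, the rescale slope/intercept are applied and the result is
    clipped to non-negative.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.suffix.lower() in (".dcm", ".dicom", ""):
        return _read_dicom(path)
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise UnsupportedFormatError(f"colour image not supported: {path}")
    if arr.ndim != 2:
        raise UnsupportedFormatError(
            f"expected a single-frame 2-D image, got shape {arr.shape}: {path}"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise UnsupportedFormatError(
            f"unsupported pixel type {arr.dtype} (need uint8/uint16): {path}"
        )
    return GrayImage(pixels=arr.astype(float), bit_depth=depth, source_id=str(path))


def _read_dicom(path: Path) -> GrayImage:
    import pydicom

    ds = pydicom.dcmread(path)
    n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if n_frames != 1:
        raise UnsupportedFormatError(f"multi-frame DICOM not supported: {path}")
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise UnsupportedFormatError(f"colour DICOM not supported: {path}")
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = np.clip(arr * slope + intercept, 0.0, None)
    bits = int(getattr(ds, "BitsAllocated", 16))
    return GrayImage(pixels=arr, bit_depth=8 if bits <= 8 else 16,
                     source_id=str(path))


def resize_image(img: GrayImage, target: tuple[int, int] = (240, 240)) -> GrayImage:
    """Bilinear resize to the working grid (default 240x240).

    A same-size input is returned numerically unchanged.
    """
    if img.pixels.size == 0:
        raise ValueError("cannot resize an empty image")
    if img.shape == tuple(target):
        return GrayImage(img.pixels.copy(), img.bit_depth, img.source_id)
    out = _sk_resize(img.pixels, target, order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return GrayImage(np.clip(out, 0.0, None), img.bit_depth, img.source_id)


def rescale_to_8bit(img: GrayImage, mode: str = "minmax") -> GrayImage:
    """Rescale intensities onto ``[0, 255]`` and round half-to-even.

    ``minmax`` (default) maps the image's own range; ``fixed`` maps
    ``[0, 2**bit_depth - 1]``.  A constant image maps to all zeros.
    """
    px = img.pixels
    if mode == "minmax":
        lo, hi = float(px.min()), float(px.max())
    elif mode == "fixed":
        lo, hi = 0.0, float(2**img.bit_depth - 1)
    else:
        raise ValueError(f"unknown rescale mode: {mode!r}")
    if hi <= lo:
        out = np.zeros_like(px)
    else:
        out = np.round((px - lo) / (hi - lo) * 255.0)
    return GrayImage(out, 8, img.source_id)


def extract_roi(img: GrayImage, roi: ROISpec, L: int = 256) -> QuantizedPatch:
    """Cut a quantized ROI from an 8-bit image.

    With ``L == 256`` the 8-bit values are the levels; with ``L < 256`` the
    8-bit range is uniformly re-binned: ``level = floor(v * L / 256)``.
    """
    if img.bit_depth != 8:
        raise ValueError("extract_roi requires an 8-bit image; rescale first")
    r, c = roi.top_left
    s = roi.size
    h, w = img.shape
    if r < 0 or c < 0 or r + s > h or c + s > w:
        raise IndexError(
            f"ROI [{r}:{r + s}, {c}:{c + s}] outside image of shape {h}x{w}"
        )
    block = img.pixels[r:r + s, c:c + s]
    vals = np.round(block).astype(np.int64)
    if L == 256:
        levels = vals
    else:
        levels = (vals * L) // 256
    return QuantizedPatch(levels=levels, L=L)
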