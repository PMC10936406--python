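"""Data model and file IO for serial SEM stacks and label masks.

Coordinate convention used throughout the package: ``x`` is the column index
(the SEM fast-scan direction, along which charging tails extend), ``y`` is the
row index (slow-scan), origin at the top-left, 0-based.  Arrays are indexed
``(slice z, row y, column x)`` and slice order equals acquisition order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from . import _mrc

__all__ = [
    "ImageStack",
    "LabelMask",
    "read_stack",
    "write_stack",
    "read_mask",
]

_MRC_SUFFIXES = {".mrc", ".mrcs", ".rec", ".map"}


@dataclass
class ImageStack:
    """An ordered 3D grayscale volume with an isotropic in-plane pixel size.

    Parameters
    ----------
    data : ndarray, shape (n_slices, height, width)
        Slice intensities, floating point, finite.
    pixel_size_nm : float, optional
        In-plane pixel size in nanometres.  Required by operations that
        report physical resolutions; purely pixel-based operations work
        without it.
    """

    data: np.ndarray
    pixel_size_nm: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3D (z, y, x), got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains NaN or Inf values")
        if self.pixel_size_nm is not None and not self.pixel_size_nm > 0:
            raise ValueError(f"pixel_size_nm must be positive, got {self.pixel_size_nm}")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    def __getitem__(self, z) -> np.ndarray:
        return self.data[z]


@dataclass
class LabelMask:
    """Integer label image marking charging centers (0 = background)."""

    data: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), dtype=np.int32))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if np.issubdtype(arr.dtype, np.floating):
            if not np.all(np.isfinite(arr)) or not np.all(arr == np.round(arr)):
                raise ValueError("floating-point mask has non-integral values")
            arr = arr.astype(np.int64)
        elif arr.dtype == bool:
            arr = arr.astype(np.int64)
        elif not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"mask dtype {arr.dtype} is not integer-like")
        if arr.min(initial=0) < 0:
            raise ValueError("mask labels must be nonnegative")
        self.data = arr

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero label values present in the mask."""
        vals = np.unique(self.data)
        return vals[vals > 0]

    def binary(self) -> np.ndarray:
        return self.data > 0


def _tiff_pixel_size_nm(tif: tifffile.TiffFile) -> float | None:
    """Pixel size from TIFF resolution tags, converted to nm when stated."""
    page = tif.pages[0]
    res = page.tags.get("XResolution")
    unit = page.tags.get("ResolutionUnit")
    if res is None or unit is None:
        return None
    num, den = res.value
    if num == 0 or den == 0:
        return None
    pixels_per_unit = num / den
    unit_nm = {2: 2.54e7, 3: 1e7}.get(int(unit.value))  # inch, cm
    if unit_nm is None:
        return None
    return unit_nm / pixels_per_unit


def read_stack(path, pixel_size_nm: float | None = None) -> ImageStack:
    """Load a multipage TIFF or MRC volume as an :class:`ImageStack`.

    Intensities are cast to float64 without rescaling.  Pixel size
    precedence: explicit argument > file metadata > error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _MRC_SUFFIXES:
        data, meta_px = _mrc.read_mrc(path)
    else:
        with tifffile.TiffFile(path) as tif:
            shapes = {p.shape for p in tif.pages}
            if len(shapes) > 1:
                raise ValueError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
            data = tif.asarray()
            meta_px = _tiff_pixel_size_nm(tif)
    px = pixel_size_nm if pixel_size_nm is not None else meta_px
    if px is None:
        raise ValueError(
            f"{path}: pixel size not present in file metadata and not given; "
            "pass pixel_size_nm explicitly"
        )
    return ImageStack(np.asarray(data, dtype=np.float64), pixel_size_nm=px)


def write_stack(stack: ImageStack, path, dtype_policy: str = "preserve-float32") -> None:
    """Write a stack as multipage TIFF (default) or MRC (by file extension).

    ``dtype_policy`` is one of ``preserve-float32``, ``rescale-uint8``,
    ``rescale-uint16``.  Rescaling maps [min, max] to the full integer
    range; non-finite values under an integer policy raise instead of
    being clipped silently.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    data = stack.data
    if dtype_policy == "preserve-float32":
        out = data.astype(np.float32)
    elif dtype_policy in ("rescale-uint8", "rescale-uint16"):
        if not np.all(np.isfinite(data)):
            raise ValueError(f"non-finite values cannot be rescaled under {dtype_policy}")
        dtype = np.uint8 if dtype_policy == "rescale-uint8" else np.uint16
        lo, hi = float(data.min()), float(data.max())
        span = hi - lo
        scaled = np.zeros_like(data) if span == 0 else (data - lo) / span
        out = np.round(scaled * np.iinfo(dtype).max).astype(dtype)
    else:
        raise ValueError(f"unknown dtype_policy {dtype_policy!r}")
    if path.suffix.lower() in _MRC_SUFFIXES:
        _mrc.write_mrc(path, out, pixel_size_nm=stack.pixel_size_nm)
    else:
        kwargs = {}
        if stack.pixel_size_nm:
            ppcm = 1e7 / stack.pixel_size_nm
            kwargs = {"resolution": (ppcm, ppcm), "resolutionunit": "CENTIMETER"}
        tifffile.imwrite(path, out, photometric="minisblack", **kwargs)


def read_mask(path, expected_shape: tuple[int, ...] | None = None) -> LabelMask:
    """Load an integer label mask from PNG or TIFF.

    Any nonzero value is a charging-center label.  If ``expected_shape``
    is given, a mismatch raises with both shapes named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:  # collapse RGB(A) to a single channel
            arr = arr[..., 0]
    mask = LabelMask(arr)
    if expected_shape is not None and tuple(mask.shape) != tuple(expected_shape):
        raise ValueError(
            f"mask shape {tuple(mask.shape)} does not match image shape "
            f"{tuple(expected_shape)}"
        )
    return mask
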