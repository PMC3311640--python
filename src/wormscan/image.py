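"""Grayscale plate-scan images with physical-resolution metadata.

A flatbed scan is a 2-D intensity array plus two pieces of physical
context: the bit depth of the scanner output (8 or 16) and the scan
resolution in dots per inch.  At the 2400 dpi used for worm plates one
pixel covers 25.4/2400 ~ 10.6 um, so an adult worm (~1 mm x 0.06 mm)
spans roughly 95 x 6 pixels.

Coordinates are (row, col), 0-based, origin at the top-left corner;
bounding boxes are half-open ``(r0, c0, r1, c1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

MM_PER_INCH = 25.4


@dataclass
class GrayscaleImage:
    """A single-channel scan with bit depth and dpi metadata.

    Parameters
    ----------
    pixels : ndarray
        2-D array of intensities. Stored as provided; operations that
        need floats normalize on the fly.
    bit_depth : int
        8 or 16; intensities must lie in ``[0, 2**bit_depth - 1]``.
    dpi : float
        Scan resolution in pixels per inch; must be positive.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    dpi: float = 2400.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected 2-D image, got shape {self.pixels.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not self.dpi > 0:
            raise ValueError(f"dpi must be positive, got {self.dpi}")
        lo, hi = self.pixels.min() if self.pixels.size else 0, self.pixels.max() if self.pixels.size else 0
        if self.pixels.size and (lo < 0 or hi > self.max_value):
            raise ValueError(
                f"intensities [{lo}, {hi}] exceed {self.bit_depth}-bit range"
            )

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def as_float(self) -> np.ndarray:
        """Intensities rescaled to [0, 1] as float64."""
        return self.pixels.astype(np.float64) / self.max_value

    def px_to_mm(self, length_px: float) -> float:
        return length_px * MM_PER_INCH / self.dpi

    def mm_to_px(self, length_mm: float) -> float:
        return length_mm * self.dpi / MM_PER_INCH


def read_tiff(path, bit_depth: int | None = None, dpi: float | None = None) -> GrayscaleImage:
    """Load a grayscale TIFF, taking dpi from the file's resolution tags when present."""
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        arr = page.asarray()
        if dpi is None:
            dpi = 2400.0
            tag = page.tags.get("XResolution")
            if tag is not None:
                num, den = tag.value
                if den and num:
                    unit = page.tags.get("ResolutionUnit")
                    val = num / den
                    if unit is not None and getattr(unit.value, "name", str(unit.value)).upper().startswith("CENT"):
                        val *= 2.54
                    if val > 0:
                        dpi = float(val)
    if arr.ndim == 3:  # collapse trivial channel axis
        arr = arr[..., 0]
    if bit_depth is None:
        bit_depth = 8 if arr.dtype == np.uint8 else 16
    return GrayscaleImage(arr, bit_depth=bit_depth, dpi=dpi)


def write_tiff(path, image: GrayscaleImage) -> None:
    """Write a scan as TIFF with resolution tags matching its dpi."""
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    tifffile.imwrite(
        str(path),
        image.pixels.astype(dtype),
        resolution=(image.dpi, image.dpi),
        resolutionunit="INCH",
    )


def write_tiff_stack(path, images: list[GrayscaleImage]) -> None:
    """Write a scan time series as a multi-page TIFF."""
    if not images:
        raise ValueError("empty image list")
    dtype = np.uint8 if images[0].bit_depth == 8 else np.uint16
    stack = np.stack([im.pixels.astype(dtype) for im in images])
    tifffile.imwrite(
        str(path),
        stack,
        photometric="minisblack",
        resolution=(images[0].dpi, images[0].dpi),
        resolutionunit="INCH",
    )


def read_tiff_stack(path, bit_depth: int | None = None, dpi: float | None = None) -> list[GrayscaleImage]:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    first = read_tiff(path, bit_depth=bit_depth, dpi=dpi)
    return [GrayscaleImage(plane, bit_depth=first.bit_depth, dpi=first.dpi) for plane in arr]
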