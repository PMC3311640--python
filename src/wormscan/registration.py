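"""Alignment of sequential plate scans.

The plate (or the scanner carriage) can shift by a few pixels between
sequential scans; uncorrected, that shift shows up in the difference
image as apparent movement of every worm.  Scans seconds apart on a
flatbed have no rotation or scale change, so a pure translation model
suffices: the shift is estimated by phase cross-correlation with
subpixel refinement and the second scan is resampled onto the first
scan's frame.  Border pixels with no source data are invalidated via a
validity mask rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .image import GrayscaleImage

__all__ = ["ScanPair", "estimate_shift", "align"]


@dataclass
class ScanPair:
    """Two sequential scans of the same plate.

    ``estimated_shift`` is the (d_row, d_col) displacement of the second
    scan relative to the first, set by :func:`align`; ``valid`` marks
    pixels of the aligned second scan backed by real data.
    """

    first: GrayscaleImage
    second: GrayscaleImage
    interval_s: float = 90.0
    estimated_shift: tuple[float, float] | None = None
    valid: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.first.shape != self.second.shape:
            raise ValueError(
                f"scan shapes differ: {self.first.shape} vs {self.second.shape}"
            )
        if self.first.dpi != self.second.dpi:
            raise ValueError("scan dpi differ")
        if not self.interval_s > 0:
            raise ValueError("inter-scan interval must be positive")

    @property
    def aligned(self) -> bool:
        return self.estimated_shift is not None


def estimate_shift(
    first: GrayscaleImage,
    second: GrayscaleImage,
    max_shift_px: float = 50.0,
    upsample_factor: int = 20,
) -> tuple[float, float]:
    """Translation (d_row, d_col) of ``second`` relative to ``first``.

    Maximizes cross-correlation in the Fourier domain with subpixel
    refinement.  Raises on constant images (no texture to register) and
    on shifts beyond ``max_shift_px``.
    """
    if first.shape != second.shape:
        raise ValueError("images must have the same shape")
    a = first.as_float()
    b = second.as_float()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("cannot register a constant image")
    shift, _error, _phase = phase_cross_correlation(
        a, b, upsample_factor=upsample_factor, normalization=None
    )
    d_row, d_col = -float(shift[0]), -float(shift[1])
    if max(abs(d_row), abs(d_col)) > max_shift_px:
        raise ValueError(
            f"estimated shift ({d_row:.1f}, {d_col:.1f}) exceeds bound {max_shift_px}"
        )
    return d_row, d_col


def align(pair: ScanPair, max_shift_px: float = 50.0) -> ScanPair:
    """Resample the second scan onto the first scan's frame.

    Integer shifts are undone exactly; subpixel residuals use linear
    interpolation.  Returns a new pair with ``estimated_shift`` set and
    a validity mask excluding border pixels that had no source data.
    """
    d_row, d_col = estimate_shift(pair.first, pair.second, max_shift_px=max_shift_px)
    arr = pair.second.as_float()
    if d_row == int(d_row) and d_col == int(d_col):
        moved = np.roll(arr, (-int(d_row), -int(d_col)), axis=(0, 1))
    else:
        moved = ndimage.shift(arr, (-d_row, -d_col), order=1, mode="nearest")
    h, w = arr.shape
    valid = np.ones((h, w), dtype=bool)
    top, bot = int(np.ceil(max(0.0, -d_row))), int(np.ceil(max(0.0, d_row)))
    left, right = int(np.ceil(max(0.0, -d_col))), int(np.ceil(max(0.0, d_col)))
    if top:
        valid[:top, :] = False
    if bot:
        valid[h - bot :, :] = False
    if left:
        valid[:, :left] = False
    if right:
        valid[:, w - right :] = False
    max_val = pair.second.max_value
    aligned = GrayscaleImage(
        np.clip(np.rint(moved * max_val), 0, max_val).astype(pair.second.pixels.dtype),
        bit_depth=pair.second.bit_depth,
        dpi=pair.second.dpi,
    )
    return ScanPair(
        first=pair.first,
        second=aligned,
        interval_s=pair.interval_s,
        estimated_shift=(d_row, d_col),
        valid=valid,
    )
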