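"""Light-stimulated movement scoring and mortality calls.

The scanner's light is an aversive stimulus: a live worm moves between
two sequential scans, a dead one does not.  Movement is quantified per
worm as the fraction of its first-scan pixels that light up in the
binarized difference image of the aligned pair -- 0 for a perfectly
still worm, 1 for a worm that vacated its footprint entirely.  The
fraction saturates at one body length of travel, so it measures
responsiveness, not speed.  A worm is scored dead when its movement is
less than 10% of its area; the 10% floor absorbs residual image noise.

The hysteresis binarization keeps difference pixels above a high
threshold plus any pixels above a low threshold that are 8-connected to
them, which picks up the faint halo around strong motion blobs without
admitting isolated noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .registration import ScanPair
from .segmentation import WormRegion

__all__ = [
    "DifferenceMap",
    "MovementRecord",
    "PlateSummary",
    "difference_image",
    "robust_noise_scale",
    "default_hysteresis_thresholds",
    "hysteresis_threshold",
    "movement_fraction",
    "classify_alive",
    "score_regions",
    "score_pair",
]

#: movement fraction below which a worm is scored dead
MORTALITY_THRESHOLD = 0.10

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class DifferenceMap:
    raw: np.ndarray
    binary: np.ndarray
    low: float
    high: float
    valid: np.ndarray | None = None


@dataclass
class MovementRecord:
    worm_id: int
    area_px: int
    movement_fraction: float
    alive: bool


@dataclass
class PlateSummary:
    n_alive: int
    n_dead: int

    @property
    def n_total(self) -> int:
        return self.n_alive + self.n_dead

    @property
    def mortality(self) -> float:
        if self.n_total == 0:
            raise ValueError("no worms scored")
        return self.n_dead / self.n_total


def difference_image(pair: ScanPair) -> np.ndarray:
    """Per-pixel absolute intensity difference of an aligned pair.

    Intensities are on the [0, 1] scale; pixels outside the validity
    mask (alignment border) are zeroed so they can never register as
    movement.
    """
    if not pair.aligned:
        raise ValueError("pair must be aligned first (missing shift metadata)")
    raw = np.abs(pair.first.as_float() - pair.second.as_float())
    if pair.valid is not None:
        raw = np.where(pair.valid, raw, 0.0)
    return raw


def robust_noise_scale(raw: np.ndarray) -> float:
    """Noise scale of a difference map: 1.4826 x median absolute deviation."""
    med = np.median(raw)
    return 1.4826 * float(np.median(np.abs(raw - med)))


def default_hysteresis_thresholds(raw: np.ndarray) -> tuple[float, float]:
    """Noise-adaptive (low, high) = (4, 8) x the robust noise scale.

    On an essentially noise-free map (robust scale 0) the thresholds
    fall back to half the smallest positive difference, so that exactly
    the nonzero pixels are retained.
    """
    scale = robust_noise_scale(raw)
    if scale <= 0:
        pos = raw[raw > 0]
        if pos.size == 0:
            mx = float(raw.max()) if raw.size else 0.0
            return mx + 1.0, mx + 1.0  # nothing retained
        t = 0.5 * float(pos.min())
        return t, t
    return 4.0 * scale, 8.0 * scale


def hysteresis_threshold(raw: np.ndarray, low: float, high: float) -> np.ndarray:
    """Two-level binarization: pixels >= high seed 8-connected regions of >= low."""
    if not 0 <= low <= high:
        raise ValueError(f"need 0 <= low <= high, got low={low}, high={high}")
    weak = raw >= low
    strong = raw >= high
    if not strong.any():
        return np.zeros_like(weak)
    labels, _n = ndimage.label(weak, structure=_EIGHT)
    keep = np.unique(labels[strong])
    return np.isin(labels, keep[keep > 0])


def movement_fraction(region: WormRegion, binary: np.ndarray) -> float:
    """Share of a first-scan worm region lying in the binary difference map.

    Integer pixel arithmetic, clamped to [0, 1]; the clamp absorbs the
    (impossible here, but guarded) case of a numerator exceeding the
    region area.
    """
    if region.area_px == 0:
        raise ValueError("empty worm region")
    rows, cols = region.pixel_coords()
    white = int(binary[rows, cols].sum())
    return min(white / region.area_px, 1.0)


def classify_alive(fraction: float, threshold: float = MORTALITY_THRESHOLD) -> bool:
    """Dead iff movement is strictly less than the threshold (default 10%)."""
    if not 0 <= fraction <= 1:
        raise ValueError(f"movement fraction {fraction} outside [0, 1]")
    return fraction >= threshold


def score_regions(
    regions: list[WormRegion],
    pair: ScanPair,
    low: float | None = None,
    high: float | None = None,
    mortality_threshold: float = MORTALITY_THRESHOLD,
) -> tuple[list[MovementRecord], PlateSummary, DifferenceMap]:
    """Score movement of pre-segmented first-scan regions on an aligned pair."""
    raw = difference_image(pair)
    if low is None or high is None:
        d_low, d_high = default_hysteresis_thresholds(raw)
        low = d_low if low is None else low
        high = d_high if high is None else high
    binary = hysteresis_threshold(raw, low, high)
    records = []
    for region in regions:
        frac = movement_fraction(region, binary)
        records.append(
            MovementRecord(
                worm_id=region.id,
                area_px=region.area_px,
                movement_fraction=frac,
                alive=classify_alive(frac, mortality_threshold),
            )
        )
    n_alive = sum(r.alive for r in records)
    summary = PlateSummary(n_alive=n_alive, n_dead=len(records) - n_alive)
    return records, summary, DifferenceMap(raw, binary, low, high, pair.valid)


def score_pair(
    pair: ScanPair,
    segmenter,
    low: float | None = None,
    high: float | None = None,
    mortality_threshold: float = MORTALITY_THRESHOLD,
    min_area_px: int = 200,
    max_area_px: int = 20000,
) -> tuple[list[MovementRecord], PlateSummary, DifferenceMap]:
    """Full scoring pass: segment first scan, align, difference, threshold, score.

    ``segmenter`` is anything with a ``segment(image, min_area_px,
    max_area_px) -> list[WormRegion]`` method (a trained
    :class:`~wormscan.segmentation.SegmentationModel` or the
    intensity-threshold fallback).  Worms present only in the second
    scan are never scored: regions come from the first scan alone.
    """
    from .registration import align

    regions = segmenter.segment(pair.first, min_area_px=min_area_px, max_area_px=max_area_px)
    if not pair.aligned:
        pair = align(pair)
    return score_regions(
        regions, pair, low=low, high=high, mortality_threshold=mortality_threshold
    )
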