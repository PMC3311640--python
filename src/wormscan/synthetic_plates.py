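"""Synthetic flatbed-scanner plates with exhaustive ground truth.

Real assay plates hold 30-150 worms on agar, scanned twice 90 s apart at
2400 dpi / 16-bit; the light of the first scan startles live worms so the
second scan catches them mid-crawl.  This module renders that situation
synthetically: dark, curved worm ribbons on a lighter background, with a
controlled per-worm displacement between scans, optional whole-plate
shift, imaging noise and sub-worm artifact specks.  Every render returns
a :class:`GroundTruth` carrying per-worm pixel masks, centerline lengths
and realized displacement fractions, so each downstream stage can be
scored against an exact oracle.

Worm geometry
-------------
A worm centerline is the graph of a two-term random-phase sinusoid along
a random axis direction, rasterized with constant half-width.  Between
scans a worm slides along its own (extended) centerline - a crude
peristaltic motion that produces the partial self-overlap geometry of a
real crawling worm.  The slide distance is solved numerically so that
the displacement fraction

    |mask_t \\ mask_{t+1}| / |mask_t|

matches the requested value to within +/-0.02; a worm asked to displace
fully (fraction 1.0) slides clear of its old footprint, falling back to
a rigid sideways jump if the plate edge is in the way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import MM_PER_INCH, GrayscaleImage
from .rle import decode_mask, encode_mask

__all__ = [
    "SyntheticPlateSpec",
    "WormTruth",
    "GroundTruth",
    "PlacementError",
    "render_plate",
    "render_scan_pair",
    "render_time_series",
]

#: step (px) between consecutive centerline samples
_CENTERLINE_STEP = 0.2
#: clearance (px) enforced between footprints of distinct worms
_SEPARATION_PX = 3


class PlacementError(RuntimeError):
    """Raised when non-overlapping placements cannot be found."""


@dataclass
class SyntheticPlateSpec:
    """Parameters of a synthetic plate render.

    Intensity levels (``background_level``, ``worm_level``) and
    ``noise_sd`` are expressed as fractions of the image dynamic range;
    worms are rendered in transmission, darker than the agar.
    """

    width_px: int = 600
    height_px: int = 600
    dpi: float = 2400.0
    bit_depth: int = 16
    n_worms: int = 30
    worm_length_mm_range: tuple[float, float] = (0.5, 1.5)
    worm_width_mm: float = 0.06
    displacement_fractions: np.ndarray | None = None
    background_level: float = 0.75
    worm_level: float = 0.35
    noise_sd: float = 0.005
    texture_amplitude: float = 0.0
    n_artifacts: int = 0
    inter_scan_shift: tuple[int, int] = (0, 0)
    seed: int = 0
    max_attempts_per_worm: int = 200

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_worms < 0 or self.n_artifacts < 0:
            raise ValueError("counts must be non-negative")
        if not self.worm_level < self.background_level:
            raise ValueError("worms must be darker than the background")
        lo, hi = self.worm_length_mm_range
        if not (0 < lo <= hi):
            raise ValueError("invalid worm length range")
        if self.displacement_fractions is not None:
            f = np.asarray(self.displacement_fractions, dtype=float)
            if f.shape != (self.n_worms,):
                raise ValueError("displacement_fractions must have one entry per worm")
            if ((f < 0) | (f > 1)).any():
                raise ValueError("displacement fractions must lie in [0, 1]")
            self.displacement_fractions = f

    @property
    def worm_half_width_px(self) -> float:
        return 0.5 * self.worm_width_mm * self.dpi / MM_PER_INCH


@dataclass
class WormTruth:
    """Ground truth for one rendered worm across all scans."""

    worm_id: int
    #: per-scan flat pixel indices (row * width + col) of the worm mask
    masks: list[np.ndarray]
    #: scan-1 centerline samples, (M, 2) float (row, col)
    centerline: np.ndarray
    #: arc length of the discretized centerline, px / mm
    length_px: float
    length_mm: float
    requested_fractions: np.ndarray
    realized_fractions: np.ndarray

    @property
    def alive(self) -> bool:
        """Alive iff first-interval displacement fraction >= 0.10."""
        if len(self.realized_fractions) == 0:
            raise ValueError("single-scan truth has no movement information")
        return bool(self.realized_fractions[0] >= 0.10)


@dataclass
class GroundTruth:
    shape: tuple[int, int]
    dpi: float
    worms: list[WormTruth] = field(default_factory=list)
    artifacts: list[np.ndarray] = field(default_factory=list)
    #: integer plate shift applied to every scan after the first
    global_shift: tuple[int, int] = (0, 0)

    def mask(self, worm_id: int, scan: int = 0) -> np.ndarray:
        """Dense boolean mask of one worm in frame-1 coordinates."""
        out = np.zeros(self.shape, dtype=bool)
        out.ravel()[self.worms[worm_id].masks[scan]] = True
        return out

    def all_worms_mask(self, scan: int = 0) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for w in self.worms:
            out.ravel()[w.masks[scan]] = True
        return out

    def label_image(self, scan: int = 0) -> np.ndarray:
        """Integer label image (0 background, worm_id + 1 elsewhere)."""
        out = np.zeros(self.shape, dtype=np.int32)
        for w in self.worms:
            out.ravel()[w.masks[scan]] = w.worm_id + 1
        return out

    def to_json(self) -> str:
        def _mask_rle(idx: np.ndarray) -> dict:
            dense = np.zeros(self.shape, dtype=bool)
            dense.ravel()[idx] = True
            return encode_mask(dense)

        payload = {
            "shape": list(self.shape),
            "dpi": self.dpi,
            "global_shift": list(self.global_shift),
            "worms": [
                {
                    "worm_id": w.worm_id,
                    "masks": [_mask_rle(m) for m in w.masks],
                    "centerline": np.asarray(w.centerline).tolist(),
                    "length_px": w.length_px,
                    "length_mm": w.length_mm,
                    "requested_fractions": np.asarray(w.requested_fractions).tolist(),
                    "realized_fractions": np.asarray(w.realized_fractions).tolist(),
                }
                for w in self.worms
            ],
            "artifacts": [_mask_rle(a) for a in self.artifacts],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        shape = tuple(d["shape"])

        def _idx(rle: dict) -> np.ndarray:
            return np.flatnonzero(decode_mask(rle).ravel())

        worms = [
            WormTruth(
                worm_id=w["worm_id"],
                masks=[_idx(m) for m in w["masks"]],
                centerline=np.asarray(w["centerline"], dtype=float),
                length_px=w["length_px"],
                length_mm=w["length_mm"],
                requested_fractions=np.asarray(w["requested_fractions"], dtype=float),
                realized_fractions=np.asarray(w["realized_fractions"], dtype=float),
            )
            for w in d["worms"]
        ]
        return cls(
            shape=shape,
            dpi=d["dpi"],
            worms=worms,
            artifacts=[_idx(a) for a in d["artifacts"]],
            global_shift=tuple(d["global_shift"]),
        )


# ---------------------------------------------------------------------------
# geometry helpers


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dr * dr + dc * dc <= radius * radius
    return np.stack([dr[keep], dc[keep]], axis=1)


class _WormTrack:
    """Extended centerline of one worm, parametrized by arc length."""

    def __init__(self, rng: np.random.Generator, length_px: float, arc_budget: float):
        self.length_px = length_px
        amp1 = rng.uniform(0.04, 0.12) * length_px
        amp2 = rng.uniform(0.01, 0.05) * length_px
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        # wavelengths fixed in px so the curve extends naturally for sliding
        w1 = 2 * np.pi / length_px
        w2 = 2 * np.pi / (0.5 * length_px)
        u_max = 1.6 * (length_px + arc_budget)
        u = np.arange(0.0, u_max, _CENTERLINE_STEP)
        v = amp1 * np.sin(w1 * u + ph1) + amp2 * np.sin(w2 * u + ph2)
        pts = np.stack([u, v], axis=1)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self._arc = np.concatenate([[0.0], np.cumsum(seg)])
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        self._pts = pts @ rot.T  # local, unanchored
        self.max_offset = self._arc[-1] - length_px
        self.anchor = np.zeros(2)

    def body_points(self, arc_offset: float) -> np.ndarray:
        """Centerline samples of the body occupying [offset, offset + L]."""
        lo = np.searchsorted(self._arc, arc_offset)
        hi = np.searchsorted(self._arc, arc_offset + self.length_px, side="right")
        return self._pts[lo:hi] + self.anchor


def _rasterize(points: np.ndarray, offsets: np.ndarray, shape: tuple[int, int]):
    """Pixel indices of a constant-width ribbon around centerline samples.

    Returns (flat_indices, in_bounds) -- indices are only valid when the
    whole ribbon fits inside the frame.
    """
    px = np.unique(np.rint(points).astype(np.int64), axis=0)
    allpx = (px[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    h, w = shape
    if (
        allpx[:, 0].min() < 0
        or allpx[:, 1].min() < 0
        or allpx[:, 0].max() >= h
        or allpx[:, 1].max() >= w
    ):
        return None, False
    flat = np.unique(allpx[:, 0] * w + allpx[:, 1])
    return flat, True


def _moved_fraction(m1: np.ndarray, m2: np.ndarray) -> float:
    """|m1 \\ m2| / |m1| on sorted flat-index arrays."""
    inter = np.intersect1d(m1, m2, assume_unique=True)
    return 1.0 - len(inter) / len(m1)


# ---------------------------------------------------------------------------
# rendering


def _solve_slide(track, offsets, shape, m_prev, start, target, tol=0.01):
    """Arc distance past ``start`` realizing ``target`` moved fraction.

    Monotone bisection on the slide distance; returns
    (delta, mask, realized) or None when the track leaves the frame.
    """
    if target <= 0.0:
        return 0.0, m_prev, 0.0

    def attempt(delta):
        if start + delta > track.max_offset:
            return None
        pts = track.body_points(start + delta)
        flat, ok = _rasterize(pts, offsets, shape)
        return flat if ok else None

    if target >= 1.0:
        # slide clear of the old footprint: start one body length out
        delta = track.length_px
        for _ in range(200):
            m2 = attempt(delta)
            if m2 is None:
                return None
            if _moved_fraction(m_prev, m2) >= 1.0:
                return delta, m2, 1.0
            delta += 2.0
        return None

    lo, f_lo = 0.0, 0.0
    hi = min(1.5 * track.length_px * target + 3.0, track.length_px)
    m_hi = attempt(hi)
    if m_hi is None:
        return None
    f_hi = _moved_fraction(m_prev, m_hi)
    # widen until the bracket contains the target
    while f_hi < target:
        hi += 0.5 * track.length_px
        m_hi = attempt(hi)
        if m_hi is None:
            return None
        f_hi = _moved_fraction(m_prev, m_hi)
        if hi > 4 * track.length_px:
            break
    best = (hi, m_hi, f_hi)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        m_mid = attempt(mid)
        if m_mid is None:
            return None
        f_mid = _moved_fraction(m_prev, m_mid)
        if abs(f_mid - target) < abs(best[2] - target):
            best = (mid, m_mid, f_mid)
        if abs(f_mid - target) <= tol or hi - lo < 0.05:
            break
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    if abs(best[2] - target) > 0.02:
        return None
    return best


def _place_worm(rng, spec, shape, occupancy, fractions, sep_offsets, offsets):
    """Sample one worm placement whose whole multi-scan swath is free."""
    lo_mm, hi_mm = spec.worm_length_mm_range
    h, w = shape
    for _ in range(spec.max_attempts_per_worm):
        length_mm = rng.uniform(lo_mm, hi_mm)
        length_px = length_mm * spec.dpi / MM_PER_INCH
        budget = length_px * (1.5 + 1.5 * float(np.sum(fractions)))
        track = _WormTrack(rng, length_px, budget)
        body0 = track.body_points(0.0)
        mid = body0.mean(axis=0)
        center = np.array([rng.uniform(0, h), rng.uniform(0, w)])
        track.anchor = center - mid
        m_first, ok = _rasterize(track.body_points(0.0), offsets, shape)
        if not ok or occupancy.ravel()[m_first].any():
            continue
        masks = [m_first]
        realized = []
        start = 0.0
        failed = False
        for target in fractions:
            res = _solve_slide(track, offsets, shape, masks[-1], start, float(target))
            if res is None:
                failed = True
                break
            delta, m_next, f = res
            if target >= 1.0 and len(fractions) == 1 and f < 1.0:
                failed = True
                break
            start += delta
            masks.append(m_next)
            realized.append(f)
        if failed:
            continue
        # the union of all scans' masks (plus clearance) must be free
        union = np.unique(np.concatenate(masks))
        coords = np.stack(np.unravel_index(union, shape), axis=1)
        swath = (coords[:, None, :] + sep_offsets[None, :, :]).reshape(-1, 2)
        swath = swath[
            (swath[:, 0] >= 0) & (swath[:, 0] < h) & (swath[:, 1] >= 0) & (swath[:, 1] < w)
        ]
        swath_flat = np.unique(swath[:, 0] * w + swath[:, 1])
        if occupancy.ravel()[swath_flat].any():
            continue
        centerline = track.body_points(0.0)
        seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
        return {
            "masks": masks,
            "centerline": centerline,
            "length_px": float(seg.sum()),
            "length_mm": float(seg.sum() * MM_PER_INCH / spec.dpi),
            "realized": np.asarray(realized, dtype=float),
            "swath": swath_flat,
        }
    raise PlacementError(
        f"could not place worm without overlap after "
        f"{spec.max_attempts_per_worm} attempts (plate too dense?)"
    )


def _place_artifacts(rng, spec, shape, occupancy):
    """Small elliptical specks of worm-like intensity but sub-worm area."""
    h, w = shape
    arts = []
    for _ in range(spec.n_artifacts):
        for _attempt in range(spec.max_attempts_per_worm):
            a = rng.uniform(1.0, 3.0)
            b = rng.uniform(1.0, a)
            phi = rng.uniform(0, np.pi)
            cr, cc = rng.uniform(5, h - 5), rng.uniform(5, w - 5)
            r = int(np.ceil(a)) + 1
            dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
            x = dr * np.cos(phi) + dc * np.sin(phi)
            y = -dr * np.sin(phi) + dc * np.cos(phi)
            keep = (x / a) ** 2 + (y / b) ** 2 <= 1.0
            rows = np.rint(dr[keep] + cr).astype(int)
            cols = np.rint(dc[keep] + cc).astype(int)
            flat = np.unique(rows * w + cols)
            if occupancy.ravel()[flat].any():
                continue
            occupancy.ravel()[flat] = True
            arts.append(flat)
            break
        else:
            raise PlacementError("could not place artifact without overlap")
    return arts


def _background_field(rng, spec, shape) -> np.ndarray:
    """Agar background: flat level plus optional smooth texture."""
    bg = np.full(shape, spec.background_level, dtype=np.float64)
    if spec.texture_amplitude > 0:
        coarse = rng.normal(0.0, 1.0, size=(max(shape[0] // 32, 2), max(shape[1] // 32, 2)))
        field = ndimage.zoom(coarse, (shape[0] / coarse.shape[0], shape[1] / coarse.shape[1]), order=1)
        field = field[: shape[0], : shape[1]]
        pad = [(0, shape[0] - field.shape[0]), (0, shape[1] - field.shape[1])]
        if any(p[1] for p in pad):
            field = np.pad(field, pad, mode="edge")
        bg += spec.texture_amplitude * field / max(np.abs(field).max(), 1e-12)
    return bg


def _quantize(clean: np.ndarray, rng, spec) -> np.ndarray:
    max_val = (1 << spec.bit_depth) - 1
    img = clean.copy()
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img * max_val), 0, max_val)
    return img.astype(np.uint8 if spec.bit_depth == 8 else np.uint16)


def render_time_series(
    spec: SyntheticPlateSpec,
    n_scans: int,
    per_scan_displacements: np.ndarray | None = None,
) -> tuple[list[GrayscaleImage], GroundTruth]:
    """Render ``n_scans`` sequential scans of one synthetic plate.

    ``per_scan_displacements`` has shape ``(n_scans - 1, n_worms)``: the
    target moved fraction of each worm over each inter-scan interval.
    When omitted, the spec's ``displacement_fractions`` row (default 0.5
    for every worm) is repeated for every interval.  Worm masks in the
    returned ground truth are in frame-1 coordinates; the plate shift
    applied to later scans is recorded separately.
    """
    if n_scans < 1:
        raise ValueError("need at least one scan")
    shape = (spec.height_px, spec.width_px)
    n_int = n_scans - 1
    if per_scan_displacements is None:
        if spec.displacement_fractions is None:
            row = np.full(spec.n_worms, 0.5)
        else:
            row = np.asarray(spec.displacement_fractions, dtype=float)
        disp = np.tile(row, (n_int, 1))
    else:
        disp = np.asarray(per_scan_displacements, dtype=float)
        if disp.shape != (n_int, spec.n_worms):
            raise ValueError(
                f"per_scan_displacements must be ({n_int}, {spec.n_worms}), got {disp.shape}"
            )
        if ((disp < 0) | (disp > 1)).any():
            raise ValueError("displacement fractions must lie in [0, 1]")

    rng = np.random.default_rng(spec.seed)
    offsets = _disk_offsets(spec.worm_half_width_px)
    sep_offsets = _disk_offsets(_SEPARATION_PX)
    occupancy = np.zeros(shape, dtype=bool)

    worms: list[WormTruth] = []
    for i in range(spec.n_worms):
        placed = _place_worm(rng, spec, shape, occupancy, disp[:, i], sep_offsets, offsets)
        occupancy.ravel()[placed["swath"]] = True
        worms.append(
            WormTruth(
                worm_id=i,
                masks=placed["masks"],
                centerline=placed["centerline"],
                length_px=placed["length_px"],
                length_mm=placed["length_mm"],
                requested_fractions=disp[:, i].copy(),
                realized_fractions=placed["realized"],
            )
        )
    artifacts = _place_artifacts(rng, spec, shape, occupancy)
    bg = _background_field(rng, spec, shape)

    truth = GroundTruth(
        shape=shape,
        dpi=spec.dpi,
        worms=worms,
        artifacts=artifacts,
        global_shift=spec.inter_scan_shift,
    )

    images: list[GrayscaleImage] = []
    dr, dc = spec.inter_scan_shift
    for t in range(n_scans):
        clean = bg.copy()
        for a in artifacts:
            clean.ravel()[a] = spec.worm_level
        for wtr in worms:
            clean.ravel()[wtr.masks[min(t, len(wtr.masks) - 1)]] = spec.worm_level
        if t > 0 and (dr, dc) != (0, 0):
            shifted = np.full(shape, spec.background_level, dtype=np.float64)
            h, w = shape
            src = clean[
                max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)
            ]
            shifted[max(0, dr) : h - max(0, -dr), max(0, dc) : w - max(0, -dc)] = src
            clean = shifted
        images.append(
            GrayscaleImage(_quantize(clean, rng, spec), bit_depth=spec.bit_depth, dpi=spec.dpi)
        )
    return images, truth


def render_plate(spec: SyntheticPlateSpec) -> tuple[GrayscaleImage, GroundTruth]:
    """Render a single scan (no movement)."""
    images, truth = render_time_series(spec, n_scans=1)
    return images[0], truth


def render_scan_pair(
    spec: SyntheticPlateSpec,
) -> tuple[GrayscaleImage, GrayscaleImage, GroundTruth]:
    """Render the canonical two sequential scans of one plate."""
    images, truth = render_time_series(spec, n_scans=2)
    return images[0], images[1], truth
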