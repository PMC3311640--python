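"""Worm length from morphological skeletons.

A worm's length is measured from the morphological skeleton of its
segmented mask: thinning reduces the curved body to a 1-pixel-wide
8-connected medial curve, and the longest geodesic path between
skeleton endpoints -- orthogonal steps counted as 1 px, diagonal steps
as sqrt(2) px -- approximates the length of the straightened worm.
Taking the longest endpoint-to-endpoint path drops short side branches,
which are thinning artifacts rather than anatomy.

Two known biases of the raw weighted geodesic are corrected in
:func:`measure_region` (the toy-exact geodesic itself stays available
as :func:`skeleton_length`):

* digital-length bias: the 1/sqrt(2) step rule over-measures straight
  digital curves by up to ~8% at orientations near 22.5 degrees.  The
  reported length is therefore the Euclidean length of the geodesic
  path after a light Gaussian smoothing of its vertices, which is exact
  on axis-aligned and diagonal lines and nearly unbiased in between;
* end erosion: thinning stops short of the body ends by up to one
  half-width per end.  Each path end is extended along its outgoing
  direction to the mask boundary, less one half-width (the rounded
  cap's own radius, taken from the medial distance transform),
  recovering the eroded tip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter1d
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize as _sk_skeletonize

from .image import MM_PER_INCH
from .segmentation import WormRegion

__all__ = [
    "SkeletonRecord",
    "skeletonize",
    "skeleton_length",
    "longest_geodesic_path",
    "count_branches",
    "to_mm",
    "measure_region",
]

_SQRT2 = float(np.sqrt(2.0))
_SMOOTH_WINDOW = 5
_SMOOTH_SIGMA = 1.2


@dataclass
class SkeletonRecord:
    worm_id: int
    skeleton: np.ndarray  # (N, 2) int pixel coordinates
    length_px: float
    length_mm: float
    n_branches: int


def skeletonize(region: WormRegion) -> np.ndarray:
    """1-px-wide medial skeleton of a worm region, as (N, 2) coordinates."""
    if region.area_px == 0:
        raise ValueError("empty worm region")
    r0, c0, r1, c1 = region.bbox
    local = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)
    local[region.rows - r0 + 1, region.cols - c0 + 1] = True
    skel = _sk_skeletonize(local)
    rows, cols = np.nonzero(skel)
    return np.stack([rows + r0 - 1, cols + c0 - 1], axis=1)


def _skeleton_graph(coords: np.ndarray):
    """Sparse weighted 8-adjacency over skeleton pixels."""
    n = len(coords)
    index = {tuple(p): i for i, p in enumerate(coords)}
    src, dst, wgt = [], [], []
    for i, (r, c) in enumerate(coords):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None and j > i:
                    w = _SQRT2 if dr and dc else 1.0
                    src.append(i)
                    dst.append(j)
                    wgt.append(w)
    adj = coo_matrix((wgt + wgt, (src + dst, dst + src)), shape=(n, n)).tocsr()
    degree = np.diff(adj.indptr)
    return adj, degree


def skeleton_length(coords: np.ndarray) -> float:
    """Length (px) of the longest geodesic between skeleton endpoints.

    Steps are weighted 1 (orthogonal) and sqrt(2) (diagonal).  Endpoints
    are pixels with at most one skeleton neighbor; a closed loop (no
    endpoints) falls back to the longest shortest path from an arbitrary
    start.  A single pixel has length 0.
    """
    coords = np.asarray(coords)
    if len(coords) == 0:
        raise ValueError("empty skeleton")
    if len(coords) == 1:
        return 0.0
    adj, degree = _skeleton_graph(coords)
    endpoints = np.flatnonzero(degree <= 1)
    if endpoints.size == 0:
        endpoints = np.array([0])
    dist = dijkstra(adj, directed=False, indices=endpoints)
    finite = dist[np.isfinite(dist)]
    return float(finite.max()) if finite.size else 0.0


def longest_geodesic_path(coords: np.ndarray) -> np.ndarray:
    """Vertex sequence of the longest endpoint-to-endpoint geodesic."""
    coords = np.asarray(coords)
    if len(coords) == 0:
        raise ValueError("empty skeleton")
    if len(coords) == 1:
        return coords.astype(float)
    adj, degree = _skeleton_graph(coords)
    endpoints = np.flatnonzero(degree <= 1)
    if endpoints.size == 0:
        endpoints = np.array([0])
    dist, pred = dijkstra(adj, directed=False, indices=endpoints, return_predecessors=True)
    dist = np.where(np.isfinite(dist), dist, -1.0)
    i, j = np.unravel_index(int(np.argmax(dist)), dist.shape)
    path = [int(j)]
    while pred[i, path[-1]] >= 0:
        path.append(int(pred[i, path[-1]]))
    return coords[np.array(path[::-1])].astype(float)


def count_branches(coords: np.ndarray) -> int:
    """Number of branch pixels (more than two skeleton neighbors)."""
    if len(coords) < 2:
        return 0
    _adj, degree = _skeleton_graph(coords)
    return int((degree > 2).sum())


def to_mm(length_px: float, dpi: float) -> float:
    """Convert a pixel length to millimetres (25.4 mm per inch)."""
    if not dpi > 0:
        raise ValueError(f"dpi must be positive, got {dpi}")
    return length_px * MM_PER_INCH / dpi


def _end_extension(pts, sm, mask, half_width):
    """Length recovered by extending both path ends to the mask boundary."""
    h, w = mask.shape
    win = min(_SMOOTH_WINDOW, len(pts) - 1)
    total = 0.0
    for end, inner in ((pts[-1], sm[len(pts) - 1 - win]), (pts[0], sm[win])):
        d = end - inner
        norm = np.linalg.norm(d)
        if norm == 0:
            continue
        d = d / norm
        t = 0.0
        while t < 4 * half_width:
            p = np.rint(end + (t + 0.5) * d).astype(int)
            if not (0 <= p[0] < h and 0 <= p[1] < w) or not mask[p[0], p[1]]:
                break
            t += 0.5
        # thinning erodes roughly one half-width per end; allow slack
        total += min(max(t - half_width, 0.0), 1.5 * half_width)
    return total


def measure_region(
    region: WormRegion,
    dpi: float,
    end_correction: bool = True,
) -> SkeletonRecord:
    """Skeletonize one worm region and report its corrected length.

    The length is the Euclidean length of the smoothed longest geodesic
    path (see module docstring), plus, when ``end_correction`` is on,
    the thinning-eroded tips recovered by ray-casting from the path
    ends to the mask boundary.
    """
    coords = skeletonize(region)
    pts = longest_geodesic_path(coords)
    if len(pts) > _SMOOTH_WINDOW:
        sm = gaussian_filter1d(pts, sigma=_SMOOTH_SIGMA, axis=0, mode="nearest")
        sm[0], sm[-1] = pts[0], pts[-1]
    else:
        sm = pts.astype(float)
    length_px = float(np.linalg.norm(np.diff(sm, axis=0), axis=1).sum())
    if end_correction and len(pts) > 1:
        mask = region.dense_mask()
        # medial half-width: distance to the boundary along the skeleton
        dt = distance_transform_edt(mask)
        half_width = float(np.median(dt[pts[:, 0].astype(int), pts[:, 1].astype(int)]))
        length_px += _end_extension(pts, sm, mask, half_width)
    return SkeletonRecord(
        worm_id=region.id,
        skeleton=coords,
        length_px=length_px,
        length_mm=to_mm(length_px, dpi),
        n_branches=count_branches(coords),
    )
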