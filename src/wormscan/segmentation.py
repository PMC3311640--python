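"""Trainable filter-bank pixel classification and particle analysis.

Worms are identified in a single scan in two stages.  First a per-pixel
classifier -- a random forest over a bank of multi-scale image features
-- scores every pixel as worm or background; the classifier is trained
once from a handful of user-labeled (or, for synthetic plates,
ground-truth) pixels and then applied to any number of scans.  Second,
particle analysis keeps only 8-connected components of the binary worm
mask whose area is plausible for a single adult worm, discarding
segmentation noise below and fused clumps above the bounds.

The feature bank covers, at each scale sigma in powers of two between
``sigma_min`` and ``sigma_max`` (default 2..16 px): Gaussian blur, a
square mean filter, a Lipschitz bottom-hat (cone slope tied to the
scale, highlighting dark structures narrower than the cone), local
variance, the largest structure-tensor eigenvalue, and all ordered
differences of the Gaussian planes.  The raw intensity plane is always
included.  Optional membrane projections (oriented line means at 30
degree steps, patch width 1, thickness 19 by default) are provided but
off by default; they are an interpretation of an underdocumented
feature of the original tool and are flagged experimental.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import ndimage
from skimage.feature import structure_tensor, structure_tensor_eigenvalues
from skimage.filters import threshold_otsu
from sklearn.ensemble import RandomForestClassifier

from .image import GrayscaleImage

__all__ = [
    "FilterBankConfig",
    "PixelTrainingSet",
    "SegmentationModel",
    "WormRegion",
    "FILTER_NAMES",
    "compute_features",
    "training_set_from_masks",
    "train_model",
    "classify_pixels",
    "particle_analysis",
    "ThresholdSegmenter",
]

FILTER_NAMES = (
    "gaussian_blur",
    "mean",
    "lipschitz",
    "difference_of_gaussians",
    "variance",
    "structure",
)

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class FilterBankConfig:
    enabled_filters: tuple[str, ...] = FILTER_NAMES
    sigma_min: float = 2.0
    sigma_max: float = 16.0
    membrane_thickness: int = 19
    membrane_patch: int = 1
    use_membrane: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.enabled_filters) - set(FILTER_NAMES)
        if unknown:
            raise ValueError(f"unknown filter name(s): {sorted(unknown)}")
        if not (0 < self.sigma_min <= self.sigma_max):
            raise ValueError("need 0 < sigma_min <= sigma_max")
        if self.membrane_thickness <= 0 or self.membrane_patch <= 0:
            raise ValueError("membrane parameters must be positive")

    @property
    def scales(self) -> tuple[float, ...]:
        """Powers of two from sigma_min to sigma_max inclusive."""
        out = []
        s = self.sigma_min
        while s <= self.sigma_max * (1 + 1e-9):
            out.append(float(s))
            s *= 2
        return tuple(out)


def _lipschitz_bottom_hat(x: np.ndarray, scale: float) -> np.ndarray:
    """Bottom-hat against the lower Lipschitz cover of the inverted image.

    The cover is the largest function below the input whose slope is
    bounded by ``1 / (2 * scale)`` per pixel; it is computed as an
    iterated grayscale erosion with a 3x3 cone element (chamfer
    min-convolution), truncated once the cone exceeds the dynamic range.
    Large values mark dark objects narrower than the cone.
    """
    slope = 1.0 / (2.0 * scale)
    inv = x.max() - x
    cone = -slope * np.array(
        [[np.sqrt(2), 1, np.sqrt(2)], [1, 0, 1], [np.sqrt(2), 1, np.sqrt(2)]]
    )
    n_iter = int(np.ceil(2 * scale))
    cover = inv
    for _ in range(n_iter):
        cover = ndimage.grey_erosion(cover, structure=cone)
    return inv - cover


def _membrane_planes(x: np.ndarray, thickness: int, patch: int) -> list[np.ndarray]:
    """Oriented line-mean responses at 30-degree steps: max and mean stacks."""
    responses = []
    half = thickness // 2
    for angle in np.arange(0, 180, 30):
        theta = np.deg2rad(angle)
        t = np.linspace(-half, half, thickness)
        rows = np.rint(t * np.sin(theta)).astype(int)
        cols = np.rint(t * np.cos(theta)).astype(int)
        size = 2 * half + 1
        kernel = np.zeros((size, size))
        kernel[rows + half, cols + half] = 1.0
        if patch > 1:
            kernel = ndimage.uniform_filter(kernel, size=patch)
        kernel /= kernel.sum()
        responses.append(ndimage.convolve(x, kernel, mode="nearest"))
    stack = np.stack(responses)
    return [stack.max(axis=0), stack.mean(axis=0)]


def compute_features(
    image: GrayscaleImage, config: FilterBankConfig = FilterBankConfig()
) -> tuple[np.ndarray, list[str]]:
    """Per-pixel feature stack, shape (H, W, F), plus feature names.

    Intensities are normalized to [0, 1] first so that feature values
    are comparable across 8- and 16-bit scans.
    """
    x = image.as_float()
    if x.size == 0:
        raise ValueError("empty image")
    planes: list[np.ndarray] = [x]
    names: list[str] = ["raw"]
    scales = config.scales
    gauss = {s: ndimage.gaussian_filter(x, s) for s in scales}
    for name in config.enabled_filters:
        if name == "gaussian_blur":
            for s in scales:
                planes.append(gauss[s])
                names.append(f"gaussian_blur_{s:g}")
        elif name == "mean":
            for s in scales:
                planes.append(ndimage.uniform_filter(x, size=int(2 * s + 1)))
                names.append(f"mean_{s:g}")
        elif name == "lipschitz":
            for s in scales:
                planes.append(_lipschitz_bottom_hat(x, s))
                names.append(f"lipschitz_{s:g}")
        elif name == "difference_of_gaussians":
            for i, s1 in enumerate(scales):
                for s2 in scales[i + 1 :]:
                    planes.append(gauss[s1] - gauss[s2])
                    names.append(f"dog_{s1:g}_{s2:g}")
        elif name == "variance":
            for s in scales:
                size = int(2 * s + 1)
                m = ndimage.uniform_filter(x, size=size)
                m2 = ndimage.uniform_filter(x * x, size=size)
                planes.append(np.maximum(m2 - m * m, 0.0))
                names.append(f"variance_{s:g}")
        elif name == "structure":
            for s in scales:
                tensor = structure_tensor(x, sigma=s, order="rc")
                planes.append(structure_tensor_eigenvalues(tensor)[0])
                names.append(f"structure_{s:g}")
    if config.use_membrane:
        mx, mn = _membrane_planes(x, config.membrane_thickness, config.membrane_patch)
        planes += [mx, mn]
        names += ["membrane_max", "membrane_mean"]
    return np.stack(planes, axis=-1).astype(np.float32), names


@dataclass
class PixelTrainingSet:
    """Labeled pixels for classifier training.

    ``labels`` are 0 (background) / 1 (worm); ``provenance`` records the
    source image id and the (row, col) of every labeled pixel.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.features.ndim != 2 or len(self.features) != len(self.labels):
            raise ValueError("features must be (n_pixels, n_features) matching labels")
        classes = set(np.unique(self.labels).tolist())
        if not classes <= {0, 1}:
            raise ValueError("labels must be 0 (background) or 1 (worm)")


def training_set_from_masks(
    image: GrayscaleImage,
    worm_mask: np.ndarray,
    background_mask: np.ndarray,
    config: FilterBankConfig = FilterBankConfig(),
    n_per_class: int = 2000,
    rng: np.random.Generator | None = None,
    image_id: str = "",
) -> PixelTrainingSet:
    """Build a training set by sampling pixels from worm/background masks.

    Stands in for the manual outlining step: on synthetic plates the
    masks come from ground truth, on real scans from a user's ROI
    annotations rasterized to masks.
    """
    rng = rng or np.random.default_rng(0)
    feats, names = compute_features(image, config)
    picks = []
    for label, mask in ((1, worm_mask), (0, background_mask)):
        idx = np.flatnonzero(np.asarray(mask, bool).ravel())
        if idx.size == 0:
            raise ValueError(f"class {label} has no labeled pixels")
        take = rng.choice(idx, size=min(n_per_class, idx.size), replace=False)
        picks.append((label, np.sort(take)))
    rows_cols = []
    fvecs, labels = [], []
    h, w = image.shape
    for label, idx in picks:
        r, c = np.unravel_index(idx, (h, w))
        fvecs.append(feats[r, c])
        labels.append(np.full(idx.size, label))
        rows_cols.append(np.stack([r, c], axis=1))
    return PixelTrainingSet(
        features=np.concatenate(fvecs),
        labels=np.concatenate(labels),
        feature_names=names,
        provenance={"image_id": image_id, "pixels": np.concatenate(rows_cols).tolist()},
    )


@dataclass
class SegmentationModel:
    """A trained filter-bank pixel classifier."""

    config: FilterBankConfig
    classifier: RandomForestClassifier
    seed: int
    class_order: tuple[int, int] = (0, 1)
    n_features: int = 0

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """P(worm) per pixel from an (N, F) feature matrix, chunked."""
        if features.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {features.shape[1]} != model's {self.n_features}"
            )
        worm_col = int(np.flatnonzero(self.classifier.classes_ == 1)[0])
        out = np.empty(len(features), dtype=np.float64)
        step = 1 << 18
        for start in range(0, len(features), step):
            out[start : start + step] = self.classifier.predict_proba(
                features[start : start + step]
            )[:, worm_col]
        return out

    def segment(
        self, image: GrayscaleImage, min_area_px: int = 200, max_area_px: int = 20000
    ) -> list["WormRegion"]:
        _prob, mask = classify_pixels(image, self)
        return particle_analysis(mask, min_area_px, max_area_px)

    def save(self, path) -> None:
        joblib.dump(
            {
                "config": self.config,
                "classifier": self.classifier,
                "seed": self.seed,
                "class_order": self.class_order,
                "n_features": self.n_features,
            },
            str(path),
        )

    @classmethod
    def load(cls, path) -> "SegmentationModel":
        d = joblib.load(str(path))
        return cls(**d)


def train_model(
    training: PixelTrainingSet,
    config: FilterBankConfig = FilterBankConfig(),
    seed: int = 0,
    n_estimators: int = 100,
) -> SegmentationModel:
    """Train the random-forest pixel classifier (deterministic given seed)."""
    if len(set(np.unique(training.labels).tolist())) < 2:
        raise ValueError("training set must contain both classes")
    clf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    clf.fit(training.features, training.labels)
    return SegmentationModel(
        config=config,
        classifier=clf,
        seed=seed,
        class_order=(0, 1),
        n_features=training.features.shape[1],
    )


def classify_pixels(
    image: GrayscaleImage, model: SegmentationModel
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel worm probability map and its 0.5-threshold binary mask."""
    feats, _names = compute_features(image, model.config)
    h, w, f = feats.shape
    prob = model.predict_proba(feats.reshape(-1, f)).reshape(h, w)
    return prob, prob >= 0.5


@dataclass
class WormRegion:
    """One segmented worm: a connected pixel set with summary geometry."""

    id: int
    rows: np.ndarray
    cols: np.ndarray
    shape: tuple[int, int]

    @property
    def area_px(self) -> int:
        return len(self.rows)

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """Half-open (r0, c0, r1, c1)."""
        return (
            int(self.rows.min()),
            int(self.cols.min()),
            int(self.rows.max()) + 1,
            int(self.cols.max()) + 1,
        )

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.rows.mean()), float(self.cols.mean())

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        return self.rows, self.cols

    def dense_mask(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        out[self.rows, self.cols] = True
        return out


def particle_analysis(
    mask: np.ndarray, min_area_px: int = 200, max_area_px: int = 20000
) -> list[WormRegion]:
    """8-connected components of a binary mask, filtered by area bounds.

    Region ids are assigned in raster order of each component's first
    pixel, starting at 0, after filtering.
    """
    if min_area_px > max_area_px:
        raise ValueError("min_area_px must not exceed max_area_px")
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return []
    areas = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero((areas >= min_area_px) & (areas <= max_area_px)) + 1
    regions = []
    # scipy assigns labels in raster order of first pixel already
    for new_id, lab in enumerate(keep):
        rows, cols = np.nonzero(labels == lab)
        regions.append(WormRegion(id=new_id, rows=rows, cols=cols, shape=mask.shape))
    return regions


class ThresholdSegmenter:
    """Global-threshold segmentation for high-contrast scans.

    Otsu's threshold on intensity, keeping the dark side (worms absorb
    the scanner's transmitted light).  A lightweight alternative to the
    trained classifier for clean or synthetic images.
    """

    def __init__(self, threshold: float | None = None):
        self.threshold = threshold

    def segment(
        self, image: GrayscaleImage, min_area_px: int = 200, max_area_px: int = 20000
    ) -> list[WormRegion]:
        x = image.as_float()
        t = self.threshold if self.threshold is not None else threshold_otsu(x)
        return particle_analysis(x < t, min_area_px, max_area_px)
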