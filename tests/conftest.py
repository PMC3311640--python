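import numpy as np
import pytest

from wormscan.registration import ScanPair, align
from wormscan.segmentation import WormRegion, train_model, training_set_from_masks
from wormscan.synthetic_plates import SyntheticPlateSpec, render_plate, render_scan_pair


def regions_from_truth(truth, scan=0):
    """Ground-truth worm masks as WormRegion objects (oracle segmentation)."""
    regions = []
    for w in truth.worms:
        rows, cols = np.unravel_index(w.masks[scan], truth.shape)
        regions.append(WormRegion(id=w.worm_id, rows=rows, cols=cols, shape=truth.shape))
    return regions


MIXED_FRACTIONS = np.array([0.0, 0.05, 0.3, 0.5, 0.5, 0.7, 1.0, 0.2])


@pytest.fixture(scope="session")
def mixed_pair():
    """A noisy, globally shifted scan pair with a spread of displacements."""
    spec = SyntheticPlateSpec(
        width_px=500,
        height_px=500,
        n_worms=8,
        displacement_fractions=MIXED_FRACTIONS,
        noise_sd=0.005,
        inter_scan_shift=(4, -3),
        seed=11,
    )
    im1, im2, truth = render_scan_pair(spec)
    pair = align(ScanPair(first=im1, second=im2))
    return spec, pair, truth


@pytest.fixture(scope="session")
def clean_pair():
    """Noise-free, unshifted pair where the difference image is exact."""
    spec = SyntheticPlateSpec(
        width_px=420,
        height_px=420,
        n_worms=6,
        displacement_fractions=np.array([0.0, 0.1, 0.25, 0.5, 0.75, 1.0]),
        noise_sd=0.0,
        seed=23,
    )
    im1, im2, truth = render_scan_pair(spec)
    pair = ScanPair(first=im1, second=im2, estimated_shift=(0.0, 0.0))
    return spec, pair, truth


@pytest.fixture(scope="session")
def trained_model():
    """Pixel classifier trained on one synthetic plate."""
    spec = SyntheticPlateSpec(
        width_px=600,
        height_px=600,
        n_worms=12,
        displacement_fractions=np.zeros(12),
        noise_sd=0.01,
        texture_amplitude=0.02,
        n_artifacts=6,
        seed=42,
    )
    image, truth = render_plate(spec)
    worm_mask = truth.all_worms_mask(0)
    training = training_set_from_masks(
        image, worm_mask, ~worm_mask, n_per_class=2000, rng=np.random.default_rng(1)
    )
    return train_model(training, seed=0)
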