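"""Filter bank, pixel classifier and particle analysis."""

import numpy as np
import pytest

from wormscan.image import GrayscaleImage
from wormscan.segmentation import (
    FilterBankConfig,
    ThresholdSegmenter,
    WormRegion,
    classify_pixels,
    compute_features,
    particle_analysis,
    train_model,
    training_set_from_masks,
)
from wormscan.synthetic_plates import SyntheticPlateSpec, render_plate

from conftest import regions_from_truth


def _img(arr, bit_depth=16):
    return GrayscaleImage(np.asarray(arr), bit_depth=bit_depth)


class TestFilterBank:
    def test_scale_set_is_powers_of_two(self):
        assert FilterBankConfig().scales == (2.0, 4.0, 8.0, 16.0)

    def test_constant_image_features(self):
        image = _img(np.full((64, 64), 30000, dtype=np.uint16))
        feats, names = compute_features(image)
        level = 30000 / 65535
        for k, name in enumerate(names):
            plane = feats[..., k]
            if name.startswith(("gaussian_blur", "mean")) or name == "raw":
                assert np.allclose(plane, level, atol=1e-5), name
            elif name.startswith(("variance", "dog", "lipschitz")):
                assert np.allclose(plane, 0.0, atol=1e-5), name

    def test_gaussian_conserves_mass_of_point_source(self):
        arr = np.zeros((65, 65), dtype=np.uint16)
        arr[32, 32] = 65535
        feats, names = compute_features(
            _img(arr), FilterBankConfig(enabled_filters=("gaussian_blur",))
        )
        k = names.index("gaussian_blur_2")
        assert abs(feats[..., k].sum() - 1.0) < 0.01

    def test_variance_responds_to_worm_edges(self):
        spec = SyntheticPlateSpec(
            width_px=300, height_px=300, n_worms=4,
            displacement_fractions=np.zeros(4), noise_sd=0.0, seed=8,
        )
        image, truth = render_plate(spec)
        feats, names = compute_features(
            image, FilterBankConfig(enabled_filters=("variance",))
        )
        from scipy import ndimage

        worms = truth.all_worms_mask(0)
        edge = ndimage.binary_dilation(worms, iterations=2) & ~worms
        flat = ~ndimage.binary_dilation(worms, iterations=20)
        for s in (2, 4, 8, 16):
            plane = feats[..., names.index(f"variance_{s}")]
            assert plane[edge].mean() > plane[flat].mean()

    def test_translation_equivariance_on_interior(self):
        rng = np.random.default_rng(0)
        arr = (rng.random((120, 120)) * 65535).astype(np.uint16)
        cfg = FilterBankConfig(sigma_min=2, sigma_max=4)
        f0, _ = compute_features(_img(arr), cfg)
        f1, _ = compute_features(_img(np.roll(arr, (3, 5), axis=(0, 1))), cfg)
        # compare interior pixels beyond the largest filter support
        sl = slice(40, 80)
        assert np.allclose(
            np.roll(f0, (3, 5), axis=(0, 1))[sl, sl], f1[sl, sl], atol=1e-4
        )

    def test_unknown_filter_rejected(self):
        with pytest.raises(ValueError, match="unknown filter"):
            FilterBankConfig(enabled_filters=("sobel",))

    def test_membrane_planes_optional(self):
        arr = np.full((40, 40), 20000, dtype=np.uint16)
        feats, names = compute_features(
            _img(arr), FilterBankConfig(use_membrane=True, sigma_min=2, sigma_max=2)
        )
        assert "membrane_max" in names and "membrane_mean" in names


class TestClassifier:
    def test_separable_blobs_reach_full_training_accuracy(self):
        from wormscan.segmentation import PixelTrainingSet

        rng = np.random.default_rng(0)
        f0 = rng.normal(0, 0.1, size=(100, 3))
        f1 = rng.normal(5, 0.1, size=(100, 3))
        ts = PixelTrainingSet(
            features=np.vstack([f0, f1]).astype(np.float32),
            labels=np.r_[np.zeros(100, int), np.ones(100, int)],
            feature_names=["a", "b", "c"],
        )
        model = train_model(ts, seed=0, n_estimators=20)
        assert model.classifier.score(ts.features, ts.labels) == 1.0

    def test_single_class_training_set_rejected(self):
        from wormscan.segmentation import PixelTrainingSet

        ts = PixelTrainingSet(
            features=np.zeros((10, 2), dtype=np.float32),
            labels=np.zeros(10, int),
            feature_names=["a", "b"],
        )
        with pytest.raises(ValueError, match="both classes"):
            train_model(ts)

    def test_training_is_deterministic(self, trained_model):
        spec = SyntheticPlateSpec(
            width_px=600, height_px=600, n_worms=12,
            displacement_fractions=np.zeros(12), noise_sd=0.01,
            texture_amplitude=0.02, n_artifacts=6, seed=42,
        )
        image, truth = render_plate(spec)
        worm_mask = truth.all_worms_mask(0)
        training = training_set_from_masks(
            image, worm_mask, ~worm_mask, n_per_class=2000,
            rng=np.random.default_rng(1),
        )
        model2 = train_model(training, seed=0)
        held_out, _ = render_plate(
            SyntheticPlateSpec(width_px=200, height_px=200, n_worms=2,
                               displacement_fractions=np.zeros(2), seed=77)
        )
        p1, _ = classify_pixels(held_out, trained_model)
        p2, _ = classify_pixels(held_out, model2)
        assert np.array_equal(p1, p2)

    def test_probability_map_bounds_and_mask_definition(self, trained_model):
        image, _ = render_plate(
            SyntheticPlateSpec(width_px=200, height_px=200, n_worms=2,
                               displacement_fractions=np.zeros(2), noise_sd=0.01, seed=55)
        )
        prob, mask = classify_pixels(image, trained_model)
        assert prob.min() >= 0 and prob.max() <= 1
        assert np.array_equal(mask, prob >= 0.5)

    def test_pure_background_classifies_empty(self, trained_model):
        image = _img(np.full((100, 100), round(0.75 * 65535), dtype=np.uint16))
        _prob, mask = classify_pixels(image, trained_model)
        assert not mask.any()

    def test_cross_plate_recall_and_precision(self, trained_model):
        spec = SyntheticPlateSpec(
            width_px=600, height_px=600, n_worms=15,
            displacement_fractions=np.zeros(15), noise_sd=0.01,
            texture_amplitude=0.02, n_artifacts=6, seed=99,
        )
        image, truth = render_plate(spec)
        _prob, mask = classify_pixels(image, trained_model)
        tm = truth.all_worms_mask(0)
        tp = (mask & tm).sum()
        recall = tp / tm.sum()
        precision = tp / max(mask.sum(), 1)
        assert recall >= 0.90 and precision >= 0.90

    def test_model_round_trips_through_disk(self, trained_model, tmp_path):
        from wormscan.segmentation import SegmentationModel

        path = tmp_path / "model.joblib"
        trained_model.save(path)
        loaded = SegmentationModel.load(path)
        image, _ = render_plate(
            SyntheticPlateSpec(width_px=150, height_px=150, n_worms=1,
                               displacement_fractions=np.zeros(1), seed=12)
        )
        p1, _ = classify_pixels(image, trained_model)
        p2, _ = classify_pixels(image, loaded)
        assert np.array_equal(p1, p2)

    def test_feature_dimension_mismatch_rejected(self, trained_model):
        with pytest.raises(ValueError, match="feature dimension"):
            trained_model.predict_proba(np.zeros((5, 3)))


class TestParticleAnalysis:
    def test_empty_mask_gives_empty_list(self):
        assert particle_analysis(np.zeros((32, 32), dtype=bool)) == []

    def test_area_filter_separates_worm_from_specks(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[10:20, 10:60] = True  # 500 px worm blob
        for r, c in ((40, 40), (60, 70), (80, 15)):
            mask[r : r + 4, c : c + 5] = True  # 20 px specks
        regions = particle_analysis(mask, min_area_px=200, max_area_px=20000)
        assert len(regions) == 1
        assert regions[0].area_px == 500
        assert regions[0].bbox == (10, 10, 20, 60)

    def test_ids_follow_raster_order_of_first_pixel(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[30:34, 2:6] = True   # later in raster order
        mask[2:6, 30:34] = True   # earlier
        regions = particle_analysis(mask, min_area_px=1, max_area_px=100)
        assert [r.id for r in regions] == [0, 1]
        assert regions[0].bbox[0] == 2 and regions[1].bbox[0] == 30

    def test_eight_connectivity_joins_diagonal_pixels(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[np.arange(8), np.arange(8)] = True
        regions = particle_analysis(mask, min_area_px=1, max_area_px=100)
        assert len(regions) == 1

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError, match="min_area_px"):
            particle_analysis(np.zeros((5, 5), dtype=bool), min_area_px=10, max_area_px=5)

    def test_plate_with_artifacts_yields_exact_worm_count(self):
        spec = SyntheticPlateSpec(
            width_px=600, height_px=600, n_worms=20, n_artifacts=10,
            displacement_fractions=np.zeros(20), noise_sd=0.005, seed=31,
        )
        image, truth = render_plate(spec)
        regions = ThresholdSegmenter().segment(image)
        assert len(regions) == 20


def test_region_geometry_matches_truth(mixed_pair):
    _spec, _pair, truth = mixed_pair
    for region, w in zip(regions_from_truth(truth), truth.worms):
        assert region.area_px == len(w.masks[0])
        r0, c0, r1, c1 = region.bbox
        assert r0 <= region.centroid[0] < r1
        assert c0 <= region.centroid[1] < c1
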