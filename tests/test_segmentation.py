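"""8-bit conversion, projection, features, pixel classifier, labelling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import scaffoldcount as sc
from scaffoldcount.errors import ConfigError, InvalidSpecError
from scaffoldcount.segmentation import compute_features, default_min_area_px
from tests.conftest import render_training_field


def _stack(arr, bit_depth=16):
    return sc.ImageStack(np.asarray(arr), pixel_size=1.3, z_spacing=20.0,
                         bit_depth=bit_depth)


class TestTo8Bit:
    def test_constant_stack_maps_to_zero(self):
        out = sc.to_8bit(_stack(np.full((3, 4, 4), 500, dtype=np.uint16)))
        assert (out.voxels == 0).all()
        assert out.bit_depth == 8

    def test_full_range_endpoints_preserved(self):
        v = np.zeros((1, 2, 2), dtype=np.uint16)
        v[0, 0, 0] = 65535
        out = sc.to_8bit(_stack(v))
        assert out.voxels[0, 0, 0] == 255
        assert out.voxels[0, 1, 1] == 0

    def test_linear_map_oracle(self):
        v = np.array([[[0, 32768, 65535]]], dtype=np.uint16)
        out = sc.to_8bit(_stack(v))
        np.testing.assert_array_equal(out.voxels[0, 0], [0, 128, 255])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hnp.arrays(np.uint8, (2, 3, 3), elements=st.integers(0, 255)))
    def test_idempotent_on_full_range_8bit(self, v):
        # once an image spans [0, 255] the conversion is a fixed point
        v[0, 0, 0], v[1, 2, 2] = 0, 255
        once = sc.to_8bit(_stack(v, bit_depth=8))
        twice = sc.to_8bit(once)
        np.testing.assert_array_equal(once.voxels, twice.voxels)


class TestMaxProject:
    def test_single_section_is_identity(self):
        v = np.arange(16, dtype=np.uint16).reshape(1, 4, 4)
        np.testing.assert_array_equal(sc.max_project(_stack(v)), v[0])

    def test_bright_voxel_survives_projection(self):
        v = np.zeros((30, 8, 8), dtype=np.uint16)
        v[17, 3, 5] = 999
        assert sc.max_project(_stack(v))[3, 5] == 999

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(0)
        v = rng.integers(0, 65535, (7, 12, 9)).astype(np.uint16)
        proj = sc.max_project(_stack(v))
        oracle = np.zeros((12, 9), dtype=np.uint16)
        for i in range(12):
            for j in range(9):
                m = 0
                for k in range(7):
                    m = max(m, v[k, i, j])
                oracle[i, j] = m
        np.testing.assert_array_equal(proj, oracle)


class TestFeatures:
    def test_gaussian_of_flat_image_is_flat(self):
        flat = np.full((32, 32), 7.0)
        feats = compute_features(flat, [("gaussian", 5.0)], pixel_size=1.3)
        np.testing.assert_allclose(feats[0], 7.0, atol=1e-4)

    def test_gradient_of_constant_is_zero(self):
        flat = np.full((32, 32), 3.0)
        feats = compute_features(flat, [("gradient", 2.5)], pixel_size=1.3)
        np.testing.assert_allclose(feats[0], 0.0, atol=1e-5)

    def test_dog_peaks_at_blob_centre(self):
        yy, xx = np.mgrid[:41, :41]
        blob = np.exp(-((yy - 20) ** 2 + (xx - 20) ** 2) / (2 * 3.0**2))
        feats = compute_features(blob, [("dog", 3.9)], pixel_size=1.3)
        assert np.unravel_index(np.argmax(feats[0]), (41, 41)) == (20, 20)

    def test_unknown_filter_rejected(self):
        with pytest.raises(ConfigError):
            compute_features(np.zeros((8, 8)), [("sobel", 1.0)])

    def test_empty_config_rejected(self):
        with pytest.raises(ConfigError):
            compute_features(np.zeros((8, 8)), [])


def _separable_image():
    """A bright square on dark background: trivially separable classes."""
    img = np.full((40, 40), 10.0)
    img[10:20, 10:20] = 200.0
    lab = np.zeros((40, 40), dtype=np.uint8)
    lab[12:18, 12:18] = 2
    lab[0:5, 0:5] = 1
    return img, lab


class TestClassifier:
    def test_single_class_labels_rejected(self):
        img, lab = _separable_image()
        lab[lab == 1] = 0
        with pytest.raises(InvalidSpecError):
            sc.train_pixel_classifier([img], [lab])

    def test_separable_case_reaches_perfect_training_accuracy(self):
        img, lab = _separable_image()
        model = sc.train_pixel_classifier([img], [lab], seed=0)
        pred = sc.segment(img, model=model)
        assert pred[lab == 2].all()
        assert not pred[lab == 1].any()

    def test_same_seed_gives_identical_predictions(self):
        img, lab = _separable_image()
        rng = np.random.default_rng(1)
        probe = img + rng.normal(0, 5, img.shape)
        m1 = sc.train_pixel_classifier([img], [lab], seed=3)
        m2 = sc.train_pixel_classifier([img], [lab], seed=3)
        np.testing.assert_array_equal(
            sc.segment(probe, model=m1), sc.segment(probe, model=m2)
        )

    def test_model_reloads_identically(self, tmp_path):
        img, lab = _separable_image()
        model = sc.train_pixel_classifier([img], [lab], seed=0)
        path = tmp_path / "m.joblib"
        model.save(path)
        loaded = sc.SegmentationModel.load(path)
        np.testing.assert_array_equal(
            sc.segment(img, model=model), sc.segment(img, model=loaded)
        )

    def test_held_out_pixel_accuracy(self, trained_model, render_cfg):
        # evaluate on a freshly rendered field with known ground truth
        model, _ = trained_model
        image, truth, _, _ = render_training_field(125_000, seed=777,
                                                   cfg=render_cfg)
        pred = sc.segment(image, model=model)
        accuracy = (pred == truth).mean()
        assert accuracy >= 0.95


class TestSegmentFallback:
    def test_blank_image_gives_empty_mask(self):
        assert not sc.segment(np.zeros((16, 16)), threshold_fallback="otsu").any()

    def test_threshold_zero_is_all_foreground(self):
        img = np.random.default_rng(0).integers(0, 255, (16, 16))
        assert sc.segment(img, threshold_fallback=0).all()

    def test_no_model_no_fallback_is_an_error(self):
        with pytest.raises(ConfigError):
            sc.segment(np.zeros((8, 8)))


class TestLabelAndFilter:
    def test_two_blobs_survive_area_filter(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:15, 5:15] = True  # 100 px
        mask[25:35, 25:35] = True
        assert sc.label_and_filter(mask, min_area_px=50).n_objects == 2

    def test_speck_removed(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:7, 5:10] = True  # 10 px
        assert sc.label_and_filter(mask, min_area_px=50).n_objects == 0

    def test_labels_are_consecutive(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[2:6, 2:6] = True
        mask[10:12, 10:12] = True  # will be filtered out (4 px)
        mask[20:26, 20:26] = True
        lm = sc.label_and_filter(mask, min_area_px=10)
        assert lm.n_objects == 2
        assert set(np.unique(lm.labels)) == {0, 1, 2}

    def test_watershed_splits_touching_nuclei(self):
        # two rendered nuclei 8 um apart merge into one blob; the
        # distance-transform watershed recovers both
        cfg = sc.RenderConfig(noise_sd=0.0)
        col = sc.ColumnSpec((0.0, 0.0), 0.1, 0.1, n_sections=1,
                            z_spacing=0.02, z_start=0.0)
        z = col.z_start + 0.5 * col.z_spacing
        pts = sc.PointPattern(
            np.array([[0.046, 0.05, z], [0.054, 0.05, z]]),
            extent=(0.2, 0.2, 0.1),
        )
        truth = sc.ground_truth_projection_mask(pts, col, cfg)
        merged = sc.label_and_filter(truth, split_touching=False)
        assert merged.n_objects == 1
        split = sc.label_and_filter(
            truth, split_touching=True,
            nucleus_radius_px=5.0 / cfg.pixel_size / 2,
        )
        assert split.n_objects == 2

    def test_default_min_area_is_half_radius_disc(self):
        # pi * (2.5 um / 1.3 um/px)^2 ~ 11.6 px
        assert default_min_area_px(1.3) == 12
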