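import numpy as np
import pytest

import scribseg as ss
from scribseg.core import AnnotationMask, ImageStack
from scribseg.features import create_extractor, make_spec
from scribseg.train import (
    predict_image,
    predict_stack,
    predict_with_downscale,
    sample_training_set,
    smooth_labels_majority,
    train_classifier,
)
from oracles import majority_oracle


def _two_class_annotation(shape=(48, 48)):
    ann = np.zeros(shape, dtype=np.int32)
    ann[5:8, 5:20] = 1
    ann[30:33, 25:40] = 2
    return AnnotationMask(ann)


class TestSampleTrainingSet:
    def test_crop_features_equal_full_image(self, rng):
        img = rng.normal(size=(48, 48))
        stack = ImageStack(img, ("y", "x"))
        ann = _two_class_annotation()
        spec = make_spec("filterbank", sigmas=[0.7, 1.6])
        ts_crop = sample_training_set(stack, ann, spec, use_crops=True)
        ts_full = sample_training_set(stack, ann, spec, use_crops=False)
        np.testing.assert_array_equal(ts_crop.X, ts_full.X)
        np.testing.assert_array_equal(ts_crop.y, ts_full.y)
        np.testing.assert_array_equal(ts_crop.coords, ts_full.coords)

    def test_row_order_plane_y_x(self, rng):
        stack = ImageStack(rng.normal(size=(2, 16, 16)), ("plane", "y", "x"))
        ann = np.zeros((2, 16, 16), dtype=np.int32)
        ann[1, 3, 4] = 2
        ann[0, 10, 2] = 1
        ann[0, 2, 9] = 1
        ts = sample_training_set(stack, AnnotationMask(ann), make_spec("gaussian_baseline"))
        np.testing.assert_array_equal(
            ts.coords, [[0, 2, 9], [0, 10, 2], [1, 3, 4]]
        )

    def test_only_annotated_planes_touched(self, rng):
        """Annotations on one plane of a 100-plane stack -> one extract call."""
        stack = ImageStack(rng.normal(size=(100, 20, 20)), ("plane", "y", "x"))
        ann = np.zeros((100, 20, 20), dtype=np.int32)
        ann[3, 4:6, 4:12] = 1
        ann[3, 14:16, 4:12] = 2
        ext = create_extractor(make_spec("gaussian_baseline"))
        calls = []
        orig = ext.extract
        ext.extract = lambda plane: (calls.append(plane.shape), orig(plane))[1]
        sample_training_set(stack, AnnotationMask(ann), ext)
        assert len(calls) == 1

    def test_fewer_than_two_classes_rejected(self, rng):
        stack = ImageStack(rng.normal(size=(16, 16)), ("y", "x"))
        ann = np.zeros((16, 16), dtype=np.int32)
        with pytest.raises(ValueError, match=">= 2"):
            sample_training_set(stack, AnnotationMask(ann), make_spec("gaussian_baseline"))
        ann[2, 2] = 1
        with pytest.raises(ValueError, match=">= 2"):
            sample_training_set(stack, AnnotationMask(ann), make_spec("gaussian_baseline"))

    def test_shape_mismatch_rejected(self, rng):
        stack = ImageStack(rng.normal(size=(16, 16)), ("y", "x"))
        ann = AnnotationMask(np.ones((17, 16), dtype=np.int32))
        with pytest.raises(ValueError, match="spatial shape"):
            sample_training_set(stack, ann, make_spec("gaussian_baseline"))


class TestTrainClassifier:
    def _separable_ts(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(0.0, 0.1, size=(40, 3))
        x2 = rng.normal(5.0, 0.1, size=(40, 3))
        X = np.vstack([x1, x2])
        y = np.array([1] * 40 + [2] * 40)
        coords = np.zeros((80, 3), dtype=int)
        return ss.TrainingSet(X=X, y=y, coords=coords,
                              extractor=make_spec("gaussian_baseline"),
                              n_image_channels=1)

    @pytest.mark.parametrize("kind", ["gradient_boosted_trees", "random_forest"])
    def test_separable_training_accuracy(self, kind):
        ts = self._separable_ts()
        model = train_classifier(ts, kind=kind, seed=0)
        assert (model.classifier.predict(ts.X) == ts.y).mean() == 1.0

    def test_determinism_same_seed(self):
        ts = self._separable_ts()
        rng = np.random.default_rng(1)
        probe = rng.normal(2.5, 2.0, size=(50, 3))
        m1 = train_classifier(ts, seed=7)
        m2 = train_classifier(ts, seed=7)
        np.testing.assert_array_equal(
            m1.classifier.predict_proba(probe), m2.classifier.predict_proba(probe)
        )

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="classifier kind"):
            train_classifier(self._separable_ts(), kind="svm")

    def test_constant_features_still_fit(self, caplog):
        X = np.ones((10, 2))
        y = np.array([1, 2] * 5)
        ts = ss.TrainingSet(X=X, y=y, coords=np.zeros((10, 3), dtype=int),
                            extractor=make_spec("gaussian_baseline"),
                            n_image_channels=1)
        model = train_classifier(ts, seed=0)  # must not raise
        assert set(model.classes) == {1, 2}


class TestPredict:
    def test_output_shape_and_classes(self, gaussian_model, small_fixture):
        stack, _ = small_fixture
        labels = predict_image(stack.plane(0), gaussian_model)
        assert labels.shape == stack.spatial_shape
        assert set(np.unique(labels)) <= set(gaussian_model.classes)

    def test_probabilities_sum_to_one(self, gaussian_model, small_fixture):
        stack, _ = small_fixture
        _, proba = predict_image(stack.plane(0), gaussian_model, return_proba=True)
        np.testing.assert_allclose(proba.sum(axis=0), 1.0, atol=1e-6)

    def test_single_texture_interior(self, rng):
        """A model trained on two intensities sees a pure class-A image."""
        img = np.concatenate([
            rng.normal(0.2, 0.02, (24, 48)), rng.normal(0.8, 0.02, (24, 48))
        ])
        stack = ImageStack(img, ("y", "x"))
        ann = np.zeros((48, 48), dtype=np.int32)
        ann[4:8, 4:40] = 1
        ann[40:44, 4:40] = 2
        ts = sample_training_set(stack, AnnotationMask(ann), make_spec("gaussian_baseline"))
        model = train_classifier(ts, seed=0)
        pure = rng.normal(0.2, 0.02, (32, 32))
        labels = predict_image(pure, model)
        assert (labels[4:-4, 4:-4] == 1).mean() >= 0.99

    def test_channel_mismatch(self, gaussian_model, rng):
        with pytest.raises(ValueError, match="channels"):
            predict_image(rng.normal(size=(3, 16, 16)), gaussian_model)


class TestPredictStack:
    def test_equals_planewise_prediction(self, gaussian_model, rng):
        data = rng.normal(size=(3, 32, 32))
        stack = ImageStack(data, ("plane", "y", "x"))
        out = predict_stack(stack, gaussian_model)
        assert out.shape == (3, 32, 32)
        for p in range(3):
            np.testing.assert_array_equal(
                out[p], predict_image(data[p], gaussian_model)
            )

    def test_plane_subset(self, gaussian_model, rng):
        data = rng.normal(size=(6, 16, 16))
        stack = ImageStack(data, ("plane", "y", "x"))
        out = predict_stack(stack, gaussian_model, planes=[0, 5])
        assert out.shape == (2, 16, 16)
        np.testing.assert_array_equal(out[1], predict_image(data[5], gaussian_model))

    def test_empty_selection_rejected(self, gaussian_model, rng):
        stack = ImageStack(rng.normal(size=(2, 16, 16)), ("plane", "y", "x"))
        with pytest.raises(ValueError, match="empty"):
            predict_stack(stack, gaussian_model, planes=[])

    def test_zarr_stack_streams_per_plane(self, gaussian_model, rng, tmp_path):
        """Zarr-backed stack is processed without full-feature materialization:
        each extract call sees exactly one plane."""
        import zarr

        z = zarr.open_array(
            str(tmp_path / "s.zarr"), mode="w", shape=(8, 24, 24), dtype="f8"
        )
        z[:] = rng.normal(size=(8, 24, 24))
        stack = ImageStack(z, ("plane", "y", "x"))
        shapes = []
        import scribseg.train as trainmod

        orig_create = trainmod.create_extractor

        def spy_create(spec):
            ext = orig_create(spec)
            orig = ext.extract
            ext.extract = lambda plane: (shapes.append(plane.shape), orig(plane))[1]
            return ext

        trainmod.create_extractor = spy_create
        try:
            out = predict_stack(stack, gaussian_model)
        finally:
            trainmod.create_extractor = orig_create
        assert out.shape == (8, 24, 24)
        assert shapes == [(1, 24, 24)] * 8  # one plane at a time


class TestMajorityFilter:
    def test_uniform_unchanged(self):
        labels = np.full((10, 10), 3, dtype=np.int32)
        np.testing.assert_array_equal(smooth_labels_majority(labels, 1), labels)

    def test_isolated_pixel_removed(self):
        labels = np.ones((9, 9), dtype=np.int32)
        labels[4, 4] = 2
        out = smooth_labels_majority(labels, 1)
        assert out[4, 4] == 1
        np.testing.assert_array_equal(out, majority_oracle(labels, 1))

    def test_matches_oracle_random(self, rng):
        labels = rng.integers(1, 4, size=(12, 12)).astype(np.int32)
        np.testing.assert_array_equal(
            smooth_labels_majority(labels, 1), majority_oracle(labels, 1)
        )

    def test_idempotent_on_two_block_map(self):
        labels = np.ones((10, 10), dtype=np.int32)
        labels[:, 5:] = 2
        once = smooth_labels_majority(labels, 1)
        twice = smooth_labels_majority(once, 1)
        np.testing.assert_array_equal(once, labels)  # straight boundary stable
        np.testing.assert_array_equal(once, twice)

    def test_radius_validated(self):
        with pytest.raises(ValueError):
            smooth_labels_majority(np.ones((4, 4), dtype=int), 0)


class TestPredictWithDownscale:
    def test_factor1_no_majority_equals_predict_image(self, gaussian_model, rng):
        img = rng.normal(size=(32, 32))
        np.testing.assert_array_equal(
            predict_with_downscale(img, gaussian_model, factor=1, majority_radius=None),
            predict_image(img, gaussian_model),
        )

    @pytest.mark.parametrize("factor", [1, 2, 3])
    def test_output_shape_unchanged(self, gaussian_model, rng, factor):
        img = rng.normal(size=(33, 47))
        out = predict_with_downscale(img, gaussian_model, factor=factor)
        assert out.shape == (33, 47)

    def test_factor_too_large(self, gaussian_model, rng):
        with pytest.raises(ValueError, match="exceeds"):
            predict_with_downscale(rng.normal(size=(16, 16)), gaussian_model, factor=20)
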