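"""AlexNet/VGG16 shape chains, shape inference and classifier training."""

import numpy as np
import pytest

from cystaug.classifiers import (
    LayerSpec,
    ShapeMismatchError,
    TrainSpec,
    alexnet_plan,
    build_alexnet,
    build_vgg16,
    flatten_width,
    infer_shapes,
    predict_scores,
    train_classifier,
    vgg16_plan,
)
from cystaug.dataset import ImageDataset
from cystaug.synthetic import SyntheticDatasetConfig, generate_dataset

ALEXNET_CHAIN = [
    (227, 227, 1),
    (55, 55, 96), (27, 27, 96), (27, 27, 256), (13, 13, 256),
    (13, 13, 384), (13, 13, 384), (13, 13, 256), (6, 6, 256),
    (9216,), (4096,), (4096,), (4,),
]

VGG16_CHAIN = [
    (224, 224, 1),
    (224, 224, 64), (112, 112, 64), (112, 112, 128), (56, 56, 128),
    (56, 56, 256), (28, 28, 256), (28, 28, 512), (14, 14, 512),
    (14, 14, 512), (7, 7, 512),
    (25088,), (4096,), (4096,), (4,),
]


class TestShapeInference:
    def test_alexnet_chain_exact(self):
        assert infer_shapes(alexnet_plan(), 227) == ALEXNET_CHAIN

    def test_vgg16_chain_exact(self):
        assert infer_shapes(vgg16_plan(), 224) == VGG16_CHAIN

    def test_flatten_widths(self):
        assert flatten_width(alexnet_plan(), 227) == 9216
        assert flatten_width(vgg16_plan(), 224) == 25088

    def test_identity_conv(self):
        chain = infer_shapes([LayerSpec("conv", 8, 1, 1, 0)], 17)
        assert chain == [(17, 17, 1), (17, 17, 8)]

    def test_pool_55_to_27(self):
        chain = infer_shapes([LayerSpec("pool", 1, 3, 2, 0)], 55)
        assert chain[-1] == (27, 27, 1)

    def test_mismatch_names_offending_layer(self):
        bad = [LayerSpec("conv", 96, 11, 4, 0, expected_size=54)]
        with pytest.raises(ShapeMismatchError, match="layer 0"):
            infer_shapes(bad, 227)


class TestRealizedNetworks:
    def test_full_alexnet_forward(self):
        """The realized full-scale network honors its plan end to end."""
        model = build_alexnet()
        assert model.shape_chain == ALEXNET_CHAIN
        scores = model.scores(np.random.default_rng(0).random((1, 227, 227)))
        assert scores.shape == (1, 4)
        assert scores.sum() == pytest.approx(1.0, abs=1e-6)

    def test_vgg16_plan_validated_on_build_input(self):
        # full VGG16 weights are large; the plan chain itself is the contract
        assert infer_shapes(vgg16_plan(), 224)[-1] == (4,)

    def test_reduced_profiles_are_flagged(self):
        a = build_alexnet(reduced=True)
        v = build_vgg16(reduced=True)
        assert a.input_size == v.input_size == 28
        assert "reduced" in a.name and "reduced" in v.name


@pytest.fixture(scope="module")
def two_class_dataset():
    cfg = SyntheticDatasetConfig(per_class_counts=(60, 60, 0, 0), master_seed=2)
    return generate_dataset(cfg)


class TestTraining:
    def test_scores_on_simplex(self, two_class_dataset):
        model = build_alexnet(reduced=True, seed=0)
        s = predict_scores(model, two_class_dataset)
        assert s.shape == (120, 4)
        assert np.allclose(s.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(s >= 0)

    def test_separable_two_class_accuracy(self, two_class_dataset):
        model = build_alexnet(reduced=True, seed=0)
        spec = TrainSpec(solver="Adam", batch_size=8, epochs=5, seed=0)
        train_classifier(model, two_class_dataset, spec)
        assert model.history[-1]["accuracy"] > 0.9

    def test_seeded_determinism(self, two_class_dataset):
        losses = []
        for _ in range(2):
            model = build_alexnet(reduced=True, seed=3)
            spec = TrainSpec(solver="RMSprop", batch_size=16, epochs=2, seed=3)
            train_classifier(model, two_class_dataset, spec)
            losses.append(model.history[-1]["loss"])
        assert losses[0] == losses[1]

    def test_missing_class_warns_but_trains(self, two_class_dataset, caplog):
        model = build_alexnet(reduced=True, seed=0)
        with caplog.at_level("WARNING", logger="cystaug.classifiers"):
            train_classifier(model, two_class_dataset, TrainSpec(epochs=1, seed=0))
        assert any("absent" in r.message for r in caplog.records)

    def test_empty_training_set_rejected(self):
        model = build_alexnet(reduced=True)
        empty = ImageDataset(np.zeros((0, 28, 28)), np.zeros(0, dtype=int))
        with pytest.raises(ValueError):
            train_classifier(model, empty, TrainSpec())

    def test_predict_empty_returns_empty_matrix(self):
        model = build_alexnet(reduced=True)
        assert predict_scores(model, np.zeros((0, 28, 28))).shape == (0, 4)

    def test_invalid_solver_rejected(self):
        with pytest.raises(ValueError):
            TrainSpec(solver="SGD")
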