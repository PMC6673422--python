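"""Three-direction CNN: gradients, determinism, learning and cross-validation."""

import numpy as np
import pytest

from scopemotion import (
    CnnConfig,
    DirectionLabel,
    build_model,
    cross_validate,
    predict_batch,
    predict_direction,
    train_model,
)
from scopemotion.direction_cnn import _Network, _prepare_images
from scopemotion.synthetic import generate_flow_color_dataset

TINY = CnnConfig(
    input_width=40,
    input_height=32,
    conv_channels=(8, 16, 16),
    fc_units=32,
    dropout_rate=0.0,
    epochs=60,
    patience=60,
    batch_size=4,
    seed=5,
    learning_rate=3e-3,
    momentum=0.9,
    l2=1e-8,
)


@pytest.fixture(scope="module")
def tiny_dataset():
    return generate_flow_color_dataset(20, image_size=(32, 40), seed=3)


@pytest.fixture(scope="module")
def trained_tiny(tiny_dataset):
    images, labels = tiny_dataset
    model, log = train_model(build_model(TINY), images, labels, TINY)
    return model, log


class TestBuildModel:
    def test_same_seed_same_weights(self):
        a = build_model(TINY)
        b = build_model(TINY)
        assert a.params.keys() == b.params.keys()
        for key in a.params:
            assert np.array_equal(a.params[key], b.params[key])

    def test_default_config_accepts_reference_input(self, rng):
        model = build_model(CnnConfig(seed=1))
        image = rng.integers(0, 256, size=(150, 170, 3), dtype=np.uint8)
        net = _Network.__new__(_Network)
        net.config, net.params = model.config, model.params
        probs, _ = net.forward(_prepare_images([image], model.config))
        assert probs.shape == (1, 3)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_collapsing_input_rejected(self):
        with pytest.raises(ValueError):
            CnnConfig(input_width=10, input_height=10)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            CnnConfig(learning_rate_range=(1e-2, 1e-7))
        with pytest.raises(ValueError):
            CnnConfig(dropout_rate=1.0)


class TestGradients:
    def test_backward_matches_numerical_gradient(self, rng):
        config = CnnConfig(
            input_width=28, input_height=24, conv_channels=(3, 4, 5), fc_units=8,
            dropout_rate=0.0, batch_size=4,
        )
        net = _Network(config, np.random.default_rng(0))
        net.params = {k: v.astype(np.float64) for k, v in net.params.items()}
        x = rng.random((3, 24, 28, 3))
        y = np.array([0, 1, 2])
        _, cache = net.forward(x)
        grads = net.backward(cache, y)

        def loss():
            p, _ = net.forward(x)
            return -np.log(p[np.arange(3), y]).mean()

        check_rng = np.random.default_rng(99)
        for key, w in net.params.items():
            for _ in range(3):
                idx = tuple(check_rng.integers(0, s) for s in w.shape)
                eps = 1e-6
                orig = w[idx]
                w[idx] = orig + eps
                lp = loss()
                w[idx] = orig - eps
                lm = loss()
                w[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                rel = abs(numeric - grads[key][idx]) / max(
                    1e-8, abs(numeric) + abs(grads[key][idx])
                )
                assert rel < 1e-5, key


class TestTraining:
    def test_learns_hue_separable_classes(self, trained_tiny, tiny_dataset):
        model, log = trained_tiny
        images, labels = tiny_dataset
        preds = predict_batch(model, images)
        assert (preds == labels).mean() >= 0.98
        # loss decreased over training
        assert log[-1]["train_loss"] < log[0]["train_loss"]

    def test_prediction_deterministic(self, trained_tiny, tiny_dataset):
        model, _ = trained_tiny
        images, _ = tiny_dataset
        label_a, probs_a = predict_direction(model, images[0])
        label_b, probs_b = predict_direction(model, images[0])
        assert label_a == label_b
        assert probs_a == probs_b
        assert sum(probs_a) == pytest.approx(1.0, abs=1e-6)

    def test_pure_class_images_classified(self, trained_tiny, tiny_dataset):
        model, _ = trained_tiny
        images, labels = tiny_dataset
        label, _ = predict_direction(model, images[0])
        assert label == DirectionLabel("insertion")

    def test_untrained_model_refuses_prediction(self, tiny_dataset):
        images, _ = tiny_dataset
        with pytest.raises(RuntimeError):
            predict_direction(build_model(TINY), images[0])

    def test_missing_class_rejected(self, tiny_dataset):
        images, labels = tiny_dataset
        keep = labels != 2
        with pytest.raises(ValueError):
            train_model(build_model(TINY), images[keep], labels[keep], TINY)

    def test_training_reproducible_with_fixed_seed(self, tiny_dataset):
        images, labels = tiny_dataset
        subset = np.r_[0:10, 20:30, 40:50]
        config = CnnConfig(
            input_width=40, input_height=32, conv_channels=(4, 8, 8), fc_units=16,
            dropout_rate=0.5, epochs=8, patience=8, batch_size=4, seed=21,
            n_search_draws=1,
        )
        runs = []
        for _ in range(2):
            _, log = train_model(
                build_model(config), images[subset], labels[subset], config
            )
            runs.append([entry["val_accuracy"] for entry in log])
        assert runs[0] == runs[1]

    def test_shuffled_labels_give_chance_accuracy(self, rng):
        images, labels = generate_flow_color_dataset(40, image_size=(32, 40), seed=9)
        shuffled = labels.copy()
        rng.shuffle(shuffled)
        config = CnnConfig(
            input_width=40, input_height=32, conv_channels=(4, 8, 8), fc_units=16,
            dropout_rate=0.0, epochs=10, patience=10, batch_size=8, seed=2,
            learning_rate=3e-3, momentum=0.9, l2=1e-8,
        )
        train_idx, test_idx = np.arange(0, 60), np.arange(60, 120)
        perm = rng.permutation(120)
        train_idx, test_idx = perm[:60], perm[60:]
        model, _ = train_model(
            build_model(config), images[train_idx], shuffled[train_idx], config
        )
        acc = (predict_batch(model, images[test_idx]) == shuffled[test_idx]).mean()
        assert abs(acc - 1 / 3) <= 0.1


class TestCrossValidate:
    def test_partition_and_perfect_separation(self, tiny_dataset):
        images, labels = tiny_dataset
        cm = cross_validate(images, labels, TINY, k=5)
        assert cm.total == len(labels)
        # column sums recover the true class counts: every sample validated once
        assert cm.column_sums.tolist() == [20, 20, 20]
        assert int(cm.counts.sum() - np.trace(cm.counts)) == 0

    def test_reproducible_fold_assignment(self, tiny_dataset):
        images, labels = tiny_dataset
        subset = np.r_[0:8, 20:28, 40:48]
        config = CnnConfig(
            input_width=40, input_height=32, conv_channels=(4, 8, 8), fc_units=16,
            dropout_rate=0.0, epochs=6, patience=6, batch_size=4, seed=13,
            learning_rate=3e-3, momentum=0.9, l2=1e-8,
        )
        a = cross_validate(images[subset], labels[subset], config, k=4)
        b = cross_validate(images[subset], labels[subset], config, k=4)
        assert np.array_equal(a.counts, b.counts)

    def test_k_larger_than_dataset_rejected(self, tiny_dataset):
        images, labels = tiny_dataset
        with pytest.raises(ValueError):
            cross_validate(images[:4], labels[:4], TINY, k=5)
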