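"""Classifier architecture contracts, seeding, and learning sanity."""

import numpy as np
import pytest

from psiscan.network import ModelConfig, MultiChannelCNN, _to_onehot_labels, build_model
from psiscan.synthetic_data import GeneratorSpec, generate
from psiscan.encoding import encode_dataset


def _random_inputs(n, rows, cols, seed=0):
    rng = np.random.default_rng(seed)
    X = np.zeros((n, rows, cols))
    X[np.arange(n)[:, None], np.arange(rows)[None, :], rng.integers(0, cols, (n, rows))] = 1
    y = rng.integers(0, 2, n)
    return X, y


class TestArchitecture:
    def test_concatenated_feature_length(self):
        cfg = ModelConfig.uniform(height=5, n_channels=9, filters_per_channel=32,
                                  input_rows=21, input_cols=12)
        model = build_model(cfg)
        # global max-pool leaves one value per filter: 9 channels x 32 filters
        assert model.w1.shape[0] == 9 * 32 == 288

    def test_conv_layer_parameter_count(self):
        cfg = ModelConfig.uniform(height=5, n_channels=1, filters_per_channel=32,
                                  input_rows=21, input_cols=12)
        # (height * width * 1 + 1 bias) * filters
        assert build_model(cfg).conv_layer_parameter_count(0) == (5 * 12 + 1) * 32 == 1952

    def test_output_is_two_class_distribution(self, small_config):
        model = build_model(small_config)
        X, _ = _random_inputs(5, 11, 4)
        probs = model.predict_proba(X)
        assert probs.shape == (5, 2)
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_filter_height_exceeding_rows_rejected(self):
        with pytest.raises(ValueError, match="height"):
            ModelConfig.uniform(height=25, n_channels=2, input_rows=21, input_cols=4)

    def test_both_alphabet_widths_accepted(self):
        for cols in (4, 12):
            cfg = ModelConfig.uniform(height=3, n_channels=2, filters_per_channel=2,
                                      input_rows=11, input_cols=cols, dense_units=8)
            X = np.zeros((2, 11, cols)); X[:, :, 0] = 1
            assert build_model(cfg).predict_proba(X).shape == (2, 2)

    def test_shape_mismatch_rejected(self, small_config):
        model = build_model(small_config)
        with pytest.raises(ValueError, match="shape"):
            model.predict_proba(np.zeros((3, 7, 4)))


class TestPredict:
    def test_empty_batch(self, small_config):
        probs, labels = build_model(small_config).predict(np.zeros((0, 11, 4)))
        assert probs.shape == (0, 2) and labels.shape == (0,)

    def test_argmax_and_tie_to_positive(self, small_config):
        model = build_model(small_config)
        # force identical logits -> exact 0.5/0.5 tie resolves to class 1
        model.w2[:] = 0.0
        model.b2[:] = 0.0
        X, _ = _random_inputs(4, 11, 4)
        probs, labels = model.predict(X)
        assert np.allclose(probs, 0.5)
        assert np.all(labels == 1)


class TestTraining:
    def test_empty_training_set_rejected(self, small_config):
        with pytest.raises(ValueError, match="empty"):
            build_model(small_config).fit(np.zeros((0, 11, 4)), np.zeros((0,)))

    def test_single_class_labels_warn(self, small_config):
        X, _ = _random_inputs(8, 11, 4)
        with pytest.warns(UserWarning, match="single class"):
            build_model(small_config).fit(X, np.ones(8))

    def test_identical_seed_identical_history(self, small_config):
        X, y = _random_inputs(20, 11, 4)
        h1 = build_model(small_config).fit(X, y, X, y).training_history
        h2 = build_model(small_config).fit(X, y, X, y).training_history
        assert h1 == h2

    def test_gradients_match_numerical(self):
        cfg = ModelConfig.uniform(height=3, n_channels=2, filters_per_channel=3,
                                  input_rows=7, input_cols=4, dense_units=5,
                                  dropout_p=0.0, seed=0)
        model = build_model(cfg)
        rng = np.random.default_rng(1)
        X = rng.random((5, 7, 4))
        y = _to_onehot_labels(rng.integers(0, 2, 5))

        def loss():
            probs, _ = model._forward(X)
            return -np.mean(np.sum(y * np.log(probs), axis=1))

        probs, cache = model._forward(X)
        grads = model._backward(X, y, probs, cache)
        eps = 1e-6
        for p, g in zip(model._params(), grads):
            flat = p.reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[idx]
                flat[idx] = orig + eps; lp = loss()
                flat[idx] = orig - eps; lm = loss()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - g.reshape(-1)[idx]) < 1e-5 * max(1.0, abs(num))

    def test_learns_separable_synthetic_signal(self):
        """On a strongly separable generator draw, a small model beats the
        0.5 chance level of the balanced classes by a wide margin."""
        spec = GeneratorSpec(n_per_class=60, xi=5, motif="GGU", strength=1.0,
                             motif_offset=-2, seed=3)
        ds = generate(spec)
        X = encode_dataset(ds, kind="general")
        y = np.array(ds.labels)
        order = np.random.default_rng(0).permutation(len(y))
        X, y = X[order], y[order]
        cfg = ModelConfig.uniform(height=3, n_channels=3, filters_per_channel=8,
                                  input_rows=11, input_cols=4, dense_units=32,
                                  dropout_p=0.2, batch_size=16, max_epochs=40,
                                  learning_rate=0.003, seed=0)
        model = build_model(cfg).fit(X[:100], y[:100], X[100:], y[100:])
        assert model.training_history[-1]["val_acc"] > 0.8


class TestPersistence:
    def test_save_load_round_trip(self, small_config, tmp_path):
        X, y = _random_inputs(16, 11, 4)
        model = build_model(small_config).fit(X, y)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = MultiChannelCNN.load(path)
        assert loaded.config == small_config
        assert np.allclose(model.predict_proba(X), loaded.predict_proba(X))
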