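"""Classifier architecture contracts, determinism and trainability."""

import numpy as np
import pytest

from mlsnet import (
    ModelConfig,
    build_model,
    load_model,
    predict,
    save_model,
    train,
)
from mlsnet.io_poly import ConfigurationError


def separable_gaussians(rng, n_per_class=120, spread=0.25):
    """Three well-separated Gaussian clusters in 10-D feature space."""
    centers = np.zeros((3, 10))
    centers[0, 5] = 3.0   # "WAKE": high EMG RMS
    centers[1, 0] = 3.0   # "NREM": high delta
    centers[2, 4] = 3.0   # "REM": high theta/delta
    X, y = [], []
    labels = ("WAKE", "NREM", "REM")
    # interleave run-structured blocks so sequences contain all classes
    for block in range(n_per_class // 10):
        for c in range(3):
            X.append(centers[c] + spread * rng.normal(size=(10, 10)))
            y.extend([labels[c]] * 10)
    return np.vstack(X), np.array(y, dtype=object)


class TestArchitecture:
    def test_mls_recurrent_width_is_twice_per_direction(self):
        m = build_model(ModelConfig(variant="mls", lstm_units_per_direction=16))
        assert m.recurrent_state_width == 32

    def test_smls_has_no_recurrent_layer(self):
        m = build_model(ModelConfig(variant="smls"))
        assert not m.has_recurrent_layer

    def test_stmls_has_recurrent_layer_and_conv(self):
        m = build_model(ModelConfig(variant="stmls"))
        assert m.has_recurrent_layer
        assert len(m._conv_layers) > 0

    def test_unknown_variant(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(variant="cnnlstm")

    def test_seeded_init_is_bit_identical(self):
        a = build_model(ModelConfig(seed=5))
        b = build_model(ModelConfig(seed=5))
        np.testing.assert_array_equal(a.parameter_vector(), b.parameter_vector())

    def test_parameter_count_independent_of_sequence_length(self):
        a = build_model(ModelConfig(sequence_length=16))
        b = build_model(ModelConfig(sequence_length=256))
        assert a.parameter_count() == b.parameter_count()


class TestPredict:
    def test_probability_simplex(self, rng):
        m = build_model(ModelConfig(seed=0))
        F = rng.normal(size=(150, 10))
        proba = m.predict_proba(F)
        assert proba.shape == (150, 3)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert (proba >= 0).all()

    def test_one_prediction_per_epoch_with_labels(self, rng):
        m = build_model(ModelConfig(seed=0))
        preds = predict(m, rng.normal(size=(37, 10)))
        assert len(preds) == 37
        assert all(p.label in ("WAKE", "NREM", "REM") for p in preds)

    def test_untrained_model_reproducible(self, rng):
        F = rng.normal(size=(64, 10))
        p1 = build_model(ModelConfig(seed=3)).predict_proba(F)
        p2 = build_model(ModelConfig(seed=3)).predict_proba(F)
        np.testing.assert_array_equal(p1, p2)

    def test_width_mismatch(self, rng):
        m = build_model(ModelConfig(seed=0))
        with pytest.raises(ValueError):
            m.predict_proba(rng.normal(size=(10, 7)))


class TestTrain:
    def test_separable_data_reaches_high_accuracy(self, rng):
        X, y = separable_gaussians(rng)
        m = build_model(ModelConfig(seed=1, sequence_length=30))
        m, curves = train(m, X, y, iterations=120)
        assert curves["accuracy"][-1] >= 0.99
        assert curves["loss"][-1] < curves["loss"][0]
        assert len(curves["loss"]) == 120

    def test_zero_iterations_is_identity(self, rng):
        X, y = separable_gaussians(rng, n_per_class=30)
        m = build_model(ModelConfig(seed=1))
        before = m.parameter_vector()
        m, curves = train(m, X, y, iterations=0)
        np.testing.assert_array_equal(m.parameter_vector(), before)
        assert curves["loss"] == [] and curves["accuracy"] == []

    def test_same_seed_same_final_parameters(self, rng):
        X, y = separable_gaussians(rng, n_per_class=30)
        finals = []
        for _ in range(2):
            m = build_model(ModelConfig(seed=9))
            m, _ = train(m, X, y, iterations=5)
            finals.append(m.parameter_vector())
        np.testing.assert_array_equal(finals[0], finals[1])

    def test_single_class_warns_but_trains(self, rng, caplog):
        X = rng.normal(size=(40, 10))
        y = np.array(["WAKE"] * 40, dtype=object)
        m = build_model(ModelConfig(seed=0))
        with caplog.at_level("WARNING"):
            train(m, X, y, iterations=2)
        assert any("single class" in r.message for r in caplog.records)


class TestVariantsOnRawSignals:
    """smls/stmls consume raw epochs; tiny epochs keep this fast."""

    def _raw(self, rng, n_epochs=60, n_samples=120):
        y = np.array(["WAKE", "NREM", "REM"] * (n_epochs // 3), dtype=object)
        X = rng.normal(size=(n_epochs, 3, n_samples))
        # class-dependent EMG-like variance on channel 1
        X[y == "WAKE", 1] *= 4.0
        return X, y

    def test_smls_trains_and_predicts(self, rng):
        X, y = self._raw(rng)
        m = build_model(ModelConfig(variant="smls", seed=0))
        m, curves = train(m, None, y, iterations=30, signals=X)
        assert curves["loss"][-1] < curves["loss"][0]
        proba = m.predict_proba(X)
        assert proba.shape == (60, 3)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_stmls_consumes_features_and_signals(self, rng):
        X, y = self._raw(rng)
        F = rng.normal(size=(60, 10))
        m = build_model(ModelConfig(variant="stmls", seed=0, sequence_length=20))
        m, curves = train(m, F, y, iterations=5, signals=X)
        proba = m.predict_proba((F, X))
        assert proba.shape == (60, 3)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)


class TestGradients:
    def test_bilstm_numerical_gradient(self, rng):
        """Analytic backward matches central finite differences."""
        from mlsnet.model import _BiLSTM

        layer = _BiLSTM(4, 3, rng)
        x = rng.normal(size=(2, 5, 4))
        y = layer.forward(x)
        g = rng.normal(size=y.shape)  # dL/dy for L = sum(g*y)
        dx = layer.backward(g.copy())
        eps = 1e-6
        num = np.zeros_like(x)
        for idx in np.ndindex(x.shape):
            xp = x.copy(); xp[idx] += eps
            xm = x.copy(); xm[idx] -= eps
            num[idx] = (np.sum(g * layer.forward(xp)) - np.sum(g * layer.forward(xm))) / (2 * eps)
        np.testing.assert_allclose(dx, num, atol=1e-5)

    def test_conv_numerical_gradient(self, rng):
        from mlsnet.model import _Conv1d

        layer = _Conv1d(2, 3, kernel=5, stride=2, rng=rng)
        x = rng.normal(size=(2, 2, 20))
        y = layer.forward(x)
        g = rng.normal(size=y.shape)
        dx = layer.backward(g.copy())
        eps = 1e-6
        num = np.zeros_like(x)
        for idx in np.ndindex(x.shape):
            xp = x.copy(); xp[idx] += eps
            xm = x.copy(); xm[idx] -= eps
            num[idx] = (np.sum(g * layer.forward(xp)) - np.sum(g * layer.forward(xm))) / (2 * eps)
        np.testing.assert_allclose(dx, num, atol=1e-5)


class TestCheckpoints:
    def test_save_load_round_trip(self, tmp_path, rng):
        m = build_model(ModelConfig(seed=2))
        X, y = separable_gaussians(rng, n_per_class=30)
        m, _ = train(m, X, y, iterations=3)
        path = tmp_path / "model.npz"
        save_model(m, path)
        back = load_model(path)
        F = rng.normal(size=(20, 10))
        np.testing.assert_array_equal(back.predict_proba(F), m.predict_proba(F))
        assert back.cfg == m.cfg
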