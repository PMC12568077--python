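import numpy as np
import pytest

from shankgait import har_model, nn
from shankgait.config import ModelConfig, TrainingConfig
from shankgait.containers import WindowSet


def small_config(**kw):
    defaults = dict(window_sz=20, n_channels=4, n_classes=3, conv_filters=4,
                    bilstm_units_per_direction=6, dropout_rate=0.0, seed=0)
    defaults.update(kw)
    return ModelConfig(**defaults)


def make_windows(n, window_sz=20, n_channels=4, labels=None, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, window_sz, n_channels))
    if labels is None:
        labels = ["static"] * n
    return WindowSet(x, np.array(labels, dtype=object),
                     np.arange(n) * window_sz, window_sz, n_channels)


def separable_windows(n_per_class, window_sz=20, n_channels=4, seed=0):
    """Static ~ small noise; walking ~ strong sinusoid: linearly separable."""
    rng = np.random.default_rng(seed)
    t = np.arange(window_sz)
    xs, labels = [], []
    for label in ("static", "walking"):
        for _ in range(n_per_class):
            if label == "static":
                w = 0.1 * rng.normal(size=(window_sz, n_channels))
            else:
                base = 3.0 * np.sin(2 * np.pi * t / 10)[:, None]
                w = base + 0.1 * rng.normal(size=(window_sz, n_channels))
            xs.append(w)
            labels.append(label)
    return WindowSet(np.stack(xs), np.array(labels, dtype=object),
                     np.arange(2 * n_per_class) * window_sz, window_sz, n_channels)


class TestArchitecture:
    def test_post_resnet_shape_default_config(self):
        """Shape-propagation oracle: actual conv output shapes for the
        default configuration."""
        model = har_model.build_model(ModelConfig())
        net = model.net
        x = np.zeros((2, 500, 6, 1), dtype=np.float32)
        y1 = net.conv1.forward(x)
        assert y1.shape == (2, 250, 3, 32)
        y2 = net.conv2.forward(y1)
        assert y2.shape == (2, 250, 3, 32)
        ysc = net.conv_sc.forward(x)
        assert ysc.shape == (2, 250, 3, 32)
        assert net.resnet_output_shape == (250, 3, 32)
        assert int(np.prod(net.resnet_output_shape)) == 24000
        # flatten -> sequence view preserves the temporal axis
        assert (net.t_steps, net.seq_features) == (250, 96)

    def test_output_width_is_seven_classes(self):
        model = har_model.build_model(ModelConfig())
        logits = model.net.forward(np.zeros((1, 500, 6)))
        assert logits.shape == (1, 7)

    def test_mismatched_shortcut_stride_rejected(self):
        with pytest.raises(ValueError, match="shortcut"):
            ModelConfig(conv1_stride=2, shortcut_stride=3)

    def test_window_not_divisible_by_stride(self):
        with pytest.raises(ValueError, match="divisible"):
            har_model.build_model(small_config(window_sz=21))

    def test_param_count_is_pure_function_of_config(self):
        model = har_model.build_model(ModelConfig())
        f, k, c = 32, 2, 6
        h, classes = 64, 7
        conv1 = k * k * 1 * f + f
        conv2 = k * k * f * f + f
        conv_sc = conv1
        bns = 2 * (2 * f)
        seq_feat = -(-c // 2) * f
        lstm = 2 * (4 * h * (seq_feat + h + 1))
        dense = 2 * h * classes + classes
        assert model.net.n_params == conv1 + conv2 + conv_sc + bns + lstm + dense
        assert model.net.n_params == 87911


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        """Central-difference check of the full network in float64."""
        cfg = small_config(window_sz=8, n_channels=2, conv_filters=3,
                           bilstm_units_per_direction=4)
        model = har_model.build_model(cfg, dtype=np.float64)
        net = model.net
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 8, 2))
        y = rng.integers(0, 3, size=5)

        def loss_fn():
            logits = net.forward(x, training=True)
            loss, _, _ = nn.softmax_cross_entropy(logits, y)
            return loss

        logits = net.forward(x, training=True)
        _, dlogits, _ = nn.softmax_cross_entropy(logits, y)
        for p in net.params():
            p.grad[...] = 0.0
        net.backward(dlogits)

        eps = 1e-6
        rng2 = np.random.default_rng(2)
        for p in net.params():
            flat = p.value.ravel()
            for idx in rng2.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_fn()
                flat[idx] = orig - eps
                down = loss_fn()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                analytic = p.grad.ravel()[idx]
                assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7), p.name


class TestTraining:
    def test_loss_decreases_on_learnable_fixture(self):
        ws = separable_windows(25)  # 50 windows
        model = har_model.build_model(small_config())
        tcfg = TrainingConfig(batch_size=16, max_epochs=6,
                              early_stopping_patience=5, seed=0)
        model = har_model.train(model, ws, ws, tcfg)
        losses = model.history["train_loss"].to_numpy()
        assert losses[4] < losses[0]

    def test_converged_model_perfect_on_separable_training_set(self):
        ws = separable_windows(20)
        model = har_model.build_model(small_config())
        tcfg = TrainingConfig(batch_size=16, max_epochs=25,
                              early_stopping_patience=20, seed=0)
        model = har_model.train(model, ws, ws, tcfg)
        preds = har_model.predict(model, ws)
        assert (preds.predicted_labels == ws.labels).mean() == 1.0

    def test_early_stopping_contract(self):
        """Validation loss rising from epoch 1 stops training at
        1 + patience epochs with best_epoch = 1."""
        train_ws = separable_windows(10, seed=0)
        # poisoned validation: same signals, swapped labels -> val loss rises
        val_ws = separable_windows(10, seed=1)
        val_ws.labels = np.array(
            ["walking" if l == "static" else "static" for l in val_ws.labels],
            dtype=object)
        tcfg = TrainingConfig(batch_size=16, max_epochs=30,
                              early_stopping_patience=3, seed=0)
        model = har_model.train(har_model.build_model(small_config()),
                                train_ws, val_ws, tcfg)
        val = model.history["val_loss"].to_numpy()
        assert np.all(np.diff(val) > 0)  # adversarial fixture behaves
        assert len(model.history) == 1 + tcfg.early_stopping_patience
        assert model.best_epoch == 1

    def test_best_epoch_weights_restored(self):
        train_ws = separable_windows(10, seed=0)
        val_ws = separable_windows(10, seed=1)
        val_ws.labels = np.array(
            ["walking" if l == "static" else "static" for l in val_ws.labels],
            dtype=object)
        tcfg = TrainingConfig(batch_size=16, max_epochs=30,
                              early_stopping_patience=3, seed=0)
        model = har_model.train(har_model.build_model(small_config()),
                                train_ws, val_ws, tcfg)
        loss, _ = har_model._evaluate(model.net, val_ws.windows,
                                      har_model._encode_labels(val_ws.labels,
                                                               model.classes), 16)
        assert loss == pytest.approx(model.history["val_loss"].iloc[0], rel=1e-5)

    def test_identical_seed_identical_history(self):
        ws = separable_windows(10)
        tcfg = TrainingConfig(batch_size=16, max_epochs=3,
                              early_stopping_patience=2, seed=5)
        h1 = har_model.train(har_model.build_model(small_config(dropout_rate=0.5)),
                             ws, ws, tcfg).history
        h2 = har_model.train(har_model.build_model(small_config(dropout_rate=0.5)),
                             ws, ws, tcfg).history
        np.testing.assert_array_equal(h1.to_numpy(), h2.to_numpy())

    def test_empty_training_set_error(self):
        empty = make_windows(0)
        with pytest.raises(ValueError, match="empty"):
            har_model.train(har_model.build_model(small_config()), empty,
                            make_windows(2), TrainingConfig(max_epochs=2,
                                                            early_stopping_patience=1))

    def test_single_class_warning(self):
        ws = make_windows(8)
        with pytest.warns(UserWarning, match="single class"):
            har_model.train(har_model.build_model(small_config()), ws, ws,
                            TrainingConfig(batch_size=8, max_epochs=2,
                                           early_stopping_patience=1))

    def test_unknown_label_rejected(self):
        ws = make_windows(4, labels=["juggling"] * 4)
        with pytest.raises(ValueError, match="juggling"):
            har_model.train(har_model.build_model(small_config()), ws, ws,
                            TrainingConfig(max_epochs=2, early_stopping_patience=1))


class TestPredict:
    def test_rows_sum_to_one_and_pure_function(self):
        ws = make_windows(6, seed=3)
        model = har_model.build_model(small_config())
        preds = har_model.predict(model, ws)
        np.testing.assert_allclose(preds.probabilities.sum(axis=1), 1.0, atol=1e-9)
        # duplicate window -> identical probability rows
        dup = WindowSet(np.concatenate([ws.windows, ws.windows[:1]]),
                        np.append(ws.labels, ws.labels[0]),
                        np.append(ws.starts, 999), ws.window_sz, ws.n_channels)
        preds2 = har_model.predict(model, dup)
        np.testing.assert_allclose(preds2.probabilities[-1],
                                   preds2.probabilities[0], atol=1e-12)

    def test_shape_mismatch_rejected(self):
        model = har_model.build_model(small_config())
        with pytest.raises(ValueError, match="match"):
            har_model.predict(model, make_windows(2, window_sz=30))

    def test_save_load_round_trip(self, tmp_path):
        ws = separable_windows(8)
        tcfg = TrainingConfig(batch_size=16, max_epochs=3,
                              early_stopping_patience=2, seed=0)
        model = har_model.train(har_model.build_model(small_config()), ws, ws, tcfg)
        model.save(tmp_path / "model")
        back = har_model.TrainedModel.load(tmp_path / "model")
        np.testing.assert_allclose(
            har_model.predict(back, ws).probabilities,
            har_model.predict(model, ws).probabilities, atol=1e-6)
        assert back.best_epoch == model.best_epoch
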