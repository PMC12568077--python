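"""The ResNet+BiLSTM activity classifier.

Layer graph: input (window_sz, n_channels, 1) -> conv(32, 2x2, stride 2,
same) -> batch norm -> ReLU -> conv(32, 2x2, stride 1, same) -> batch norm;
shortcut conv(32, 2x2, stride 2, same) from the input; residual add -> ReLU
-> dropout 0.5 -> flatten -> reshape to a (window_sz/2)-step sequence
(preserving the temporal axis) -> BiLSTM -> dropout 0.5 -> dense -> softmax.

Training minimizes sparse categorical cross-entropy with Adam (batch 64),
early-stops on validation loss with patience 10, and restores the weights
of the best epoch.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .config import ModelConfig, TrainingConfig
from .containers import CLASSES, PredictionSet, WindowSet


class ResNetBiLSTMNetwork:
    """The layer graph with explicit residual wiring."""

    def __init__(self, cfg: ModelConfig, dtype=np.float32):
        if cfg.window_sz % cfg.conv1_stride != 0:
            raise ValueError(
                f"window_sz {cfg.window_sz} not divisible by conv1 stride "
                f"{cfg.conv1_stride}"
            )
        self.cfg = cfg
        self.dtype = dtype
        ss = np.random.SeedSequence(cfg.seed)
        init_rng, drop_rng1, drop_rng2 = (np.random.default_rng(s) for s in ss.spawn(3))
        f = cfg.conv_filters
        k = cfg.conv_kernel
        self.conv1 = nn.Conv2D(1, f, k, cfg.conv1_stride, init_rng, dtype, "conv1")
        self.bn1 = nn.BatchNorm(f, dtype=dtype, name="bn1")
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2D(f, f, k, cfg.conv2_stride, init_rng, dtype, "conv2")
        self.bn2 = nn.BatchNorm(f, dtype=dtype, name="bn2")
        self.conv_sc = nn.Conv2D(1, f, k, cfg.shortcut_stride, init_rng, dtype, "conv_sc")
        self.relu2 = nn.ReLU()
        self.drop1 = nn.Dropout(cfg.dropout_rate, drop_rng1)
        self.t_steps = cfg.window_sz // cfg.conv1_stride
        w_out = -(-cfg.n_channels // cfg.conv1_stride)
        self.seq_features = w_out * f
        self.resnet_output_shape = (self.t_steps, w_out, f)
        self.bilstm = nn.BiLSTM(self.seq_features, cfg.bilstm_units_per_direction,
                                init_rng, dtype, "bilstm")
        self.drop2 = nn.Dropout(cfg.dropout_rate, drop_rng2)
        self.dense = nn.Dense(2 * cfg.bilstm_units_per_direction, cfg.n_classes,
                              init_rng, dtype, "dense")
        self._layers = [self.conv1, self.bn1, self.conv2, self.bn2, self.conv_sc,
                        self.bilstm, self.dense]

    def params(self):
        out = []
        for layer in self._layers:
            out.extend(layer.params())
        return out

    @property
    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Windows (B, window_sz, n_channels) -> logits (B, n_classes)."""
        x = np.ascontiguousarray(x, dtype=self.dtype)[..., None]
        main = self.bn2.forward(
            self.conv2.forward(
                self.relu1.forward(
                    self.bn1.forward(self.conv1.forward(x, training), training),
                    training,
                ),
                training,
            ),
            training,
        )
        shortcut = self.conv_sc.forward(x, training)
        if main.shape != shortcut.shape:
            raise ValueError(
                f"residual add requires equal shapes; main {main.shape} vs "
                f"shortcut {shortcut.shape}"
            )
        y = self.relu2.forward(main + shortcut, training)
        y = self.drop1.forward(y, training)
        b = y.shape[0]
        y = y.reshape(b, -1)  # flatten
        y = y.reshape(b, self.t_steps, self.seq_features)  # sequence view
        y = self.bilstm.forward(y, training)
        y = self.drop2.forward(y, training)
        return self.dense.forward(y, training)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.dense.backward(dlogits)
        d = self.drop2.backward(d)
        d = self.bilstm.backward(d)
        b = d.shape[0]
        d = d.reshape((b,) + self.resnet_output_shape)
        d = self.drop1.backward(d)
        d = self.relu2.backward(d)
        d_main = self.bn2.backward(d)
        d_main = self.conv2.backward(d_main)
        d_main = self.relu1.backward(d_main)
        d_main = self.bn1.backward(d_main)
        self.conv1.backward(d_main)
        self.conv_sc.backward(d)

    def get_state(self) -> dict:
        state = {f"param_{i}": p.value.copy() for i, p in enumerate(self.params())}
        for j, layer in enumerate(self._layers):
            for key, val in layer.state().items():
                state[f"layer{j}_{key}"] = val
        return state

    def set_state(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            p.value = state[f"param_{i}"].copy()
        for j, layer in enumerate(self._layers):
            sub = {
                key[len(f"layer{j}_"):]: val
                for key, val in state.items()
                if key.startswith(f"layer{j}_")
            }
            if sub:
                layer.set_state(sub)


@dataclass
class TrainedModel:
    """Architecture + weights, label mapping, training history."""

    net: ResNetBiLSTMNetwork
    config: ModelConfig
    classes: tuple = CLASSES
    history: pd.DataFrame = field(default_factory=pd.DataFrame)
    best_epoch: int = -1

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.net.get_state())
        meta = {
            "model_config": {**self.config.__dict__,
                             "conv_kernel": list(self.config.conv_kernel)},
            "classes": list(self.classes),
            "best_epoch": self.best_epoch,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))
        self.history.to_csv(directory / "history.csv", index=False)

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        mc = dict(meta["model_config"])
        mc["conv_kernel"] = tuple(mc["conv_kernel"])
        cfg = ModelConfig(**mc)
        model = build_model(cfg)
        with np.load(directory / "weights.npz") as data:
            model.net.set_state({k: data[k] for k in data.files})
        model.classes = tuple(meta["classes"])
        model.best_epoch = int(meta["best_epoch"])
        hist_path = directory / "history.csv"
        if hist_path.exists() and hist_path.stat().st_size > 1:
            model.history = pd.read_csv(hist_path)
        return model


def build_model(cfg: ModelConfig | None = None, dtype=np.float32) -> TrainedModel:
    """Construct the (untrained) classifier for a configuration."""
    cfg = cfg or ModelConfig()
    net = ResNetBiLSTMNetwork(cfg, dtype=dtype)
    return TrainedModel(net=net, config=cfg, classes=CLASSES[: cfg.n_classes]
                        if cfg.n_classes <= len(CLASSES) else CLASSES)


def _encode_labels(labels, classes) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(classes)}
    unknown = set(labels) - set(classes)
    if unknown:
        raise ValueError(f"labels {sorted(map(str, unknown))} not in model classes")
    return np.array([lookup[l] for l in labels], dtype=np.int64)


def _evaluate(net, x, y, batch_size) -> tuple:
    losses, correct = [], 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i:i + batch_size], y[i:i + batch_size]
        logits = net.forward(xb, training=False)
        loss, _, probs = nn.softmax_cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((probs.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(
    model: TrainedModel,
    train_ws: WindowSet,
    val_ws: WindowSet,
    tcfg: TrainingConfig | None = None,
) -> TrainedModel:
    """Fit the classifier with Adam + early stopping on validation loss.

    Stops when validation loss has not improved for ``patience`` epochs (or
    at ``max_epochs``) and restores the best epoch's weights. The history
    records per-epoch training and validation loss and accuracy.
    """
    tcfg = tcfg or TrainingConfig()
    if train_ws.n_windows == 0:
        raise ValueError("training set is empty")
    y_train = _encode_labels(train_ws.labels, model.classes)
    y_val = _encode_labels(val_ws.labels, model.classes)
    if len(set(y_train)) < 2:
        warnings.warn("training set contains a single class")
    x_train = np.ascontiguousarray(train_ws.windows, dtype=model.net.dtype)
    x_val = np.ascontiguousarray(val_ws.windows, dtype=model.net.dtype)

    rng = np.random.default_rng(tcfg.seed)
    params = model.net.params()
    opt = nn.Adam(params, lr=tcfg.learning_rate)
    best_loss = np.inf
    best_state = None
    best_epoch = -1
    since_best = 0
    rows = []
    n = len(x_train)
    for epoch in range(1, tcfg.max_epochs + 1):
        perm = rng.permutation(n)
        epoch_loss, correct = 0.0, 0
        for i in range(0, n, tcfg.batch_size):
            idx = perm[i:i + tcfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = model.net.forward(xb, training=True)
            loss, dlogits, probs = nn.softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            model.net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(xb)
            correct += int((probs.argmax(axis=1) == yb).sum())
        train_loss = epoch_loss / n
        val_loss, val_acc = _evaluate(model.net, x_val, y_val, tcfg.batch_size)
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "train_accuracy": correct / n,
                     "val_loss": val_loss, "val_accuracy": val_acc})
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.net.get_state()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= tcfg.early_stopping_patience:
                break
    if best_state is not None:
        model.net.set_state(best_state)
    model.best_epoch = best_epoch
    model.history = pd.DataFrame(rows)
    return model


def predict(model: TrainedModel, ws: WindowSet, batch_size: int = 64) -> PredictionSet:
    """Class probabilities and argmax labels for a WindowSet (dropout off)."""
    if ws.n_windows and ws.windows.shape[1:] != (model.config.window_sz,
                                                 model.config.n_channels):
        raise ValueError(
            f"window shape {ws.windows.shape[1:]} does not match model "
            f"({model.config.window_sz}, {model.config.n_channels})"
        )
    probs = []
    for i in range(0, ws.n_windows, batch_size):
        logits = model.net.forward(ws.windows[i:i + batch_size], training=False)
        probs.append(nn.softmax(logits.astype(np.float64)))
    probabilities = (np.concatenate(probs) if probs
                     else np.empty((0, model.config.n_classes)))
    labels = np.array(
        [model.classes[j] for j in probabilities.argmax(axis=1)], dtype=object
    ) if len(probabilities) else np.array([], dtype=object)
    return PredictionSet(probabilities, labels, ws.starts.copy(), ws.window_sz,
                         tuple(model.classes))
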