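"""The three frame-level sex classifiers: BPNN, DNN and CNN.

All three consume the 36-dimensional MFCC+delta+delta-delta frame vector
and emit a 2-way softmax over (female, male):

* **bpnn** -- a three-hidden-layer perceptron with 18, 9 and 4 ReLU units.
* **dnn** -- a deeper perceptron with 48, 32, 16 and 8 ReLU units and
  dropout 0.1 after every hidden layer.
* **cnn** -- four 3x3 same-padding convolution blocks with 128, 128, 64 and
  32 channels (ReLU, dropout 0.3 each), then flatten and a dense softmax
  head.  The 36-vector is reshaped to a 6x6 single-channel map by default;
  an optional ``context_window`` stacks w consecutive frames into a w x 36
  map instead.

Training minimizes softmax cross-entropy with Adam for a fixed number of
epochs, holding out a validation fraction of frames, and records per-epoch
accuracy/loss history.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, ShapeError
from . import nets
from .nets import Adam, Conv2D, Dense, Dropout, Flatten, Network, ReLU, softmax_cross_entropy

logger = logging.getLogger(__name__)

#: Class index convention: column 0 = female (negative), column 1 = male (positive).
CLASSES = ("female", "male")

MODEL_KINDS = ("bpnn", "dnn", "cnn")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative architecture description for one of the three classifiers."""

    kind: str = "bpnn"
    bpnn_hidden: tuple[int, ...] = (18, 9, 4)
    dnn_hidden: tuple[int, ...] = (48, 32, 16, 8)
    dnn_dropout: float = 0.1
    cnn_channels: tuple[int, ...] = (128, 128, 64, 32)
    cnn_kernel: int = 3
    cnn_dropout: float = 0.3
    context_window: int | None = None
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ParameterError(f"unknown model kind {self.kind!r}; use one of {MODEL_KINDS}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: 100 epochs of Adam at 1e-3, batch 256."""

    epochs: int = 100
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0
    validation_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ParameterError(f"epochs must be >= 1, got {self.epochs}")
        if not (0 <= self.validation_fraction < 1):
            raise ParameterError(
                f"validation fraction must lie in [0, 1), got {self.validation_fraction}"
            )


@dataclass
class TrainedModel:
    """A fitted network plus everything needed to reproduce it."""

    spec: ModelSpec
    config: TrainConfig
    network: Network
    history: pd.DataFrame
    seed: int
    norm_stats: tuple[np.ndarray, np.ndarray] | None = None
    input_dim: int = 36


def build_model(spec: ModelSpec, input_dim: int = 36, seed: int = 0) -> Network:
    """Instantiate an untrained network for ``spec`` with seeded init."""
    rng = np.random.default_rng(seed)
    layers: list[nets.Layer] = []
    if spec.kind == "bpnn":
        sizes = (input_dim, *spec.bpnn_hidden)
        for a, b in zip(sizes[:-1], sizes[1:]):
            layers += [Dense(a, b, rng), ReLU()]
        layers.append(Dense(sizes[-1], spec.n_classes, rng))
        return Network(layers, input_shape=(input_dim,))
    if spec.kind == "dnn":
        sizes = (input_dim, *spec.dnn_hidden)
        for a, b in zip(sizes[:-1], sizes[1:]):
            layers += [Dense(a, b, rng), ReLU(), Dropout(spec.dnn_dropout)]
        layers.append(Dense(sizes[-1], spec.n_classes, rng))
        return Network(layers, input_shape=(input_dim,))
    # cnn: per-frame vector reshaped to a square map, or a context stack.
    if spec.context_window is not None:
        shape = (1, spec.context_window, input_dim)
    else:
        side = int(round(np.sqrt(input_dim)))
        if side * side != input_dim:
            raise ParameterError(
                f"cnn needs input_dim a perfect square (got {input_dim}) or a "
                "context_window"
            )
        shape = (1, side, side)
    c_in = 1
    for c_out in spec.cnn_channels:
        layers += [Conv2D(c_in, c_out, rng, spec.cnn_kernel), ReLU(),
                   Dropout(spec.cnn_dropout)]
        c_in = c_out
    flat = c_in * shape[1] * shape[2]
    layers += [Flatten(), Dense(flat, spec.n_classes, rng)]
    return Network(layers, input_shape=shape)


def _validate_training_data(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    features = np.asarray(features)
    labels = np.asarray(labels)
    if features.ndim != 2:
        raise ShapeError(f"features must be 2-D, got shape {features.shape}")
    if labels.shape != (features.shape[0],):
        raise ShapeError(
            f"labels shape {labels.shape} does not match {features.shape[0]} frames"
        )
    uniq = np.unique(labels)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ParameterError(f"labels must be 0 (female) or 1 (male), got {uniq}")
    if uniq.size < 2:
        raise ParameterError("training data contains a single class")
    return labels.astype(np.int64)


def train(network: Network, features: np.ndarray, labels: np.ndarray,
          config: TrainConfig, spec: ModelSpec | None = None,
          norm_stats=None) -> TrainedModel:
    """Fit ``network`` with Adam on softmax cross-entropy.

    A validation fraction of frames is split off (seeded shuffle) and scored
    after every epoch with dropout disabled.  Raises on NaN loss.
    """
    labels = _validate_training_data(features, labels)
    x = np.asarray(features, dtype=np.float32)
    rng = np.random.default_rng(config.seed)

    n = x.shape[0]
    order = rng.permutation(n)
    n_val = int(round(config.validation_fraction * n))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if train_idx.size == 0:
        raise ParameterError("no training examples left after validation split")
    x_tr, y_tr = x[train_idx], labels[train_idx]
    x_val, y_val = x[val_idx], labels[val_idx]

    opt = Adam(network, lr=config.learning_rate)
    hist: list[dict] = []
    for epoch in range(config.epochs):
        perm = rng.permutation(x_tr.shape[0])
        losses, correct = [], 0
        for start in range(0, perm.size, config.batch_size):
            idx = perm[start:start + config.batch_size]
            logits = network.forward(x_tr[idx], train=True, rng=rng)
            loss, grad = softmax_cross_entropy(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}; lower the learning rate"
                )
            network.backward(grad)
            opt.step()
            losses.append(loss * idx.size)
            correct += int(np.sum(np.argmax(logits, axis=1) == y_tr[idx]))
        row = {"epoch": epoch,
               "train_loss": float(np.sum(losses) / perm.size),
               "train_acc": correct / perm.size}
        if x_val.shape[0]:
            val_logits = network.forward(x_val, train=False)
            val_loss, _ = softmax_cross_entropy(val_logits, y_val)
            row["val_loss"] = val_loss
            row["val_acc"] = float(np.mean(np.argmax(val_logits, axis=1) == y_val))
        else:
            row["val_loss"] = np.nan
            row["val_acc"] = np.nan
        hist.append(row)
    return TrainedModel(spec=spec or ModelSpec(), config=config, network=network,
                        history=pd.DataFrame(hist), seed=config.seed,
                        norm_stats=norm_stats,
                        input_dim=int(np.prod(network.input_shape)))


def fit(spec: ModelSpec, features: np.ndarray, labels: np.ndarray,
        config: TrainConfig, norm_stats=None) -> TrainedModel:
    """Convenience: build a seeded network for ``spec`` and train it."""
    network = build_model(spec, input_dim=features.shape[1], seed=config.seed)
    return train(network, features, labels, config, spec=spec, norm_stats=norm_stats)


def predict_frames(model: TrainedModel | Network, features: np.ndarray) -> np.ndarray:
    """Per-frame class probabilities, shape (num_frames, 2); rows sum to 1."""
    network = model.network if isinstance(model, TrainedModel) else model
    features = np.asarray(features, dtype=np.float32)
    if features.ndim != 2 or features.shape[1] != int(np.prod(network.input_shape)):
        raise ShapeError(
            f"feature width {features.shape} does not match model input "
            f"{network.input_shape}"
        )
    return network.predict_proba(features)


def save_checkpoint(model: TrainedModel, path: str | Path) -> None:
    """Persist spec, train config, seed, parameters and normalization stats.

    The checkpoint is a .npz container with a JSON metadata entry; the
    training history is written alongside as ``<path>.history.csv``.
    """
    path = Path(path)
    meta = {"spec": asdict(model.spec), "config": asdict(model.config),
            "seed": model.seed, "input_dim": model.input_dim}
    arrays = {"meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for i, (p, _) in enumerate(model.network.parameters()):
        arrays[f"param_{i}"] = p
    if model.norm_stats is not None:
        arrays["norm_mean"], arrays["norm_std"] = model.norm_stats
    np.savez(path, **arrays)
    model.history.to_csv(path.with_suffix(path.suffix + ".history.csv"), index=False)


def load_checkpoint(path: str | Path) -> TrainedModel:
    path = Path(path)
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        spec = ModelSpec(**{**meta["spec"],
                            "bpnn_hidden": tuple(meta["spec"]["bpnn_hidden"]),
                            "dnn_hidden": tuple(meta["spec"]["dnn_hidden"]),
                            "cnn_channels": tuple(meta["spec"]["cnn_channels"])})
        config = TrainConfig(**meta["config"])
        network = build_model(spec, input_dim=meta["input_dim"], seed=meta["seed"])
        for i, (p, _) in enumerate(network.parameters()):
            p[...] = data[f"param_{i}"]
        norm_stats = None
        if "norm_mean" in data:
            norm_stats = (data["norm_mean"].copy(), data["norm_std"].copy())
    history_path = path.with_suffix(path.suffix + ".history.csv")
    history = pd.read_csv(history_path) if history_path.exists() else pd.DataFrame()
    return TrainedModel(spec=spec, config=config, network=network, history=history,
                        seed=meta["seed"], norm_stats=norm_stats,
                        input_dim=meta["input_dim"])
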