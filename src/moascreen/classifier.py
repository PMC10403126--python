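"""Image CNN and feature-table MLP for 11-class MoA prediction.

Both classifiers predict one of the ten MoA classes or the DMSO control
from a single imaging site.  The image model is a small strided
convolutional backbone (configurable widths) ending in global average
pooling — the pooled vector is the penultimate-layer embedding used by the
profiling stages — followed by a linear output layer.  The feature model
is a one-hidden-layer perceptron (default 512 units) with ReLU and batch
normalization over engineered per-site feature vectors.

Training minimizes softmax cross-entropy with Adam; the checkpoint kept is
the epoch with the best validation macro-F1, with early stopping after a
configurable patience.  Compound-level splits are enforced here: the data
each partition sees is drawn exclusively through
:func:`moascreen.splits.partition_sites`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from . import nn
from .config import ModelConfig
from .splits import SplitAssignment, partition_sites

META_COLUMNS = ["plate_id", "well", "site_index", "compound_id", "moa_label"]


@dataclass
class ImageDataset:
    """Site images plus their metadata, aligned row-for-row."""

    images: np.ndarray  # (N, C, H, W)
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.images) != len(self.meta):
            raise ValueError("images and metadata length mismatch")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata lacks columns {missing}")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_channels(self) -> int:
        return self.images.shape[1]


@dataclass
class TrainedModel:
    """A fitted classifier: network, config, label vocabulary, diagnostics."""

    net: nn.Sequential
    config: ModelConfig
    class_labels: list[str]
    kind: str  # "cnn" | "mlp"
    log: list[dict] = field(default_factory=list)
    trained_compounds: frozenset[str] = frozenset()
    best_epoch: int = -1

    @property
    def label_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.class_labels)}

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net.get_state())
        meta = {
            "config": self.config.to_dict(),
            "class_labels": self.class_labels,
            "kind": self.kind,
            "log": self.log,
            "trained_compounds": sorted(self.trained_compounds),
            "best_epoch": self.best_epoch,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        config = ModelConfig.from_dict(meta["config"])
        if meta["kind"] == "cnn":
            net = _build_cnn(config)
        else:
            state = np.load(path.with_suffix(".npz"))
            d_in = state["0.W"].shape[0]
            net = _build_mlp(config, d_in)
        with np.load(path.with_suffix(".npz")) as state:
            net.set_state({k: state[k] for k in state.files})
        return cls(net=net, config=config, class_labels=meta["class_labels"],
                   kind=meta["kind"], log=meta["log"],
                   trained_compounds=frozenset(meta["trained_compounds"]),
                   best_epoch=meta["best_epoch"])


def _build_cnn(config: ModelConfig) -> nn.Sequential:
    rng = np.random.default_rng([config.seed, 21])
    layers: list[nn.Layer] = []
    c_in = config.input_channels
    for width in config.conv_widths:
        layers += [nn.Conv2d(c_in, width, rng), nn.ReLU()]
        c_in = width
    layers.append(nn.GlobalAvgPool())
    layers.append(nn.Dense(c_in, config.n_classes, rng))
    return nn.Sequential(layers)


def _build_mlp(config: ModelConfig, d_in: int) -> nn.Sequential:
    rng = np.random.default_rng([config.seed, 22])
    return nn.Sequential([
        nn.Dense(d_in, config.hidden_dim, rng),
        nn.ReLU(),
        nn.BatchNorm1d(config.hidden_dim),
        nn.Dense(config.hidden_dim, config.n_classes, rng),
    ])


def _augment(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal/vertical flips and 90-degree rotations per batch."""
    if rng.random() < 0.5:
        x = x[:, :, :, ::-1]
    if rng.random() < 0.5:
        x = x[:, :, ::-1, :]
    k = int(rng.integers(0, 4))
    if k:
        x = np.rot90(x, k, axes=(2, 3))
    return np.ascontiguousarray(x)


def _forward_batches(net: nn.Sequential, x: np.ndarray, batch: int,
                     upto: int | None = None) -> np.ndarray:
    outs = [net.forward(x[i:i + batch], train=False, upto=upto)
            for i in range(0, len(x), batch)]
    return np.concatenate(outs, axis=0)


def _fit(net: nn.Sequential, x_train: np.ndarray, y_train: np.ndarray,
         x_val: np.ndarray, y_val: np.ndarray, config: ModelConfig,
         augment_images: bool) -> tuple[list[dict], int]:
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("empty train or validation partition")
    rng = np.random.default_rng([config.seed, 23])
    opt = nn.Adam(net, lr=config.lr)
    best_f1, best_epoch, best_state = -np.inf, -1, net.get_state()
    log: list[dict] = []
    stall = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_train))
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb = x_train[idx]
            if augment_images:
                xb = _augment(xb, rng)
            logits = net.forward(xb, train=True)
            loss, grad = nn.cross_entropy_grad(logits, y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"lr={config.lr}, batch={i // config.batch_size}")
            net.backward(grad)
            opt.step()
            losses.append(loss)
        val_logits = _forward_batches(net, x_val, config.batch_size)
        val_pred = val_logits.argmax(axis=1)
        val_f1 = f1_score(y_val, val_pred, average="macro", zero_division=0)
        log.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                    "val_macro_f1": float(val_f1)})
        if val_f1 > best_f1:
            best_f1, best_epoch, best_state = val_f1, epoch, net.get_state()
            stall = 0
        else:
            stall += 1
            if stall > config.patience:
                break
    net.set_state(best_state)
    return log, best_epoch


def _encode_labels(meta: pd.DataFrame, class_labels: list[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_labels)}
    unknown = set(meta.moa_label) - set(index)
    if unknown:
        raise ValueError(f"labels outside the class vocabulary: {sorted(unknown)}")
    return meta.moa_label.map(index).to_numpy()


def train_classifier(dataset: ImageDataset, split: SplitAssignment,
                     config: ModelConfig,
                     class_labels: list[str]) -> TrainedModel:
    """Train the image CNN on the train partition of one split.

    The model checkpoint returned is the epoch with the best validation
    macro-F1.  Test-partition sites are never touched here; the returned
    model records the compounds it saw so leakage is auditable.
    """
    if dataset.n_channels != config.input_channels:
        raise ValueError(
            f"dataset has {dataset.n_channels} channels, model expects "
            f"{config.input_channels}")
    meta = dataset.meta
    parts = {}
    for part in ("train", "val"):
        sel = partition_sites(meta.assign(_row=np.arange(len(meta))),
                              split, part)
        parts[part] = sel._row.to_numpy()
    net = _build_cnn(config)
    y = _encode_labels(meta, class_labels)
    log, best_epoch = _fit(
        net,
        dataset.images[parts["train"]], y[parts["train"]],
        dataset.images[parts["val"]], y[parts["val"]],
        config, augment_images=config.augment)
    trained = frozenset(meta.compound_id.iloc[parts["train"]])
    return TrainedModel(net=net, config=config, class_labels=class_labels,
                        kind="cnn", log=log, trained_compounds=trained,
                        best_epoch=best_epoch)


def train_feature_mlp(features: pd.DataFrame, split: SplitAssignment,
                      config: ModelConfig, feature_cols: list[str],
                      class_labels: list[str]) -> TrainedModel:
    """Train the benchmark MLP on a (normalized) per-site feature table."""
    x = features[feature_cols].to_numpy(dtype=np.float64)
    y = _encode_labels(features, class_labels)
    parts = {}
    for part in ("train", "val"):
        sel = partition_sites(features.assign(_row=np.arange(len(features))),
                              split, part)
        parts[part] = sel._row.to_numpy()
    net = _build_mlp(config, d_in=x.shape[1])
    log, best_epoch = _fit(
        net, x[parts["train"]], y[parts["train"]],
        x[parts["val"]], y[parts["val"]], config, augment_images=False)
    trained = frozenset(features.compound_id.iloc[parts["train"]])
    return TrainedModel(net=net, config=config, class_labels=class_labels,
                        kind="mlp", log=log, trained_compounds=trained,
                        best_epoch=best_epoch)


def _check_input(model: TrainedModel, x: np.ndarray) -> None:
    if model.kind == "cnn":
        if x.ndim != 4 or x.shape[1] != model.config.input_channels:
            raise ValueError(
                f"expected (N, {model.config.input_channels}, H, W) images, "
                f"got shape {x.shape}")
    elif x.ndim != 2:
        raise ValueError(f"expected (N, d) feature matrix, got {x.shape}")


def predict(model: TrainedModel, x: np.ndarray,
            meta: pd.DataFrame) -> pd.DataFrame:
    """Per-site class probabilities and argmax labels.

    Returns the metadata with ``prob_<class>`` columns (a probability
    simplex per row) and ``pred_label``.
    """
    _check_input(model, x)
    logits = _forward_batches(model.net, x, model.config.batch_size)
    probs = nn.softmax(logits)
    prob_df = pd.DataFrame(
        probs, columns=[f"prob_{c}" for c in model.class_labels])
    prob_df["pred_label"] = [model.class_labels[i]
                             for i in probs.argmax(axis=1)]
    return pd.concat([meta.reset_index(drop=True), prob_df], axis=1)


def extract_features(model: TrainedModel, x: np.ndarray,
                     meta: pd.DataFrame) -> pd.DataFrame:
    """Penultimate-layer embeddings (inference mode), one row per site."""
    _check_input(model, x)
    emb = _forward_batches(model.net, x, model.config.batch_size, upto=-1)
    emb_df = pd.DataFrame(emb, columns=[f"f{j}" for j in range(emb.shape[1])])
    return pd.concat([meta.reset_index(drop=True), emb_df], axis=1)
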