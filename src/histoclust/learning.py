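"""Weakly supervised feature learning.

A binary tumour / non-tumour classifier is trained on weakly labelled
tiles; once trained, its classification head is discarded and the last
convolutional layer serves as the feature extractor for tumour tiles.
Freezing the first ``n_frozen_conv_layers`` and fine-tuning the remainder
mirrors the transfer-learning recipe the pipeline is built around; with
the compact random-initialised backbone the default is to train every
layer.

Training uses Adam with an exponentially decaying learning rate
(``lr_e = lr_0 * decay^e`` applied at the start of epoch ``e``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .nn import AdamOptimizer, SmallCNN, bce_with_logits, sigmoid
from .tiling import Patch

__all__ = [
    "BackboneConfig",
    "TrainingReport",
    "PatchFeature",
    "train_weak_classifier",
    "extract_features",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class BackboneConfig:
    """Architecture and optimisation settings for the weak classifier.

    ``architecture`` selects the backbone: ``small_cnn`` is the compact
    four-conv-layer network trainable on a desk CPU; ``resnet18`` names
    the 17-conv-layer transfer-learning configuration (first 9 conv
    layers frozen, last 8 fine-tuned) and requires a deep-learning
    runtime plus pretrained weights that this package does not bundle.
    """

    architecture: str = "small_cnn"
    pretrained: bool = False
    n_frozen_conv_layers: int = 0
    learning_rate: float = 0.03
    lr_decay_factor: float = 0.5
    epochs: int = 10
    batch_size: int = 64
    channels: tuple[int, ...] = (8, 16, 32, 32)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("small_cnn", "resnet18"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 < self.lr_decay_factor <= 1:
            raise ValueError("lr_decay_factor must be in (0, 1]")
        if self.n_frozen_conv_layers < 0:
            raise ValueError("n_frozen_conv_layers must be >= 0")


@dataclass
class TrainingReport:
    """Per-epoch optimisation trace and final accuracies."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy_per_epoch: list[float] = field(default_factory=list)
    val_accuracy_per_epoch: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)
    train_accuracy: float = 0.0
    val_accuracy: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PatchFeature:
    """Deep-feature representation of one tumour tile."""

    slide_id: str
    grid_row: int
    grid_col: int
    pooled_vector: np.ndarray  # (F,) spatial mean of the last conv map
    feature_map: np.ndarray | None = None  # (F, h, w), kept only on request
    reduced_vector: np.ndarray | None = None  # filled after PCA

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.slide_id, self.grid_row, self.grid_col)


def _patches_to_array(patches: Sequence[Patch]) -> np.ndarray:
    """Stack tiles into (N, 3, H, W) floats in [0, 1]."""
    x = np.stack([p.pixels for p in patches]).astype(np.float64) / 255.0
    return x.transpose(0, 3, 1, 2)


def _labels(patches: Sequence[Patch]) -> np.ndarray:
    return np.array([1.0 if p.weak_label == "tumour" else 0.0 for p in patches])


def _accuracy(model: SmallCNN, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    correct = 0
    for i in range(0, len(x), batch):
        logits, _ = model.forward(model.normalise(x[i : i + batch]))
        correct += int(((logits.ravel() > 0) == (y[i : i + batch] > 0.5)).sum())
    return correct / len(x)


def train_weak_classifier(
    train_patches: Sequence[Patch],
    val_patches: Sequence[Patch],
    config: BackboneConfig,
) -> tuple[SmallCNN, TrainingReport]:
    """Train the tumour/non-tumour classifier on weakly labelled tiles.

    Raises on a single-class training set and aborts on a NaN loss.  The
    first ``n_frozen_conv_layers`` convolutional layers receive no
    parameter updates.
    """
    if config.architecture == "resnet18":
        raise NotImplementedError(
            "the resnet18 backbone requires a deep-learning runtime and "
            "pretrained weights that histoclust does not bundle; use "
            "architecture='small_cnn'"
        )
    y_train = _labels(train_patches)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single weak-label class")

    x_train = _patches_to_array(train_patches)
    x_val = _patches_to_array(val_patches) if len(val_patches) else np.empty((0,))
    y_val = _labels(val_patches) if len(val_patches) else np.empty((0,))

    model = SmallCNN(in_channels=3, channels=config.channels, seed=config.seed)
    # dataset channel statistics (random-init backbone: no canonical stats)
    model.input_mean = x_train.mean(axis=(0, 2, 3))
    model.input_std = x_train.std(axis=(0, 2, 3)) + 1e-8

    if config.n_frozen_conv_layers > model.n_conv_layers:
        raise ValueError(
            f"cannot freeze {config.n_frozen_conv_layers} of "
            f"{model.n_conv_layers} conv layers"
        )

    rng = np.random.default_rng(config.seed)
    opt = AdamOptimizer(lr=config.learning_rate)
    report = TrainingReport()
    n = len(x_train)
    for epoch in range(config.epochs):
        lr = config.learning_rate * config.lr_decay_factor**epoch
        opt.lr = lr
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, config.batch_size):
            sel = order[i : i + config.batch_size]
            xb = model.normalise(x_train[sel])
            yb = y_train[sel]
            logits, cache = model.forward(xb)
            loss, dlogits = bce_with_logits(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch {i // config.batch_size} (lr={lr:g})"
                )
            epoch_loss += loss * len(sel)
            conv_dw, conv_db, ddw, ddb = model.backward(dlogits, cache)
            params: dict[str, np.ndarray] = {"dense_w": model.dense_w, "dense_b": model.dense_b}
            grads: dict[str, np.ndarray] = {"dense_w": ddw, "dense_b": ddb}
            for li in range(config.n_frozen_conv_layers, model.n_conv_layers):
                params[f"conv{li}_w"] = model.conv_w[li]
                params[f"conv{li}_b"] = model.conv_b[li]
                grads[f"conv{li}_w"] = conv_dw[li]
                grads[f"conv{li}_b"] = conv_db[li]
            opt.step(params, grads)
        report.learning_rates.append(lr)
        report.train_loss.append(epoch_loss / n)
        report.train_accuracy_per_epoch.append(_accuracy(model, x_train, y_train, config.batch_size))
        if len(y_val):
            report.val_accuracy_per_epoch.append(_accuracy(model, x_val, y_val, config.batch_size))
    report.train_accuracy = report.train_accuracy_per_epoch[-1]
    report.val_accuracy = report.val_accuracy_per_epoch[-1] if len(y_val) else float("nan")
    return model, report


def extract_features(
    model: SmallCNN,
    patches: Sequence[Patch],
    pooled: bool = True,
    keep_maps: bool = False,
    allow_non_tumour: bool = False,
    batch_size: int = 64,
) -> list[PatchFeature]:
    """Last-conv-layer features for tumour tiles, in input order.

    Non-tumour tiles are dropped with a warning unless
    ``allow_non_tumour=True`` (exploration mode).  ``pooled_vector`` is
    the global spatial mean of the feature map; with ``keep_maps`` the
    full map is retained as well.
    """
    kept: list[Patch] = []
    for p in patches:
        if p.weak_label != "tumour" and not allow_non_tumour:
            warnings.warn(
                f"dropping non-tumour patch {p.key} from feature extraction",
                stacklevel=2,
            )
            continue
        kept.append(p)
    feats: list[PatchFeature] = []
    for i in range(0, len(kept), batch_size):
        chunk = kept[i : i + batch_size]
        x = model.normalise(_patches_to_array(chunk))
        maps = model.features(x, pooled=False)  # (n, F, h, w)
        pooled_vecs = maps.mean(axis=(2, 3))
        for j, p in enumerate(chunk):
            feats.append(
                PatchFeature(
                    slide_id=p.slide_id,
                    grid_row=p.grid_row,
                    grid_col=p.grid_col,
                    pooled_vector=pooled_vecs[j],
                    feature_map=maps[j] if keep_maps else None,
                )
            )
    return feats


def save_checkpoint(model: SmallCNN, config: BackboneConfig, path: str | Path) -> None:
    """Weights as .npz plus a JSON sidecar with the configuration."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(".json")
    cfg = asdict(config)
    cfg["channels"] = list(cfg["channels"])
    sidecar.write_text(json.dumps(cfg, indent=2))


def load_checkpoint(path: str | Path) -> tuple[SmallCNN, BackboneConfig]:
    path = Path(path)
    cfg_dict = json.loads(path.with_suffix(".json").read_text())
    cfg_dict["channels"] = tuple(cfg_dict["channels"])
    config = BackboneConfig(**cfg_dict)
    model = SmallCNN(in_channels=3, channels=config.channels, seed=config.seed)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as state:
        model.load_state_dict(dict(state))
    return model, config
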