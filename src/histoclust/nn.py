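"""A compact convolutional network implemented on NumPy.

Four 3x3 convolution + ReLU + 2x2 max-pool stages, global average pooling
and a single logit head, trained with Adam on binary cross-entropy.  The
implementation is deliberately self-contained and deterministic: given a
seed, initialisation, batch order and arithmetic are all reproducible,
which the training-reproducibility contract relies on.

Convolutions use an im2col formulation (stride 1, zero padding 1) so both
the forward and backward passes are dense matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SmallCNN", "AdamOptimizer", "bce_with_logits", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits; returns (loss, dloss/dlogits)."""
    z = logits.ravel()
    y = y.ravel().astype(float)
    # log(1 + e^z) computed stably
    softplus = np.logaddexp(0.0, z)
    loss = float(np.mean(softplus - y * z))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad.reshape(logits.shape)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """3x3 conv, stride 1, pad 1. x: (N,C,H,W), w: (F,C,3,3) -> (N,F,H,W)."""
    n, c, h, wd = x.shape
    f = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, c * 9)
    out = cols @ w.reshape(f, c * 9).T + b
    return out.reshape(n, h, wd, f).transpose(0, 3, 1, 2), cols


def _conv_backward(dout: np.ndarray, cols: np.ndarray, w: np.ndarray, x_shape):
    n, c, h, wd = x_shape
    f = w.shape[0]
    d2 = dout.transpose(0, 2, 3, 1).reshape(n * h * wd, f)
    dw = (d2.T @ cols).reshape(f, c, 3, 3)
    db = d2.sum(axis=0)
    dcols = (d2 @ w.reshape(f, c * 9)).reshape(n, h, wd, c, 3, 3)
    dxp = np.zeros((n, c, h + 2, wd + 2))
    for ki in range(3):
        for kj in range(3):
            dxp[:, :, ki : ki + h, kj : kj + wd] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
    return dxp[:, :, 1 : h + 1, 1 : wd + 1], dw, db


def _maxpool_forward(x: np.ndarray):
    """2x2 max pool, stride 2. x: (N,F,H,W) with even H, W."""
    n, f, h, w = x.shape
    xr = (
        x.reshape(n, f, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, f, h // 2, w // 2, 4)
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool_backward(dout: np.ndarray, idx: np.ndarray, x_shape):
    n, f, h, w = x_shape
    dxr = np.zeros((n, f, h // 2, w // 2, 4))
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    return (
        dxr.reshape(n, f, h // 2, w // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, f, h, w)
    )


class SmallCNN:
    """Four-stage conv/ReLU/max-pool backbone with a single-logit head.

    ``features()`` exposes the last convolutional layer's post-activation
    map — the representation used downstream for clustering — either as
    the full spatial map or pooled to one vector per tile.
    """

    def __init__(
        self,
        in_channels: int = 3,
        channels: tuple[int, ...] = (8, 16, 32, 32),
        seed: int = 0,
    ):
        self.in_channels = in_channels
        self.channels = tuple(channels)
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.conv_w: list[np.ndarray] = []
        self.conv_b: list[np.ndarray] = []
        c_prev = in_channels
        for c_out in self.channels:
            fan_in = c_prev * 9
            self.conv_w.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_prev, 3, 3)))
            self.conv_b.append(np.zeros(c_out))
            c_prev = c_out
        self.dense_w = rng.normal(0.0, np.sqrt(1.0 / c_prev), (c_prev, 1))
        self.dense_b = np.zeros(1)
        # channel normalisation applied to inputs, set from training data
        self.input_mean = np.zeros(in_channels)
        self.input_std = np.ones(in_channels)

    @property
    def n_conv_layers(self) -> int:
        return len(self.channels)

    @property
    def feature_dim(self) -> int:
        return self.channels[-1]

    # ---- forward / backward -------------------------------------------------

    def normalise(self, x: np.ndarray) -> np.ndarray:
        return (x - self.input_mean[None, :, None, None]) / self.input_std[None, :, None, None]

    def forward(self, x: np.ndarray):
        """x: normalised (N,C,H,W) float. Returns (logits, cache)."""
        cache = {"conv": [], "act": x}
        a = x
        for w, b in zip(self.conv_w, self.conv_b):
            z, cols = _conv_forward(a, w, b)
            relu_mask = z > 0
            a_relu = z * relu_mask
            pooled, pool_idx = _maxpool_forward(a_relu)
            cache["conv"].append(
                {"x_shape": a.shape, "cols": cols, "relu_mask": relu_mask,
                 "relu_shape": a_relu.shape, "pool_idx": pool_idx}
            )
            a = pooled
        cache["last_map"] = a  # (N, F, h, w) after final pool
        gap = a.mean(axis=(2, 3))  # (N, F)
        cache["gap"] = gap
        logits = gap @ self.dense_w + self.dense_b
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache):
        """Returns gradients: (conv_dw, conv_db, dense_dw, dense_db)."""
        gap = cache["gap"]
        d_dense_w = gap.T @ dlogits
        d_dense_b = dlogits.sum(axis=0)
        dgap = dlogits @ self.dense_w.T  # (N, F)
        a = cache["last_map"]
        n, f, h, w = a.shape
        da = np.broadcast_to(dgap[:, :, None, None], (n, f, h, w)) / (h * w)
        conv_dw: list[np.ndarray] = [None] * self.n_conv_layers  # type: ignore
        conv_db: list[np.ndarray] = [None] * self.n_conv_layers  # type: ignore
        for i in range(self.n_conv_layers - 1, -1, -1):
            c = cache["conv"][i]
            d_relu = _maxpool_backward(da, c["pool_idx"], c["relu_shape"])
            d_z = d_relu * c["relu_mask"]
            da, dw, db = _conv_backward(d_z, c["cols"], self.conv_w[i], c["x_shape"])
            conv_dw[i] = dw
            conv_db[i] = db
        return conv_dw, conv_db, d_dense_w, d_dense_b

    # ---- feature extraction -------------------------------------------------

    def features(self, x: np.ndarray, pooled: bool = True) -> np.ndarray:
        """Last-conv-layer representation of normalised inputs.

        ``pooled=True`` -> (N, F) global spatial means; otherwise the full
        (N, F, h, w) post-pool spatial map.
        """
        a = x
        for w, b in zip(self.conv_w, self.conv_b):
            z, _ = _conv_forward(a, w, b)
            a, _ = _maxpool_forward(z * (z > 0))
        return a.mean(axis=(2, 3)) if pooled else a

    # ---- (de)serialisation --------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {"dense_w": self.dense_w, "dense_b": self.dense_b,
                 "input_mean": self.input_mean, "input_std": self.input_std}
        for i, (w, b) in enumerate(zip(self.conv_w, self.conv_b)):
            state[f"conv{i}_w"] = w
            state[f"conv{i}_b"] = b
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i in range(self.n_conv_layers):
            self.conv_w[i] = np.asarray(state[f"conv{i}_w"])
            self.conv_b[i] = np.asarray(state[f"conv{i}_b"])
        self.dense_w = np.asarray(state["dense_w"])
        self.dense_b = np.asarray(state["dense_b"])
        self.input_mean = np.asarray(state["input_mean"])
        self.input_std = np.asarray(state["input_std"])

    def weights_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for key in sorted(self.state_dict()):
            h.update(np.ascontiguousarray(self.state_dict()[key]).tobytes())
        return h.hexdigest()


@dataclass
class AdamOptimizer:
    """Adam with bias correction; one (m, v) slot per parameter array."""

    lr: float
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: dict = field(default_factory=dict)
    _v: dict = field(default_factory=dict)
    _t: int = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self._t += 1
        for key, g in grads.items():
            if key not in self._m:
                self._m[key] = np.zeros_like(g)
                self._v[key] = np.zeros_like(g)
            m = self._m[key] = self.beta1 * self._m[key] + (1 - self.beta1) * g
            v = self._v[key] = self.beta2 * self._v[key] + (1 - self.beta2) * g * g
            m_hat = m / (1 - self.beta1**self._t)
            v_hat = v / (1 - self.beta2**self._t)
            params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
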