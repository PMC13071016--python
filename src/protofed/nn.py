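"""A small, fully deterministic NumPy convolutional network.

Implements the desk-scale backbone used throughout the simulator: three
3x3 convolution blocks with ReLU and 2x2 max pooling, global average
pooling and a linear classifier head. Convolutions run through im2col so
the heavy lifting is BLAS matrix multiplication; everything is float64,
which makes client-side training bit-reproducible under a seed and lets
secure-aggregation transparency checks hold to ~1e-13.

Parameter groups (conv1, conv2, conv3, head) are the unit of layer
skipping: a frozen group receives no optimizer update and is returned
bit-identical after training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["TinyCNN", "AdamOptimizer", "softmax", "cross_entropy_grad"]


def _im2col(x: np.ndarray, k: int = 3, pad: int = 1) -> np.ndarray:
    # x: (N, C, H, W) -> (N*H*W, C*k*k), stride 1
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


def _col2im(dcols: np.ndarray, xshape: tuple[int, ...], k: int = 3, pad: int = 1) -> np.ndarray:
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    d = dcols.reshape(n, h, w, c, k, k).transpose(0, 3, 4, 5, 1, 2)  # (N,C,k,k,H,W)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    g = p.copy()
    g[np.arange(n), y] -= 1.0
    return float(loss), g / n


class TinyCNN:
    """Three-block CNN: conv(3x3)->ReLU->maxpool x2, conv->ReLU->GAP, linear head.

    Parameters live in ``self.params`` as {group: {name: array}}; the group
    order defines the flattened state layout used by the federation layer.
    Input images are standardized with fixed (mean, sd) set at build time.
    """

    GROUP_ORDER = ("conv1", "conv2", "conv3", "head")

    def __init__(
        self,
        num_classes: int,
        in_channels: int = 1,
        channels: tuple[int, int, int] = (8, 16, 32),
        seed: int = 0,
        input_stats: tuple[float, float] = (0.5, 0.25),
    ) -> None:
        if num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        self.num_classes = num_classes
        self.in_channels = in_channels
        self.channels = tuple(channels)
        self.input_stats = (float(input_stats[0]), float(input_stats[1]))
        self.feature_width = channels[2]
        rng = np.random.default_rng(seed)
        c1, c2, c3 = channels

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params: dict[str, dict[str, np.ndarray]] = {
            "conv1": {"W": he((c1, in_channels, 3, 3), in_channels * 9), "b": np.zeros(c1)},
            "conv2": {"W": he((c2, c1, 3, 3), c1 * 9), "b": np.zeros(c2)},
            "conv3": {"W": he((c3, c2, 3, 3), c2 * 9), "b": np.zeros(c3)},
            "head": {"W": he((num_classes, c3), c3), "b": np.zeros(num_classes)},
        }
        self.frozen: set[str] = set()
        self._cache: dict | None = None

    # -- parameter bookkeeping -------------------------------------------

    def group_sizes(self) -> dict[str, int]:
        return {g: sum(a.size for a in p.values()) for g, p in self.params.items()}

    def get_group_vector(self, group: str) -> np.ndarray:
        p = self.params[group]
        return np.concatenate([p["W"].ravel(), p["b"].ravel()])

    def set_group_vector(self, group: str, vec: np.ndarray) -> None:
        p = self.params[group]
        nw = p["W"].size
        if vec.size != nw + p["b"].size:
            raise ValueError(f"vector length mismatch for group {group}")
        p["W"] = vec[:nw].reshape(p["W"].shape).astype(np.float64).copy()
        p["b"] = vec[nw:].astype(np.float64).copy()

    # -- forward / backward ----------------------------------------------

    def _conv_forward(self, x, group):
        w = self.params[group]["W"]
        b = self.params[group]["b"]
        cout = w.shape[0]
        n, c, h, wd = x.shape
        cols = _im2col(x)
        out = cols @ w.reshape(cout, -1).T + b
        out = out.reshape(n, h, wd, cout).transpose(0, 3, 1, 2)
        return out, cols

    def _pool_forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        return out, idx

    def _pool_backward(self, dout, idx, xshape):
        n, c, h, w = xshape
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Compute logits for an (N, C, H, W) batch of [0,1] images."""
        if x.ndim != 4:
            raise ValueError("expected an (N, C, H, W) batch")
        if x.shape[0] == 0:
            raise ValueError("empty batch")
        mu, sd = self.input_stats
        x0 = (np.asarray(x, dtype=np.float64) - mu) / sd
        z1, cols1 = self._conv_forward(x0, "conv1")
        a1 = np.maximum(z1, 0.0)
        p1, idx1 = self._pool_forward(a1)
        z2, cols2 = self._conv_forward(p1, "conv2")
        a2 = np.maximum(z2, 0.0)
        p2, idx2 = self._pool_forward(a2)
        z3, cols3 = self._conv_forward(p2, "conv3")
        a3 = np.maximum(z3, 0.0)
        feats = a3.mean(axis=(2, 3))  # global average pool -> (N, c3)
        logits = feats @ self.params["head"]["W"].T + self.params["head"]["b"]
        if train:
            self._cache = dict(
                x0=x0, z1=z1, a1=a1, p1=p1, idx1=idx1, cols1=cols1,
                z2=z2, a2=a2, p2=p2, idx2=idx2, cols2=cols2,
                z3=z3, a3=a3, cols3=cols3, feats=feats,
            )
        else:
            self._cache = None
        return logits

    def features(self, x: np.ndarray) -> np.ndarray:
        """Globally pooled penultimate activations, one vector per image."""
        if x.ndim != 4 or x.shape[0] == 0:
            raise ValueError("expected a non-empty (N, C, H, W) batch")
        mu, sd = self.input_stats
        x0 = (np.asarray(x, dtype=np.float64) - mu) / sd
        z1, _ = self._conv_forward(x0, "conv1")
        p1, _ = self._pool_forward(np.maximum(z1, 0.0))
        z2, _ = self._conv_forward(p1, "conv2")
        p2, _ = self._pool_forward(np.maximum(z2, 0.0))
        z3, _ = self._conv_forward(p2, "conv3")
        return np.maximum(z3, 0.0).mean(axis=(2, 3))

    def backward(self, dlogits: np.ndarray, dfeats_extra: np.ndarray | None = None):
        """Gradients for every parameter given d(loss)/d(logits).

        dfeats_extra, if given, is an additional gradient flowing directly
        into the pooled feature vector (used by the prototype-alignment
        regularizer).
        """
        if self._cache is None:
            raise RuntimeError("forward(train=True) must precede backward")
        c = self._cache
        grads: dict[str, dict[str, np.ndarray]] = {}
        feats = c["feats"]
        grads["head"] = {
            "W": dlogits.T @ feats,
            "b": dlogits.sum(axis=0),
        }
        dfeats = dlogits @ self.params["head"]["W"]
        if dfeats_extra is not None:
            dfeats = dfeats + dfeats_extra
        n, c3, h3, w3 = c["a3"].shape
        da3 = (dfeats / (h3 * w3))[:, :, None, None] * np.ones((n, c3, h3, w3))
        dz3 = da3 * (c["z3"] > 0)
        grads["conv3"], dp2 = self._conv_backward(dz3, c["cols3"], "conv3", c["p2"].shape)
        da2 = self._pool_backward(dp2, c["idx2"], c["a2"].shape)
        dz2 = da2 * (c["z2"] > 0)
        grads["conv2"], dp1 = self._conv_backward(dz2, c["cols2"], "conv2", c["p1"].shape)
        da1 = self._pool_backward(dp1, c["idx1"], c["a1"].shape)
        dz1 = da1 * (c["z1"] > 0)
        grads["conv1"], _ = self._conv_backward(dz1, c["cols1"], "conv1", c["x0"].shape)
        return grads

    def _conv_backward(self, dz, cols, group, xshape):
        w = self.params[group]["W"]
        cout = w.shape[0]
        n, _, h, wd = dz.shape
        dmat = dz.transpose(0, 2, 3, 1).reshape(n * h * wd, cout)
        gW = (dmat.T @ cols).reshape(w.shape)
        gb = dmat.sum(axis=0)
        dcols = dmat @ w.reshape(cout, -1)
        dx = _col2im(dcols, xshape)
        return {"W": gW, "b": gb}, dx


@dataclass
class AdamOptimizer:
    """Adam with L2 weight decay added to the gradient (coupled, as in
    classic Adam; the decay realizes an L2 penalty on the weights)."""

    lr: float = 1e-3
    weight_decay: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: dict = field(default_factory=dict)
    _v: dict = field(default_factory=dict)
    _t: int = 0

    def step(self, model: TinyCNN, grads: dict) -> None:
        self._t += 1
        b1t = 1.0 - self.beta1**self._t
        b2t = 1.0 - self.beta2**self._t
        for group, pdict in model.params.items():
            if group in model.frozen:
                continue
            for name, w in pdict.items():
                g = grads[group][name] + self.weight_decay * w
                key = (group, name)
                m = self._m.setdefault(key, np.zeros_like(w))
                v = self._v.setdefault(key, np.zeros_like(w))
                m += (1.0 - self.beta1) * (g - m)
                v += (1.0 - self.beta2) * (g * g - v)
                w -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
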