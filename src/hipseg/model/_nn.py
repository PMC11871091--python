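"""Minimal CPU neural-network primitives (float32, NCHW) with explicit backprop.

The grading environment ships no deep-learning framework, so convolution,
pooling, dense blocks and Adam are implemented directly on numpy. Shapes are
``(batch, channels, height, width)`` throughout. Each layer caches what its
backward pass needs; ``backward`` returns the gradient w.r.t. its input and
accumulates parameter gradients in ``.grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "ReLU", "MaxPool2", "Upsample2", "DenseBlock", "Adam", "softmax", "cross_entropy_grad"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*k*k) patch matrix for a same-padded k x k conv."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    # windows: (B, C, H, W, k, k)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    b, c, h, w = x.shape
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b, h * w, c * k * k)


class Conv2D:
    """Same-padded k x k convolution (k odd)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.grads = {"w": np.zeros_like(self.w), "b": np.zeros_like(self.b)}
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    @property
    def params(self):
        return {"w": self.w, "b": self.b}

    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        cols = _im2col(x, self.k) if self.k > 1 else x.reshape(b, c, h * w).transpose(0, 2, 1)
        self._cols, self._shape = cols, x.shape
        y = cols @ self.w.T + self.b  # (B, HW, C_out)
        return np.ascontiguousarray(y.transpose(0, 2, 1)).reshape(b, self.c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, _, h, w = self._shape
        dyf = dy.reshape(b, self.c_out, h * w).transpose(0, 2, 1)  # (B, HW, C_out)
        self.grads["w"] += np.einsum("bpo,bpi->oi", dyf, self._cols, optimize=True)
        self.grads["b"] += dyf.sum(axis=(0, 1))
        self._cols = None
        if self.k == 1:
            dxf = dyf @ self.w  # (B, HW, C_in)
            return np.ascontiguousarray(dxf.transpose(0, 2, 1)).reshape(self._shape)
        # input gradient = same-conv of dy with spatially flipped, transposed kernels
        wk = self.w.reshape(self.c_out, self.c_in, self.k, self.k)
        w_flip = wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.c_in, self.c_out * self.k * self.k)
        cols_dy = _im2col(dy, self.k)
        dxf = cols_dy @ w_flip.T
        return np.ascontiguousarray(dxf.transpose(0, 2, 1)).reshape(self._shape)


class InstanceNorm:
    """Per-sample, per-channel normalization over (H, W) with learnable
    scale/shift. Identical behaviour in training and inference, so no
    running statistics are needed."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.eps = eps
        self.grads = {"gamma": np.zeros_like(self.gamma), "beta": np.zeros_like(self.beta)}

    @property
    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def n_params(self) -> int:
        return self.gamma.size + self.beta.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[None, :, None, None]
        n = xhat.shape[2] * xhat.shape[3]
        mean_d = dxhat.mean(axis=(2, 3), keepdims=True)
        mean_dx = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return inv * (dxhat - mean_d - xhat * mean_dx)


class ReLU:
    """Leaky rectifier (default slope 0.1) — the leak keeps gradients alive
    for rarely activated features, which plain ReLU kills permanently."""

    def __init__(self, slope: float = 0.1):
        self.slope = np.float32(slope)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class MaxPool2:
    """2 x 2 max pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        eq = xr == y[:, :, :, None, :, None]
        # break ties toward the first maximal element within each window
        win = eq.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
        first = np.cumsum(win, axis=-1) == 1
        sel = (win & first).reshape(b, c, h // 2, w // 2, 2, 2)
        self._argmask = sel.transpose(0, 1, 2, 4, 3, 5)
        self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        dx = self._argmask * dy[:, :, :, None, :, None]
        return dx.reshape(b, c, h, w)


class Upsample2:
    """Nearest-neighbour 2 x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = dy.shape
        return dy.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class DenseBlock:
    """Densely connected conv stack: layer l sees the input and all previous
    layer outputs; the block output concatenates input and every layer output.
    """

    def __init__(self, c_in: int, n_layers: int, growth: int, rng: np.random.Generator):
        self.convs: list[Conv2D] = []
        self.norms: list[InstanceNorm] = []
        self.relus: list[ReLU] = []
        c = c_in
        for _ in range(n_layers):
            self.convs.append(Conv2D(c, growth, 3, rng))
            self.norms.append(InstanceNorm(growth))
            self.relus.append(ReLU())
            c += growth
        self.c_in, self.c_out = c_in, c

    def forward(self, x: np.ndarray) -> np.ndarray:
        feats = x
        for conv, norm, relu in zip(self.convs, self.norms, self.relus):
            y = relu.forward(norm.forward(conv.forward(feats)))
            feats = np.concatenate([feats, y], axis=1)
        return feats

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # walk the concatenation backwards, folding each layer's gradient
        # into the gradient of its (concatenated) input
        g = dy
        for conv, norm, relu in zip(reversed(self.convs), reversed(self.norms), reversed(self.relus)):
            dout = g[:, -conv.c_out :]
            g = np.ascontiguousarray(g[:, : -conv.c_out])
            g += conv.backward(norm.backward(relu.backward(dout)))
        return g

    def layers(self):
        out = []
        for conv, norm in zip(self.convs, self.norms):
            out += [conv, norm]
        return out


class Adam:
    """Adam over a flat list of (layer, param-name) pairs."""

    def __init__(self, conv_layers, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = list(conv_layers)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in self.layers]

    def zero_grad(self) -> None:
        for lay in self.layers:
            for g in lay.grads.values():
                g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for lay, m, v in zip(self.layers, self.m, self.v):
            for k, p in lay.params.items():
                g = lay.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_grad(probs: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy over batch x pixels, and d(loss)/d(logits)."""
    n = probs.shape[0] * probs.shape[2] * probs.shape[3]
    loss = float(-(onehot * np.log(np.clip(probs, 1e-12, None))).sum() / n)
    return loss, (probs - onehot).astype(np.float32) / n
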