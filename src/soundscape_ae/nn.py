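"""Minimal convolutional-network engine on numpy.

Implements exactly what the autoencoder needs — strided 2-D convolution,
transposed convolution, ReLU, sigmoid, mean-squared-error loss and an Adam
optimizer — with explicit forward/backward passes.  Convolutions are
evaluated as matrix products over im2col patch matrices; the transposed
convolution is the adjoint of the strided convolution (a col2im
scatter-add), so the two share their patch machinery and their gradients
mirror each other.  All math is float32; gradients are verified against
finite differences in the test suite.

Shapes follow the (batch, channels, height, width) convention.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "ReLU",
    "Sigmoid",
    "Sequential",
    "Adam",
    "mse_loss",
    "conv_output_size",
    "conv_transpose_output_size",
]

DTYPE = np.float32


def conv_output_size(size: int, kernel: int, stride: int, padding: int) -> int:
    return (size + 2 * padding - kernel) // stride + 1


def conv_transpose_output_size(
    size: int, kernel: int, stride: int, padding: int, output_padding: int
) -> int:
    return (size - 1) * stride - 2 * padding + kernel + output_padding


def _im2col(
    x: np.ndarray, kernel: int, stride: int, padding: int, n_frames: Tuple[int, int]
) -> np.ndarray:
    """(B, C, H, W) → patch tensor (B, C, k, k, Fh, Fw)."""
    fh, fw = n_frames
    if padding > 0:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    b, c = x.shape[:2]
    cols = np.empty((b, c, kernel, kernel, fh, fw), dtype=x.dtype)
    for i in range(kernel):
        for j in range(kernel):
            cols[:, :, i, j] = x[:, :, i : i + stride * fh : stride, j : j + stride * fw : stride]
    return cols


def _col2im(
    cols: np.ndarray,
    out_hw: Tuple[int, int],
    kernel: int,
    stride: int,
    padding: int,
) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to (B, C, H, W)."""
    b, c, _, _, fh, fw = cols.shape
    h, w = out_hw
    xp = np.zeros((b, c, h + 2 * padding, w + 2 * padding), dtype=cols.dtype)
    for i in range(kernel):
        for j in range(kernel):
            xp[:, :, i : i + stride * fh : stride, j : j + stride * fw : stride] += cols[:, :, i, j]
    if padding > 0:
        xp = xp[:, :, padding:-padding, padding:-padding]
    return xp


class Layer:
    """Base layer: parameter dict + cached forward state for backward."""

    def __init__(self):
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        padding: int = 0,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        self.cin, self.cout = in_channels, out_channels
        self.k, self.s, self.p = kernel, stride, padding
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_channels * kernel * kernel)
        self.params["W"] = rng.uniform(-bound, bound, (out_channels, in_channels, kernel, kernel)).astype(DTYPE)
        self.params["b"] = rng.uniform(-bound, bound, out_channels).astype(DTYPE)
        self._cache = None

    def out_hw(self, h: int, w: int) -> Tuple[int, int]:
        return (
            conv_output_size(h, self.k, self.s, self.p),
            conv_output_size(w, self.k, self.s, self.p),
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        fh, fw = self.out_hw(h, w)
        cols = _im2col(x, self.k, self.s, self.p, (fh, fw))
        colmat = cols.reshape(b, c * self.k * self.k, fh * fw)
        wm = self.params["W"].reshape(self.cout, -1)
        y = np.matmul(wm[None], colmat) + self.params["b"][None, :, None]
        self._cache = (colmat, x.shape, (fh, fw))
        return y.reshape(b, self.cout, fh, fw)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        colmat, x_shape, (fh, fw) = self._cache
        b = x_shape[0]
        dyf = dy.reshape(b, self.cout, fh * fw)
        self.grads["b"] = dyf.sum(axis=(0, 2)).astype(DTYPE)
        dwm = np.einsum("bof,bcf->oc", dyf, colmat)
        self.grads["W"] = dwm.reshape(self.params["W"].shape).astype(DTYPE)
        wm = self.params["W"].reshape(self.cout, -1)
        dcol = np.matmul(wm.T[None], dyf)
        dcols = dcol.reshape(b, self.cin, self.k, self.k, fh, fw)
        return _col2im(dcols, x_shape[2:], self.k, self.s, self.p)


class ConvTranspose2d(Layer):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        padding: int = 0,
        output_padding: int = 0,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        if not 0 <= output_padding < stride:
            raise ValueError("output_padding must lie in [0, stride)")
        self.cin, self.cout = in_channels, out_channels
        self.k, self.s, self.p, self.op = kernel, stride, padding, output_padding
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_channels * kernel * kernel)
        self.params["W"] = rng.uniform(-bound, bound, (in_channels, out_channels, kernel, kernel)).astype(DTYPE)
        self.params["b"] = rng.uniform(-bound, bound, out_channels).astype(DTYPE)
        self._cache = None

    def out_hw(self, h: int, w: int) -> Tuple[int, int]:
        return (
            conv_transpose_output_size(h, self.k, self.s, self.p, self.op),
            conv_transpose_output_size(w, self.k, self.s, self.p, self.op),
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        oh, ow = self.out_hw(h, w)
        xf = x.reshape(b, self.cin, h * w)
        wm = self.params["W"].reshape(self.cin, -1)  # (cin, cout*k*k)
        cols = np.matmul(wm.T[None], xf)  # (b, cout*k*k, h*w)
        colt = cols.reshape(b, self.cout, self.k, self.k, h, w)
        y = _col2im(colt, (oh, ow), self.k, self.s, self.p)
        y += self.params["b"][None, :, None, None]
        self._cache = (xf, (h, w))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xf, (h, w) = self._cache
        b = xf.shape[0]
        self.grads["b"] = dy.sum(axis=(0, 2, 3)).astype(DTYPE)
        dcols = _im2col(dy, self.k, self.s, self.p, (h, w))
        dcolmat = dcols.reshape(b, self.cout * self.k * self.k, h * w)
        dwm = np.einsum("bcf,bkf->ck", xf, dcolmat)
        self.grads["W"] = dwm.reshape(self.params["W"].shape).astype(DTYPE)
        wm = self.params["W"].reshape(self.cin, -1)
        dx = np.matmul(wm[None], dcolmat)
        return dx.reshape(b, self.cin, h, w)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        # numerically stable split by sign
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._out * (1.0 - self._out)


class Sequential:
    def __init__(self, layers: Sequence[Layer]):
        self.layers: List[Layer] = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        """Flat list of (name, layer, key) triples for the optimizer."""
        out = []
        for i, layer in enumerate(self.layers):
            for key in layer.params:
                out.append((f"layer{i}.{key}", layer, key))
        return out

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {name: layer.params[key].copy() for name, layer, key in self.parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for name, layer, key in self.parameters():
            if name not in state:
                raise KeyError(f"missing parameter {name}")
            if state[name].shape != layer.params[key].shape:
                raise ValueError(f"shape mismatch for {name}")
            layer.params[key] = state[name].astype(DTYPE).copy()


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error over all elements → (loss, dL/dpred)."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    grad = (2.0 / diff.size) * diff
    return loss, grad


class Adam:
    """Adam with bias correction; state keyed by parameter name."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        # state keyed by position: parameter names may repeat across networks
        self.m = [np.zeros_like(layer.params[key]) for _, layer, key in self.params]
        self.v = [np.zeros_like(layer.params[key]) for _, layer, key in self.params]

    def step(self) -> None:
        self.t += 1
        for i, (_, layer, key) in enumerate(self.params):
            g = layer.grads[key]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            layer.params[key] = (
                layer.params[key] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(DTYPE)
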