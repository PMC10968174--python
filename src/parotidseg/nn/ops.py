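"""Minimal 3D neural-network layers on numpy with hand-written backprop.

Tensors are float32 arrays of shape (N, C, D, H, W).  Convolutions use the
shift-and-GEMM formulation (one small matrix product per kernel offset),
which keeps 96-cube forward passes tractable on a single CPU.  Each layer
caches what its backward pass needs only when ``cache=True``, so full-volume
inference runs at low memory.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "Layer",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "Sigmoid",
    "MaxPool2x",
    "AvgPool2x",
    "ConvTranspose2x",
    "UpsampleLinear2x",
    "softmax_channels",
]


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    """Base class: parameterized layers expose params/grads dicts."""

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}
        self._cache: Optional[tuple] = None

    def forward(self, x: np.ndarray, train: bool = False, cache: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, kernel 1 or 3, stride 1, size-preserving padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel**3
        self.params["W"] = _he_init(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False, cache: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        W, b = self.params["W"], self.params["b"]
        k = self.kernel
        if k == 1:
            y = np.tensordot(W[:, :, 0, 0, 0], x, axes=(1, 1))  # (Co, N, D, H, W)
            y = np.ascontiguousarray(np.moveaxis(y, 0, 1))
            xp = x
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
            N, _, D, H, Wd = x.shape
            acc = None
            for a in range(3):
                for bb in range(3):
                    for c in range(3):
                        view = xp[:, :, a : a + D, bb : bb + H, c : c + Wd]
                        t = np.tensordot(W[:, :, a, bb, c], view, axes=(1, 1))
                        acc = t if acc is None else acc + t
            y = np.ascontiguousarray(np.moveaxis(acc, 0, 1))
        y += b.reshape(1, -1, 1, 1, 1)
        if cache:
            self._cache = (x.shape, xp)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x_shape, xp = self._cache
        W = self.params["W"]
        k = self.kernel
        self.grads["b"] = gy.sum(axis=(0, 2, 3, 4)).astype(np.float32)
        if k == 1:
            gW = np.tensordot(gy, xp, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
            self.grads["W"] = gW.reshape(W.shape).astype(np.float32)
            gx = np.tensordot(W[:, :, 0, 0, 0], gy, axes=(0, 1))
            return np.ascontiguousarray(np.moveaxis(gx, 0, 1))
        N, _, D, H, Wd = x_shape
        gW = np.empty_like(W)
        gxp = np.zeros_like(xp)
        for a in range(3):
            for bb in range(3):
                for c in range(3):
                    view = xp[:, :, a : a + D, bb : bb + H, c : c + Wd]
                    gW[:, :, a, bb, c] = np.tensordot(
                        gy, view, axes=([0, 2, 3, 4], [0, 2, 3, 4])
                    )
                    t = np.tensordot(W[:, :, a, bb, c], gy, axes=(0, 1))  # (Ci,N,D,H,W)
                    gxp[:, :, a : a + D, bb : bb + H, c : c + Wd] += np.moveaxis(t, 0, 1)
        self.grads["W"] = gW
        return np.ascontiguousarray(gxp[:, :, 1:-1, 1:-1, 1:-1])


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W).

    Training mode uses mini-batch statistics and updates running averages;
    evaluation mode uses the running averages.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False, cache: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(1, -1, 1, 1, 1)) * inv_std.reshape(1, -1, 1, 1, 1)
        y = self.params["gamma"].reshape(1, -1, 1, 1, 1) * xhat + self.params[
            "beta"
        ].reshape(1, -1, 1, 1, 1)
        if cache:
            self._cache = (xhat, inv_std.astype(np.float32), train)
        return y.astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std, train = self._cache
        axes = (0, 2, 3, 4)
        gamma = self.params["gamma"].reshape(1, -1, 1, 1, 1)
        self.grads["gamma"] = (gy * xhat).sum(axis=axes).astype(np.float32)
        self.grads["beta"] = gy.sum(axis=axes).astype(np.float32)
        gxhat = gy * gamma
        if not train:
            return gxhat * inv_std.reshape(1, -1, 1, 1, 1)
        m = gy.shape[0] * gy.shape[2] * gy.shape[3] * gy.shape[4]
        s1 = gxhat.sum(axis=axes).reshape(1, -1, 1, 1, 1)
        s2 = (gxhat * xhat).sum(axis=axes).reshape(1, -1, 1, 1, 1)
        gx = (gxhat - s1 / m - xhat * s2 / m) * inv_std.reshape(1, -1, 1, 1, 1)
        return gx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False, cache: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if cache:
            self._cache = (x > 0.0,)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        (mask,) = self._cache
        return gy * mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = False, cache: bool = False) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))
        y = y.astype(np.float32)
        if cache:
            self._cache = (y,)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        (y,) = self._cache
        return gy * y * (1.0 - y)


def _blocks(x: np.ndarray) -> np.ndarray:
    """Reshape (N,C,D,H,W) into (N,C,D/2,H/2,W/2,8) non-overlapping 2-blocks."""
    N, C, D, H, W = x.shape
    r = x.reshape(N, C, D // 2, 2, H // 2, 2, W // 2, 2)
    return np.ascontiguousarray(r.transpose(0, 1, 2, 4, 6, 3, 5, 7)).reshape(
        N, C, D // 2, H // 2, W // 2, 8
    )


def _unblocks(b: np.ndarray, shape) -> np.ndarray:
    N, C, D, H, W = shape
    r = b.reshape(N, C, D // 2, H // 2, W // 2, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
    return np.ascontiguousarray(r).reshape(N, C, D, H, W)


class MaxPool2x(Layer):
    """2x2x2 max pooling, stride 2."""

    def forward(self, x: np.ndarray, train: bool = False, cache: bool = False) -> np.ndarray:
        if any(s % 2 for s in x.shape[2:]):
            raise ValueError(f"spatial dims must be even for 2x pooling, got {x.shape[2:]}")
        b = _blocks(x)
        idx = b.argmax(axis=-1)
        y = np.take_along_axis(b, idx[..., None], axis=-1)[..., 0]
        if cache:
            self._cache = (idx, x.shape)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        gb = np.zeros(gy.shape + (8,), dtype=np.float32)
        np.put_along_axis(gb, idx[..., None], gy[..., None], axis=-1)
        return _unblocks(gb, shape)


class AvgPool2x(Layer):
    """2x2x2 average pooling, stride 2 (used to bring the skip path onto the
    gating signal's coarser grid inside the attention gate)."""

    def forward(self, x: np.ndarray, train: bool = False, cache: bool = False) -> np.ndarray:
        b = _blocks(x)
        if cache:
            self._cache = (x.shape,)
        return b.mean(axis=-1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        (shape,) = self._cache
        gb = np.repeat(gy[..., None] / 8.0, 8, axis=-1)
        return _unblocks(gb.astype(np.float32), shape)


class ConvTranspose2x(Layer):
    """Transpose convolution, kernel 2, stride 2: doubles each spatial dim."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params["W"] = _he_init(rng, (in_ch, out_ch, 2, 2, 2), in_ch)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False, cache: bool = False) -> np.ndarray:
        W, b = self.params["W"], self.params["b"]
        N, C, D, H, Wd = x.shape
        y = np.empty((N, self.out_ch, 2 * D, 2 * H, 2 * Wd), dtype=np.float32)
        for a in range(2):
            for bb in range(2):
                for c in range(2):
                    t = np.tensordot(W[:, :, a, bb, c], x, axes=(0, 1))  # (Co,N,D,H,W)
                    y[:, :, a::2, bb::2, c::2] = np.moveaxis(t, 0, 1)
        y += b.reshape(1, -1, 1, 1, 1)
        if cache:
            self._cache = (x,)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        (x,) = self._cache
        W = self.params["W"]
        self.grads["b"] = gy.sum(axis=(0, 2, 3, 4)).astype(np.float32)
        gW = np.empty_like(W)
        gx = np.zeros_like(x)
        for a in range(2):
            for bb in range(2):
                for c in range(2):
                    gslice = gy[:, :, a::2, bb::2, c::2]
                    gW[:, :, a, bb, c] = np.tensordot(
                        x, gslice, axes=([0, 2, 3, 4], [0, 2, 3, 4])
                    )
                    t = np.tensordot(W[:, :, a, bb, c], gslice, axes=(1, 1))  # (Ci,N,...)
                    gx += np.moveaxis(t, 0, 1)
        self.grads["W"] = gW
        return gx


def _linear2_weights(n_out: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index/weight arrays for x2 linear interpolation along one axis."""
    coord = (np.arange(n_out) + 0.5) / 2.0 - 0.5
    i0 = np.floor(coord).astype(int)
    frac = (coord - i0).astype(np.float32)
    n_in = n_out // 2
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    i0 = np.clip(i0, 0, n_in - 1)
    return i0, i1, frac


class UpsampleLinear2x(Layer):
    """Trilinear x2 upsampling with fixed weights (the gate's grid resampler)."""

    def forward(self, x: np.ndarray, train: bool = False, cache: bool = False) -> np.ndarray:
        y = x
        plans = []
        for axis in (2, 3, 4):
            n_out = 2 * y.shape[axis]
            i0, i1, frac = _linear2_weights(n_out)
            sh = [1] * y.ndim
            sh[axis] = n_out
            w = frac.reshape(sh)
            y = (1.0 - w) * np.take(y, i0, axis=axis) + w * np.take(y, i1, axis=axis)
            plans.append((i0, i1, frac, n_out))
        if cache:
            self._cache = (plans, x.shape)
        return y.astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        plans, x_shape = self._cache
        g = gy
        for axis, (i0, i1, frac, n_out) in zip((4, 3, 2), reversed(plans)):
            n_in = n_out // 2
            sh = [1] * g.ndim
            sh[axis] = n_out
            w = frac.reshape(sh)
            out_shape = list(g.shape)
            out_shape[axis] = n_in
            gx = np.zeros(out_shape, dtype=np.float32)
            gm = np.moveaxis(gx, axis, 0)
            np.add.at(gm, i0, np.moveaxis(g * (1.0 - w), axis, 0))
            np.add.at(gm, i1, np.moveaxis(g * w, axis, 0))
            g = gx
        return g


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Per-voxel softmax over the channel axis (axis 1); dtype-preserving."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
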