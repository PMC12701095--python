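"""Minimal numpy neural-network core for the SegNet/SegDSC family.

Implements exactly the layers the architecture family needs — 3x3 convolution
(standard, depthwise and 1x1 pointwise), batch normalisation, ReLU, 2x2
max-pooling that records argmax indices, index-based max-unpooling, and a
sigmoid head — each with a hand-written backward pass, plus the Adam
optimiser and a batched soft Dice loss.

Tensors are ``float32`` arrays in NCHW layout.  Convolutions use "same"
padding (pad 1 for 3x3), stride 1, and carry no bias: an affine batch norm
always follows.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

__all__ = [
    "Param",
    "Conv3x3",
    "DepthwiseConv3x3",
    "PointwiseConv",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2x2",
    "MaxUnpool2x2",
    "Adam",
    "soft_dice_loss_batch",
]


class Param:
    """A trainable array and its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """Standard 3x3 convolution, stride 1, pad 1, no bias.

    Implemented as nine shifted channel-mixing matmuls, which keeps memory at
    one padded copy of the input instead of a full im2col buffer.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / (9 * cin))  # He initialisation for ReLU stacks
        self.weight = Param(rng.normal(0.0, std, size=(cout, cin, 3, 3)), "conv3x3.weight")
        self._xpad: np.ndarray | None = None

    def parameters(self) -> list[Param]:
        return [self.weight]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xpad = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        out = np.zeros((n, self.cout, h * w), dtype=np.float32)
        W = self.weight.value
        for a in range(3):
            for b in range(3):
                sl = xpad[:, :, a : a + h, b : b + w].reshape(n, c, h * w)
                out += W[:, :, a, b] @ sl
        if training:
            self._xpad = xpad
        self._shape = (n, c, h, w)
        return out.reshape(n, self.cout, h, w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        g = grad.reshape(n, self.cout, h * w)
        W = self.weight.value
        dxpad = np.zeros((n, c, h + 2, w + 2), dtype=np.float32)
        for a in range(3):
            for b in range(3):
                sl = self._xpad[:, :, a : a + h, b : b + w].reshape(n, c, h * w)
                # dW[o, c] = sum_n g[n, o, :] @ sl[n, c, :]^T
                self.weight.grad[:, :, a, b] += np.einsum("noq,ncq->oc", g, sl, optimize=True)
                dxpad[:, :, a : a + h, b : b + w] += (W[:, :, a, b].T @ g).reshape(n, c, h, w)
        self._xpad = None
        return dxpad[:, :, 1:-1, 1:-1]


class DepthwiseConv3x3(Layer):
    """Per-channel 3x3 convolution (the depthwise half of a DSC), no bias."""

    def __init__(self, channels: int, rng: np.random.Generator) -> None:
        self.channels = channels
        std = np.sqrt(2.0 / 9.0)
        self.weight = Param(rng.normal(0.0, std, size=(channels, 3, 3)), "dwconv.weight")
        self._xpad: np.ndarray | None = None

    def parameters(self) -> list[Param]:
        return [self.weight]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xpad = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        out = np.zeros_like(x)
        K = self.weight.value
        for a in range(3):
            for b in range(3):
                out += xpad[:, :, a : a + h, b : b + w] * K[None, :, a, b, None, None]
        if training:
            self._xpad = xpad
        self._shape = (n, c, h, w)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        K = self.weight.value
        dxpad = np.zeros((n, c, h + 2, w + 2), dtype=np.float32)
        for a in range(3):
            for b in range(3):
                sl = self._xpad[:, :, a : a + h, b : b + w]
                self.weight.grad[:, a, b] += np.einsum("nchw,nchw->c", grad, sl, optimize=True)
                dxpad[:, :, a : a + h, b : b + w] += grad * K[None, :, a, b, None, None]
        self._xpad = None
        return dxpad[:, :, 1:-1, 1:-1]


class PointwiseConv(Layer):
    """1x1 channel-mixing convolution (the pointwise half of a DSC), no bias."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / cin)
        self.weight = Param(rng.normal(0.0, std, size=(cout, cin)), "pwconv.weight")
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Param]:
        return [self.weight]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        out = self.weight.value @ x.reshape(n, c, h * w)
        if training:
            self._x = x
        self._shape = (n, c, h, w)
        return out.reshape(n, self.cout, h, w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        g = grad.reshape(n, self.cout, h * w)
        xs = self._x.reshape(n, c, h * w)
        self.weight.grad += np.einsum("noq,ncq->oc", g, xs, optimize=True)
        self._x = None
        return (self.weight.value.T @ g).reshape(n, c, h, w)


class BatchNorm2d(Layer):
    """Affine batch normalisation over (N, H, W) per channel."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=np.float32), "bn.gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if training:
            self._xhat = xhat
            self._inv_std = inv_std
            self._m = x.shape[0] * x.shape[2] * x.shape[3]
        return (
            self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        ).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, m = self._xhat, self._inv_std, self._m
        self.gamma.grad += np.einsum("nchw,nchw->c", grad, xhat, optimize=True)
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (g - sum_g / m - xhat * sum_gx / m) * inv_std[None, :, None, None]
        self._xhat = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._out * (1.0 - self._out)
        self._out = None
        return out


class MaxPool2x2(Layer):
    """2x2/stride-2 max-pooling that records per-window argmax indices."""

    def forward(self, x: np.ndarray, training: bool) -> tuple[np.ndarray, np.ndarray]:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size {h}x{w} not divisible by 2 at a pooling stage")
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, h // 2, w // 2, 4)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        self._shape = (n, c, h, w)
        self._idx = idx
        return out, idx

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return _unpool_scatter(grad, self._idx, self._shape)

    @property
    def indices(self) -> np.ndarray:
        return self._idx


def _unpool_scatter(values: np.ndarray, idx: np.ndarray, out_shape) -> np.ndarray:
    n, c, h, w = out_shape
    win = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
    np.put_along_axis(win, idx[..., None], values[..., None].astype(np.float32), axis=-1)
    win = win.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return win.reshape(n, c, h, w)


class MaxUnpool2x2(Layer):
    """Index-based 2x2 unpooling: places each value at its paired pool argmax."""

    def forward(self, x: np.ndarray, indices: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        self._idx = indices
        self._in_shape = x.shape
        return _unpool_scatter(x, indices, (n, c, 2 * h, 2 * w))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        win = grad.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, h // 2, w // 2, 4)
        return np.take_along_axis(win, self._idx[..., None], axis=-1)[..., 0]


class Adam:
    """Adam optimiser over a list of :class:`Param`."""

    def __init__(
        self,
        params: Iterable[Param],
        lr: float = 0.01,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def soft_dice_loss_batch(
    p: np.ndarray, y: np.ndarray, eps: float = 1.0
) -> tuple[float, np.ndarray]:
    """Mean per-sample soft Dice loss over a batch, with its gradient in p.

    ``p`` and ``y`` are (N, 1, H, W); returns ``(loss, dloss/dp)``.
    """
    p = p.astype(np.float64)
    y = y.astype(np.float64)
    n = p.shape[0]
    axes = tuple(range(1, p.ndim))
    inter = (p * y).sum(axis=axes)
    sums = p.sum(axis=axes) + y.sum(axis=axes)
    num = 2.0 * inter + eps
    den = sums + eps
    loss = float(np.mean(1.0 - num / den))
    # d/dp of -(2 inter + eps)/(den): quotient rule, then average over batch
    grad = (-2.0 * y * den[:, None, None, None] + num[:, None, None, None]) / den[
        :, None, None, None
    ] ** 2
    return loss, (grad / n).astype(np.float32)
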