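"""Layers: dilated Conv1d, BatchNorm1d, LeakyReLU.

Every layer implements ``forward(x, training)`` and ``backward(dy)``;
``backward`` accumulates parameter gradients and returns the gradient with
respect to the layer input. Shapes are ``(N, C, L)`` float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Layer", "Conv1d", "BatchNorm1d", "LeakyReLU", "softmax"]


class Param:
    """A trainable array with its gradient and a freeze flag."""

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = True

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[tuple[str, Param]]:
        return []

    def buffers(self) -> list[tuple[str, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """1-D convolution, stride 1, 'same' zero padding, optional dilation.

    Odd kernel widths only, so the output length always equals the input
    length; receptive-field trimming is done once at the network output
    (the cropping layer) rather than per convolution.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        width: int,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        if width % 2 == 0:
            raise ValueError(f"kernel width must be odd, got {width}")
        if dilation < 1:
            raise ValueError(f"dilation must be >= 1, got {dilation}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.width = width
        self.dilation = dilation
        rng = rng or np.random.default_rng()
        # He initialization for the LeakyReLU family
        std = np.sqrt(2.0 / (in_channels * width))
        self.weight = Param(rng.normal(0.0, std, size=(out_channels, in_channels, width)))
        self.bias = Param(np.zeros(out_channels))
        self._xp: np.ndarray | None = None

    @property
    def pad(self) -> int:
        return self.dilation * (self.width - 1) // 2

    def params(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, length = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        w = self.weight.value
        y = np.empty((n, self.out_channels, length), dtype=np.float32)
        y[...] = self.bias.value[None, :, None]
        d = self.dilation
        for k in range(self.width):
            # (O,C) x (N,C,L) -> (N,O,L)
            y += np.einsum("oc,ncl->nol", w[:, :, k], xp[:, :, k * d : k * d + length])
        self._xp = xp
        self._in_len = length
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        length = self._in_len
        d, p = self.dilation, self.pad
        self.bias.grad += dy.sum(axis=(0, 2))
        dxp = np.zeros_like(xp)
        w = self.weight.value
        for k in range(self.width):
            sl = slice(k * d, k * d + length)
            self.weight.grad[:, :, k] += np.einsum("nol,ncl->oc", dy, xp[:, :, sl])
            dxp[:, :, sl] += np.einsum("oc,nol->ncl", w[:, :, k], dy)
        return dxp[:, :, p : p + length] if p else dxp


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length).

    Training mode normalizes with mini-batch statistics and updates running
    averages; evaluation mode uses the running averages, which makes
    inference deterministic.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def buffers(self):
        return [("running_mean", self.running_mean), ("running_var", self.running_var)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.running_mean += m * (mean - self.running_mean)
            self.running_var += m * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._xhat, self._inv, self._training = xhat, inv, training
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        g = self.gamma.value[None, :, None]
        if not self._training:
            return dy * g * inv[None, :, None]
        n = dy.shape[0] * dy.shape[2]
        dxhat = dy * g
        term = dxhat - dxhat.mean(axis=(0, 2), keepdims=True) - xhat * (dxhat * xhat).sum(
            axis=(0, 2), keepdims=True
        ) / n
        return term * inv[None, :, None]


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1) -> None:
        self.alpha = alpha

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.alpha * dy)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax."""
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
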