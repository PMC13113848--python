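"""Minimal CPU conv-net layers with manual backpropagation.

Implements exactly what the adversarial delay-prediction network needs:
2-D convolution (arbitrary stride, symmetric or asymmetric zero padding),
2x2 stride-2 transposed convolution, batch normalization, 2x2 max pooling,
and the usual pointwise activations.  Arrays are NCHW ``float64``; every
layer caches what its backward pass needs, so a forward/backward pair must
be called in sequence on the same batch.

Gradient correctness is verified against finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "MaxPool2d",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
]


class Parameter:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _pad4(pad) -> tuple[int, int, int, int]:
    """Normalize padding to (top, bottom, left, right)."""
    if isinstance(pad, int):
        return (pad, pad, pad, pad)
    if len(pad) == 2:
        return (pad[0], pad[0], pad[1], pad[1])
    return tuple(pad)


class Conv2d(Layer):
    """2-D convolution (cross-correlation), NCHW.

    ``out = (H + pt + pb - k) // stride + 1`` per spatial axis.  Weights are
    He-initialized from the supplied generator.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad=0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        self.w = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      size=(c_out, c_in, kernel, kernel)))
        self.b = Parameter(np.zeros(c_out))
        self.k = kernel
        self.stride = stride
        self.pad = _pad4(pad)
        self._xp: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self) -> list[Parameter]:
        return [self.w, self.b]

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        pt, pb, pl, pr = self.pad
        return ((h + pt + pb - self.k) // self.stride + 1,
                (w + pl + pr - self.k) // self.stride + 1)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        pt, pb, pl, pr = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        n, _, hp, wp = xp.shape
        oh, ow = self.out_shape(x.shape[2], x.shape[3])
        if oh < 1 or ow < 1:
            raise ValueError(
                f"Conv2d: input {x.shape[2]}x{x.shape[3]} too small for "
                f"kernel {self.k} stride {self.stride} pad {self.pad}"
            )
        out = np.zeros((n, self.w.value.shape[0], oh, ow))
        st = self.stride
        for di in range(self.k):
            for dj in range(self.k):
                sub = xp[:, :, di:di + st * oh:st, dj:dj + st * ow:st]
                out += np.moveaxis(
                    np.tensordot(sub, self.w.value[:, :, di, dj], axes=([1], [1])),
                    3, 1,
                )
        out += self.b.value[None, :, None, None]
        self._xp = xp
        self._xshape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp = self._xp
        st = self.stride
        oh, ow = grad.shape[2], grad.shape[3]
        self.b.grad += grad.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        for di in range(self.k):
            for dj in range(self.k):
                sub = xp[:, :, di:di + st * oh:st, dj:dj + st * ow:st]
                self.w.grad[:, :, di, dj] += np.tensordot(
                    grad, sub, axes=([0, 2, 3], [0, 2, 3])
                )
                dxp[:, :, di:di + st * oh:st, dj:dj + st * ow:st] += np.moveaxis(
                    np.tensordot(grad, self.w.value[:, :, di, dj], axes=([1], [0])),
                    3, 1,
                )
        pt, pb, pl, pr = self.pad
        h, w = self._xshape[2], self._xshape[3]
        return dxp[:, :, pt:pt + h, pl:pl + w]


class ConvTranspose2d(Layer):
    """2x2 stride-2 transposed convolution (exact 2x spatial upsampling).

    Kernel size equals the stride, so output positions do not overlap.
    """

    def __init__(self, c_in: int, c_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Parameter(rng.normal(0.0, np.sqrt(2.0 / c_in),
                                      size=(c_in, c_out, 2, 2)))
        self.b = Parameter(np.zeros(c_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, _, h, w = x.shape
        c_out = self.w.value.shape[1]
        out = np.empty((n, c_out, 2 * h, 2 * w))
        for dh in range(2):
            for dw in range(2):
                out[:, :, dh::2, dw::2] = np.moveaxis(
                    np.tensordot(x, self.w.value[:, :, dh, dw], axes=([1], [0])),
                    3, 1,
                )
        out += self.b.value[None, :, None, None]
        self._x = x
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        self.b.grad += grad.sum(axis=(0, 2, 3))
        dx = np.zeros_like(x)
        for dh in range(2):
            for dw in range(2):
                g = grad[:, :, dh::2, dw::2]
                self.w.grad[:, :, dh, dw] += np.tensordot(
                    x, g, axes=([0, 2, 3], [0, 2, 3])
                )
                dx += np.moveaxis(
                    np.tensordot(g, self.w.value[:, :, dh, dw], axes=([1], [1])),
                    3, 1,
                )
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization with learned scale/shift.

    Training mode normalizes with batch statistics and updates running
    moments; eval mode uses the running moments.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]
        self._cache = (xhat, inv, training, x.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, training, shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        if not training:
            return g * inv[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / m) * (
            m * g - sum_g - xhat * sum_gx
        )


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2 (spatial sizes must be even)."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2d requires even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2) \
              .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, idx[..., None], grad[..., None], axis=-1)
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2) \
                  .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.slope * grad)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)
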