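"""Minimal NumPy layer framework with manual backpropagation.

Only what the segmentation network needs: same-padding 3x3 / 1x1
convolutions, batch normalisation, ReLU, 2x2 max pooling, strided transposed
convolutions for one-shot upsampling, channel concatenation and softmax.
Arrays are NCHW float32 throughout.  Each layer implements ``forward`` and
``backward``; trainable layers expose ``params()`` yielding
(array, gradient) pairs consumed by :class:`Adam`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "ConvTranspose2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2x2",
    "Softmax",
    "Adam",
]

DTYPE = np.float32


class Layer:
    training: bool = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self):
        return []

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patch matrix for stride-1 same conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp, (n, c, k, k, h, w), (s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return np.ascontiguousarray(windows.transpose(0, 4, 5, 1, 2, 3)).reshape(
        n * h * w, c * k * k
    )


def _col2im(cols: np.ndarray, shape: tuple, k: int, pad: int) -> np.ndarray:
    """Scatter-add inverse of :func:`_im2col`."""
    n, c, h, w = shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=DTYPE)
    cols = cols.reshape(n, h, w, c, k, k)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += cols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2D(Layer):
    """Stride-1 convolution with 'same' zero padding (odd kernel)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("Conv2D requires an odd kernel")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = c_in * kernel * kernel
        # He initialisation for ReLU networks
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, kernel, kernel)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        self._cols = _im2col(x, self.kernel, self.kernel // 2)
        out = self._cols @ self.w.reshape(self.c_out, -1).T + self.b
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, _, h, w = self._shape
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.dw[...] = (g.T @ self._cols).reshape(self.w.shape)
        self.db[...] = g.sum(axis=0)
        dcols = g @ self.w.reshape(self.c_out, -1)
        return _col2im(dcols, self._shape, self.kernel, self.kernel // 2)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ConvTranspose2D(Layer):
    """Transposed convolution upsampling by ``stride`` with kernel = 2*stride.

    Output spatial side = input side * stride (padding = stride // 2).
    """

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        if stride < 2 or stride % 2:
            raise ValueError("stride must be an even integer >= 2")
        self.c_in, self.c_out, self.stride = c_in, c_out, stride
        self.kernel = 2 * stride
        fan_in = c_in * 4  # each output pixel draws from (k/stride)^2 = 4 taps
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (c_in, c_out, self.kernel, self.kernel)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        k, s = self.kernel, self.stride
        p = s // 2
        full_h, full_w = (h - 1) * s + k, (w - 1) * s + k
        # (N*H*W, Cin) @ (Cin, Cout*k*k) does all the arithmetic in one GEMM
        contrib = (
            x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
            @ self.w.reshape(c, -1)
        ).reshape(n, h, w, self.c_out, k, k)
        ypad = np.zeros((n, self.c_out, full_h, full_w), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                ypad[:, :, i : i + (h - 1) * s + 1 : s, j : j + (w - 1) * s + 1 : s] += (
                    contrib[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        out = ypad[:, :, p : p + h * s, p : p + w * s]
        return out + self.b[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        k, s = self.kernel, self.stride
        p = s // 2
        full_h, full_w = (h - 1) * s + k, (w - 1) * s + k
        gpad = np.zeros((n, self.c_out, full_h, full_w), dtype=DTYPE)
        gpad[:, :, p : p + h * s, p : p + w * s] = grad
        # gather the k*k contribution gradients back per input pixel
        gcontrib = np.empty((n, h, w, self.c_out, k, k), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                gcontrib[:, :, :, :, i, j] = gpad[
                    :, :, i : i + (h - 1) * s + 1 : s, j : j + (w - 1) * s + 1 : s
                ].transpose(0, 2, 3, 1)
        gmat = gcontrib.reshape(n * h * w, -1)
        xmat = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        self.dw[...] = (xmat.T @ gmat).reshape(self.w.shape)
        self.db[...] = grad.sum(axis=(0, 2, 3))
        dx = gmat @ self.w.reshape(c, -1).T
        return dx.reshape(n, h, w, c).transpose(0, 3, 1, 2)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class BatchNorm2D(Layer):
    """Per-channel batch normalisation with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._inv_std[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.dgamma[...] = (grad * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = grad.sum(axis=(0, 2, 3))
        if not self.training:
            return grad * (self.gamma * self._inv_std)[None, :, None, None]
        gxhat = grad * self.gamma[None, :, None, None]
        mean_g = gxhat.mean(axis=(0, 2, 3), keepdims=True)
        mean_gx = (gxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        return self._inv_std[None, :, None, None] * (
            gxhat - mean_g - self._xhat * mean_gx
        )

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0).astype(DTYPE)


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2x2 needs even spatial sides")
        self._shape = x.shape
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, h // 2, w // 2, 4)
        self._arg = win.argmax(axis=-1)
        return win.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(out, self._arg[..., None], grad[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, h, w)


class Softmax(Layer):
    """Channelwise softmax; pairs with cross entropy which bypasses backward."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=1, keepdims=True)
        return self._p

    def backward(self, grad: np.ndarray) -> np.ndarray:
        # general Jacobian-vector product (unused on the CE fast path)
        p = self._p
        return p * (grad - (grad * p).sum(axis=1, keepdims=True))


class Adam:
    """Adam optimiser over a list of (param, grad) pairs."""

    def __init__(self, params, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self) -> None:
        if self.lr == 0:
            return
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
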