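"""Minimal neural-network primitives on numpy arrays.

Everything here operates on channels-first sequence tensors of shape
``(C, B, L)`` (channels, batch, time), which lets causal dilated
convolutions run as plain BLAS tensordots.  Gradients are accumulated into
``Parameter.grad`` by explicit ``backward`` methods; optimization is a
hand-rolled Adam.  float64 throughout for bit-stable reproducibility.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact (erf-based) Gaussian error linear unit."""
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * _INV_SQRT_2PI * np.exp(-0.5 * x * x)


class CausalConv1d:
    """Causal dilated 1-D convolution with weight normalization.

    Output ``y[t]`` depends on inputs at ``t, t-d, ..., t-(k-1)d`` only;
    the sequence is left-padded with zeros.  The weight is parametrized as
    ``W = g * V / ||V||`` with the norm taken per output channel.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, dilation: int, rng):
        self.c_in, self.c_out = c_in, c_out
        self.k, self.d = kernel_size, dilation
        bound = 1.0 / np.sqrt(c_in * kernel_size)
        v = rng.uniform(-bound, bound, size=(c_out, c_in, kernel_size))
        self.v = Parameter(v)
        self.g = Parameter(np.sqrt((v**2).sum(axis=(1, 2))))
        self.b = Parameter(rng.uniform(-bound, bound, size=c_out))
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.v, self.g, self.b]

    def _weight(self):
        norm = np.sqrt((self.v.data**2).sum(axis=(1, 2), keepdims=True))
        w = self.g.data[:, None, None] * self.v.data / norm
        return w, norm

    @property
    def pad(self) -> int:
        return (self.k - 1) * self.d

    def _tap_view(self, xp: np.ndarray, length: int) -> np.ndarray:
        """Read-only strided view (c_in, k, B, L): tap j at dilation offsets."""
        ci, bsz, _ = xp.shape
        s = xp.strides
        return np.lib.stride_tricks.as_strided(
            xp,
            shape=(ci, self.k, bsz, length),
            strides=(s[0], self.d * s[2], s[1], s[2]),
            writeable=False,
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (c_in, B, L) -> (c_out, B, L)."""
        _, bsz, length = x.shape
        w, norm = self._weight()
        xp = np.zeros((self.c_in, bsz, length + self.pad))
        xp[:, :, self.pad :] = x
        view = self._tap_view(xp, length)
        y = np.tensordot(w, view, axes=([1, 2], [0, 1]))
        y += self.b.data[:, None, None]
        self._cache = (xp, w, norm, length)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, w, norm, length = self._cache
        view = self._tap_view(xp, length)
        dw = np.tensordot(dy, view, axes=([1, 2], [2, 3]))  # (c_out, c_in, k)
        dxp = np.zeros_like(xp)
        dyw = np.tensordot(w, dy, axes=(0, 0))  # (c_in, k, B, L)
        for j in range(self.k):
            dxp[:, :, j * self.d : j * self.d + length] += dyw[:, j]
        self.b.grad += dy.sum(axis=(1, 2))
        # weight-norm chain rule
        vhat = self.v.data / norm
        dot = (dw * vhat).sum(axis=(1, 2), keepdims=True)
        self.g.grad += dot[:, 0, 0]
        self.v.grad += (self.g.data[:, None, None] / norm) * (dw - dot * vhat)
        return dxp[:, :, self.pad :]


class Dropout:
    """Inverted dropout; identity outside training."""

    def __init__(self, p: float):
        if not (0 <= p < 1):
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x: np.ndarray, training: bool, rng) -> np.ndarray:
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Adam:
    """Adam with L2-style weight decay added to the raw gradient."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        weight_decay: float = 0.0,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.betas = lr, betas
        self.weight_decay, self.eps = weight_decay, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
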