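"""Multistage temporal convolutional network for gradient prediction.

The network maps a causal window of the normalized nominal gradient waveform
(channel 1) and its amplitude code (channel 2, the commanded peak amplitude
divided by the system reference amplitude, constant over a window) to the
normalized distorted sample at the window's final time point.

Architecture: ``n_res_blocks`` residual blocks; block i holds two causal
dilated convolutions (kernel ``kernel_size``, dilation ``2**i``), each under
weight normalization and followed by a GELU activation and dropout; a
kernel-1 convolution bypasses the pair and is summed with its output.  A
final linear (kernel-1) layer reads one scalar per time index, so applying
the network convolutionally over a full left-padded sequence is
mathematically identical to sliding a window one sample at a time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import CausalConv1d, Dropout, Parameter, gelu, gelu_grad


@dataclass
class TCNConfig:
    n_res_blocks: int = 5
    kernel_size: int = 16
    window_length: int = 48
    dropout: float = 0.2
    channels: int = 64
    #: add the current nominal sample to the network output, so the network
    #: models the distortion residual rather than the whole waveform
    residual_input: bool = True

    def __post_init__(self) -> None:
        if self.n_res_blocks < 1 or self.kernel_size < 2 or self.window_length < 1:
            raise ValueError("invalid TCN configuration")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")

    @property
    def dilations(self) -> list[int]:
        return [2**i for i in range(self.n_res_blocks)]

    @property
    def receptive_field(self) -> int:
        """1 + 2(k-1)(2^Nres - 1): two convs of dilation 2^i per block."""
        return 1 + 2 * (self.kernel_size - 1) * (2**self.n_res_blocks - 1)


class _ResBlock:
    def __init__(self, c_in: int, c_out: int, k: int, d: int, p: float, rng):
        self.conv1 = CausalConv1d(c_in, c_out, k, d, rng)
        self.conv2 = CausalConv1d(c_out, c_out, k, d, rng)
        self.drop1 = Dropout(p)
        self.drop2 = Dropout(p)
        self.bypass = CausalConv1d(c_in, c_out, 1, 1, rng)

    def parameters(self) -> list[Parameter]:
        return (
            self.conv1.parameters()
            + self.conv2.parameters()
            + self.bypass.parameters()
        )

    def forward(self, x, training, rng):
        z1 = self.conv1.forward(x)
        a1 = self.drop1.forward(gelu(z1), training, rng)
        z2 = self.conv2.forward(a1)
        a2 = self.drop2.forward(gelu(z2), training, rng)
        self._z1, self._z2 = z1, z2
        return a2 + self.bypass.forward(x)

    def backward(self, dy):
        dx = self.bypass.backward(dy)
        da2 = self.drop2.backward(dy)
        dz2 = da2 * gelu_grad(self._z2)
        da1 = self.conv2.backward(dz2)
        dz1 = self.drop1.backward(da1) * gelu_grad(self._z1)
        dx += self.conv1.backward(dz1)
        return dx


class TCN:
    """Causal dilated-convolution predictor; see module docstring."""

    def __init__(self, config: TCNConfig, rng: np.random.Generator, c_in: int = 2):
        self.config = config
        self.blocks = []
        c_prev = c_in
        for d in config.dilations:
            self.blocks.append(
                _ResBlock(
                    c_prev, config.channels, config.kernel_size, d, config.dropout, rng
                )
            )
            c_prev = config.channels
        self.head = CausalConv1d(c_prev, 1, 1, 1, rng)
        if config.residual_input:
            # zero-initialized head: the network starts as the identity map
            # (output = nominal sample) and learns the distortion residual
            self.head.g.data[:] = 0.0
            self.head.b.data[:] = 0.0

    def parameters(self) -> list[Parameter]:
        out = []
        for b in self.blocks:
            out += b.parameters()
        return out + self.head.parameters()

    def forward_sequence(
        self, x: np.ndarray, training: bool = False, rng=None
    ) -> np.ndarray:
        """x: (2, B, L) normalized inputs -> (B, L) normalized predictions."""
        h = x
        for b in self.blocks:
            h = b.forward(h, training, rng)
        y = self.head.forward(h)[0]
        if self.config.residual_input:
            y = y + x[0]
        return y

    def backward_sequence(self, dy: np.ndarray) -> np.ndarray:
        """dy: (B, L) gradient of the loss w.r.t. the output."""
        dh = self.head.backward(dy[None])
        for b in reversed(self.blocks):
            dh = b.backward(dh)
        if self.config.residual_input:
            dh = dh.copy()
            dh[0] += dy
        return dh

    def predict_window(self, window: np.ndarray) -> float:
        """One scalar prediction from a (T, 2) window (inference mode)."""
        x = np.ascontiguousarray(window.T)[:, None, :]  # (2, 1, T)
        return float(self.forward_sequence(x)[0, -1])

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data[...] = state[f"p{i}"]
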