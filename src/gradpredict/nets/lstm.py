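"""LSTM baseline for gradient waveform prediction.

A stacked LSTM consuming the same (normalized waveform, amplitude code)
channels as the TCN, with a linear head applied to the hidden state at every
time step.  Backpropagation through time is written out explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Parameter


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class LSTMConfig:
    n_layers: int = 2
    hidden: int = 96

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.hidden < 1:
            raise ValueError("invalid LSTM configuration")


class _LSTMLayer:
    """Single LSTM layer; gate order (i, f, g, o)."""

    def __init__(self, c_in: int, hidden: int, rng):
        h = hidden
        bound = 1.0 / np.sqrt(h)
        self.wx = Parameter(rng.uniform(-bound, bound, size=(4 * h, c_in)))
        self.wh = Parameter(rng.uniform(-bound, bound, size=(4 * h, h)))
        self.b = Parameter(rng.uniform(-bound, bound, size=4 * h))
        self.h = h

    def parameters(self):
        return [self.wx, self.wh, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (C, B, L) -> hidden states (H, B, L)."""
        c_in, bsz, length = x.shape
        h_dim = self.h
        hs = np.zeros((h_dim, bsz, length))
        cache = []
        h_prev = np.zeros((h_dim, bsz))
        c_prev = np.zeros((h_dim, bsz))
        for t in range(length):
            z = (
                self.wx.data @ x[:, :, t]
                + self.wh.data @ h_prev
                + self.b.data[:, None]
            )
            i = _sigmoid(z[:h_dim])
            f = _sigmoid(z[h_dim : 2 * h_dim])
            g = np.tanh(z[2 * h_dim : 3 * h_dim])
            o = _sigmoid(z[3 * h_dim :])
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_new = o * tc
            hs[:, :, t] = h_new
            cache.append((x[:, :, t], h_prev, c_prev, i, f, g, o, c, tc))
            h_prev, c_prev = h_new, c
        self._cache = cache
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        """dhs: (H, B, L) -> gradient w.r.t. the layer input (C, B, L)."""
        cache = self._cache
        length = dhs.shape[2]
        bsz = dhs.shape[1]
        c_in = self.wx.data.shape[1]
        h_dim = self.h
        dx = np.zeros((c_in, bsz, length))
        dh_next = np.zeros((h_dim, bsz))
        dc_next = np.zeros((h_dim, bsz))
        for t in range(length - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c, tc = cache[t]
            dh = dhs[:, :, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ]
            )
            self.wx.grad += dz @ x_t.T
            self.wh.grad += dz @ h_prev.T
            self.b.grad += dz.sum(axis=1)
            dx[:, :, t] = self.wx.data.T @ dz
            dh_next = self.wh.data.T @ dz
        return dx


class LSTMNet:
    """Stacked LSTM with a per-time-step linear scalar head."""

    def __init__(self, config: LSTMConfig, rng: np.random.Generator, c_in: int = 2):
        self.config = config
        self.layers = []
        c_prev = c_in
        for _ in range(config.n_layers):
            self.layers.append(_LSTMLayer(c_prev, config.hidden, rng))
            c_prev = config.hidden
        bound = 1.0 / np.sqrt(config.hidden)
        self.w_out = Parameter(rng.uniform(-bound, bound, size=(1, config.hidden)))
        self.b_out = Parameter(rng.uniform(-bound, bound, size=1))

    def parameters(self) -> list[Parameter]:
        out = []
        for layer in self.layers:
            out += layer.parameters()
        return out + [self.w_out, self.b_out]

    def forward_sequence(
        self, x: np.ndarray, training: bool = False, rng=None
    ) -> np.ndarray:
        h = x
        for layer in self.layers:
            h = layer.forward(h)
        self._h_last = h
        y = np.tensordot(self.w_out.data[0], h, axes=(0, 0)) + self.b_out.data[0]
        return y  # (B, L)

    def backward_sequence(self, dy: np.ndarray) -> np.ndarray:
        h = self._h_last
        self.w_out.grad[0] += np.tensordot(dy, h, axes=([0, 1], [1, 2]))
        self.b_out.grad += dy.sum()
        dh = self.w_out.data[0][:, None, None] * dy[None]
        for layer in reversed(self.layers):
            dh = layer.backward(dh)
        return dh

    def predict_window(self, window: np.ndarray) -> float:
        x = np.ascontiguousarray(window.T)[:, None, :]
        return float(self.forward_sequence(x)[0, -1])

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data[...] = state[f"p{i}"]
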