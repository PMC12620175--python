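"""Dataset construction, training and inference for the gradient predictors.

Windows are built with stride 1 and left zero-padding, one sample per time
point per waveform, never crossing waveform boundaries.  Training evaluates
the stride-1 window set convolutionally: sequences of equal length are
batched and the causal network is applied to the whole left-padded
sequence, which yields exactly the per-window predictions in one pass.
The mean-absolute-error loss weights every time point equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..core import GradientWaveform, Library, WaveformPair
from ..waveforms import SYSTEM_MAX_GRAD
from .layers import Adam
from .lstm import LSTMConfig, LSTMNet
from .tcn import TCN, TCNConfig


class TrainingError(RuntimeError):
    """Raised when optimization diverges; carries the epoch index."""

    def __init__(self, epoch: int, message: str = "training diverged"):
        super().__init__(f"{message} at epoch {epoch}")
        self.epoch = epoch


@dataclass
class TrainingConfig:
    """Adam/MAE training hyperparameters.

    ``batch_size`` counts full sequences per optimizer step (each sequence
    contributes one stride-1 window per time point).
    """

    learning_rate: float = 8.4e-4
    batch_size: int = 4
    weight_decay: float = 9e-8
    adam_beta1: float = 0.9
    adam_beta2: float = 1.0 - 1e-6
    epochs: int = 30
    #: 'constant' or 'cosine' (cosine decay of the learning rate to ~0
    #: over the training run, reducing the late-training MAE floor)
    lr_schedule: str = "constant"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("invalid training configuration")


@dataclass
class TrainedModel:
    """A trained (or untrained) predictor for one gradient axis."""

    axis: str
    architecture: str  # 'tcn' | 'lstm'
    net: object
    config: object
    training_config: TrainingConfig | None = None
    loss_trace: list[float] = field(default_factory=list)
    a_sys: float = SYSTEM_MAX_GRAD


def build_tcn(
    config: TCNConfig | None = None, axis: str = "z", seed: int = 0
) -> TrainedModel:
    config = config or TCNConfig()
    rng = np.random.default_rng(seed)
    return TrainedModel(axis=axis, architecture="tcn", net=TCN(config, rng), config=config)


def build_lstm(
    n_layers: int = 2, hidden: int = 96, axis: str = "z", seed: int = 0
) -> TrainedModel:
    config = LSTMConfig(n_layers=n_layers, hidden=hidden)
    rng = np.random.default_rng(seed)
    return TrainedModel(
        axis=axis, architecture="lstm", net=LSTMNet(config, rng), config=config
    )


def _normalized_xy(
    pair: WaveformPair, a_sys: float
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize by |amp_scale|: channel 1 keeps the waveform's sign and the
    amplitude code (channel 2) is unsigned, so sign-flipped waveforms (e.g.
    rotated readout shots) stay inside the trained input distribution.
    Gradient chains are odd-symmetric, so no information is lost."""
    nom = pair.nominal
    if nom.amp_scale == 0:
        raise ValueError("cannot normalize a zero-amplitude waveform")
    a = abs(nom.amp_scale)
    x1 = nom.samples / a
    x2 = np.full(nom.n, a / a_sys)
    target = pair.measured.samples / a if pair.measured is not None else None
    return np.stack([x1, x2]), target


def build_windows(
    pairs: Library | Sequence[WaveformPair],
    window_length: int,
    a_sys: float = SYSTEM_MAX_GRAD,
) -> tuple[np.ndarray, np.ndarray]:
    """Explicit windowed dataset: (windows [N, T, 2], targets [N]).

    Stride-1 windows with left zero-padding: waveform of length L yields
    exactly L samples.  Channel 2 (the amplitude code) is constant within a
    window, including over the zero-padded region.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty library")
    t_len = window_length
    wins, targets = [], []
    for p in pairs:
        if p.measured is None:
            raise ValueError("pairs must carry measured waveforms")
        x, y = _normalized_xy(p, a_sys)
        xp = np.zeros((2, x.shape[1] + t_len - 1))
        xp[:, t_len - 1 :] = x
        xp[1, : t_len - 1] = x[1, 0]
        for n in range(x.shape[1]):
            wins.append(xp[:, n : n + t_len].T)
            targets.append(y[n])
    return np.asarray(wins), np.asarray(targets)


def _sequence_batches(
    pairs: list[WaveformPair], a_sys: float
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group pairs by length into (X [2, B, L], Y [B, L]) arrays."""
    by_len: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
    for p in pairs:
        x, y = _normalized_xy(p, a_sys)
        by_len.setdefault(x.shape[1], []).append((x, y))
    out = []
    for length in sorted(by_len):
        xs = np.stack([x for x, _ in by_len[length]], axis=1)
        ys = np.stack([y for _, y in by_len[length]], axis=0)
        out.append((xs, ys))
    return out


def train_model(
    model: TrainedModel,
    pairs: Library | Sequence[WaveformPair],
    tcfg: TrainingConfig | None = None,
) -> TrainedModel:
    """Train in place with Adam on the mean absolute error; returns the model.

    Sequences are shuffled each epoch (seeded), grouped by length, and
    consumed in mini-batches of ``batch_size`` sequences.  Reproducible for
    a fixed seed.
    """
    tcfg = tcfg or TrainingConfig()
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty training set")
    rng = np.random.default_rng(tcfg.rng_seed)
    groups = _sequence_batches(list(pairs), model.a_sys)
    opt = Adam(
        model.net.parameters(),
        lr=tcfg.learning_rate,
        betas=(tcfg.adam_beta1, tcfg.adam_beta2),
        weight_decay=tcfg.weight_decay,
    )
    if tcfg.lr_schedule not in ("constant", "cosine"):
        raise ValueError(f"unknown lr schedule {tcfg.lr_schedule!r}")
    model.training_config = tcfg
    model.loss_trace = []
    for epoch in range(tcfg.epochs):
        if tcfg.lr_schedule == "cosine":
            opt.lr = tcfg.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * epoch / tcfg.epochs)
            )
        # deterministic shuffle of sequences within groups and of batch order
        batches = []
        for xs, ys in groups:
            perm = rng.permutation(xs.shape[1])
            for lo in range(0, perm.size, tcfg.batch_size):
                idx = perm[lo : lo + tcfg.batch_size]
                batches.append((xs[:, idx], ys[idx]))
        order = rng.permutation(len(batches))
        total_abs = 0.0
        total_n = 0
        for bi in order:
            xb, yb = batches[bi]
            opt.zero_grad()
            pred = model.net.forward_sequence(xb, training=True, rng=rng)
            err = pred - yb
            total_abs += float(np.abs(err).sum())
            total_n += err.size
            dloss = np.sign(err) / err.size
            model.net.backward_sequence(dloss)
            opt.step()
        loss = total_abs / total_n
        if not np.isfinite(loss):
            raise TrainingError(epoch)
        model.loss_trace.append(loss)
    return model


def predict_waveform(
    model: TrainedModel,
    nominal: GradientWaveform,
    a_sys: float | None = None,
) -> GradientWaveform:
    """Full-sequence causal prediction of the played-out waveform.

    Identical (to floating-point tolerance) to sliding-window inference
    (:func:`sliding_window_predict`) whenever the window covers the
    network's receptive field.
    """
    if nominal.axis != model.axis:
        raise ValueError(
            f"model is for axis {model.axis!r}, waveform is {nominal.axis!r}"
        )
    a_sys = model.a_sys if a_sys is None else a_sys
    if nominal.amp_scale == 0:
        x = np.zeros((2, 1, nominal.n))
        pred = model.net.forward_sequence(x)[0]
        return nominal.with_samples(pred * 0.0)
    a = abs(nominal.amp_scale)
    x1 = nominal.samples / a
    x2 = np.full(nominal.n, a / a_sys)
    x = np.stack([x1, x2])[:, None, :]
    pred = model.net.forward_sequence(x)[0]
    return nominal.with_samples(pred * a)


def sliding_window_predict(
    model: TrainedModel,
    nominal: GradientWaveform,
    context: int | None = None,
) -> GradientWaveform:
    """Per-window inference: one network evaluation per time point.

    Each window holds the ``context`` most recent samples, truncated (not
    padded) at the sequence start so the causal convolutions see exactly
    the same layerwise zero padding as in full-sequence mode.  With
    ``context`` at least the receptive field this reproduces
    :func:`predict_waveform` sample for sample; it is the reference
    implementation the fast full-sequence path is checked against.
    """
    if nominal.axis != model.axis:
        raise ValueError("axis mismatch")
    if context is None:
        context = getattr(model.config, "receptive_field", nominal.n)
    a = abs(nominal.amp_scale)
    x1 = nominal.samples / a if a != 0 else nominal.samples * 0.0
    x2 = np.full(nominal.n, a / model.a_sys)
    x = np.stack([x1, x2])
    out = np.array(
        [
            model.net.predict_window(x[:, max(0, n - context + 1) : n + 1].T)
            for n in range(nominal.n)
        ]
    )
    return nominal.with_samples(out * (a if a != 0 else 1.0))
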