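"""File formats: TSV waveform tables, JSON manifests, GIRF tables, model
checkpoints, and NIfTI images.

Waveform files are two-column TSV (time_s, grad_mT_per_m) with a header
row; a library directory holds one file per waveform plus a
``manifest.json`` listing class label, axis, amplitude and split.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import GradientWaveform, Library, WaveformPair
from .girf import GIRFModel
from .nets.lstm import LSTMConfig
from .nets.tcn import TCNConfig
from .nets.train import TrainedModel, TrainingConfig, build_lstm, build_tcn


def write_waveform_tsv(w: GradientWaveform, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": w.times, "grad_mT_per_m": w.samples})
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_waveform_table(
    path: str | Path,
    axis: str = "z",
    amp_scale: float | None = None,
    label: str = "",
) -> GradientWaveform:
    """Read a TSV waveform; dt is inferred from the (uniform) time column."""
    df = pd.read_csv(path, sep="\t")
    for col in ("time_s", "grad_mT_per_m"):
        if col not in df.columns:
            raise ValueError(f"waveform table missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    g = df["grad_mT_per_m"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("waveform table needs at least two samples")
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise ValueError("time column must be strictly increasing")
    dt = float(np.mean(dts))
    if np.max(np.abs(dts - dt)) > 1e-9 * dt:
        raise ValueError("time column is not uniformly sampled")
    # snap away float-parsing jitter so waveforms from one library share dt
    dt = float(f"{dt:.9g}")
    return GradientWaveform(g, dt, axis=axis, amp_scale=amp_scale, label=label)


def write_library(lib: Library, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, p in enumerate(lib):
        stem = f"{p.nominal.label}_{p.nominal.axis}_{i:04d}"
        write_waveform_tsv(p.nominal, out / f"{stem}_nominal.tsv")
        entry = {
            "label": p.nominal.label,
            "axis": p.nominal.axis,
            "amplitude_mT_per_m": p.nominal.amp_scale,
            "split": p.split,
            "nominal_file": f"{stem}_nominal.tsv",
        }
        if p.measured is not None:
            write_waveform_tsv(p.measured, out / f"{stem}_measured.tsv")
            entry["measured_file"] = f"{stem}_measured.tsv"
        manifest.append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_library(in_dir: str | Path) -> Library:
    src = Path(in_dir)
    manifest_path = src / "manifest.json"
    if not manifest_path.exists():
        raise ValueError("library directory has no manifest.json")
    pairs = []
    for entry in json.loads(manifest_path.read_text()):
        for key in ("label", "axis", "amplitude_mT_per_m", "split", "nominal_file"):
            if key not in entry:
                raise ValueError(f"manifest entry missing field {key!r}")
        nominal = read_waveform_table(
            src / entry["nominal_file"],
            axis=entry["axis"],
            amp_scale=entry["amplitude_mT_per_m"],
            label=entry["label"],
        )
        measured = None
        if "measured_file" in entry:
            measured = read_waveform_table(
                src / entry["measured_file"],
                axis=entry["axis"],
                amp_scale=entry["amplitude_mT_per_m"],
                label=entry["label"],
            )
        pairs.append(WaveformPair(nominal=nominal, measured=measured, split=entry["split"]))
    return Library(pairs)


def write_girf(girf: GIRFModel, path: str | Path) -> None:
    """TSV (freq_Hz, Re, Im) plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "freq_Hz": girf.freqs,
            "Re": girf.transfer_function.real,
            "Im": girf.transfer_function.imag,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    meta = {
        "axis": girf.axis,
        "fft_length": girf.fft_length,
        "regularization": girf.regularization,
        "dt": girf.dt,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_girf(path: str | Path) -> GIRFModel:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    h = df["Re"].to_numpy() + 1j * df["Im"].to_numpy()
    return GIRFModel(
        axis=meta["axis"],
        transfer_function=h,
        fft_length=meta["fft_length"],
        regularization=meta["regularization"],
        dt=meta["dt"],
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Checkpoint: npz weights + JSON config snapshot."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.net.state_dict())
    meta = {
        "axis": model.axis,
        "architecture": model.architecture,
        "config": asdict(model.config),
        "training_config": asdict(model.training_config)
        if model.training_config
        else None,
        "loss_trace": model.loss_trace,
        "a_sys": model.a_sys,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta["architecture"] == "tcn":
        model = build_tcn(TCNConfig(**meta["config"]), axis=meta["axis"])
    else:
        cfg = LSTMConfig(**meta["config"])
        model = build_lstm(cfg.n_layers, cfg.hidden, axis=meta["axis"])
    with np.load(path.with_suffix(".npz")) as data:
        model.net.load_state_dict(dict(data))
    if meta["training_config"]:
        model.training_config = TrainingConfig(**meta["training_config"])
    model.loss_trace = list(meta["loss_trace"])
    model.a_sys = meta["a_sys"]
    return model


def save_nifti(image: np.ndarray, fov: float, path: str | Path) -> None:
    """Save a (magnitude) image or map as NIfTI with isotropic in-plane voxels."""
    arr = np.asarray(image)
    if np.iscomplexobj(arr):
        arr = np.abs(arr)
    vox = fov / arr.shape[0] * 1e3  # mm
    affine = np.diag([vox, vox, 1.0, 1.0])
    nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), str(path))
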