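"""File formats: CSV spectra, YAML configs, HDF5 datasets and models."""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np
import pandas as pd
import yaml

from .ml import APTRegressor
from .params import ZSpectrum
from .synth_data import TrainingRecord

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "load_config",
    "save_config",
    "save_records",
    "load_records",
    "save_model",
    "load_model",
]


def read_spectrum(path) -> ZSpectrum:
    """Read a two-column (offset_ppm, signal_norm) CSV/TSV spectrum."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (offset_ppm, signal_norm)")
    off = df.iloc[:, 0].to_numpy(float)
    val = df.iloc[:, 1].to_numpy(float)
    order = np.argsort(off)
    return ZSpectrum(off[order], val[order], meta={"source": str(path)})


def write_spectrum(path, z: ZSpectrum):
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame({"offset_ppm": z.offsets, "signal_norm": z.values}).to_csv(
        path, sep=sep, index=False
    )


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(path, config: dict):
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def save_records(path, records: list[TrainingRecord], manifest: dict | None = None):
    """Write training records to HDF5 (/features, /targets, /truth, /gen_params)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("offsets", data=records[0].offsets)
        f.create_dataset("truth_offsets", data=records[0].truth_offsets)
        f.create_dataset("features", data=np.stack([r.features for r in records]))
        f.create_dataset(
            "targets", data=np.array([(r.target_A, r.target_W) for r in records])
        )
        f.create_dataset("truth", data=np.stack([r.truth_spectrum for r in records]))
        f.create_dataset(
            "gen_params",
            data=np.array([json.dumps(r.gen_params) for r in records], dtype="S"),
        )
        if manifest:
            f.attrs["manifest"] = json.dumps(manifest)


def load_records(path) -> list[TrainingRecord]:
    with h5py.File(path, "r") as f:
        offsets = f["offsets"][...]
        truth_offsets = f["truth_offsets"][...]
        feats = f["features"][...]
        targets = f["targets"][...]
        truth = f["truth"][...]
        gp = [json.loads(s.decode()) for s in f["gen_params"][...]]
    return [
        TrainingRecord(
            offsets=offsets, features=feats[i], target_A=float(targets[i, 0]),
            target_W=float(targets[i, 1]), truth_offsets=truth_offsets,
            truth_spectrum=truth[i], gen_params=gp[i],
        )
        for i in range(feats.shape[0])
    ]


def save_model(path, model: APTRegressor):
    """Serialize a fitted regressor (weights + normalization + metadata)."""
    if not hasattr(model, "weights_"):
        raise ValueError("model is not fitted")
    with h5py.File(path, "w") as f:
        for i, (w, b) in enumerate(zip(model.weights_, model.biases_)):
            f.create_dataset(f"weights/{i}", data=w)
            f.create_dataset(f"biases/{i}", data=b)
        f.create_dataset("x_mean", data=model.x_mean_)
        f.create_dataset("x_scale", data=model.x_scale_)
        if model.feature_offsets_ is not None:
            f.create_dataset("feature_offsets", data=model.feature_offsets_)
        f.attrs["spec"] = json.dumps(model.get_params())
        f.attrs["n_epochs"] = model.n_epochs_


def load_model(path) -> APTRegressor:
    with h5py.File(path, "r") as f:
        model = APTRegressor(**json.loads(f.attrs["spec"]))
        n_layers = len(f["weights"])
        model.weights_ = [f[f"weights/{i}"][...] for i in range(n_layers)]
        model.biases_ = [f[f"biases/{i}"][...] for i in range(n_layers)]
        model.x_mean_ = f["x_mean"][...]
        model.x_scale_ = f["x_scale"][...]
        model.feature_offsets_ = (
            f["feature_offsets"][...] if "feature_offsets" in f else None
        )
        model.n_epochs_ = int(f.attrs["n_epochs"])
    model.n_features_in_ = model.x_mean_.size
    model.n_clamped_ = 0
    return model
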