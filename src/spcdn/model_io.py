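"""Serialization: HDF5 model files, TOML/JSON configs, CSV exports.

Model files store the weight matrix as dataset ``/A`` (L x M, float64) with
the homeostasis spec and run metadata as root attributes, versioned with a
``format_version`` attribute.  Configs are read from TOML (via ``tomllib``)
or JSON; all metadata this package writes is JSON.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .homeostasis import HomeostasisSpec
from .network import SPCNetwork

__all__ = [
    "FORMAT_VERSION",
    "save_model",
    "load_model",
    "read_config",
    "write_json",
    "curve_to_csv",
    "report_to_csv",
]

FORMAT_VERSION = 1


def save_model(path, net: SPCNetwork, metadata: dict | None = None) -> None:
    """Write an SPC network to an HDF5 file."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=np.asarray(net.A, dtype=np.float64))
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["nonnegative"] = bool(net.nonnegative)
        f.attrs["homeostasis"] = json.dumps(net.hspec.to_dict())
        if metadata:
            f.attrs["metadata"] = json.dumps(metadata, default=str)


def load_model(path) -> SPCNetwork:
    """Read an SPC network from an HDF5 file, validating its integrity."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "A" not in f:
            raise ValueError(f"{path}: missing dataset /A")
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported format_version {version}")
        A = np.asarray(f["A"][...], dtype=float)
        hspec = HomeostasisSpec.from_dict(json.loads(f.attrs["homeostasis"]))
        nonnegative = bool(f.attrs.get("nonnegative", True))
    if A.ndim != 2 or not np.all(np.isfinite(A)):
        raise ValueError(f"{path}: /A is not a finite 2-D matrix")
    norms = np.linalg.norm(A, axis=0)
    if np.any(norms == 0):
        raise ValueError(f"{path}: model contains all-zero weight columns")
    return SPCNetwork(A=A, hspec=hspec, nonnegative=nonnegative)


def read_config(path) -> dict:
    """Read a TOML or JSON config file into a nested dict."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return json.loads(path.read_text())
    with open(path, "rb") as f:
        return tomllib.load(f)


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    return str(o)


def curve_to_csv(path, contrasts, responses, fitted=None) -> None:
    """Export a contrast-response curve (and optional fit) to CSV."""
    cols = {"contrast": np.asarray(contrasts), "response": np.asarray(responses)}
    if fitted is not None:
        cols["fitted_response"] = np.asarray(fitted)
    pd.DataFrame(cols).to_csv(path, index=False)


def report_to_csv(path, report) -> None:
    """Export a TrainingReport's per-batch telemetry to CSV."""
    pd.DataFrame(
        {
            "batch": np.arange(report.mean_reconstruction_error.size),
            "mean_reconstruction_error": report.mean_reconstruction_error,
            "mean_sparsity": report.mean_sparsity,
        }
    ).to_csv(path, index=False)
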