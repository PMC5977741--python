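"""Dataset and model serialisation.

HDF5 is the canonical container: datasets are stored as ``/X`` (N x J1 x J2,
float64) and ``/y`` (N, int).  A plain-text alternative is accepted for
loading: a directory of per-trial CSV matrices listed by ``labels.csv``
(columns file,label) plus ``meta.json`` giving the expected shape.  Projection
and BDCA models are stored as ``/U1``, ``/U2`` (+ ``/V``) with attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .bdca import BdcaModel
from .core import ProjectionModel, Structure, TensorDataset

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_model",
    "load_model",
    "save_bdca_model",
    "load_bdca_model",
]


class SchemaError(ValueError):
    """A file exists but does not match the expected schema."""


def save_dataset(data: TensorDataset, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=data.X, dtype="f8")
        f.create_dataset("y", data=data.y.astype(np.int64))


def _load_csv_dir(path: Path) -> TensorDataset:
    meta_path = path / "meta.json"
    labels_path = path / "labels.csv"
    for p in (meta_path, labels_path):
        if not p.exists():
            raise FileNotFoundError(f"dataset directory is missing {p}")
    meta = json.loads(meta_path.read_text())
    try:
        j1, j2 = int(meta["shape"][0]), int(meta["shape"][1])
    except (KeyError, IndexError, TypeError) as err:
        raise SchemaError(f"meta.json: invalid or missing 'shape' field ({err})")
    labels = pd.read_csv(labels_path)
    if not {"file", "label"} <= set(labels.columns):
        raise SchemaError("labels.csv must have columns 'file' and 'label'")
    trials, ys = [], []
    for _, row in labels.iterrows():
        M = np.loadtxt(path / str(row["file"]), delimiter=",", ndmin=2)
        if M.shape != (j1, j2):
            raise SchemaError(
                f"{row['file']}: trial shape {M.shape} != meta shape {(j1, j2)}"
            )
        trials.append(M)
        ys.append(int(row["label"]))
    return TensorDataset(np.stack(trials), np.array(ys))


def load_dataset(path: str | Path) -> TensorDataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset not found: {path}")
    if path.is_dir():
        return _load_csv_dir(path)
    with h5py.File(path, "r") as f:
        for key in ("X", "y"):
            if key not in f:
                raise SchemaError(f"{path}: missing dataset '/{key}'")
        X = np.asarray(f["X"], dtype=float)
        y = np.asarray(f["y"], dtype=int)
    if X.ndim != 3:
        raise SchemaError(f"{path}: /X must be 3-dimensional, got shape {X.shape}")
    if y.shape != (X.shape[0],):
        raise SchemaError(f"{path}: /y length {y.shape} does not match /X")
    return TensorDataset(X, y)


def save_model(model: ProjectionModel, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("U1", data=model.factors[0])
        f.create_dataset("U2", data=model.factors[1])
        f.create_dataset("objective_trace", data=np.asarray(model.objective_trace))
        f.attrs["structure"] = model.structure.value
        f.attrs["orthonormal"] = model.orthonormal
        f.attrs["method_tag"] = model.method_tag


def load_model(path: str | Path) -> ProjectionModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model not found: {path}")
    with h5py.File(path, "r") as f:
        for key in ("U1", "U2"):
            if key not in f:
                raise SchemaError(f"{path}: missing dataset '/{key}'")
        return ProjectionModel(
            factors=[np.asarray(f["U1"]), np.asarray(f["U2"])],
            structure=Structure(f.attrs.get("structure", "tucker")),
            orthonormal=bool(f.attrs.get("orthonormal", False)),
            objective_trace=np.asarray(f.get("objective_trace", np.empty(0))),
            method_tag=str(f.attrs.get("method_tag", "")),
        )


def save_bdca_model(model: BdcaModel, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("U1", data=model.U1)
        f.create_dataset("U2", data=model.U2)
        if model.V is not None:
            f.create_dataset("V", data=model.V)
        f.attrs["w0"] = model.w0
        f.attrs["structure"] = model.structure.value


def load_bdca_model(path: str | Path) -> BdcaModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model not found: {path}")
    with h5py.File(path, "r") as f:
        return BdcaModel(
            U1=np.asarray(f["U1"]),
            U2=np.asarray(f["U2"]),
            V=np.asarray(f["V"]) if "V" in f else None,
            w0=float(f.attrs["w0"]),
            structure=Structure(f.attrs["structure"]),
        )
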