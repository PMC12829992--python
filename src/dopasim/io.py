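"""Snapshot and trace output helpers (HDF5 fields, CSV traces)."""

from __future__ import annotations

import hashlib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "save_field",
    "load_field",
    "save_trace",
    "save_sites",
    "file_sha256",
]


def save_field(path, values: np.ndarray, voxel_size: float, time: float = 0.0):
    """Write a 3-D concentration snapshot to HDF5.

    Dataset ``concentration`` (nM) with ``voxel_size`` (µm) and ``time``
    (s) attributes.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("concentration", data=np.asarray(values),
                              compression="gzip", compression_opts=4)
        ds.attrs["voxel_size"] = voxel_size
        ds.attrs["time"] = time


def load_field(path):
    """Read a snapshot back; returns ``(values, voxel_size, time)``."""
    with h5py.File(path, "r") as f:
        ds = f["concentration"]
        return ds[...], float(ds.attrs["voxel_size"]), float(ds.attrs["time"])


def save_trace(path, columns: dict):
    """Write named, aligned 1-D traces (e.g. time, value) to CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(columns).to_csv(path, index=False, float_format="%.10g")


def save_sites(path, sites):
    """Write a release-site map to CSV (x, y, z, neuron, active)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sites.to_dataframe().to_csv(path, index=False)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
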