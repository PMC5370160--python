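"""Trace readers and writers: CSV (one trace per column), HDF5 (2-D
dataset, traces x time) and raw binary arrays."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import FluorescenceTrace

__all__ = ["load_traces", "load_csv", "load_hdf5", "load_raw",
           "save_result_csv", "save_results_hdf5"]


def load_csv(path, frame_rate: float = 30.0) -> list:
    """One trace per column; a header row is detected automatically."""
    df = pd.read_csv(path, header=None)
    if df.iloc[0].apply(lambda x: isinstance(x, str)).any():
        df = pd.read_csv(path)
    return [FluorescenceTrace(df[col].to_numpy(dtype=float), frame_rate)
            for col in df.columns]


def load_hdf5(path, dataset: str = "traces", frame_rate: float = 30.0) -> list:
    """2-D dataset (traces x time); frame rate read from an attribute if
    present."""
    with h5py.File(path, "r") as f:
        if dataset not in f:
            raise KeyError(f"dataset {dataset!r} not in {path}")
        arr = np.atleast_2d(f[dataset][()])
        frame_rate = float(f[dataset].attrs.get("frame_rate", frame_rate))
    return [FluorescenceTrace(row, frame_rate) for row in arr]


def load_raw(path, dtype="float64", n_traces: int = 1,
             frame_rate: float = 30.0) -> list:
    """Flat binary array reshaped to (n_traces, T)."""
    arr = np.fromfile(path, dtype=dtype).astype(float)
    if arr.size % n_traces:
        raise ValueError("file size is not a multiple of n_traces")
    return [FluorescenceTrace(row, frame_rate)
            for row in arr.reshape(n_traces, -1)]


def load_traces(path, frame_rate: float = 30.0, **kwargs) -> list:
    """Dispatch on file extension (.csv, .h5/.hdf5, else raw binary)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return load_csv(path, frame_rate)
    if suffix in (".h5", ".hdf5"):
        return load_hdf5(path, frame_rate=frame_rate, **kwargs)
    return load_raw(path, frame_rate=frame_rate, **kwargs)


def save_result_csv(path, y, c, s):
    """Write input and inferred traces side by side (columns y, c, s)."""
    pd.DataFrame({"y": np.asarray(y), "c": np.asarray(c),
                  "s": np.asarray(s)}).to_csv(path, index=False)


def save_results_hdf5(path, results, traces=None):
    """Write per-trace groups with datasets y (optional), c and s."""
    with h5py.File(path, "w") as f:
        for i, res in enumerate(results):
            grp = f.create_group(f"trace_{i:04d}")
            if traces is not None:
                grp.create_dataset("y", data=np.asarray(traces[i].values))
            if res.c is not None:
                grp.create_dataset("c", data=res.c)
                grp.create_dataset("s", data=res.s)
            for key, val in res.diagnostics.items():
                grp.attrs[f"diag_{key}"] = str(val)
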