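"""Readers and writers for signals, comodulograms, features, and reports.

Native formats are plain delimited text (portable, diff-able) plus an
optional ``.npy`` columnar binary for large arrays.  Every written bundle
carries a JSON sidecar with the configuration and seeds that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .comodulogram import ComodulogramGrid
from .core import BandSpec, TimeSeries
from .decoding import FeatureMatrix

__all__ = [
    "read_signal",
    "write_signal",
    "write_comodulogram",
    "read_comodulogram",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_report",
]

_REL_TOL = 1e-6


def read_signal(path: str | Path, fs: float | None = None) -> TimeSeries:
    """Read a signal from delimited text or a ``.npy`` array.

    Delimited text may be two-column ``time,value`` (sampling rate is
    inferred from the uniform time column) or multi-column with a channel
    -name header (``fs`` must then be given, unless a ``time`` column is
    present).  Non-uniform time axes are rejected.
    """
    path = Path(path)
    if path.suffix == ".npy":
        if fs is None:
            raise ValueError("fs is required for .npy input")
        return TimeSeries(np.load(path), fs)
    df = pd.read_csv(path, sep=None, engine="python")
    cols = [str(c) for c in df.columns]
    time_col = next((c for c in cols if c.lower() in ("time", "t", "seconds")), None)
    if time_col is None and fs is None:
        # headerless two-column file: first column is time
        df = pd.read_csv(path, sep=None, engine="python", header=None)
        if df.shape[1] != 2:
            raise ValueError("cannot infer sampling rate: provide fs or a time column")
        df.columns = ["time", "value"]
        time_col = "time"
        cols = ["time", "value"]
    if time_col is not None:
        t = df[time_col].to_numpy(dtype=float)
        dt = np.diff(t)
        if t.size < 2 or dt.min() <= 0:
            raise ValueError("time column must be strictly increasing")
        if (dt.max() - dt.min()) > _REL_TOL * dt.mean():
            raise ValueError("non-uniform time column: cannot attach a sampling rate")
        inferred = 1.0 / dt.mean()
        if fs is not None and abs(inferred - fs) > _REL_TOL * fs:
            raise ValueError(f"time column implies fs={inferred:g}, conflicting with fs={fs:g}")
        fs = inferred if fs is None else fs
        df = df.drop(columns=[time_col])
        cols = [c for c in cols if c != time_col]
    assert fs is not None
    data = df.to_numpy(dtype=float)
    if data.shape[1] == 1:
        return TimeSeries(data[:, 0], fs)
    return TimeSeries(data.T, fs, channel_names=tuple(cols))


def write_signal(ts: TimeSeries, path: str | Path, include_time: bool = True) -> None:
    """Write a signal as delimited text (CSV)."""
    path = Path(path)
    if ts.values.ndim == 1:
        df = pd.DataFrame({"value": ts.values})
    else:
        names = ts.channel_names or tuple(f"ch{i}" for i in range(ts.n_channels))
        df = pd.DataFrame(ts.values.T, columns=list(names))
    if include_time:
        df.insert(0, "time", ts.times)
    df.to_csv(path, index=False, float_format="%.12g")


def _band_to_list(b: BandSpec) -> list[float]:
    return [b.low, b.high]


def write_comodulogram(grid: ComodulogramGrid, path: str | Path) -> None:
    """Write a coupling map as delimited text plus a JSON sidecar.

    The text table carries band-edge headers: columns are amplitude bands,
    rows phase bands.  The sidecar records the estimator name and grids.
    """
    path = Path(path)
    col_labels = [f"{b.low:g}-{b.high:g}" for b in grid.amp_bands]
    row_labels = [f"{b.low:g}-{b.high:g}" for b in grid.phase_bands]
    df = pd.DataFrame(grid.values, index=row_labels, columns=col_labels)
    df.index.name = "phase_band\\amp_band"
    df.to_csv(path, float_format="%.12g")
    sidecar = {
        "method": grid.method,
        "phase_bands": [_band_to_list(b) for b in grid.phase_bands],
        "amp_bands": [_band_to_list(b) for b in grid.amp_bands],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_comodulogram(path: str | Path) -> ComodulogramGrid:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ComodulogramGrid(
        tuple(BandSpec(lo, hi) for lo, hi in sidecar["phase_bands"]),
        tuple(BandSpec(lo, hi) for lo, hi in sidecar["amp_bands"]),
        df.to_numpy(dtype=float),
        sidecar["method"],
    )


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """Feature matrix as CSV: feature-name header plus a label column."""
    df = pd.DataFrame(fm.values, columns=list(fm.feature_names))
    df["label"] = fm.labels
    df.to_csv(path, index=False, float_format="%.12g")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError("feature file must contain a 'label' column")
    labels = df.pop("label").to_numpy()
    return FeatureMatrix(df.to_numpy(dtype=float), tuple(df.columns), labels)


def write_report(results: dict, path: str | Path) -> None:
    """Write a results dictionary as JSON (arrays converted to lists)."""

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"unserializable object of type {type(obj)}")

    Path(path).write_text(json.dumps(results, indent=2, default=_default))
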