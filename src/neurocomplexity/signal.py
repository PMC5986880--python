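"""Sampled-signal containers and plain-text I/O.

Two containers carry every signal in the package: :class:`TimeSeries` for a
single channel and :class:`NodeTimeSeriesSet` for a nodes-by-time panel with
optional module labels.  Both are thin, validated wrappers around NumPy
arrays; analysis code receives and returns them rather than bare arrays so
that the sampling rate travels with the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TimeSeries", "NodeTimeSeriesSet", "read_node_table", "write_node_table"]


@dataclass(frozen=True)
class TimeSeries:
    """A single uniformly sampled real-valued signal.

    Parameters
    ----------
    values : array-like of float
        Ordered samples.  Must be finite and non-empty.
    fs : float
        Sampling rate in Hz, finite and positive.
    label : str, optional
        Free-text channel label.
    """

    values: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("TimeSeries requires a non-empty 1-D sample array")
        if not np.all(np.isfinite(v)):
            raise ValueError("TimeSeries samples must be finite")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"sampling rate must be finite and positive, got {self.fs}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Length of the record in seconds."""
        return len(self) / self.fs

    def sd(self) -> float:
        """Population standard deviation (divide by N)."""
        return float(np.std(self.values))


@dataclass(frozen=True)
class NodeTimeSeriesSet:
    """A nodes-by-time panel of signals sharing one sampling rate.

    ``data`` has shape ``(n_nodes, n_samples)``.  ``modules`` assigns each
    node to exactly one labeled group (a single group by default).
    """

    data: np.ndarray
    fs: float
    names: tuple[str, ...] = ()
    modules: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=np.float64)
        if d.ndim != 2 or d.shape[1] < 1:
            raise ValueError("data must be a 2-D (n_nodes, n_samples) array")
        if not np.all(np.isfinite(d)):
            raise ValueError("node signals must be finite")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"sampling rate must be finite and positive, got {self.fs}")
        names = tuple(self.names) or tuple(f"node{i}" for i in range(d.shape[0]))
        modules = tuple(self.modules) or ("M0",) * d.shape[0]
        if len(names) != d.shape[0] or len(modules) != d.shape[0]:
            raise ValueError("names/modules length must equal the node count")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "fs", float(self.fs))
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "modules", modules)

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def node(self, i: int) -> TimeSeries:
        """Extract one node as a :class:`TimeSeries`."""
        return TimeSeries(self.data[i], self.fs, label=self.names[i])

    def module_indices(self, label: str) -> np.ndarray:
        """Indices of the nodes belonging to one module."""
        idx = np.flatnonzero(np.asarray(self.modules) == label)
        if idx.size == 0:
            raise KeyError(f"no nodes in module {label!r}")
        return idx

    @property
    def module_labels(self) -> tuple[str, ...]:
        """Distinct module labels in first-appearance order."""
        seen: dict[str, None] = {}
        for m in self.modules:
            seen.setdefault(m, None)
        return tuple(seen)


def write_node_table(ts: NodeTimeSeriesSet, path: str | Path, sidecar: bool = True) -> None:
    """Write a node set as delimited text (one column per node, header row).

    A JSON sidecar ``<path>.json`` records the sampling rate and module
    labels so the table round-trips losslessly.
    """
    path = Path(path)
    df = pd.DataFrame(ts.data.T, columns=list(ts.names))
    df.to_csv(path, index=False)
    if sidecar:
        meta = {"fs": ts.fs, "names": list(ts.names), "modules": list(ts.modules)}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_node_table(path: str | Path, fs: float | None = None) -> NodeTimeSeriesSet:
    """Read a delimited node-by-time table written by :func:`write_node_table`.

    ``fs`` overrides the sidecar value; one of the two must be available.
    """
    path = Path(path)
    df = pd.read_csv(path)
    modules: tuple[str, ...] = ()
    side = Path(str(path) + ".json")
    if side.exists():
        meta = json.loads(side.read_text())
        fs = fs if fs is not None else meta.get("fs")
        modules = tuple(meta.get("modules", ()))
    if fs is None:
        raise ValueError("sampling rate not given and no JSON sidecar found")
    return NodeTimeSeriesSet(df.to_numpy().T, fs=fs, names=tuple(df.columns), modules=modules)
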