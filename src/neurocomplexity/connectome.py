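"""Weighted structural connectomes with a module partition."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["StructuralConnectome", "load_connectome"]


@dataclass(frozen=True)
class StructuralConnectome:
    """An n-by-n non-negative coupling matrix with labeled node groups.

    ``weights[i, j]`` is the strength of the projection from node ``j`` onto
    node ``i``; the diagonal is zero.  Every node belongs to exactly one
    module (a single module when no partition is given).
    """

    weights: np.ndarray
    modules: tuple[str, ...] = ()
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            bad = np.argwhere(~np.isfinite(w))[0]
            raise ValueError(f"non-finite weight at row {bad[0]}, column {bad[1]}")
        if np.any(w < 0):
            bad = np.argwhere(w < 0)[0]
            raise ValueError(f"negative weight at row {bad[0]}, column {bad[1]}")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero (no self-coupling)")
        n = w.shape[0]
        names = tuple(self.names) or tuple(f"node{i}" for i in range(n))
        modules = tuple(self.modules) or ("M0",) * n
        if len(names) != n or len(modules) != n:
            raise ValueError("names/modules length must equal the node count")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "modules", modules)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def module_labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for m in self.modules:
            seen.setdefault(m, None)
        return tuple(seen)

    def row_normalized(self) -> np.ndarray:
        """Weights scaled to unit in-strength per row (zero rows left zero)."""
        s = self.weights.sum(axis=1, keepdims=True)
        out = np.divide(self.weights, s, out=np.zeros_like(self.weights), where=s > 0)
        return out


def load_connectome(
    path: str | Path, module_labels: str | Path | None = None
) -> StructuralConnectome:
    """Read a connectome from a delimited numeric matrix file.

    ``module_labels``, if given, is a two-column ``node,label`` file (no
    header) assigning every node to a module; otherwise all nodes share one
    module.  Non-square matrices, negative entries and NaNs are format
    errors reported with their location.
    """
    path = Path(path)
    try:
        mat = pd.read_csv(path, header=None, sep=None, engine="python").to_numpy(
            dtype=np.float64
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: cannot parse numeric matrix: {exc}") from exc
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: matrix is {mat.shape[0]}x{mat.shape[1]}, not square")
    modules: tuple[str, ...] = ()
    names: tuple[str, ...] = ()
    if module_labels is not None:
        lab = pd.read_csv(module_labels, header=None)
        if len(lab) != mat.shape[0]:
            raise ValueError(
                f"{module_labels}: {len(lab)} labels for {mat.shape[0]} nodes"
            )
        names = tuple(str(x) for x in lab.iloc[:, 0])
        modules = tuple(str(x) for x in lab.iloc[:, 1])
    return StructuralConnectome(mat, modules=modules, names=names)
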