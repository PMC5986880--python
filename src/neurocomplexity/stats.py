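"""Functional connectivity and association statistics.

Functional connectivity (FC) here is zero-lag Pearson correlation between
nodal activity time courses — the whole-network summary is the mean of the
upper-triangle off-diagonal entries.  Association between complexity and
connectivity summaries across runs or subjects is quantified by Pearson
correlation with a t-based two-sided p-value, by partial correlation
controlling a grouping factor (group-mean removal with degrees of freedom
``N - n_groups - 1``), and by competing linear and quadratic least-squares
fits adjudicated with a nested-model F-test at alpha = 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .signal import NodeTimeSeriesSet

__all__ = [
    "FCMatrix",
    "AssociationResult",
    "fc_matrix",
    "mean_fc",
    "seed_fc",
    "pearson_with_p",
    "partial_correlation",
    "fit_linear_quadratic",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric matrix of pairwise Pearson correlations between nodes.

    Rows/columns of zero-variance nodes are NaN and listed in
    ``undefined_nodes``.
    """

    values: np.ndarray
    names: tuple[str, ...] = ()
    modules: tuple[str, ...] = ()
    undefined_nodes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T], atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        if np.any(np.abs(v[finite]) > 1 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")
        n = v.shape[0]
        names = tuple(self.names) or tuple(f"node{i}" for i in range(n))
        modules = tuple(self.modules) or ("M0",) * n
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "modules", modules)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def module_indices(self, label: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.modules) == label)
        if idx.size == 0:
            raise KeyError(f"no nodes in module {label!r}")
        return idx


@dataclass(frozen=True)
class AssociationResult:
    """Correlation and linear/quadratic fit summary for one x-y pairing.

    ``linear_fit`` is ``(intercept, slope)``; ``quad_fit`` is
    ``(intercept, slope, curvature)``.  ``quad_better`` is True iff the
    quadratic term is significant by the nested-model F-test at alpha=0.05.
    """

    r: float
    p: float
    linear_fit: tuple[float, float] = (np.nan, np.nan)
    quad_fit: tuple[float, float, float] = (np.nan, np.nan, np.nan)
    quad_better: bool = False
    f_stat: float = np.nan
    f_p: float = np.nan


def fc_matrix(ts: NodeTimeSeriesSet) -> FCMatrix:
    """Pairwise Pearson correlation matrix of a node panel.

    Requires at least 3 time points.  Zero-variance nodes are flagged and
    their rows/columns set to NaN (diagonal kept at 1).
    """
    if ts.n_samples < 3:
        raise ValueError(f"need >= 3 time points, got {ts.n_samples}")
    sd = ts.data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(ts.data)
    c = np.clip(c, -1.0, 1.0)
    if dead.size:
        logger.warning("zero-variance nodes flagged in FC matrix: %s", dead.tolist())
        c[dead, :] = np.nan
        c[:, dead] = np.nan
    np.fill_diagonal(c, 1.0)
    return FCMatrix(c, names=ts.names, modules=ts.modules, undefined_nodes=tuple(dead))


def mean_fc(fc: FCMatrix, node_subset=None) -> float:
    """Mean off-diagonal correlation over a node subset (default: all nodes)."""
    idx = np.arange(fc.n_nodes) if node_subset is None else np.asarray(node_subset)
    if idx.size < 2:
        raise ValueError("node subset must contain at least 2 nodes")
    sub = fc.values[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(np.nanmean(sub[iu]))


def seed_fc(ts: NodeTimeSeriesSet, seed_nodes) -> np.ndarray:
    """Correlation of every node with the mean series of a seed subset."""
    seed_idx = np.asarray(seed_nodes)
    if seed_idx.size == 0:
        raise ValueError("seed subset must be non-empty")
    if ts.n_samples < 3:
        raise ValueError(f"need >= 3 time points, got {ts.n_samples}")
    seed = ts.data[seed_idx].mean(axis=0)
    out = np.empty(ts.n_nodes)
    for i in range(ts.n_nodes):
        out[i] = pearson_with_p(seed, ts.data[i])[0]
    return out


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-transform p-value (df = n - 2).

    Returns ``(nan, nan)`` when either input has zero variance.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return (float("nan"), float("nan"))
    res = sps.pearsonr(x, y)
    return (float(res.statistic), float(res.pvalue))


def partial_correlation(x, y, group) -> tuple[float, float]:
    """Correlation of x and y after removing group means.

    Controls a categorical factor (e.g. repeated measures per animal) by
    residualizing both variables on the group indicator — equivalent to
    dummy-coded least squares — then correlating the residuals, with the
    p-value computed at ``df = N - n_groups - 1``.  Groups with a single
    observation are dropped with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    g = np.asarray(group)
    if not (x.shape == y.shape == g.shape):
        raise ValueError("x, y and group must have equal length")
    labels, counts = np.unique(g, return_counts=True)
    singletons = labels[counts < 2]
    if singletons.size:
        logger.warning("dropping singleton group(s): %s", singletons.tolist())
        keep = ~np.isin(g, singletons)
        x, y, g = x[keep], y[keep], g[keep]
        labels = labels[counts >= 2]
    n = x.size
    k = labels.size
    df = n - k - 1
    if k == 0 or df < 1:
        raise ValueError(f"insufficient residual degrees of freedom (n={n}, groups={k})")
    rx = x.copy()
    ry = y.copy()
    for lab in labels:
        m = g == lab
        rx[m] -= rx[m].mean()
        ry[m] -= ry[m].mean()
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return (float("nan"), float("nan"))
    r = float(np.dot(rx, ry) / (n * sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return (r, 0.0)
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return (r, p)


def fit_linear_quadratic(x, y) -> AssociationResult:
    """Least-squares linear and quadratic fits with a nested F-test.

    ``quad_better`` is True iff adding the quadratic term significantly
    reduces residual variance (F-test, alpha = 0.05).  Requires >= 4 points
    and a full-rank quadratic design.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need >= 4 equal-length points for the quadratic fit")
    design_q = np.column_stack([np.ones_like(x), x, x * x])
    if np.linalg.matrix_rank(design_q) < 3:
        raise ValueError("rank-deficient design: x values do not span a quadratic")
    lin = sm.OLS(y, design_q[:, :2]).fit()
    quad = sm.OLS(y, design_q).fit()
    anova = sm.stats.anova_lm(lin, quad)
    f_stat = float(anova["F"].iloc[1])
    f_p = float(anova["Pr(>F)"].iloc[1])
    if not np.isfinite(f_stat):  # perfect quadratic interpolation: RSS_quad == 0
        f_p = 0.0 if quad.ssr < lin.ssr else 1.0
    r, p = pearson_with_p(x, y)
    return AssociationResult(
        r=r,
        p=p,
        linear_fit=tuple(lin.params),
        quad_fit=tuple(quad.params),
        quad_better=bool(f_p < 0.05),
        f_stat=f_stat,
        f_p=f_p,
    )
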