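"""Experimental-stage analysis procedures.

Covers the signal conditioning used on concurrently recorded
electrophysiology (scanner-artifact scrubbing of local field potentials) and
on multi-subject fMRI node series (confound regression, band-pass), plus the
across-subject analyses relating nodal/network multi-scale entropy to
functional connectivity.

LFP scrubbing follows the two-pass interpolation scheme used for
MR-contaminated recordings: each fixed-length segment after a slice trigger
is first bridged linearly endpoint-to-endpoint, then re-estimated by a cubic
spline fitted on short flanking windows, and the trace is finally low-pass
filtered and down-sampled.  Down-sampling always applies an anti-alias
low-pass at 0.4 x the target rate first.

The cohort analyses compute, per subject and session, each node's MSE curve
and mean connectivity to the rest of the network, average over sessions, and
then correlate the two across subjects per node and scale (or at the
network level using the mean over all node pairs and all nodes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal as spsig

from .entropy import EntropyParams, mse_curve
from .frequency import scale_to_frequency  # re-exported; part of this stage's surface
from .signal import NodeTimeSeriesSet, TimeSeries
from .stats import fc_matrix, pearson_with_p

__all__ = [
    "SubjectNodeData",
    "CohortAssociation",
    "scale_to_frequency",
    "clean_lfp",
    "regress_confounds",
    "bandpass",
    "subject_summaries",
    "nodal_mse_fc_correlation",
    "network_mse_fc_correlation",
    "voxelwise_mse_maps",
    "roi_series",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubjectNodeData:
    """One subject's sessions of node time series over a common node set."""

    subject: str
    sessions: tuple[NodeTimeSeriesSet, ...]

    def __post_init__(self) -> None:
        if not self.sessions:
            raise ValueError("subject must have at least one session")
        names = self.sessions[0].names
        for s in self.sessions[1:]:
            if s.names != names:
                raise ValueError(f"sessions of {self.subject!r} have differing node sets")
        object.__setattr__(self, "sessions", tuple(self.sessions))

    @property
    def names(self) -> tuple[str, ...]:
        return self.sessions[0].names


@dataclass(frozen=True)
class CohortAssociation:
    """Across-subject correlation of MSE with FC, per scale (and node).

    ``r``/``p`` have shape ``(n_scales,)`` for network-level results or
    ``(n_nodes, n_scales)`` for nodal results.
    """

    scales: np.ndarray
    r: np.ndarray
    p: np.ndarray
    fs: float
    names: tuple[str, ...] = ()
    convention: str = "nyquist"

    @property
    def significant(self) -> np.ndarray:
        """Mask of correlations with p < 0.05."""
        return self.p < 0.05

    def frequencies(self) -> np.ndarray:
        return scale_to_frequency(self.scales, self.fs, self.convention)


# ---------------------------------------------------------------------------
# signal conditioning


def _zero_phase_lowpass(v: np.ndarray, cutoff: float, fs: float) -> np.ndarray:
    sos = spsig.butter(4, cutoff, btype="low", fs=fs, output="sos")
    return spsig.sosfiltfilt(sos, v)


def clean_lfp(
    x: TimeSeries,
    triggers,
    artifact_ms: float = 60.0,
    context_ms: float = 35.0,
    lowpass_hz: float = 100.0,
    fs_out: float = 50.0,
) -> TimeSeries:
    """Scrub slice-trigger artifacts from an LFP trace, filter, down-sample.

    Parameters
    ----------
    x : TimeSeries
        Raw recording.
    triggers : array of float
        Artifact onset times in seconds (one per scanner slice trigger).
    artifact_ms : float
        Contaminated segment length after each trigger.
    context_ms : float
        Flank length before and after the segment used to fit the spline.
    lowpass_hz : float
        Zero-phase low-pass cutoff applied after scrubbing (skipped when at
        or above Nyquist).
    fs_out : float
        Output rate; ``x.fs`` must be an integer multiple.  An anti-alias
        low-pass at ``0.4 * fs_out`` is applied before decimation.

    Triggers whose artifact or context window falls outside the series are
    skipped with a warning.
    """
    v = x.values.copy()
    n = v.size
    na = int(round(artifact_ms * 1e-3 * x.fs))
    nc = int(round(context_ms * 1e-3 * x.fs))
    for t in np.atleast_1d(np.asarray(triggers, dtype=np.float64)):
        a0 = int(round(t * x.fs))
        a1 = a0 + na
        if a0 < nc or a1 + nc > n:
            logger.warning("trigger at %.4f s: window outside series, skipped", t)
            continue
        # pass 1: endpoint-to-endpoint linear bridge
        v[a0:a1] = np.linspace(v[a0 - 1], v[a1], na + 2)[1:-1]
        # pass 2: cubic spline through block-mean anchors spanning the flanks
        # and the bridged segment.  Anchoring on block means keeps the spline
        # well conditioned; a spline interpolating every noisy flank sample
        # oscillates across the gap with amplitude exceeding the artifact
        # being removed.
        lo, hi = a0 - nc, a1 + nc
        block = max(4, nc // 3)
        edges = np.linspace(lo, hi, (hi - lo) // block + 1).astype(int)
        anchors_i = [0.5 * (b0 + b1 - 1) for b0, b1 in zip(edges[:-1], edges[1:])]
        anchors_v = [v[b0:b1].mean() for b0, b1 in zip(edges[:-1], edges[1:])]
        cs = interpolate.CubicSpline(anchors_i, anchors_v)
        v[a0:a1] = cs(np.arange(a0, a1))
    if lowpass_hz < x.fs / 2:
        v = _zero_phase_lowpass(v, lowpass_hz, x.fs)
    factor = x.fs / fs_out
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(f"fs {x.fs} is not an integer multiple of fs_out {fs_out}")
    factor = int(round(factor))
    if factor > 1:
        v = _zero_phase_lowpass(v, 0.4 * fs_out, x.fs)
        v = v[::factor]
    return TimeSeries(v, fs=fs_out, label=x.label)


def regress_confounds(ts: NodeTimeSeriesSet, confounds) -> NodeTimeSeriesSet:
    """Residualize every node on a confound design (intercept always added).

    Raises on rank deficiency, naming the collinear column indices.
    """
    c = np.atleast_2d(np.asarray(confounds, dtype=np.float64))
    if c.shape[0] != ts.n_samples:
        if c.shape[1] == ts.n_samples:
            c = c.T
        else:
            raise ValueError(
                f"confounds have {c.shape[0]} rows for {ts.n_samples} time points"
            )
    design = np.column_stack([np.ones(ts.n_samples), c])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns whose removal restores full rank
        bad = [
            j - 1
            for j in range(1, design.shape[1])
            if np.linalg.matrix_rank(np.delete(design, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient confound design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, ts.data.T, rcond=None)
    resid = ts.data.T - design @ beta
    return NodeTimeSeriesSet(resid.T, fs=ts.fs, names=ts.names, modules=ts.modules)


def bandpass(ts, f_lo: float, f_hi: float):
    """Zero-phase order-4 Butterworth band-pass (low-pass when ``f_lo == 0``).

    Accepts a single :class:`TimeSeries` or a :class:`NodeTimeSeriesSet`
    (every node filtered identically) and returns the same type.
    """
    nyq = ts.fs / 2
    if not (0 <= f_lo < f_hi < nyq):
        raise ValueError(f"band [{f_lo}, {f_hi}] Hz invalid for Nyquist {nyq} Hz")
    if f_lo == 0:
        sos = spsig.butter(4, f_hi, btype="low", fs=ts.fs, output="sos")
    else:
        sos = spsig.butter(4, [f_lo, f_hi], btype="band", fs=ts.fs, output="sos")
    if isinstance(ts, NodeTimeSeriesSet):
        return NodeTimeSeriesSet(
            spsig.sosfiltfilt(sos, ts.data, axis=-1),
            fs=ts.fs, names=ts.names, modules=ts.modules,
        )
    return TimeSeries(spsig.sosfiltfilt(sos, ts.values), fs=ts.fs, label=ts.label)


# ---------------------------------------------------------------------------
# cohort analyses


def subject_summaries(subj: SubjectNodeData, scales, params: EntropyParams):
    """Session-averaged nodal MSE curves and nodal mean connectivity.

    Per session, every node's MSE curve and its mean Pearson correlation to
    all other nodes are computed; sessions are then averaged (not
    concatenated).  Returns ``(mse, nodal_fc)`` with shapes
    ``(n_nodes, n_scales)`` and ``(n_nodes,)``.
    """
    scales = np.asarray(scales, dtype=np.int64)
    mse_acc = []
    fc_acc = []
    for sess in subj.sessions:
        m = np.vstack(
            [mse_curve(sess.node(i), scales, params).entropy for i in range(sess.n_nodes)]
        )
        fc = fc_matrix(sess).values
        nodal = (np.nansum(fc, axis=1) - 1.0) / (sess.n_nodes - 1)
        mse_acc.append(m)
        fc_acc.append(nodal)
    return np.mean(mse_acc, axis=0), np.mean(fc_acc, axis=0)


def _check_cohort(cohort) -> tuple[str, ...]:
    if len(cohort) < 4:
        raise ValueError(f"need >= 4 subjects, got {len(cohort)}")
    names = cohort[0].names
    for s in cohort[1:]:
        if s.names != names:
            raise ValueError("subjects must share a common node set")
    return names


def nodal_mse_fc_correlation(
    cohort, scales, params: EntropyParams = EntropyParams(2, 0.5)
) -> CohortAssociation:
    """Across-subject correlation of nodal MSE with nodal mean FC.

    For every node and scale, Pearson r (and p) between the subjects'
    session-averaged MSE values and their session-averaged mean connectivity
    of that node to the rest of the network.
    """
    names = _check_cohort(cohort)
    scales = np.asarray(scales, dtype=np.int64)
    mse_all = []
    fc_all = []
    for subj in cohort:
        m, f = subject_summaries(subj, scales, params)
        mse_all.append(m)
        fc_all.append(f)
    mse_all = np.stack(mse_all)  # (n_subj, n_nodes, n_scales)
    fc_all = np.stack(fc_all)  # (n_subj, n_nodes)
    n_nodes, n_scales = mse_all.shape[1:]
    r = np.full((n_nodes, n_scales), np.nan)
    p = np.full((n_nodes, n_scales), np.nan)
    for i in range(n_nodes):
        for k in range(n_scales):
            col = mse_all[:, i, k]
            if np.all(np.isfinite(col)):
                r[i, k], p[i, k] = pearson_with_p(col, fc_all[:, i])
    fs = cohort[0].sessions[0].fs
    return CohortAssociation(scales, r, p, fs=fs, names=names)


def network_mse_fc_correlation(
    cohort, scales, params: EntropyParams = EntropyParams(2, 0.5)
) -> CohortAssociation:
    """Across-subject correlation of overall network MSE with overall FC.

    Subject-level summaries are the mean over all nodes' MSE (per scale) and
    the mean over all node-to-node connections; the two are correlated
    across subjects at every scale.
    """
    names = _check_cohort(cohort)
    if len(names) < 2:
        raise ValueError("network-level analysis needs >= 2 nodes (no connections otherwise)")
    scales = np.asarray(scales, dtype=np.int64)
    mse_net = []
    fc_net = []
    for subj in cohort:
        m, f = subject_summaries(subj, scales, params)
        mse_net.append(np.nanmean(m, axis=0))
        # mean over all distinct pairs equals mean of nodal means
        fc_net.append(float(np.mean(f)))
    mse_net = np.stack(mse_net)
    fc_net = np.asarray(fc_net)
    n_scales = scales.size
    r = np.full(n_scales, np.nan)
    p = np.full(n_scales, np.nan)
    for k in range(n_scales):
        col = mse_net[:, k]
        if np.all(np.isfinite(col)):
            r[k], p[k] = pearson_with_p(col, fc_net)
    fs = cohort[0].sessions[0].fs
    return CohortAssociation(scales, r, p, fs=fs, names=names)


# ---------------------------------------------------------------------------
# volumetric helpers (4-D NIfTI in, per-scale 3-D maps out)


def voxelwise_mse_maps(img, mask, scales, params: EntropyParams, tr: float | None = None):
    """Per-scale MSE maps from a 4-D NIfTI image within a 3-D mask.

    ``img``/``mask`` are nibabel images (or paths).  Returns a list of 3-D
    arrays, one per scale, NaN outside the mask.
    """
    import nibabel as nib

    img = nib.load(img) if isinstance(img, str) else img
    mask_img = nib.load(mask) if isinstance(mask, str) else mask
    data = np.asarray(img.dataobj, dtype=np.float64)
    m = np.asarray(mask_img.dataobj).astype(bool)
    if data.ndim != 4:
        raise ValueError("expected a 4-D image")
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    fs = 1.0 / tr
    scales = np.asarray(scales, dtype=np.int64)
    vox = data[m]  # (n_voxels, T)
    coords = np.argwhere(m)
    maps = [np.full(m.shape, np.nan) for _ in scales]
    for v_idx in range(vox.shape[0]):
        curve = mse_curve(TimeSeries(vox[v_idx], fs=fs), scales, params)
        for k in range(scales.size):
            maps[k][tuple(coords[v_idx])] = curve.entropy[k]
    return maps


def roi_series(img, mask, tr: float | None = None) -> TimeSeries:
    """Mean time course over a 3-D mask of a 4-D image."""
    import nibabel as nib

    img = nib.load(img) if isinstance(img, str) else img
    mask_img = nib.load(mask) if isinstance(mask, str) else mask
    data = np.asarray(img.dataobj, dtype=np.float64)
    m = np.asarray(mask_img.dataobj).astype(bool)
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    return TimeSeries(data[m].mean(axis=0), fs=1.0 / tr, label="roi")
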