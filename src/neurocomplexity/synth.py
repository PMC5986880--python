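"""Seeded synthetic-data generators.

Everything the analysis stages consume can be generated here: modular
structural connectomes standing in for anatomical matrices, calibrated
white/1/f reference noise, LFP-like traces with injected scanner artifacts
(plus their clean ground truth), hemodynamically smoothed BOLD-like panels,
and multi-subject cohorts whose low-frequency structure is shared across
nodes while high-frequency structure is node-local.

The cohort generator is the statistical model behind the human-stage
analyses: each subject draws a factor ``g`` that simultaneously raises the
amplitude of the shared slow component and lowers the amplitude of the local
fast components.  Subjects with larger ``g`` therefore have higher
functional connectivity, higher coarse-scale entropy (richer slow shared
structure relative to the matching tolerance), and lower fine-scale entropy
— inducing, by construction, a positive across-subject MSE-FC correlation
at coarse scales and a negative one at the finest scales.  All generators
are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd

from .connectome import StructuralConnectome
from .imaging import SubjectNodeData
from .signal import NodeTimeSeriesSet, TimeSeries

__all__ = [
    "CohortSpec",
    "gen_modular_connectome",
    "gen_colored_noise",
    "gen_lfp_with_artifacts",
    "gen_bold_like",
    "gen_coupled_cohort",
    "default_hrf_kernel",
]


def gen_modular_connectome(
    n_nodes: int = 47,
    n_modules: int = 5,
    p_within: float = 0.8,
    p_between: float = 0.1,
    weight_scale: float = 1.0,
    seed: int = 0,
) -> StructuralConnectome:
    """Random modular connectome: dense within modules, sparse between.

    Edges are drawn Bernoulli (``p_within`` inside a module, ``p_between``
    across modules) on the upper triangle, mirrored to an undirected matrix,
    then given uniform weights in ``(0.5, 1.5) * weight_scale``.  Modules
    are near-equal contiguous blocks labeled ``M1..Mk``.  The default preset
    (47 nodes, 5 modules) mimics the scale and modular organization of the
    macaque anatomical matrix used in the simulation study.
    """
    if not (0 <= p_between < p_within <= 1):
        raise ValueError("need 0 <= p_between < p_within <= 1")
    if not (1 <= n_modules <= n_nodes):
        raise ValueError("need 1 <= n_modules <= n_nodes")
    rng = np.random.default_rng(seed)
    sizes = np.full(n_modules, n_nodes // n_modules)
    sizes[: n_nodes % n_modules] += 1
    labels = np.repeat([f"M{i + 1}" for i in range(n_modules)], sizes)
    same = labels[:, None] == labels[None, :]
    p = np.where(same, p_within, p_between)
    iu = np.triu_indices(n_nodes, k=1)
    adj = np.zeros((n_nodes, n_nodes))
    edges = rng.random(iu[0].size) < p[iu]
    w = rng.uniform(0.5, 1.5, size=iu[0].size) * weight_scale
    adj[iu] = edges * w
    adj = adj + adj.T
    return StructuralConnectome(adj, modules=tuple(labels))


def gen_colored_noise(
    exponent: float, length: int, fs: float = 1.0, seed: int = 0
) -> TimeSeries:
    """Unit-variance Gaussian noise with power spectrum proportional to 1/f^n.

    Spectral shaping is done by frequency-domain amplitude scaling of seeded
    white noise (exact and deterministic); the DC component is zeroed and
    the output standardized to zero mean, unit SD.  ``exponent = 0`` gives
    white noise, ``exponent = 1`` pink noise.
    """
    if exponent < 0:
        raise ValueError("spectral exponent must be >= 0")
    if length < 16:
        raise ValueError("length must be >= 16")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(length)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(length, d=1.0 / fs)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * amp, n=length)
    x = (x - x.mean()) / x.std()
    return TimeSeries(x, fs=fs, label=f"1/f^{exponent:g}")


def gen_lfp_with_artifacts(
    base: TimeSeries,
    trigger_period_s: float,
    artifact_ms: float = 60.0,
    amplitude: float = 5.0,
    seed: int = 0,
):
    """Inject high-amplitude fast-changing segments after periodic triggers.

    Emulates MR slice-trigger contamination of an LFP recording: every
    ``trigger_period_s`` a segment of ``artifact_ms`` is overwritten by
    sign-alternating uniform noise of the given amplitude (volts-scale
    against a unit-scale base).  Returns ``(contaminated, triggers,
    ground_truth)`` where ``ground_truth`` is the untouched base signal, for
    oracle testing of the cleaning procedure.
    """
    if amplitude <= 0:
        raise ValueError("artifact amplitude must be positive")
    if trigger_period_s <= artifact_ms * 1e-3:
        raise ValueError("trigger period must exceed the artifact duration")
    rng = np.random.default_rng(seed)
    v = base.values.copy()
    na = int(round(artifact_ms * 1e-3 * base.fs))
    first = trigger_period_s  # leave a clean lead-in
    triggers = np.arange(first, base.duration - artifact_ms * 1e-3, trigger_period_s)
    for t in triggers:
        a0 = int(round(t * base.fs))
        seg = rng.uniform(0.2, 1.0, size=na) * amplitude
        seg *= (-1.0) ** np.arange(na)  # fast alternating polarity
        v[a0 : a0 + na] = seg
    return TimeSeries(v, fs=base.fs, label=base.label), triggers, base


def default_hrf_kernel(fs: float) -> np.ndarray:
    """The versioned double-gamma hemodynamic kernel resampled to ``fs``."""
    text = resources.files("neurocomplexity.data").joinpath(
        "hrf_double_gamma_10hz.csv"
    ).read_text()
    tab = pd.read_csv(StringIO(text), comment="#")
    t_out = np.arange(0, tab["time_s"].iloc[-1] + 1e-9, 1.0 / fs)
    h = np.interp(t_out, tab["time_s"], tab["amplitude"])
    return h / h.sum()


def gen_bold_like(
    neural: NodeTimeSeriesSet, tr: float, hrf_kernel: np.ndarray | None = None
) -> NodeTimeSeriesSet:
    """Hemodynamically smooth a neural panel and sample it at one per TR.

    Each node is convolved with the kernel (default: the package's
    double-gamma kernel resampled to the input rate) and decimated to
    ``1/tr`` Hz.  ``tr`` must be an integer multiple of the input sample
    spacing.
    """
    if tr < 1.0 / neural.fs:
        raise ValueError("TR must be at least one input sample interval")
    kernel = default_hrf_kernel(neural.fs) if hrf_kernel is None else np.asarray(hrf_kernel)
    if kernel.size > neural.n_samples:
        raise ValueError("kernel longer than the input series")
    factor = tr * neural.fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"TR {tr} is not an integer multiple of 1/fs")
    factor = int(round(factor))
    conv = np.apply_along_axis(
        lambda row: np.convolve(row, kernel)[: neural.n_samples], 1, neural.data
    )
    out = conv[:, ::factor]
    return NodeTimeSeriesSet(
        out, fs=1.0 / tr, names=neural.names, modules=neural.modules
    )


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of the coupled multi-subject cohort generator.

    Defaults emulate a fast-TR resting-state cohort: 30 subjects, 20 nodes,
    TR 0.72 s, 1200 frames, a shared slow band of 0.02-0.087 Hz and local
    fast bands of 0.347-0.694 Hz.  ``coupling_strength`` in [0, 1) sets how
    strongly the per-subject factor trades shared slow amplitude against
    local fast amplitude (0 decouples complexity from connectivity).
    """

    n_subjects: int = 30
    n_nodes: int = 20
    tr: float = 0.72
    n_timepoints: int = 1200
    shared_lowfreq_band: tuple[float, float] = (0.02, 0.087)
    local_highfreq_band: tuple[float, float] = (0.347, 0.694)
    coupling_strength: float = 0.8
    noise_sd: float = 0.3
    n_sessions: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("need at least 4 subjects")
        nyq = 1.0 / (2.0 * self.tr)
        for band in (self.shared_lowfreq_band, self.local_highfreq_band):
            if not (0 < band[0] < band[1] <= nyq + 1e-9):
                raise ValueError(f"band {band} violates Nyquist {nyq:.4f} Hz at TR {self.tr}")
        if not (0 <= self.coupling_strength < 1):
            raise ValueError("coupling_strength must lie in [0, 1)")


def _band_noise(rng: np.random.Generator, n: int, fs: float, band) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited by exact spectral masking."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(spec, n=n)
    return (x - x.mean()) / x.std()


def gen_coupled_cohort(spec: CohortSpec) -> list[SubjectNodeData]:
    """Cohort whose complexity-connectivity coupling is known by construction.

    Per subject, a factor ``g ~ U(-1, 1)`` is drawn.  Every node's series is

    ``(1 + c g) * shared + (1 - c g) * local_i + noise_sd * white``

    with ``shared`` one band-limited slow component common to all nodes of a
    session, ``local_i`` an independent fast component per node, and ``c``
    the coupling strength.  Large ``g`` means more shared slow power (higher
    FC, higher coarse-scale MSE) and less local fast power (lower
    fine-scale MSE).
    """
    rng = np.random.default_rng(spec.seed)
    fs = 1.0 / spec.tr
    cohort = []
    for s in range(spec.n_subjects):
        g = rng.uniform(-1.0, 1.0)
        shared_amp = 1.0 + spec.coupling_strength * g
        local_amp = 1.0 - spec.coupling_strength * g
        sessions = []
        for _ in range(spec.n_sessions):
            shared = _band_noise(rng, spec.n_timepoints, fs, spec.shared_lowfreq_band)
            data = np.empty((spec.n_nodes, spec.n_timepoints))
            for i in range(spec.n_nodes):
                local = _band_noise(rng, spec.n_timepoints, fs, spec.local_highfreq_band)
                data[i] = (
                    shared_amp * shared
                    + local_amp * local
                    + spec.noise_sd * rng.standard_normal(spec.n_timepoints)
                )
            sessions.append(NodeTimeSeriesSet(data, fs=fs))
        cohort.append(SubjectNodeData(subject=f"sub{s:03d}", sessions=tuple(sessions)))
    return cohort
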