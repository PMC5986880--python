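"""Regularity statistics: approximate entropy, sample entropy, and
multi-scale entropy (MSE) with frequency-band averaging.

Sample entropy (SampEn) is ``-ln(A/B)`` where ``B`` counts ordered template
pairs of length ``m`` lying within Chebyshev distance ``r * sd`` of each
other (self-matches excluded) and ``A`` counts the same pairs still matching
when extended to length ``m + 1``.  Approximate entropy (ApEn) is the older
self-match-inclusive variant ``Phi(m) - Phi(m+1)``.  MSE evaluates SampEn on
successively coarse-grained (non-overlapping block-averaged) versions of the
signal, holding the matching tolerance fixed at ``r`` times the standard
deviation of the *original* series so entropy values are comparable across
scales.

White noise loses entropy as the scale grows (block averaging smooths
independent fluctuations away) while 1/f-like signals keep a roughly constant
entropy across scales; this contrast is the reason MSE separates complex
signals from mere randomness, and it is exercised directly by the test suite.

Undefined results (no template matches at the given tolerance) are reported
as NaN, never as infinity; band averages skip NaN scales and warn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .frequency import scale_to_frequency
from .signal import TimeSeries

__all__ = [
    "EntropyParams",
    "FrequencyBand",
    "MSECurve",
    "coarse_grain",
    "sample_entropy",
    "approximate_entropy",
    "mse_curve",
    "band_average_mse",
    "band_scale_masks",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EntropyParams:
    """Template length ``m`` and matching tolerance ``r``.

    ``r`` is expressed as a fraction of the standard deviation of the
    original (scale-1) series.  Conventional choices: ``m=2, r=0.2`` for
    generic physiological series; ``m=3, r=0.2`` for long low-noise records;
    ``m=2, r=0.5`` for short noisy experimental recordings.
    """

    m: int = 2
    r: float = 0.2

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 1:
            raise ValueError(f"m must be a positive integer, got {self.m}")
        if not (self.r > 0):
            raise ValueError(f"r must be positive, got {self.r}")
        object.__setattr__(self, "m", int(self.m))
        object.__setattr__(self, "r", float(self.r))


@dataclass(frozen=True)
class FrequencyBand:
    """A named frequency interval ``[f_lo, f_hi]`` in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"need 0 < f_lo < f_hi, got [{self.f_lo}, {self.f_hi}]")


#: The electrophysiological bands used throughout the simulation analyses.
#: Delta is carried both at its broad range and at a narrow high-delta range
#: whose scale count matches the other bands.
EEG_BANDS = (
    FrequencyBand("delta", 0.5, 4.0),
    FrequencyBand("delta_narrow", 2.7, 4.0),
    FrequencyBand("theta", 4.0, 7.0),
    FrequencyBand("alpha", 8.0, 15.0),
    FrequencyBand("beta", 16.0, 31.0),
    FrequencyBand("gamma", 32.0, 200.0),
)


@dataclass(frozen=True)
class MSECurve:
    """Entropy per coarse-graining scale, with parameter provenance.

    ``entropy[i]`` is the sample entropy of the scale-``scales[i]``
    coarse-grained series (NaN where undefined).  ``fs`` is the sampling
    rate of the source series, needed to map scales to frequencies.
    """

    scales: np.ndarray
    entropy: np.ndarray
    params: EntropyParams
    fs: float

    def __post_init__(self) -> None:
        s = np.asarray(self.scales, dtype=np.int64)
        e = np.asarray(self.entropy, dtype=np.float64)
        if s.ndim != 1 or e.shape != s.shape:
            raise ValueError("scales and entropy must be 1-D arrays of equal length")
        if np.any(s < 1) or np.any(np.diff(s) <= 0):
            raise ValueError("scales must be strictly increasing positive integers")
        if np.any(e[np.isfinite(e)] < -1e-12):
            raise ValueError("entropy values must be non-negative where defined")
        object.__setattr__(self, "scales", s)
        object.__setattr__(self, "entropy", e)
        object.__setattr__(self, "fs", float(self.fs))

    def frequencies(self, convention: str = "direct") -> np.ndarray:
        """Representative frequency of every scale under a convention."""
        return scale_to_frequency(self.scales, self.fs, convention)


# ---------------------------------------------------------------------------
# core estimators


def coarse_grain(x: TimeSeries, scale: int) -> TimeSeries:
    """Non-overlapping block average of ``x`` at factor ``scale``.

    Element ``j`` of the output is the mean of samples
    ``x[j*scale : (j+1)*scale]``; a trailing partial block is dropped.  The
    output sampling rate is ``x.fs / scale``.
    """
    if int(scale) != scale or scale < 1:
        raise ValueError(f"scale must be a positive integer, got {scale}")
    scale = int(scale)
    n = len(x)
    if scale > n:
        raise ValueError(f"scale {scale} exceeds series length {n}")
    nb = n // scale
    v = x.values[: nb * scale].reshape(nb, scale).mean(axis=1)
    return TimeSeries(v, fs=x.fs / scale, label=x.label)


@njit(cache=True)
def _sampen_counts(y: np.ndarray, m: int, tol: float):  # pragma: no cover - jitted
    n = y.size
    nt = n - m  # identical template count for both lengths
    b = 0
    a = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            match = True
            for k in range(m):
                if abs(y[i + k] - y[j + k]) > tol:
                    match = False
                    break
            if match:
                b += 1
                if abs(y[i + m] - y[j + m]) <= tol:
                    a += 1
    return b, a


@njit(cache=True)
def _apen_phi(y: np.ndarray, m: int, tol: float) -> float:  # pragma: no cover - jitted
    n = y.size
    nm = n - m + 1
    s = 0.0
    for i in range(nm):
        c = 0
        for j in range(nm):
            match = True
            for k in range(m):
                if abs(y[i + k] - y[j + k]) > tol:
                    match = False
                    break
            if match:
                c += 1
        s += np.log(c / nm)  # c >= 1 (self-match)
    return s / nm


def sample_entropy(
    x: TimeSeries, params: EntropyParams, sd_ref: float | None = None
) -> float:
    """Sample entropy of ``x``; NaN when no template pairs match.

    Parameters
    ----------
    x : TimeSeries
        Input signal with more than ``m + 1`` samples.
    params : EntropyParams
        Template length and relative tolerance.
    sd_ref : float, optional
        Standard deviation used to scale the tolerance.  Defaults to the
        population SD of ``x`` itself; MSE passes the SD of the original
        uncoarsened series here.

    Notes
    -----
    A constant series is defined to have entropy 0 (perfect regularity); this
    bypasses the zero-tolerance division.
    """
    m = params.m
    n = len(x)
    if n <= m + 1:
        raise ValueError(f"series length {n} too short for m={m} (need > m+1)")
    sd = x.sd()
    if sd == 0.0:
        return 0.0
    tol = params.r * (sd if sd_ref is None else float(sd_ref))
    if tol <= 0:
        raise ValueError("matching tolerance must be positive")
    b, a = _sampen_counts(np.ascontiguousarray(x.values), m, tol)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def approximate_entropy(x: TimeSeries, params: EntropyParams) -> float:
    """Approximate entropy ``Phi(m) - Phi(m+1)`` (self-matches included).

    Always finite and non-negative up to floating error; a constant series
    gives exactly 0.
    """
    m = params.m
    n = len(x)
    if n <= m + 1:
        raise ValueError(f"series length {n} too short for m={m} (need > m+1)")
    sd = x.sd()
    if sd == 0.0:
        return 0.0
    tol = params.r * sd
    y = np.ascontiguousarray(x.values)
    return float(_apen_phi(y, m, tol) - _apen_phi(y, m + 1, tol))


def mse_curve(x: TimeSeries, scales, params: EntropyParams) -> MSECurve:
    """Multi-scale entropy: SampEn of each coarse-grained series.

    The tolerance is anchored to the SD of the original series for every
    scale.  Scales too large to leave at least ``m + 2`` coarse-grained
    points are marked NaN with a logged warning rather than raising.
    """
    scales = np.asarray(scales, dtype=np.int64)
    sd0 = x.sd()
    ent = np.full(scales.shape, np.nan)
    max_ok = len(x) // (params.m + 2)
    for i, s in enumerate(scales):
        if s > max_ok:
            logger.warning(
                "scale %d exceeds length/(m+2)=%d for series %r; marked undefined",
                s, max_ok, x.label,
            )
            continue
        ent[i] = sample_entropy(coarse_grain(x, int(s)), params, sd_ref=sd0)
    return MSECurve(scales=scales, entropy=ent, params=params, fs=x.fs)


# ---------------------------------------------------------------------------
# frequency-band averaging


def band_scale_masks(
    scales,
    fs: float,
    bands,
    convention: str = "direct",
) -> dict[str, np.ndarray]:
    """Boolean scale masks per band, with a deterministic boundary rule.

    A scale belongs to band ``[f_lo, f_hi]`` iff its mapped frequency lies in
    the closed interval.  When two bands in ``bands`` share a boundary
    frequency (one band's ``f_hi`` equals another's ``f_lo``), a scale
    mapping exactly onto it is assigned to the lower-frequency band only.
    """
    scales = np.asarray(scales, dtype=np.int64)
    f = scale_to_frequency(scales, fs, convention)
    hi_edges = {b.f_hi for b in bands}
    masks: dict[str, np.ndarray] = {}
    for b in bands:
        mask = (f >= b.f_lo - 1e-12) & (f <= b.f_hi + 1e-12)
        if any(np.isclose(b.f_lo, h) for h in hi_edges if not np.isclose(h, b.f_hi)):
            # another band ends where this one starts: cede the boundary scale
            mask &= ~np.isclose(f, b.f_lo)
        masks[b.name] = mask
    return masks


def band_average_mse(
    curve: MSECurve, band: FrequencyBand, convention: str = "direct"
) -> float:
    """Unweighted mean of defined entropy values over a frequency band.

    The integer scales retained are those whose mapped frequency lies in
    ``[band.f_lo, band.f_hi]`` under the stated convention.  NaN scales are
    skipped with a warning; an empty scale set raises.
    """
    f = curve.frequencies(convention)
    mask = (f >= band.f_lo - 1e-12) & (f <= band.f_hi + 1e-12)
    if not mask.any():
        raise ValueError(
            f"band {band.name!r} [{band.f_lo}, {band.f_hi}] Hz maps to no scale of the curve"
        )
    vals = curve.entropy[mask]
    defined = np.isfinite(vals)
    if not defined.any():
        logger.warning("all entropies undefined in band %r", band.name)
        return float("nan")
    if not defined.all():
        logger.warning(
            "band %r: skipping %d undefined scale(s)", band.name, int((~defined).sum())
        )
    return float(vals[defined].mean())
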