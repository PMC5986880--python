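"""Mapping between coarse-graining scales and representative frequencies.

A coarse-graining scale ``s`` at sampling rate ``fs`` can be assigned a
representative temporal frequency under two conventions:

``direct``
    ``f(s) = fs / s`` — the sampling rate of the coarse-grained series.
``nyquist``
    ``f(s) = fs / (2 s)`` — the Nyquist frequency of the coarse-grained
    series, i.e. the highest frequency it can still represent.

The direct convention is the natural reading for broadband
electrophysiology-rate signals; the Nyquist convention is the usual one for
slow fMRI sampling, where the scale-s series is band-limited well below
``fs/s``.  The convention is always an explicit argument; nothing in the
package silently assumes one.
"""

from __future__ import annotations

import numpy as np

__all__ = ["scale_to_frequency", "CONVENTIONS"]

CONVENTIONS = ("direct", "nyquist")


def scale_to_frequency(scale, fs: float, convention: str = "direct"):
    """Representative frequency (Hz) of coarse-graining scale(s).

    Parameters
    ----------
    scale : int or array of int
        Coarse-graining factor(s), each >= 1.
    fs : float
        Sampling rate of the original series in Hz.
    convention : {"direct", "nyquist"}
        ``direct`` gives ``fs/s``; ``nyquist`` gives ``fs/(2 s)``.

    Returns
    -------
    float or ndarray
        Strictly decreasing in ``scale`` under both conventions.
    """
    s = np.asarray(scale, dtype=np.float64)
    if np.any(s < 1):
        raise ValueError("scales must be >= 1")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if convention == "direct":
        f = fs / s
    elif convention == "nyquist":
        f = fs / (2.0 * s)
    else:
        raise ValueError(f"unknown convention {convention!r}; use one of {CONVENTIONS}")
    return float(f) if np.isscalar(scale) else f
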