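"""Entropy estimators against independent brute-force oracles.

The oracles below are deliberately naive O(N^2) pure-Python/NumPy
re-statements of the published definitions, written from the definitions
(not from the package code) so that agreement is evidence of correctness
rather than of shared bugs.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import norm

from neurocomplexity import (
    EEG_BANDS,
    EntropyParams,
    FrequencyBand,
    TimeSeries,
    approximate_entropy,
    band_average_mse,
    coarse_grain,
    mse_curve,
    sample_entropy,
)
from neurocomplexity.entropy import band_scale_masks
from neurocomplexity.synth import gen_colored_noise

from oracles import oracle_apen, oracle_coarse, oracle_sampen

# ---------------------------------------------------------------------------
# coarse graining


def test_coarse_grain_example():
    ts = TimeSeries([1, 2, 3, 4, 5, 6], fs=10.0)
    cg = coarse_grain(ts, 2)
    np.testing.assert_allclose(cg.values, [1.5, 3.5, 5.5])
    assert cg.fs == 5.0


def test_coarse_grain_drops_partial_block():
    ts = TimeSeries([1, 2, 3, 4, 5], fs=1.0)
    np.testing.assert_allclose(coarse_grain(ts, 2).values, [1.5, 3.5])


def test_coarse_grain_identity_at_scale_1(rng):
    ts = TimeSeries(rng.standard_normal(40), fs=3.0)
    np.testing.assert_array_equal(coarse_grain(ts, 1).values, ts.values)


@given(
    x=arrays(np.float64, st.integers(12, 120),
             elements=st.floats(-1e6, 1e6, allow_nan=False)),
    scale=st.integers(1, 10),
)
@settings(max_examples=60, deadline=None)
def test_coarse_grain_matches_oracle(x, scale):
    if x.size < scale:
        return
    cg = coarse_grain(TimeSeries(x, fs=1.0), scale)
    np.testing.assert_allclose(cg.values, oracle_coarse(x, scale), rtol=1e-12, atol=1e-9)


def test_coarse_grain_composition(rng):
    x = TimeSeries(rng.standard_normal(240), fs=1.0)
    ab = coarse_grain(x, 6)
    two_step = coarse_grain(coarse_grain(x, 2), 3)
    np.testing.assert_allclose(ab.values, two_step.values, rtol=1e-12)


@pytest.mark.parametrize("bad", [0, -1, 2.5])
def test_coarse_grain_rejects_bad_scale(bad):
    with pytest.raises(ValueError):
        coarse_grain(TimeSeries(np.arange(10.0), fs=1.0), bad)


# ---------------------------------------------------------------------------
# sample entropy


@pytest.mark.parametrize("n,m,r,seed", [
    (60, 1, 0.3, 0), (80, 2, 0.2, 1), (120, 2, 0.5, 2),
    (150, 3, 0.2, 3), (90, 3, 0.35, 4),
])
def test_sampen_matches_oracle(n, m, r, seed):
    x = np.random.default_rng(seed).standard_normal(n)
    got = sample_entropy(TimeSeries(x, fs=1.0), EntropyParams(m, r))
    want = oracle_sampen(x, m, r)
    np.testing.assert_allclose(got, want, rtol=1e-12)


def test_sampen_sd_ref_matches_oracle(rng):
    x = rng.standard_normal(100)
    got = sample_entropy(TimeSeries(x, fs=1.0), EntropyParams(2, 0.2), sd_ref=2.5)
    np.testing.assert_allclose(got, oracle_sampen(x, 2, 0.2, sd_ref=2.5), rtol=1e-12)


def test_sampen_constant_series_is_zero():
    assert sample_entropy(TimeSeries(np.full(50, 3.7), fs=1.0), EntropyParams(2, 0.2)) == 0.0


def test_sampen_no_matches_is_nan():
    # a ramp with tolerance below the step size: no two templates match
    x = np.arange(20, dtype=float)
    val = sample_entropy(TimeSeries(x, fs=1.0), EntropyParams(2, 0.05))
    assert np.isnan(val)


def test_sampen_too_short_raises():
    with pytest.raises(ValueError):
        sample_entropy(TimeSeries(np.arange(3.0), fs=1.0), EntropyParams(2, 0.2))


@given(
    a=st.floats(0.1, 50), b=st.floats(-100, 100),
    seed=st.integers(0, 1000),
)
@settings(max_examples=25, deadline=None)
def test_sampen_affine_invariance(a, b, seed):
    """r is relative to SD, so affine rescaling leaves SampEn unchanged."""
    x = np.random.default_rng(seed).standard_normal(80)
    p = EntropyParams(2, 0.2)
    v1 = sample_entropy(TimeSeries(x, fs=1.0), p)
    v2 = sample_entropy(TimeSeries(a * x + b, fs=1.0), p)
    np.testing.assert_allclose(v1, v2, rtol=1e-9)


def test_sampen_gaussian_closed_form():
    """For i.i.d. Gaussian data SampEn(m, r) -> -ln(2*Phi(r/sqrt(2)) - 1)."""
    x = np.random.default_rng(7).standard_normal(50_000)
    got = sample_entropy(TimeSeries(x, fs=1.0), EntropyParams(2, 0.2))
    want = -np.log(2 * norm.cdf(0.2 / np.sqrt(2)) - 1)
    assert abs(got - want) < 0.05, (got, want)


def test_sampen_regular_below_irregular():
    t = np.arange(400)
    periodic = np.sin(2 * np.pi * t / 25)
    noise = np.random.default_rng(3).standard_normal(400)
    p = EntropyParams(2, 0.2)
    assert sample_entropy(TimeSeries(periodic, fs=1.0), p) < sample_entropy(
        TimeSeries(noise, fs=1.0), p
    )


# ---------------------------------------------------------------------------
# approximate entropy


@pytest.mark.parametrize("n,m,r,seed", [(60, 1, 0.3, 0), (80, 2, 0.2, 1), (70, 2, 0.5, 5)])
def test_apen_matches_oracle(n, m, r, seed):
    x = np.random.default_rng(seed).standard_normal(n)
    got = approximate_entropy(TimeSeries(x, fs=1.0), EntropyParams(m, r))
    np.testing.assert_allclose(got, oracle_apen(x, m, r), rtol=1e-12)


def test_apen_constant_is_zero():
    assert approximate_entropy(TimeSeries(np.ones(40), fs=1.0), EntropyParams(2, 0.2)) == 0.0


def test_apen_always_finite_on_spiky_data():
    x = 2.0 ** np.arange(20)
    assert np.isfinite(approximate_entropy(TimeSeries(x, fs=1.0), EntropyParams(2, 0.05)))


# ---------------------------------------------------------------------------
# multi-scale entropy


def test_mse_tolerance_anchored_to_original_sd(rng):
    """Entropy at scale s must equal SampEn of the coarse series with the
    ORIGINAL series SD as tolerance reference."""
    x = rng.standard_normal(600)
    ts = TimeSeries(x, fs=100.0)
    p = EntropyParams(2, 0.2)
    curve = mse_curve(ts, [1, 2, 5], p)
    for i, s in enumerate([1, 2, 5]):
        direct = sample_entropy(coarse_grain(ts, s), p, sd_ref=ts.sd())
        np.testing.assert_allclose(curve.entropy[i], direct, rtol=1e-12)
    # and that this differs from re-normalizing per scale (sanity of the test)
    renorm = sample_entropy(coarse_grain(ts, 5), p)
    assert not np.isclose(curve.entropy[2], renorm)


def test_mse_oversized_scale_is_nan(caplog):
    ts = TimeSeries(np.random.default_rng(0).standard_normal(50), fs=1.0)
    curve = mse_curve(ts, [1, 30], EntropyParams(2, 0.2))
    assert np.isfinite(curve.entropy[0]) and np.isnan(curve.entropy[1])


def test_mse_white_noise_decreases_with_scale():
    ts = gen_colored_noise(0.0, 20_000, fs=200.0, seed=11)
    curve = mse_curve(ts, [1, 5, 10, 20], EntropyParams(2, 0.2))
    assert np.all(np.diff(curve.entropy) < 0)


def test_mse_pink_above_white_at_coarse_scales():
    """The classic MSE signature: 1/f noise overtakes white noise at
    coarse scales while white noise is at least as complex at scale 1."""
    p = EntropyParams(2, 0.2)
    white = mse_curve(gen_colored_noise(0.0, 20_000, fs=200.0, seed=1), [1, 10, 20], p)
    pink = mse_curve(gen_colored_noise(1.0, 20_000, fs=200.0, seed=2), [1, 10, 20], p)
    assert white.entropy[0] > pink.entropy[0]
    assert pink.entropy[2] > white.entropy[2]


def test_mse_frequencies_both_conventions():
    ts = TimeSeries(np.random.default_rng(0).standard_normal(300), fs=200.0)
    curve = mse_curve(ts, [1, 2, 400][:2], EntropyParams(2, 0.2))
    np.testing.assert_allclose(curve.frequencies("direct"), [200.0, 100.0])
    np.testing.assert_allclose(curve.frequencies("nyquist"), [100.0, 50.0])


# ---------------------------------------------------------------------------
# bands


def test_band_masks_cover_expected_scales_at_200hz():
    scales = np.arange(1, 401)
    masks = band_scale_masks(scales, 200.0, EEG_BANDS)
    def rng_of(name):
        s = scales[masks[name]]
        return int(s.min()), int(s.max())
    assert rng_of("gamma") == (1, 6)
    assert rng_of("beta") == (7, 12)
    assert rng_of("alpha") == (14, 25)
    assert rng_of("theta") == (29, 49)
    assert rng_of("delta") == (50, 400)
    assert rng_of("delta_narrow") == (50, 74)


def test_band_boundary_scale_goes_to_lower_frequency_band():
    """fs/s = 4.0 Hz exactly at s=50: theta's f_lo == delta's f_hi, so the
    scale belongs to delta (the lower band), not theta."""
    scales = np.arange(1, 401)
    masks = band_scale_masks(scales, 200.0, EEG_BANDS)
    assert masks["delta"][scales == 50][0]
    assert not masks["theta"][scales == 50][0]
    # theta/alpha and alpha/beta boundaries don't land on integer scales at
    # 200 Hz, so adjacent masks are disjoint everywhere
    for a, b in [("delta", "theta"), ("theta", "alpha"), ("alpha", "beta"), ("beta", "gamma")]:
        assert not np.any(masks[a] & masks[b])


def test_band_average_mse_empty_band_raises():
    ts = TimeSeries(np.random.default_rng(0).standard_normal(200), fs=200.0)
    curve = mse_curve(ts, [1, 2, 3], EntropyParams(2, 0.2))
    with pytest.raises(ValueError):
        band_average_mse(curve, FrequencyBand("slow", 0.5, 1.0))


def test_band_average_mse_is_mean_of_member_scales(rng):
    ts = TimeSeries(rng.standard_normal(3000), fs=200.0)
    scales = np.arange(1, 15)
    curve = mse_curve(ts, scales, EntropyParams(2, 0.2))
    gamma = next(b for b in EEG_BANDS if b.name == "gamma")
    want = np.nanmean(curve.entropy[:6])  # scales 1..6 map to 200..33.3 Hz
    np.testing.assert_allclose(band_average_mse(curve, gamma), want, rtol=1e-12)
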