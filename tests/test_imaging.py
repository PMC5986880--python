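"""Experimental-stage procedures: cleaning, confounds, filters, cohorts."""

import numpy as np
import pytest

from neurocomplexity import (
    CohortSpec,
    EntropyParams,
    NodeTimeSeriesSet,
    SubjectNodeData,
    TimeSeries,
    bandpass,
    clean_lfp,
    gen_colored_noise,
    gen_coupled_cohort,
    gen_lfp_with_artifacts,
    nodal_mse_fc_correlation,
    network_mse_fc_correlation,
    regress_confounds,
    scale_to_frequency,
)
from neurocomplexity.imaging import subject_summaries, roi_series, voxelwise_mse_maps

# ---------------------------------------------------------------------------
# scale -> frequency


def test_scale_to_frequency_direct_examples():
    assert scale_to_frequency(1, 200.0) == pytest.approx(200.0)
    assert scale_to_frequency(400, 200.0) == pytest.approx(0.5)


def test_scale_to_frequency_nyquist_fmri_examples():
    """At TR 0.72 s (fs = 1.389 Hz), scales 1-2 map to 0.694/0.347 Hz."""
    fs = 1.0 / 0.72
    assert scale_to_frequency(1, fs, "nyquist") == pytest.approx(0.694, abs=5e-4)
    assert scale_to_frequency(2, fs, "nyquist") == pytest.approx(0.347, abs=5e-4)


def test_scale_to_frequency_validation():
    with pytest.raises(ValueError):
        scale_to_frequency(0, 200.0)
    with pytest.raises(ValueError):
        scale_to_frequency(2, 200.0, "bogus")


# ---------------------------------------------------------------------------
# LFP cleaning


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


def test_clean_lfp_recovers_smooth_ground_truth():
    """On a steep-spectrum (1/f^2, LFP-like) base the scrubbed trace matches
    the identically filtered/decimated ground truth to 5% of signal SD."""
    base = gen_colored_noise(2.0, 60_000, fs=1000.0, seed=3)
    cont, triggers, gt = gen_lfp_with_artifacts(base, 0.5, amplitude=5.0)
    cleaned = clean_lfp(cont, triggers, fs_out=50.0)
    reference = clean_lfp(gt, np.array([]), fs_out=50.0)  # filter/decimate only
    rms_err = _rms(cleaned.values - reference.values)
    assert rms_err < 0.05 * reference.values.std(), rms_err
    # and vastly better than not cleaning at all
    dirty = clean_lfp(cont, np.array([]), fs_out=50.0)
    assert rms_err < 0.2 * _rms(dirty.values - reference.values)


def test_clean_lfp_improves_broadband_ground_truth():
    """On broadband 1/f noise the gap content above ~8 Hz is unrecoverable
    by any interpolation, but cleaning must still beat no cleaning."""
    base = gen_colored_noise(1.0, 60_000, fs=1000.0, seed=3)
    cont, triggers, gt = gen_lfp_with_artifacts(base, 0.5, amplitude=5.0)
    cleaned = clean_lfp(cont, triggers, fs_out=50.0)
    reference = clean_lfp(gt, np.array([]), fs_out=50.0)
    dirty = clean_lfp(cont, np.array([]), fs_out=50.0)
    rms_err = _rms(cleaned.values - reference.values)
    assert rms_err < 0.8 * _rms(dirty.values - reference.values)


def test_clean_lfp_no_triggers_is_filter_decimate_only():
    base = gen_colored_noise(1.0, 10_000, fs=1000.0, seed=5)
    out = clean_lfp(base, np.array([]), fs_out=50.0)
    assert out.fs == 50.0
    assert out.values.size == 500


def test_clean_lfp_skips_out_of_bounds_triggers(caplog):
    base = gen_colored_noise(1.0, 5_000, fs=1000.0, seed=5)
    with caplog.at_level("WARNING", logger="neurocomplexity.imaging"):
        out = clean_lfp(base, np.array([0.001, 4.999, 2.0]), fs_out=50.0)
    assert sum("skipped" in r.message for r in caplog.records) == 2
    assert out.values.size == 250


def test_clean_lfp_non_integer_decimation_raises():
    base = gen_colored_noise(1.0, 5_000, fs=1000.0, seed=5)
    with pytest.raises(ValueError):
        clean_lfp(base, np.array([]), fs_out=300.0)


# ---------------------------------------------------------------------------
# confound regression


def test_regress_confounds_residuals_orthogonal(rng):
    data = rng.standard_normal((4, 300))
    conf = rng.standard_normal((300, 3))
    out = regress_confounds(NodeTimeSeriesSet(data, fs=1.0), conf)
    design = np.column_stack([np.ones(300), conf])
    assert np.max(np.abs(design.T @ out.data.T)) < 1e-8
    assert np.max(np.abs(out.data.mean(axis=1))) < 1e-12


def test_regress_confounds_matches_lstsq_oracle(rng):
    data = rng.standard_normal((2, 100))
    conf = rng.standard_normal((100, 2))
    out = regress_confounds(NodeTimeSeriesSet(data, fs=1.0), conf)
    design = np.column_stack([np.ones(100), conf])
    beta, *_ = np.linalg.lstsq(design, data.T, rcond=None)
    np.testing.assert_allclose(out.data, (data.T - design @ beta).T, atol=1e-10)


def test_regress_confounds_collinear_raises(rng):
    data = rng.standard_normal((2, 50))
    c1 = rng.standard_normal(50)
    conf = np.column_stack([c1, 2 * c1])
    with pytest.raises(ValueError, match="collinear"):
        regress_confounds(NodeTimeSeriesSet(data, fs=1.0), conf)


# ---------------------------------------------------------------------------
# band-pass


def test_bandpass_attenuates_out_of_band(rng):
    fs = 100.0
    t = np.arange(4000) / fs
    inband = np.sin(2 * np.pi * 10 * t)
    outband = np.sin(2 * np.pi * 35 * t)
    ts = TimeSeries(inband + outband, fs=fs)
    out = bandpass(ts, 5.0, 15.0)
    core = slice(500, 3500)  # ignore filter edge effects
    resid = out.values[core] - inband[core]
    assert np.sqrt(np.mean(resid**2)) < 0.05


def test_bandpass_lowpass_mode_and_validation(rng):
    ts = TimeSeries(rng.standard_normal(1000), fs=100.0)
    out = bandpass(ts, 0.0, 20.0)
    assert out.values.shape == ts.values.shape
    with pytest.raises(ValueError):
        bandpass(ts, 30.0, 20.0)
    with pytest.raises(ValueError):
        bandpass(ts, 10.0, 60.0)  # beyond Nyquist


# ---------------------------------------------------------------------------
# cohort analyses


def test_subject_summaries_shapes_and_session_average(rng):
    d1 = rng.standard_normal((5, 300))
    d2 = rng.standard_normal((5, 300))
    subj = SubjectNodeData("s0", (NodeTimeSeriesSet(d1, fs=1.0),
                                  NodeTimeSeriesSet(d2, fs=1.0)))
    scales = [1, 2, 4]
    params = EntropyParams(2, 0.5)
    m, f = subject_summaries(subj, scales, params)
    assert m.shape == (5, 3) and f.shape == (5,)
    m1, f1 = subject_summaries(SubjectNodeData("a", (subj.sessions[0],)), scales, params)
    m2, f2 = subject_summaries(SubjectNodeData("b", (subj.sessions[1],)), scales, params)
    np.testing.assert_allclose(m, (m1 + m2) / 2, atol=1e-12)
    np.testing.assert_allclose(f, (f1 + f2) / 2, atol=1e-12)


def test_subject_node_set_mismatch_raises(rng):
    a = NodeTimeSeriesSet(rng.standard_normal((3, 50)), fs=1.0, names=("x", "y", "z"))
    b = NodeTimeSeriesSet(rng.standard_normal((3, 50)), fs=1.0, names=("x", "y", "w"))
    with pytest.raises(ValueError, match="differing node sets"):
        SubjectNodeData("s", (a, b))


def test_cohort_needs_four_subjects(rng):
    subj = SubjectNodeData("s", (NodeTimeSeriesSet(rng.standard_normal((3, 64)), fs=1.0),))
    with pytest.raises(ValueError):
        network_mse_fc_correlation([subj] * 3, [1, 2])


def test_network_correlation_shapes_and_convention():
    spec = CohortSpec(n_subjects=6, n_nodes=5, n_timepoints=256, seed=2)
    cohort = gen_coupled_cohort(spec)
    assoc = network_mse_fc_correlation(cohort, [1, 2, 3], EntropyParams(2, 0.5))
    assert assoc.r.shape == (3,) and assoc.p.shape == (3,)
    assert assoc.convention == "nyquist"
    np.testing.assert_allclose(assoc.frequencies()[1],
                               scale_to_frequency(2, 1 / 0.72, "nyquist"))
    assert assoc.significant.shape == (3,)


def test_nodal_correlation_shapes():
    spec = CohortSpec(n_subjects=6, n_nodes=4, n_timepoints=256, seed=3)
    cohort = gen_coupled_cohort(spec)
    assoc = nodal_mse_fc_correlation(cohort, [1, 2], EntropyParams(2, 0.5))
    assert assoc.r.shape == (4, 2)
    assert np.all(np.abs(assoc.r[np.isfinite(assoc.r)]) <= 1.0)


# ---------------------------------------------------------------------------
# volumetric helpers


def test_voxelwise_maps_and_roi_series(tmp_path, rng):
    nib = pytest.importorskip("nibabel")
    data = rng.standard_normal((3, 3, 2, 120))
    img = nib.Nifti1Image(data, np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, 0.72))
    mask = np.zeros((3, 3, 2))
    mask[1, 1, 0] = mask[0, 2, 1] = 1
    mask_img = nib.Nifti1Image(mask, np.eye(4))
    maps = voxelwise_mse_maps(img, mask_img, [1, 2], EntropyParams(2, 0.5))
    assert len(maps) == 2
    assert np.isfinite(maps[0][1, 1, 0]) and np.isfinite(maps[0][0, 2, 1])
    assert np.isnan(maps[0][0, 0, 0])
    roi = roi_series(img, mask_img)
    assert roi.fs == pytest.approx(1 / 0.72)
    np.testing.assert_allclose(
        roi.values, (data[1, 1, 0] + data[0, 2, 1]) / 2, atol=1e-12
    )
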