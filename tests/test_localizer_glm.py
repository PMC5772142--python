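"""Echo combination, design construction, GLM fitting, contrasts, and
seed localization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from streamconn.imaging_io import RoiSpec, VolumeImage, build_sphere_roi
from streamconn.localizer_glm import (
    BlockDesign,
    build_design,
    combine_echoes,
    contrast_map,
    contrast_tstats,
    dct_drift_basis,
    fit_glm,
    localize_seed,
    smooth_volume,
)
from streamconn.synthetic_data import generate_localizer_run, make_block_design


def _volume(data, tr=2.0):
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = 2.0
    affine[:3, 3] = -np.array(data.shape[:3]) + 1.0
    return VolumeImage(data, affine, tr_s=tr)


# ---------------------------------------------------------------- echoes


def test_identical_echoes_pass_through():
    rng = np.random.default_rng(0)
    data = rng.standard_normal((4, 4, 4, 40)) + 10
    echoes = [_volume(data.copy()) for _ in range(3)]
    combined = combine_echoes(echoes, [10.0, 25.0, 40.0])
    np.testing.assert_allclose(combined.data, data, rtol=1e-12)


def test_equal_tsnr_weights_proportional_to_te():
    rng = np.random.default_rng(1)
    base = rng.standard_normal((3, 3, 3, 50)) + 20
    # scaling a timeseries leaves tSNR unchanged
    e1, e2 = base.copy(), 2.0 * base
    te = np.array([15.0, 30.0])
    combined = combine_echoes([_volume(e1), _volume(e2)], list(te))
    w = te / te.sum()
    expected = w[0] * e1 + w[1] * e2
    np.testing.assert_allclose(combined.data, expected, rtol=1e-10)


def test_single_echo_rejected():
    data = np.zeros((2, 2, 2, 10))
    with pytest.raises(ValueError, match="at least 2"):
        combine_echoes([_volume(data)], [10.0])


def test_zero_variance_voxel_falls_back_to_te_weights():
    rng = np.random.default_rng(2)
    d1 = rng.standard_normal((2, 2, 2, 40)) + 5
    d2 = rng.standard_normal((2, 2, 2, 40)) + 5
    d1[0, 0, 0, :] = 1.0  # constant voxel
    d2[0, 0, 0, :] = 3.0
    combined = combine_echoes([_volume(d1), _volume(d2)], [10.0, 30.0])
    expected = (10.0 * 1.0 + 30.0 * 3.0) / 40.0
    np.testing.assert_allclose(combined.data[0, 0, 0], expected)


# ---------------------------------------------------------------- design


def _simple_design(n=120, tr=2.0):
    return BlockDesign(
        conditions={
            "bodies": (np.array([16.0, 112.0]), np.array([16.0, 16.0])),
            "objects": (np.array([64.0, 160.0]), np.array([16.0, 16.0])),
        }
    )


def test_design_columns_and_motion_derivatives():
    motion = pd.DataFrame(
        np.random.default_rng(0).standard_normal((120, 6)),
        columns=[f"m{i}" for i in range(6)],
    )
    X = build_design(_simple_design(), 2.0, 120, motion)
    names = list(X.columns)
    assert "bodies" in names and "bodies_derivative" in names
    assert sum(n.endswith("_derivative") for n in names) >= 8
    assert names[-1] == "constant"
    np.testing.assert_allclose(
        X["m0_derivative"].to_numpy()[1:], np.diff(X["m0"].to_numpy())
    )


def test_design_motion_row_mismatch_raises():
    motion = pd.DataFrame(np.zeros((100, 6)))
    with pytest.raises(ValueError, match="motion"):
        build_design(_simple_design(), 2.0, 120, motion)


def test_design_without_conditions_is_nuisance_only():
    X = build_design(BlockDesign(conditions={}), 2.0, 50, None)
    assert list(X.columns) == ["constant"]


def test_hrf_peak_lag_matches_convolution_oracle():
    """Peak of a 20 s block regressor should match a direct convolution
    of the boxcar with an independently built double-gamma response."""
    tr, n = 2.0, 100
    design = BlockDesign(conditions={"c": (np.array([40.0]), np.array([20.0]))})
    X = build_design(design, tr, n, None)
    col = X["c"].to_numpy()

    dt = 0.1
    t = np.arange(0, 32, dt)
    hrf = stats.gamma.pdf(t, 6) - stats.gamma.pdf(t, 16) / 6.0
    box = np.zeros(int(n * tr / dt))
    box[int(40 / dt): int(60 / dt)] = 1.0
    conv = np.convolve(box, hrf)[: box.size] * dt
    peak_oracle_s = np.argmax(conv) * dt
    peak_col_s = np.argmax(col) * tr
    assert abs(peak_col_s - peak_oracle_s) <= tr


# ---------------------------------------------------------------- GLM fit


def test_noiseless_recovery_is_exact():
    rng = np.random.default_rng(3)
    X = build_design(_simple_design(), 2.0, 120, None)
    beta_true = rng.standard_normal((X.shape[1], 30))
    Y = X.to_numpy() @ beta_true
    fit = fit_glm(Y, X, tr_s=2.0, highpass_s=128.0)
    np.testing.assert_allclose(fit.betas, beta_true, atol=1e-8)


def test_slow_drift_removed_by_highpass():
    tr, n = 2.0, 150
    X = build_design(_simple_design(), tr, n, None)
    t = np.arange(n) * tr
    Y = np.cos(2 * np.pi * t / 300.0)[:, None]  # period 300 s > cutoff
    fit = fit_glm(Y, X, tr_s=tr, highpass_s=128.0)
    assert abs(fit.beta_of("bodies")[0]) < 1e-2


def test_highpass_projection_idempotent():
    rng = np.random.default_rng(4)
    n, tr = 200, 2.0
    D = dct_drift_basis(n, tr, 128.0)
    y = rng.standard_normal(n)
    P = np.eye(n) - D @ np.linalg.pinv(D)
    np.testing.assert_allclose(P @ (P @ y), P @ y, atol=1e-10)


def test_ar1_rho_recovered_from_simulations():
    """Pooled AR(1) estimate averaged over Monte-Carlo runs is close to
    the generating coefficient."""
    rng = np.random.default_rng(5)
    rho_true, n, n_sim = 0.4, 500, 100
    X = pd.DataFrame({"constant": np.ones(n)})
    est = []
    for _ in range(n_sim):
        e = rng.standard_normal(n)
        y = np.empty(n)
        y[0] = e[0]
        for t in range(1, n):
            y[t] = rho_true * y[t - 1] + np.sqrt(1 - rho_true**2) * e[t]
        fit = fit_glm(y, X, tr_s=2.0, highpass_s=None)
        est.append(fit.ar1_rho)
    assert abs(np.mean(est) - rho_true) < 0.05


def test_rank_deficiency_names_columns():
    X = build_design(_simple_design(), 2.0, 120, None)
    X["bodies_copy"] = X["bodies"]
    with pytest.raises(ValueError, match="rank deficient"):
        fit_glm(np.random.default_rng(0).standard_normal((120, 3)), X, tr_s=2.0)


# ---------------------------------------------------------------- contrasts


def test_zero_contrast_gives_zero_map():
    X = build_design(_simple_design(), 2.0, 120, None)
    Y = np.random.default_rng(1).standard_normal((120, 20))
    fit = fit_glm(Y, X, tr_s=2.0)
    t = contrast_tstats(fit, {"bodies": 0.0})
    np.testing.assert_array_equal(t, np.zeros(20))


def test_planted_effect_with_zero_noise_gives_infinite_t():
    X = build_design(_simple_design(), 2.0, 120, None)
    Y = np.outer(X["bodies"].to_numpy() - X["objects"].to_numpy(), [2.0])
    fit = fit_glm(Y, X, tr_s=2.0)
    t = contrast_tstats(fit, {"bodies": 1.0, "objects": -1.0})
    # residual variance is zero to machine precision, so t diverges
    assert t[0] > 1e10


def test_null_type_one_error_calibrated():
    rng = np.random.default_rng(6)
    n, v = 400, 4000
    X = pd.DataFrame(
        {"x": rng.standard_normal(n), "constant": np.ones(n)}
    )
    Y = rng.standard_normal((n, v))
    fit = fit_glm(Y, X, tr_s=2.0, highpass_s=None)
    t = contrast_tstats(fit, {"x": 1.0})
    crit = stats.t.ppf(0.975, fit.dof)
    frac = np.mean(np.abs(t) > crit)
    assert abs(frac - 0.05) < 0.01


def test_white_noise_tstats_match_student_t():
    rng = np.random.default_rng(7)
    n, v = 200, 2000
    X = pd.DataFrame({"x": rng.standard_normal(n), "constant": np.ones(n)})
    Y = rng.standard_normal((n, v))
    fit = fit_glm(Y, X, tr_s=2.0, highpass_s=None)
    t = contrast_tstats(fit, {"x": 1.0})
    ks = stats.kstest(t, "t", args=(fit.dof,)).statistic
    assert ks < 0.05


# ---------------------------------------------------------------- localization


def test_seed_recovered_within_one_voxel(clean_cfg):
    cfg = clean_cfg
    site = cfg.seed_sites[0]
    run = generate_localizer_run(
        cfg, 0,
        amplitudes={"EBA": {"bodies": 5.0, "objects": 1.0, "scrambled": 0.5}},
    )
    # tiny noise floor so the GLM has residual variance
    rng = np.random.default_rng(0)
    noisy = VolumeImage(
        run.volume.data + 0.01 * rng.standard_normal(run.volume.data.shape),
        run.volume.affine, run.volume.tr_s,
    )
    design = make_block_design(cfg)
    X = build_design(design, cfg.tr_s, cfg.localizer_n_volumes, None)
    fit = fit_glm(noisy, X, tr_s=cfg.tr_s)
    tmap = contrast_map(fit, {"bodies": 1.0, "objects": -1.0})
    seed = localize_seed(tmap, RoiSpec("search", site.center_mm, 10.0), name="EBA")
    err = np.linalg.norm(np.array(seed.coord_mm) - np.array(site.center_mm))
    assert err <= np.sqrt(3) * cfg.voxel_size_mm + 1e-9


def test_uniform_tmap_ties_break_lexicographically(grid2mm):
    affine, shape = grid2mm
    tmap = VolumeImage(np.ones(shape), affine)
    seed = localize_seed(tmap, RoiSpec("s", (0.0, 0.0, 0.0), 4.0))
    mask = build_sphere_roi(RoiSpec("s", (0.0, 0.0, 0.0), 4.0), affine, shape)
    assert seed.voxel_index == tuple(mask.voxel_indices[0])


def test_zero_radius_search_returns_that_voxel(grid2mm):
    affine, shape = grid2mm
    rng = np.random.default_rng(8)
    tmap = VolumeImage(rng.standard_normal(shape), affine)
    seed = localize_seed(tmap, RoiSpec("s", (0.0, 0.0, 0.0), 0.0))
    assert seed.coord_mm == (0.0, 0.0, 0.0)


def test_all_nan_region_raises(grid2mm):
    affine, shape = grid2mm
    tmap = VolumeImage(np.full(shape, np.nan), affine)
    with pytest.raises(ValueError, match="NaN"):
        localize_seed(tmap, RoiSpec("s", (0.0, 0.0, 0.0), 4.0))


def test_smoothing_preserves_mean(grid2mm):
    affine, shape = grid2mm
    rng = np.random.default_rng(9)
    vol = VolumeImage(rng.standard_normal(shape), affine)
    sm = smooth_volume(vol, fwhm_mm=6.0)
    assert sm.data.std() < vol.data.std()
    assert sm.data.mean() == pytest.approx(vol.data.mean(), abs=0.02)
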