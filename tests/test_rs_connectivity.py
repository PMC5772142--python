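"""Eigenvariate extraction, seed-beta GLMs, stream aggregation, ANOVAs,
and group-level cluster inference."""

import numpy as np
import pandas as pd
import pytest

from streamconn.imaging_io import (
    ParcellationVolume,
    RoiMask,
    RoiSpec,
    StreamTable,
    VolumeImage,
    build_sphere_roi,
    load_stream_table,
)
from streamconn.rs_connectivity import (
    BetaMap,
    build_nuisance,
    first_eigenvariate,
    group_map,
    pairwise_interaction_anovas,
    repeated_anova,
    screen_motion,
    seed_beta_map,
    stream_strength,
)
from streamconn.synthetic_data import (
    SyntheticCohortConfig,
    compartment_masks,
    generate_rest_run,
    make_parcellation,
)


def _grid(shape=(10, 10, 10)):
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = 2.0
    affine[:3, 3] = -(np.array(shape) - 1)
    return affine, shape


def _mask_all(affine, shape):
    idx = np.argwhere(np.ones(shape, bool))
    return RoiMask(idx, affine, shape)


# ------------------------------------------------------------ eigenvariate


def test_rank_one_roi_returns_shared_timeseries():
    affine, shape = _grid((4, 4, 4))
    rng = np.random.default_rng(0)
    ts = rng.standard_normal(80)
    gains = rng.uniform(0.5, 2.0, np.prod(shape))
    data = (gains[:, None] * ts[None, :]).reshape(*shape, 80)
    run = VolumeImage(data, affine, tr_s=2.0)
    ev = first_eigenvariate(run, _mask_all(affine, shape))
    r = np.corrcoef(ev.values, ts)[0, 1]
    assert r == pytest.approx(1.0, abs=1e-10)


def test_anticorrelated_groups_align_with_majority():
    """60/40 split of anti-correlated voxels: the component follows the
    majority group, matching a direct SVD oracle."""
    affine, shape = _grid((5, 4, 5))
    rng = np.random.default_rng(1)
    ts = rng.standard_normal(100)
    nvox = np.prod(shape)
    n_major = int(0.6 * nvox)
    signs = np.r_[np.ones(n_major), -np.ones(nvox - n_major)]
    data = (signs[:, None] * ts[None, :]).reshape(*shape, 100)
    data = data + 0.01 * rng.standard_normal(data.shape)
    run = VolumeImage(data, affine, tr_s=2.0)
    ev = first_eigenvariate(run, _mask_all(affine, shape))
    assert np.corrcoef(ev.values, ts)[0, 1] > 0.99

    # oracle: leading right-singular direction of the demeaned matrix
    Y = data.reshape(nvox, 100).T
    Y = Y - Y.mean(0)
    U, S, Vt = np.linalg.svd(Y, full_matrices=False)
    u = U[:, 0] * np.sign(Vt[0].mean())
    assert abs(np.corrcoef(ev.values, u)[0, 1]) > 0.999999


def test_single_voxel_mask_returns_scaled_series():
    affine, shape = _grid((4, 4, 4))
    rng = np.random.default_rng(2)
    data = rng.standard_normal((*shape, 60))
    run = VolumeImage(data, affine, tr_s=2.0)
    mask = RoiMask(np.array([[1, 2, 3]]), affine, shape)
    ev = first_eigenvariate(run, mask)
    voxel = data[1, 2, 3] - data[1, 2, 3].mean()
    assert abs(np.corrcoef(ev.values, voxel)[0, 1]) == pytest.approx(1.0, abs=1e-12)


def test_constant_roi_rejected():
    affine, shape = _grid((3, 3, 3))
    run = VolumeImage(np.ones((*shape, 30)), affine, tr_s=2.0)
    with pytest.raises(ValueError, match="constant"):
        first_eigenvariate(run, _mask_all(affine, shape))


# ------------------------------------------------------------ seed GLM


def _nuisance_frame(n, rng):
    cols = {f"m{i}": rng.standard_normal(n) for i in range(6)}
    for i in range(6):
        d = np.zeros(n)
        d[1:] = np.diff(cols[f"m{i}"])
        cols[f"m{i}_derivative"] = d
    for c in ("white_matter", "csf", "out_of_brain"):
        cols[c] = rng.standard_normal(n)
    return pd.DataFrame(cols)


def test_noiseless_seed_beta_recovery_exact():
    affine, shape = _grid((6, 6, 6))
    rng = np.random.default_rng(3)
    n = 150
    seed = rng.standard_normal(n)
    nuis = _nuisance_frame(n, rng)
    a = rng.uniform(-2, 2, np.prod(shape))
    mix = nuis.to_numpy() @ rng.standard_normal((15, np.prod(shape)))
    data = (a[None, :] * seed[:, None] + mix).T.reshape(*shape, n)
    run = VolumeImage(data, affine, tr_s=2.0)
    from streamconn.rs_connectivity import SeedTimeseries

    beta = seed_beta_map(run, SeedTimeseries("s", seed), nuis)
    np.testing.assert_allclose(beta.volume.data.ravel(), a, atol=1e-8)


def test_pure_nuisance_voxel_has_zero_seed_beta():
    affine, shape = _grid((4, 4, 4))
    rng = np.random.default_rng(4)
    n = 120
    seed = rng.standard_normal(n)
    nuis = _nuisance_frame(n, rng)
    data = np.tile(nuis["csf"].to_numpy(), (np.prod(shape), 1)).reshape(
        *shape, n
    ).copy()
    data += 1e-6 * rng.standard_normal(data.shape)
    run = VolumeImage(data, affine, tr_s=2.0)
    from streamconn.rs_connectivity import SeedTimeseries

    beta = seed_beta_map(run, SeedTimeseries("s", seed), nuis)
    assert np.abs(beta.volume.data).max() < 1e-3


def test_beta_invariant_to_added_nuisance_combination():
    affine, shape = _grid((4, 4, 4))
    rng = np.random.default_rng(5)
    n = 120
    seed = rng.standard_normal(n)
    nuis = _nuisance_frame(n, rng)
    base = rng.standard_normal((n, np.prod(shape)))
    extra = nuis.to_numpy() @ rng.standard_normal((15, np.prod(shape)))
    from streamconn.rs_connectivity import SeedTimeseries

    b0 = seed_beta_map(
        VolumeImage(base.T.reshape(*shape, n), affine, tr_s=2.0),
        SeedTimeseries("s", seed), nuis,
    )
    b1 = seed_beta_map(
        VolumeImage((base + extra).T.reshape(*shape, n), affine, tr_s=2.0),
        SeedTimeseries("s", seed), nuis,
    )
    np.testing.assert_allclose(
        b0.volume.data, b1.volume.data, atol=1e-6
    )


def test_planted_loading_recovered_through_pipeline(small_cfg):
    """Seed eigenvariate regression recovers the planted coupling of a
    distant site within 10%."""
    from streamconn.synthetic_data import SeedSite

    cfg = SyntheticCohortConfig(
        n_subjects=1,
        grid_shape=(12, 14, 12),
        n_volumes=500,
        seed_sites=[
            SeedSite("SEED", "left", (-5.0, -5.0, 3.0), 1.0, 0.0),
            SeedSite("TARGET", "left", (5.0, 7.0, -3.0), 0.8, 0.0),
        ],
        noise_sd=0.3,
        rng_seed=11,
    )
    run = generate_rest_run(cfg, 0)
    nuis = build_nuisance(run.motion, run.volume, run.compartments)
    mask = build_sphere_roi(
        RoiSpec("SEED", (-5.0, -5.0, 3.0), 4.0), cfg.affine, cfg.grid_shape
    )
    ts = first_eigenvariate(run.volume, mask, name="SEED")
    beta = seed_beta_map(run.volume, ts, nuis)
    tmask = build_sphere_roi(
        RoiSpec("TARGET", (5.0, 7.0, -3.0), 4.0), cfg.affine, cfg.grid_shape
    )
    got = beta.volume.data[tuple(tmask.voxel_indices.T)].mean()
    assert got == pytest.approx(0.8, rel=0.10)


# ------------------------------------------------------------ aggregation


def _toy_parcellation():
    affine, shape = _grid((6, 6, 6))
    labels = np.zeros(shape, int)
    labels[0:2, 0:2, 4:6] = 1   # dorsal A (8 vox)
    labels[4:6, 0:3, 4:6] = 2   # dorsal B (12 vox)
    labels[0:2, 4:6, 0:2] = 3   # ventral C (8 vox)
    parc = ParcellationVolume(labels, affine, {1: "A", 2: "B", 3: "C"})
    streams = StreamTable(
        pd.DataFrame(
            {"area_name": ["A", "B", "C"], "stream": ["dorsal", "dorsal", "ventral"]}
        )
    )
    return affine, shape, parc, streams


def test_constant_map_gives_constant_strengths():
    affine, shape, parc, streams = _toy_parcellation()
    beta = BetaMap(VolumeImage(np.full(shape, 0.7), affine), "EBA", 0, "left")
    st, _ = stream_strength(beta, parc, streams)
    assert set(st["value"].round(12)) == {0.7}


def test_indicator_map_separates_streams():
    affine, shape, parc, streams = _toy_parcellation()
    data = np.where(np.isin(parc.label_data, [1, 2]), 1.0, 0.0)
    beta = BetaMap(VolumeImage(data, affine), "EBA", 0, "left")
    st, _ = stream_strength(beta, parc, streams)
    st = st.set_index("stream")["value"]
    assert st["dorsal"] == 1.0 and st["ventral"] == 0.0


def test_stream_mean_is_voxel_weighted_parcel_mean():
    affine, shape, parc, streams = _toy_parcellation()
    rng = np.random.default_rng(6)
    data = rng.standard_normal(shape)
    beta = BetaMap(VolumeImage(data, affine), "EBA", 0, "left")
    st, pc = stream_strength(beta, parc, streams)
    # oracle: direct summation over all dorsal voxels
    dorsal_vox = np.isin(parc.label_data, [1, 2])
    assert st.set_index("stream")["value"]["dorsal"] == pytest.approx(
        data[dorsal_vox].mean()
    )
    # and equals the voxel-count-weighted mean of parcel means
    d = pc[pc.stream == "dorsal"]
    weighted = (d["value"] * d["n_voxels"]).sum() / d["n_voxels"].sum()
    assert st.set_index("stream")["value"]["dorsal"] == pytest.approx(weighted)


# ------------------------------------------------------------ ANOVA


def _strength_table(rng, n_sub=8, interaction=0.0):
    rows = []
    for s in range(n_sub):
        for seed in ("EBA", "FBA", "LOC"):
            for stream in ("dorsal", "ventral"):
                mu = 0.2
                if seed == "EBA" and stream == "dorsal":
                    mu += interaction
                rows.append((s, seed, "left", stream, mu + rng.normal(0, 0.05)))
    return pd.DataFrame(
        rows, columns=["subject", "seed", "hemisphere", "stream", "value"]
    )


def test_equal_cells_give_zero_interaction():
    rows = [
        (s, seed, "left", stream, 0.5 + 0.1 * s)
        for s in range(6)
        for seed in ("EBA", "FBA", "LOC")
        for stream in ("dorsal", "ventral")
    ]
    df = pd.DataFrame(rows, columns=["subject", "seed", "hemisphere", "stream", "value"])
    res = repeated_anova(df)
    inter = next(r for r in res if r.effect == "seed:stream")
    assert inter.F == 0.0 and inter.p == 1.0


def test_single_level_factor_rejected():
    df = _strength_table(np.random.default_rng(0))
    df = df[df.stream == "dorsal"]
    with pytest.raises(ValueError, match="levels"):
        repeated_anova(df)


def test_missing_cells_reported():
    df = _strength_table(np.random.default_rng(0))
    df = df.drop(df[(df.subject == 0) & (df.seed == "EBA")].index)
    with pytest.raises(ValueError, match="missing"):
        repeated_anova(df)


def test_planted_interaction_detected():
    rng = np.random.default_rng(7)
    df = _strength_table(rng, n_sub=16, interaction=0.15)
    res = repeated_anova(df)
    inter = next(r for r in res if r.effect == "seed:stream")
    assert inter.p < 0.05
    pw = pairwise_interaction_anovas(df)
    assert all(r.correction == "Bonferroni" for r in pw)


def test_motion_screening_threshold():
    good = pd.DataFrame(np.zeros((10, 6)))
    bad = good.copy()
    bad.iloc[5, 0] = 3.5
    assert screen_motion(good)
    assert not screen_motion(bad, threshold_mm=3.0)


# ------------------------------------------------------------ group maps


def _beta(data, affine):
    return BetaMap(VolumeImage(data, affine), "EBA", 0, "left")


def test_planted_blob_yields_single_significant_cluster():
    affine, shape = _grid((10, 10, 10))
    rng = np.random.default_rng(8)
    blob = np.zeros(shape)
    blob[4:7, 4:7, 4:7] = 1.0
    maps = [
        _beta(blob + 0.05 * rng.standard_normal(shape), affine) for _ in range(10)
    ]
    tmap, table = group_map(maps, n_perm=200, rng_seed=1)
    sig = table[table.significant]
    assert len(sig) == 1
    assert sig.iloc[0]["size_voxels"] == 27


def test_self_paired_contrast_is_empty():
    affine, shape = _grid((8, 8, 8))
    rng = np.random.default_rng(9)
    maps = [_beta(rng.standard_normal(shape), affine) for _ in range(5)]
    _, table = group_map(maps, betas_b=maps, n_perm=50, rng_seed=0)
    assert len(table) == 0


def test_group_map_needs_two_subjects():
    affine, shape = _grid((6, 6, 6))
    with pytest.raises(ValueError, match="2 subjects"):
        group_map([_beta(np.zeros(shape), affine)])


def test_cluster_fwe_calibrated_under_null():
    """Family-wise error of the sign-flip cluster test stays near the
    nominal 5% over repeated null group analyses."""
    affine, shape = _grid((10, 10, 10))
    rng = np.random.default_rng(10)
    n_sims, n_sub = 200, 8
    false_positives = 0
    for i in range(n_sims):
        maps = [
            _beta(rng.standard_normal(shape), affine) for _ in range(n_sub)
        ]
        _, table = group_map(maps, n_perm=99, rng_seed=1000 + i)
        if len(table) and (table["p_fwe"] < 0.05).any():
            false_positives += 1
    rate = false_positives / n_sims
    # binomial 95% envelope around 0.05 at 200 simulations
    assert rate <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_sims) + 1e-9
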