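"""Seed-based resting-state connectivity.

Per subject and seed, the seed timeseries (first eigenvariate of a 4 mm
sphere) is regressed against every voxel alongside 15 nuisance
regressors (6 motion + 6 motion derivatives + white-matter, CSF and
out-of-brain compartment means), with the same high-pass and AR(1)
handling as the localizer GLM. Downstream: stream-level strength
aggregation, repeated-measures ANOVAs, and sign-flip cluster-mass group
inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.anova import AnovaRM

from .imaging_io import ParcellationVolume, RoiMask, StreamTable, VolumeImage
from .localizer_glm import fit_glm

logger = logging.getLogger(__name__)

__all__ = [
    "SeedTimeseries",
    "BetaMap",
    "AnovaResult",
    "first_eigenvariate",
    "build_nuisance",
    "seed_beta_map",
    "stream_strength",
    "repeated_anova",
    "pairwise_interaction_anovas",
    "screen_motion",
    "group_map",
]


@dataclass
class SeedTimeseries:
    name: str
    values: np.ndarray
    method: str = "eigenvariate"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("seed timeseries contains non-finite values")


@dataclass
class BetaMap:
    """Whole-brain map of seed-coupling regression coefficients."""

    volume: VolumeImage
    seed: str
    subject: int | str = ""
    hemisphere: str = ""


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    correction: str = "none"

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be >= 0")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def first_eigenvariate(
    run: VolumeImage, mask: RoiMask, name: str = "seed"
) -> SeedTimeseries:
    """First principal component of the ROI voxel x time matrix.

    Conventions (fixed for determinism): per-voxel means are removed; the
    component sign is chosen so the mean voxel loading is positive; the
    component is scaled to the standard deviation of the ROI mean
    timeseries.
    """
    if run.data.ndim != 4:
        raise ValueError("first_eigenvariate expects a 4D run")
    if len(mask) == 0:
        raise ValueError("empty ROI mask")
    Y = run.data[tuple(mask.voxel_indices.T)].astype(float).T  # (t, v)
    Y = Y - Y.mean(axis=0)
    if not (Y.std(axis=0) > 0).any():
        raise ValueError("all ROI voxels are constant; eigenvariate undefined")
    U, S, Vt = np.linalg.svd(Y, full_matrices=False)
    ts = U[:, 0]
    loading_mean = Vt[0].mean()
    if loading_mean < 0:
        ts = -ts
    mean_ts = Y.mean(axis=1)
    sd = ts.std()
    target_sd = mean_ts.std()
    if sd > 0 and target_sd > 0:
        ts = ts / sd * target_sd
    return SeedTimeseries(name=name, values=ts, method="eigenvariate")


def build_nuisance(
    motion: pd.DataFrame,
    run: VolumeImage,
    compartments: dict[str, np.ndarray],
) -> pd.DataFrame:
    """The 15-column nuisance set: 6 motion parameters, their first
    temporal differences, and mean signals of the white-matter, CSF and
    out-of-brain compartments."""
    if motion.shape[1] != 6:
        raise ValueError("motion table must have 6 columns")
    n = run.n_volumes
    if len(motion) != n:
        raise ValueError("motion rows must match run length")
    cols: dict[str, np.ndarray] = {}
    for c in motion.columns:
        vals = motion[c].to_numpy(dtype=float)
        cols[str(c)] = vals
        d = np.zeros_like(vals)
        d[1:] = np.diff(vals)
        cols[f"{c}_derivative"] = d
    for key in ("white_matter", "csf", "out_of_brain"):
        if key not in compartments:
            raise ValueError(f"missing compartment mask {key!r}")
        m = np.asarray(compartments[key], dtype=bool)
        cols[key] = run.data[m].mean(axis=0)
    out = pd.DataFrame(cols)
    assert out.shape[1] == 15
    return out


def seed_beta_map(
    run: VolumeImage,
    seed_ts: SeedTimeseries,
    nuisance: pd.DataFrame,
    highpass_s: float | None = 128.0,
    subject: int | str = "",
    hemisphere: str = "",
) -> BetaMap:
    """Per-voxel coefficient of the seed regressor in a GLM with the
    nuisance set, DCT high-pass and pooled AR(1) prewhitening."""
    n = run.n_volumes
    if len(seed_ts.values) != n or len(nuisance) != n:
        raise ValueError("seed/nuisance lengths must match run length")
    X = pd.concat(
        [pd.DataFrame({"seed": seed_ts.values}), nuisance.reset_index(drop=True)],
        axis=1,
    )
    X["constant"] = 1.0
    fit = fit_glm(run, X, tr_s=run.tr_s, highpass_s=highpass_s)
    beta = fit.beta_of("seed").reshape(run.shape3d)
    return BetaMap(
        VolumeImage(beta, run.affine),
        seed=seed_ts.name,
        subject=subject,
        hemisphere=hemisphere,
    )


def stream_strength(
    beta: BetaMap,
    parcellation: ParcellationVolume,
    streams: StreamTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean beta over all voxels of all parcels of each stream.

    Returns (stream_means, parcel_means); the stream mean is the
    voxel-count-weighted mean over its parcels.
    """
    if parcellation.label_data.shape != beta.volume.shape3d:
        raise ValueError("parcellation grid does not match beta map")
    data = beta.volume.data
    parcel_rows = []
    stream_rows = []
    for stream in ("dorsal", "ventral"):
        values = []
        for area in streams.areas(stream):
            vox = parcellation.voxels_of(area)
            if vox.size == 0:
                logger.warning("area %r empty; skipped", area)
                continue
            vals = data[tuple(vox.T)]
            parcel_rows.append(
                (beta.subject, beta.seed, beta.hemisphere, stream, area,
                 float(vals.mean()), len(vals))
            )
            values.append(vals)
        if not values:
            raise ValueError(f"stream {stream!r} has zero voxels")
        allv = np.concatenate(values)
        stream_rows.append(
            (beta.subject, beta.seed, beta.hemisphere, stream, float(allv.mean()))
        )
    stream_df = pd.DataFrame(
        stream_rows, columns=["subject", "seed", "hemisphere", "stream", "value"]
    )
    parcel_df = pd.DataFrame(
        parcel_rows,
        columns=["subject", "seed", "hemisphere", "stream", "area", "value", "n_voxels"],
    )
    return stream_df, parcel_df


def _check_balanced(df: pd.DataFrame, within: list[str], subject: str) -> None:
    cells = df.groupby([subject, *within], observed=True).size()
    levels = [df[w].nunique() for w in within]
    expected = int(np.prod(levels))
    per_subject = cells.groupby(level=0).size()
    missing = per_subject[per_subject != expected]
    if len(missing):
        raise ValueError(
            f"unbalanced within-subject layout; subjects with missing cells: "
            f"{missing.index.tolist()}"
        )
    for w in within:
        if df[w].nunique() < 2:
            raise ValueError(f"factor {w!r} has fewer than 2 levels")


def repeated_anova(
    table: pd.DataFrame,
    within: list[str] | None = None,
    dv: str = "value",
    subject: str = "subject",
) -> list[AnovaResult]:
    """Repeated-measures ANOVA over within-subject factors (balanced
    layout required), returning main effects and interactions."""
    if within is None:
        within = ["seed", "stream"]
    df = table.copy()
    # collapse replicate rows (e.g. hemispheres when not a factor)
    group_cols = [subject, *within]
    df = df.groupby(group_cols, observed=True, as_index=False)[dv].mean()
    _check_balanced(df, within, subject)
    # degenerate case: no within-subject variance at all -> every effect
    # SS is round-off; report F = 0, p = 1 rather than a 0/0 artefact
    centered = df[dv] - df.groupby(subject, observed=True)[dv].transform("mean")
    if np.abs(centered).max() <= 1e-12 * (1.0 + np.abs(df[dv]).max()):
        out = []
        n_sub = df[subject].nunique()
        levels = {w: df[w].nunique() for w in within}
        from itertools import combinations

        for r in range(1, len(within) + 1):
            for combo in combinations(within, r):
                df_num = float(np.prod([levels[w] - 1 for w in combo]))
                out.append(
                    AnovaResult(
                        effect=":".join(combo),
                        F=0.0,
                        df_num=df_num,
                        df_den=df_num * (n_sub - 1),
                        p=1.0,
                    )
                )
        return out
    res = AnovaRM(df, depvar=dv, subject=subject, within=within).fit()
    out = []
    for effect, row in res.anova_table.iterrows():
        F = float(row["F Value"])
        p = float(row["Pr > F"])
        if not np.isfinite(F):  # zero effect and zero error variance
            F, p = 0.0, 1.0
        out.append(
            AnovaResult(
                effect=str(effect),
                F=max(F, 0.0),
                df_num=float(row["Num DF"]),
                df_den=float(row["Den DF"]),
                p=float(min(max(p, 0.0), 1.0)) if np.isfinite(p) else 1.0,
            )
        )
    return out


def pairwise_interaction_anovas(
    table: pd.DataFrame,
    factor: str = "seed",
    other: str = "stream",
    dv: str = "value",
    subject: str = "subject",
) -> list[AnovaResult]:
    """Follow-up 2x2 interaction tests for every level pair of ``factor``,
    Bonferroni-corrected over the number of pairs."""
    levels = sorted(table[factor].unique())
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    out = []
    for a, b in pairs:
        sub = table[table[factor].isin([a, b])]
        res = repeated_anova(sub, within=[factor, other], dv=dv, subject=subject)
        inter = next(r for r in res if ":" in r.effect)
        out.append(
            AnovaResult(
                effect=f"{a}-vs-{b} x {other}",
                F=inter.F,
                df_num=inter.df_num,
                df_den=inter.df_den,
                p=min(inter.p * len(pairs), 1.0),
                correction="Bonferroni",
            )
        )
    return out


def screen_motion(motion: pd.DataFrame, threshold_mm: float = 3.0) -> bool:
    """Motion screening: False (exclude) when any translation parameter
    exceeds the threshold in absolute displacement."""
    trans = motion.iloc[:, :3].to_numpy(dtype=float)
    return bool(np.abs(trans).max() <= threshold_mm)


def _cluster_stats(
    t3d: np.ndarray, threshold: float, structure: np.ndarray
) -> tuple[np.ndarray, list[dict]]:
    supra = t3d > threshold
    labels, n = ndimage.label(supra, structure=structure)
    clusters = []
    for lab in range(1, n + 1):
        m = labels == lab
        mass = float(t3d[m].sum())
        peak_flat = np.flatnonzero(m.ravel() & (t3d.ravel() == t3d[m].max()))[0]
        clusters.append(
            {
                "label": lab,
                "size": int(m.sum()),
                "mass": mass,
                "peak_index": np.unravel_index(peak_flat, t3d.shape),
            }
        )
    return labels, clusters


def group_map(
    betas: list[BetaMap],
    betas_b: list[BetaMap] | None = None,
    cluster_p: float = 0.001,
    alpha: float = 0.05,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> tuple[VolumeImage, pd.DataFrame]:
    """Group-level one-sample (or paired-difference) t map with
    cluster-mass FWE inference by sign-flip permutation.

    Clusters are formed from contiguous voxels (26-connectivity) above the
    one-sided t threshold for ``cluster_p``; family-wise significance is
    assessed against the permutation distribution of the maximum cluster
    mass under per-subject sign flips.
    """
    if len(betas) < 2:
        raise ValueError("group analysis needs at least 2 subjects")
    stack = np.stack([b.volume.data for b in betas])
    if betas_b is not None:
        if len(betas_b) != len(betas):
            raise ValueError("paired contrast requires equal-length map lists")
        stack = stack - np.stack([b.volume.data for b in betas_b])
    n = stack.shape[0]
    shape3d = stack.shape[1:]
    affine = betas[0].volume.affine
    Y = stack.reshape(n, -1)

    sq_sum = (Y**2).sum(axis=0)

    def t_of(mean: np.ndarray) -> np.ndarray:
        var = (sq_sum / n - mean**2) * n / (n - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, mean / np.sqrt(var / n), 0.0)
        return t

    t_obs = t_of(Y.mean(axis=0))
    threshold = float(stats.t.ppf(1.0 - cluster_p, n - 1))
    structure = np.ones((3, 3, 3), dtype=bool)
    t3d = t_obs.reshape(shape3d)
    _, clusters = _cluster_stats(t3d, threshold, structure)

    rng = np.random.default_rng(rng_seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n))
    max_mass = np.zeros(n_perm)
    for p in range(n_perm):
        t_p = t_of((flips[p][:, None] * Y).mean(axis=0)).reshape(shape3d)
        _, cl = _cluster_stats(t_p, threshold, structure)
        if cl:
            max_mass[p] = max(c["mass"] for c in cl)

    rows = []
    for c in clusters:
        p_fwe = float((1 + (max_mass >= c["mass"]).sum()) / (1 + n_perm))
        peak_mm = (affine[:3, :3] @ np.asarray(c["peak_index"])) + affine[:3, 3]
        rows.append(
            {
                "peak_x_mm": float(peak_mm[0]),
                "peak_y_mm": float(peak_mm[1]),
                "peak_z_mm": float(peak_mm[2]),
                "size_voxels": c["size"],
                "mass": c["mass"],
                "p_fwe": p_fwe,
                "significant": p_fwe < alpha,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "peak_x_mm", "peak_y_mm", "peak_z_mm",
            "size_voxels", "mass", "p_fwe", "significant",
        ],
    )
    if len(table):
        table = table.sort_values("mass", ascending=False, ignore_index=True)
    return VolumeImage(t3d, affine), table
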