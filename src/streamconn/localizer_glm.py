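"""Block-design fMRI GLM: multi-echo combination, design construction,
high-pass + AR(1) prewhitened fitting, t contrasts, and peak seed selection.

The temporal model follows the common SPM-style conventions: task
square-waves convolved with the canonical double-gamma haemodynamic
response function and its temporal derivative (via nilearn, 16x microtime
oversampling), a discrete-cosine drift basis with periods above the
high-pass cutoff (default 128 s), and a single pooled first-order
autoregressive coefficient estimated from OLS residuals and removed by
prewhitening before the final fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from nilearn.glm.first_level import compute_regressor
from scipy import ndimage, stats

from .imaging_io import RoiMask, RoiSpec, VolumeImage, build_sphere_roi

logger = logging.getLogger(__name__)

__all__ = [
    "BlockDesign",
    "GlmFit",
    "SeedLocation",
    "combine_echoes",
    "build_design",
    "dct_drift_basis",
    "fit_glm",
    "contrast_map",
    "contrast_tstats",
    "localize_seed",
    "smooth_volume",
]


@dataclass
class BlockDesign:
    """Onsets/durations (seconds) per condition, plus nuisance events."""

    conditions: dict[str, tuple[np.ndarray, np.ndarray]]  # name -> (onsets, durations)
    nuisance_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    nuisance_duration_s: float = 0.5

    def __post_init__(self) -> None:
        for name, (onsets, durations) in self.conditions.items():
            onsets = np.asarray(onsets, dtype=float)
            durations = np.asarray(durations, dtype=float)
            if (durations <= 0).any():
                raise ValueError(f"condition {name!r}: durations must be > 0")
            order = np.argsort(onsets)
            onsets, durations = onsets[order], durations[order]
            if (onsets[1:] < onsets[:-1] + durations[:-1] - 1e-9).any():
                raise ValueError(f"condition {name!r}: overlapping blocks")
            self.conditions[name] = (onsets, durations)
        self.nuisance_onsets = np.asarray(self.nuisance_onsets, dtype=float)

    def validate_run(self, tr_s: float, n_volumes: int) -> None:
        run_s = tr_s * n_volumes
        for name, (onsets, durations) in self.conditions.items():
            if (onsets < 0).any() or (onsets + durations > run_s + 1e-9).any():
                raise ValueError(f"condition {name!r}: blocks outside run duration")


@dataclass
class GlmFit:
    """Prewhitened least-squares fit of a voxelwise GLM."""

    betas: np.ndarray          # (p, n_voxels)
    column_names: list[str]
    sigma2: np.ndarray         # (n_voxels,) residual variance
    ar1_rho: float
    dof: float
    xtx_inv: np.ndarray        # (p, p) of the whitened, filtered design
    shape3d: tuple[int, int, int] | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dof <= 0:
            raise ValueError("non-positive degrees of freedom")
        if not (-1.0 < self.ar1_rho < 1.0):
            raise ValueError("AR(1) rho outside (-1, 1)")

    def beta_of(self, name: str) -> np.ndarray:
        return self.betas[self.column_names.index(name)]


@dataclass
class SeedLocation:
    """Peak-activation coordinate for a localizer seed region."""

    name: str
    hemisphere: str
    coord_mm: tuple[float, float, float]
    peak_stat: float
    voxel_index: tuple[int, int, int] | None = None


def combine_echoes(
    echoes: list[VolumeImage], te_ms: list[float], n_est: int = 30
) -> VolumeImage:
    """Weighted multi-echo combination.

    Per-voxel weights are proportional to TE_n * tSNR_n, with tSNR
    (mean / SD over time) estimated from the first ``n_est`` volumes, then
    normalized to sum to one and applied to the whole timeseries. Voxels
    with zero variance in the estimation window fall back to
    TE-proportional weights.
    """
    if len(echoes) < 2:
        raise ValueError("echo combination requires at least 2 echoes")
    if len(te_ms) != len(echoes):
        raise ValueError("te_ms length must match number of echoes")
    shapes = {e.data.shape for e in echoes}
    if len(shapes) != 1:
        raise ValueError("all echoes must share the same grid and length")
    first = echoes[0]
    if first.data.ndim != 4:
        raise ValueError("echoes must be 4D timeseries")
    n_est = min(n_est, first.n_volumes)
    te = np.asarray(te_ms, dtype=float)

    weights = []
    for e, t in zip(echoes, te):
        window = e.data[..., :n_est].astype(float)
        sd = window.std(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tsnr = np.where(sd > 0, window.mean(axis=-1) / sd, np.nan)
        weights.append(t * tsnr)
    w = np.stack(weights)  # (n_echo, x, y, z)
    bad = ~np.isfinite(w).all(axis=0)
    if bad.any():
        logger.info(
            "echo combination: %d voxel(s) with zero variance, using "
            "TE-proportional weights there",
            int(bad.sum()),
        )
        w[:, bad] = te[:, None]
    total = w.sum(axis=0)
    degenerate = total <= 0
    if degenerate.any():
        w[:, degenerate] = te[:, None]
        total = w.sum(axis=0)
    w /= total
    combined = sum(
        wi[..., None] * e.data.astype(float) for wi, e in zip(w, echoes)
    )
    return VolumeImage(combined, first.affine, tr_s=first.tr_s)


def _condition_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    frame_times: np.ndarray,
    name: str,
    derivative: bool,
) -> tuple[np.ndarray, list[str]]:
    cond = (
        np.asarray(onsets, dtype=float),
        np.asarray(durations, dtype=float),
        np.ones(len(onsets)),
    )
    model = "spm + derivative" if derivative else "spm"
    reg, names = compute_regressor(
        cond, model, frame_times, con_id=name, oversampling=16
    )
    return reg, list(names)


def build_design(
    design: BlockDesign,
    tr_s: float,
    n_volumes: int,
    motion: pd.DataFrame | None = None,
    add_constant: bool = True,
) -> pd.DataFrame:
    """Assemble the first-level design matrix.

    Columns: one HRF-convolved regressor plus its temporal derivative per
    condition, an HRF-convolved button-press regressor when nuisance
    events exist, six rigid-body motion parameters and their first-order
    temporal differences (backward difference, first row zero), and a
    constant.
    """
    design.validate_run(tr_s, n_volumes)
    frame_times = np.arange(n_volumes) * tr_s
    cols: dict[str, np.ndarray] = {}
    for name, (onsets, durations) in design.conditions.items():
        if len(onsets) == 0:
            logger.warning("condition %r has no blocks; skipped", name)
            continue
        reg, names = _condition_regressor(onsets, durations, frame_times, name, True)
        for j, n in enumerate(names):
            cols[n] = reg[:, j]
    if not cols:
        logger.warning("design has no task columns; nuisance-only model")
    if design.nuisance_onsets.size:
        reg, _ = _condition_regressor(
            design.nuisance_onsets,
            np.full(design.nuisance_onsets.size, design.nuisance_duration_s),
            frame_times,
            "button_press",
            False,
        )
        cols["button_press"] = reg[:, 0]
    if motion is not None:
        if len(motion) != n_volumes:
            raise ValueError(
                f"motion table has {len(motion)} rows, expected {n_volumes}"
            )
        if motion.shape[1] != 6:
            raise ValueError("motion table must have 6 columns")
        for c in motion.columns:
            vals = motion[c].to_numpy(dtype=float)
            cols[str(c)] = vals
            d = np.zeros_like(vals)
            d[1:] = np.diff(vals)
            cols[f"{c}_derivative"] = d
    if add_constant:
        cols["constant"] = np.ones(n_volumes)
    X = pd.DataFrame(cols)
    task = [c for c in X.columns if c not in ("constant",)]
    for c in task:
        if np.allclose(X[c].to_numpy(), X[c].iloc[0]):
            logger.warning("design column %r is constant; possible collinearity", c)
    return X


def dct_drift_basis(n_volumes: int, tr_s: float, highpass_s: float) -> np.ndarray:
    """Discrete-cosine drift basis with periods longer than the cutoff
    (constant term excluded)."""
    n_basis = int(np.floor(2.0 * n_volumes * tr_s / highpass_s))
    t = np.arange(n_volumes)
    cols = [
        np.sqrt(2.0 / n_volumes)
        * np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_volumes))
        for k in range(1, n_basis + 1)
    ]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.stack(cols, axis=1)


def _as_2d(Y: VolumeImage | np.ndarray) -> tuple[np.ndarray, tuple | None, np.ndarray | None]:
    if isinstance(Y, VolumeImage):
        if Y.data.ndim != 4:
            raise ValueError("GLM expects a 4D timeseries")
        shape3d = Y.shape3d
        return (
            Y.data.reshape(-1, Y.data.shape[3]).T.astype(float),
            shape3d,
            Y.affine,
        )
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y, None, None


def _name_collinear(Xf: np.ndarray, names: list[str]) -> list[str]:
    _, R = np.linalg.qr(Xf)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xf.shape) * np.finfo(float).eps
    return [n for n, d in zip(names, diag) if d < max(tol, 1e-10)]


def fit_glm(
    Y: VolumeImage | np.ndarray,
    X: pd.DataFrame,
    tr_s: float | None = None,
    highpass_s: float | None = 128.0,
    prewhiten: bool = True,
) -> GlmFit:
    """Mass-univariate GLM with DCT high-pass and pooled AR(1) prewhitening.

    The drift basis is projected out of both data and design, an OLS fit
    provides residuals from which a single pooled lag-1 autocorrelation is
    estimated, and data and design are prewhitened before the final fit.
    """
    Y2d, shape3d, affine = _as_2d(Y)
    if isinstance(Y, VolumeImage) and tr_s is None:
        tr_s = Y.tr_s
    n = Y2d.shape[0]
    if len(X) != n:
        raise ValueError(f"design has {len(X)} rows, data has {n} volumes")
    names = [str(c) for c in X.columns]
    Xm = X.to_numpy(dtype=float)

    n_drift = 0
    if highpass_s is not None and highpass_s > 0:
        if tr_s is None:
            raise ValueError("tr_s required for high-pass filtering")
        D = dct_drift_basis(n, tr_s, highpass_s)
        n_drift = D.shape[1]
        if n_drift:
            # residual-forming projection (idempotent); DCT columns are
            # zero-mean, so a constant regressor passes through untouched
            coefY, *_ = np.linalg.lstsq(D, Y2d, rcond=None)
            Y2d = Y2d - D @ coefY
            coefX, *_ = np.linalg.lstsq(D, Xm, rcond=None)
            Xm = Xm - D @ coefX

    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        raise ValueError(
            f"design is rank deficient; suspect columns: {_name_collinear(Xm, names)}"
        )

    beta, *_ = np.linalg.lstsq(Xm, Y2d, rcond=None)
    resid = Y2d - Xm @ beta
    rho = 0.0
    if prewhiten and n > 2:
        num = float((resid[1:] * resid[:-1]).sum())
        den = float((resid**2).sum())
        rho = num / den if den > 0 else 0.0
        rho = float(np.clip(rho, -0.99, 0.99))
        if abs(rho) > 1e-12:
            Yw = np.empty_like(Y2d)
            Xw = np.empty_like(Xm)
            scale = np.sqrt(1.0 - rho**2)
            Yw[0] = scale * Y2d[0]
            Xw[0] = scale * Xm[0]
            Yw[1:] = Y2d[1:] - rho * Y2d[:-1]
            Xw[1:] = Xm[1:] - rho * Xm[:-1]
            beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
            resid = Yw - Xw @ beta
            Xm = Xw

    dof = n - rank - n_drift
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.pinv(Xm.T @ Xm)
    return GlmFit(
        betas=beta,
        column_names=names,
        sigma2=sigma2,
        ar1_rho=rho,
        dof=dof,
        xtx_inv=xtx_inv,
        shape3d=shape3d,
        affine=affine,
    )


def _contrast_vector(fit: GlmFit, weights) -> np.ndarray:
    if isinstance(weights, dict):
        c = np.zeros(len(fit.column_names))
        for name, w in weights.items():
            if name not in fit.column_names:
                raise ValueError(f"unknown design column {name!r}")
            c[fit.column_names.index(name)] = w
        return c
    c = np.asarray(weights, dtype=float)
    if c.size != len(fit.column_names):
        raise ValueError("contrast weight length must equal column count")
    return c


def contrast_tstats(fit: GlmFit, weights) -> np.ndarray:
    """Per-voxel t statistics for a contrast of design columns."""
    c = _contrast_vector(fit, weights)
    effect = c @ fit.betas
    var = fit.sigma2 * float(c @ fit.xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, effect / np.sqrt(var), np.sign(effect) * np.inf)
    n_inf = int(np.isinf(t).sum())
    if n_inf:
        logger.info("contrast: %d voxel(s) with zero residual variance", n_inf)
    t = np.where((var <= 0) & (effect == 0), 0.0, t)
    return t


def contrast_map(fit: GlmFit, weights) -> VolumeImage:
    """Contrast t map as a volume (requires a fit from a VolumeImage)."""
    if fit.shape3d is None or fit.affine is None:
        raise ValueError("fit carries no spatial grid; use contrast_tstats")
    t = contrast_tstats(fit, weights)
    return VolumeImage(t.reshape(fit.shape3d), fit.affine)


def localize_seed(
    tmap: VolumeImage,
    search: RoiSpec,
    name: str | None = None,
    hemisphere: str | None = None,
) -> SeedLocation:
    """Most significantly activated voxel within a spherical search region.

    Ties are broken by the lexicographically smallest voxel index.
    """
    mask = build_sphere_roi(search, tmap.affine, tmap.shape3d)
    vals = tmap.data[tuple(mask.voxel_indices.T)].astype(float)
    finite = np.isfinite(vals) | np.isposinf(vals)
    if not np.any(~np.isnan(vals)):
        raise ValueError(f"search region {search.name!r} contains only NaN values")
    vals = np.where(np.isnan(vals), -np.inf, vals)
    best = int(np.argmax(vals))  # argmax returns the first (lexicographic) max
    ijk = tuple(int(v) for v in mask.voxel_indices[best])
    coord = tmap.voxel_to_world(np.asarray(ijk))[0]
    hemi = hemisphere if hemisphere is not None else ("left" if coord[0] < 0 else "right")
    return SeedLocation(
        name=name or search.name,
        hemisphere=hemi,
        coord_mm=tuple(float(v) for v in coord),
        peak_stat=float(vals[best]),
        voxel_index=ijk,
    )


def smooth_volume(vol: VolumeImage, fwhm_mm: float = 6.0) -> VolumeImage:
    """Isotropic Gaussian smoothing parameterized by FWHM in millimetres."""
    if fwhm_mm <= 0:
        return VolumeImage(vol.data.copy(), vol.affine, vol.tr_s)
    voxel_sizes = np.sqrt((vol.affine[:3, :3] ** 2).sum(axis=0))
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_sizes
    data = vol.data.astype(float)
    if data.ndim == 3:
        out = ndimage.gaussian_filter(data, sigma=sigma_vox)
    else:
        out = np.stack(
            [
                ndimage.gaussian_filter(data[..., t], sigma=sigma_vox)
                for t in range(data.shape[3])
            ],
            axis=-1,
        )
    return VolumeImage(out, vol.affine, vol.tr_s)


def cluster_forming_threshold(dof: float, p: float = 0.001) -> float:
    """One-sided Student-t threshold for cluster formation."""
    return float(stats.t.ppf(1.0 - p, dof))
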