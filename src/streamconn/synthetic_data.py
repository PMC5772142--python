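"""Synthetic multi-subject cohorts with known ground truth.

The generator emulates, at desk scale, the data layout of a body-area
connectivity study: per-subject resting-state runs whose voxel timeseries
load onto two latent "network" signals (dorsal and ventral), localizer
runs with planted block activations at the seed sites, motion and
compartment confounds, a toy dorsal/ventral parcellation, and streamline
path-count tables with planted dorsal:ventral rate ratios.

Every generator derives its random stream from ``rng_seed`` via
``numpy.random.SeedSequence`` spawn keys ``(kind, subject)``, so each run
is individually reproducible and independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .imaging_io import (
    ParcellationVolume,
    RoiSpec,
    StreamTable,
    VolumeImage,
    build_sphere_roi,
    load_stream_table,
)
from .localizer_glm import BlockDesign, _condition_regressor

__all__ = [
    "SeedSite",
    "SyntheticCohortConfig",
    "default_seed_sites",
    "make_parcellation",
    "compartment_masks",
    "generate_rest_run",
    "generate_localizer_run",
    "make_block_design",
    "generate_tract_counts",
    "simulate_stream_strengths",
    "ar1_series",
    "RestRun",
    "LocalizerRun",
]

_KIND_REST, _KIND_LOC, _KIND_TRACT, _KIND_MISC = 0, 1, 2, 3


@dataclass(frozen=True)
class SeedSite:
    """A planted seed region with its couplings onto the latent networks."""

    name: str
    hemisphere: str
    center_mm: tuple[float, float, float]
    loading_dorsal: float
    loading_ventral: float


def default_seed_sites() -> list[SeedSite]:
    """Six seed sites (three per hemisphere) with graded dorsal affinity:
    the EBA-like site loads most strongly on the dorsal network, the
    FBA-like site on the ventral network, the LOC-like site in between."""
    base = [
        ("EBA", (16.0, -18.0, 8.0), 0.8, 0.4),
        ("LOC", (12.0, -22.0, -6.0), 0.6, 0.6),
        ("FBA", (14.0, 8.0, -10.0), 0.4, 0.8),
    ]
    sites = []
    for name, (x, y, z), ld, lv in base:
        sites.append(SeedSite(name, "left", (-x, y, z), ld, lv))
        sites.append(SeedSite(name, "right", (x, y, z), ld, lv))
    return sites


@dataclass
class SyntheticCohortConfig:
    """Study conditions for a synthetic cohort (desk-scale defaults)."""

    n_subjects: int = 8
    grid_shape: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: float = 2.0
    tr_s: float = 2.0
    n_volumes: int = 200
    seed_sites: list[SeedSite] = field(default_factory=default_seed_sites)
    site_radius_mm: float = 4.0
    parcel_loading: float = 0.7
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    motion_amplitude_mm: float = 0.3
    motion_gain: float = 0.5
    compartment_gain: float = 1.0
    localizer_n_volumes: int = 150
    localizer_amplitude: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ValueError("ar1_rho must be in [0, 1)")
        for s in self.seed_sites:
            if not np.isfinite([s.loading_dorsal, s.loading_ventral]).all():
                raise ValueError(f"non-finite loading for site {s.name}")

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[0, 0] = A[1, 1] = A[2, 2] = self.voxel_size_mm
        A[:3, 3] = -(np.asarray(self.grid_shape) - 1) / 2.0 * self.voxel_size_mm
        return A

    def rng(self, kind: int, subject: int = 0) -> np.random.Generator:
        ss = np.random.SeedSequence(self.rng_seed, spawn_key=(kind, subject))
        return np.random.default_rng(ss)


def ar1_series(
    rng: np.random.Generator, n: int, rho: float, size: int = 1
) -> np.ndarray:
    """Stationary unit-variance AR(1) processes, shape (size, n)."""
    innov = rng.standard_normal((size, n))
    out = np.empty_like(innov)
    out[:, 0] = innov[:, 0]
    scale = np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        out[:, t] = rho * out[:, t - 1] + scale * innov[:, t]
    return out


def compartment_masks(cfg: SyntheticCohortConfig) -> dict[str, np.ndarray]:
    """Fixed geometric compartments: an ellipsoidal brain, a central
    white-matter core, a small CSF box, and the out-of-brain remainder."""
    nx, ny, nz = cfg.grid_shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    c = (np.asarray(cfg.grid_shape) - 1) / 2.0
    r = np.asarray(cfg.grid_shape) / 2.0 - 1.0
    ell = (
        ((ii - c[0]) / r[0]) ** 2
        + ((jj - c[1]) / r[1]) ** 2
        + ((kk - c[2]) / r[2]) ** 2
    )
    brain = ell <= 1.0
    wm = ell <= 0.15
    csf = (
        (np.abs(ii - c[0]) <= 1) & (np.abs(jj - (c[1] + 4)) <= 1) & (np.abs(kk - c[2]) <= 1)
    ) & brain & ~wm
    return {
        "brain": brain,
        "white_matter": wm,
        "csf": csf,
        "out_of_brain": ~brain,
    }


def make_parcellation(
    cfg: SyntheticCohortConfig, streams: StreamTable | None = None
) -> ParcellationVolume:
    """Toy dorsal/ventral parcellation: each stream area becomes a small
    cube, dorsal areas in the superior half of the grid, ventral areas in
    the inferior half, laid out on a deterministic lattice."""
    if streams is None:
        streams = load_stream_table()
    nx, ny, nz = cfg.grid_shape
    labels = np.zeros(cfg.grid_shape, dtype=np.int32)
    label_map: dict[int, str] = {}
    comp = compartment_masks(cfg)
    next_label = 1
    for stream, z0 in (("dorsal", int(nz * 0.70)), ("ventral", int(nz * 0.22))):
        areas = streams.areas(stream)
        n_cols = max(4, int(np.ceil(np.sqrt(len(areas)))))
        for idx, area in enumerate(areas):
            gx = 3 + (idx % n_cols) * max(3, (nx - 6) // n_cols)
            gy = 3 + (idx // n_cols) * max(3, (ny - 6) // n_cols)
            gx = min(gx, nx - 3)
            gy = min(gy, ny - 3)
            block = np.zeros(cfg.grid_shape, dtype=bool)
            block[gx : gx + 2, gy : gy + 2, z0 : z0 + 2] = True
            block &= labels == 0
            if not block.any():  # fall back to a single free voxel
                free = np.argwhere((labels == 0) & comp["brain"])
                block[tuple(free[0])] = True
            labels[block] = next_label
            label_map[next_label] = area
            next_label += 1
    return ParcellationVolume(labels, cfg.affine, label_map)


def _loading_maps(
    cfg: SyntheticCohortConfig,
    parcellation: ParcellationVolume | None,
    streams: StreamTable | None,
) -> tuple[np.ndarray, np.ndarray]:
    Ld = np.zeros(cfg.grid_shape)
    Lv = np.zeros(cfg.grid_shape)
    for site in cfg.seed_sites:
        spec = RoiSpec(site.name, site.center_mm, cfg.site_radius_mm)
        mask = build_sphere_roi(spec, cfg.affine, cfg.grid_shape)
        ix = tuple(mask.voxel_indices.T)
        Ld[ix] = site.loading_dorsal
        Lv[ix] = site.loading_ventral
    if parcellation is not None:
        if streams is None:
            streams = load_stream_table()
        for area in streams.areas("dorsal"):
            vox = parcellation.voxels_of(area)
            Ld[tuple(vox.T)] = cfg.parcel_loading
        for area in streams.areas("ventral"):
            vox = parcellation.voxels_of(area)
            Lv[tuple(vox.T)] = cfg.parcel_loading
    return Ld, Lv


@dataclass
class RestRun:
    volume: VolumeImage
    motion: pd.DataFrame
    compartments: dict[str, np.ndarray]
    ground_truth: dict


@dataclass
class LocalizerRun:
    volume: VolumeImage
    events: pd.DataFrame
    motion: pd.DataFrame
    ground_truth: dict


def _motion_table(
    rng: np.random.Generator, n: int, amplitude: float
) -> pd.DataFrame:
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    steps = rng.standard_normal((n, 6)) * amplitude / np.sqrt(max(n, 1))
    walk = np.cumsum(steps, axis=0)
    return pd.DataFrame(walk, columns=cols)


def generate_rest_run(
    cfg: SyntheticCohortConfig,
    subject: int,
    parcellation: ParcellationVolume | None = None,
    streams: StreamTable | None = None,
) -> RestRun:
    """One subject's resting-state run.

    Voxel timeseries are a sum of loading-weighted latent network signals
    (independent unit-variance AR(1) processes for the dorsal and ventral
    networks), compartment nuisance signals, a motion-coupled confound,
    and AR(1) Gaussian noise.
    """
    rng = cfg.rng(_KIND_REST, subject)
    n = cfg.n_volumes
    latents = ar1_series(rng, n, cfg.ar1_rho, size=2)
    z_dorsal, z_ventral = latents
    comp = compartment_masks(cfg)
    comp_signals = {
        name: ar1_series(rng, n, cfg.ar1_rho, size=1)[0]
        for name in ("white_matter", "csf", "out_of_brain")
    }
    motion = _motion_table(rng, n, cfg.motion_amplitude_mm)

    Ld, Lv = _loading_maps(cfg, parcellation, streams)
    data = (
        Ld[..., None] * z_dorsal
        + Lv[..., None] * z_ventral
    )
    for name, sig in comp_signals.items():
        data = data + cfg.compartment_gain * comp[name][..., None] * sig
    motion_conf = cfg.motion_gain * motion.to_numpy().sum(axis=1)
    data = data + comp["brain"][..., None] * motion_conf
    noise = ar1_series(rng, n, cfg.ar1_rho, size=int(np.prod(cfg.grid_shape)))
    data = data + cfg.noise_sd * noise.reshape(*cfg.grid_shape, n)

    gt = {
        "subject": subject,
        "seed_sites": [asdict(s) for s in cfg.seed_sites],
        "latent_ar1_rho": cfg.ar1_rho,
        "noise_sd": cfg.noise_sd,
        "latents": {"dorsal": z_dorsal.tolist(), "ventral": z_ventral.tolist()},
    }
    vol = VolumeImage(data, cfg.affine, tr_s=cfg.tr_s)
    return RestRun(vol, motion, comp, gt)


def make_block_design(
    cfg: SyntheticCohortConfig,
    conditions: tuple[str, ...] = ("bodies", "objects", "scrambled"),
    block_s: float = 16.0,
    rest_s: float = 8.0,
) -> BlockDesign:
    """Interleaved block design cycling through the conditions, separated
    by rest, fitted to the localizer run duration."""
    run_s = cfg.localizer_n_volumes * cfg.tr_s
    onsets: dict[str, list[float]] = {c: [] for c in conditions}
    t = rest_s
    i = 0
    while t + block_s <= run_s - 1e-9:
        onsets[conditions[i % len(conditions)]].append(t)
        t += block_s + rest_s
        i += 1
    return BlockDesign(
        conditions={
            c: (np.asarray(v), np.full(len(v), block_s)) for c, v in onsets.items()
        }
    )


def default_localizer_amplitudes(cfg: SyntheticCohortConfig) -> dict[str, dict[str, float]]:
    """Planted per-site condition amplitudes: body-selective sites respond
    to bodies > objects, the object-selective site to objects > scrambled."""
    a = cfg.localizer_amplitude
    return {
        "EBA": {"bodies": a, "objects": a / 3.0, "scrambled": a / 6.0},
        "FBA": {"bodies": a, "objects": a / 3.0, "scrambled": a / 6.0},
        "LOC": {"bodies": a / 3.0, "objects": a, "scrambled": a / 6.0},
    }


def generate_localizer_run(
    cfg: SyntheticCohortConfig,
    subject: int,
    design: BlockDesign | None = None,
    amplitudes: dict[str, dict[str, float]] | None = None,
) -> LocalizerRun:
    """One subject's localizer run with planted block activations.

    Condition-specific amplitudes are added at the seed sites after
    convolution with the same canonical HRF the analysis uses.
    """
    rng = cfg.rng(_KIND_LOC, subject)
    n = cfg.localizer_n_volumes
    if design is None:
        design = make_block_design(cfg)
    design.validate_run(cfg.tr_s, n)
    if amplitudes is None:
        amplitudes = default_localizer_amplitudes(cfg)
    frame_times = np.arange(n) * cfg.tr_s
    regressors = {}
    for cond, (onsets, durations) in design.conditions.items():
        if len(onsets) == 0:
            continue
        reg, _ = _condition_regressor(onsets, durations, frame_times, cond, False)
        regressors[cond] = reg[:, 0]

    data = cfg.noise_sd * rng.standard_normal((*cfg.grid_shape, n))
    gt_amp: dict[str, dict[str, float]] = {}
    for site in cfg.seed_sites:
        amps = amplitudes.get(site.name, {})
        spec = RoiSpec(site.name, site.center_mm, cfg.site_radius_mm)
        mask = build_sphere_roi(spec, cfg.affine, cfg.grid_shape)
        ix = tuple(mask.voxel_indices.T)
        signal = np.zeros(n)
        for cond, amp in amps.items():
            if cond in regressors:
                signal = signal + amp * regressors[cond]
        data[ix] += signal
        gt_amp[f"{site.hemisphere}_{site.name}"] = dict(amps)

    events = pd.DataFrame(
        [
            (cond, float(o), float(d))
            for cond, (onsets, durations) in design.conditions.items()
            for o, d in zip(onsets, durations)
        ],
        columns=["trial_type", "onset", "duration"],
    ).sort_values("onset", ignore_index=True)
    motion = _motion_table(rng, n, cfg.motion_amplitude_mm)
    gt = {
        "subject": subject,
        "amplitudes": gt_amp,
        "seed_sites": [asdict(s) for s in cfg.seed_sites],
    }
    vol = VolumeImage(data, cfg.affine, tr_s=cfg.tr_s)
    return LocalizerRun(vol, events, motion, gt)


def default_tract_rates() -> dict[str, tuple[float, float]]:
    """Planted (dorsal, ventral) reach rates. All seeds reach the ventral
    target more often in absolute terms, but the dorsal:ventral ratio is
    graded EBA > LOC > FBA."""
    return {
        "EBA": (0.10, 0.15),
        "LOC": (0.06, 0.18),
        "FBA": (0.03, 0.22),
    }


def generate_tract_counts(
    n_subjects: int = 8,
    rates: dict[str, tuple[float, float]] | None = None,
    total: int = 5000,
    hemispheres: tuple[str, ...] = ("left", "right"),
    subject_sd: float = 0.2,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Streamline path-count tables with planted dorsal/ventral rates.

    Counts are drawn multinomially over {dorsal, ventral, lost} per
    (subject, seed, hemisphere). ``subject_sd`` is the SD of a lognormal
    per-subject rate multiplier creating between-subject variance.
    """
    if rates is None:
        rates = default_tract_rates()
    if total < 1:
        raise ValueError("total must be >= 1")
    for seed, (rd, rv) in rates.items():
        if rd < 0 or rv < 0:
            raise ValueError(f"rates for {seed} must be >= 0")
        if rd + rv > 1:
            raise ValueError(f"rates for {seed} sum above 1")
    rng = np.random.default_rng(
        np.random.SeedSequence(rng_seed, spawn_key=(_KIND_TRACT,))
    )
    rows = []
    for subject in range(n_subjects):
        for seed, (rd, rv) in rates.items():
            for hemi in hemispheres:
                mult = rng.lognormal(mean=0.0, sigma=subject_sd, size=2)
                pd_, pv = rd * mult[0], rv * mult[1]
                scale = pd_ + pv
                if scale > 0.95:  # keep a 'lost' bin
                    pd_, pv = pd_ * 0.95 / scale, pv * 0.95 / scale
                counts = rng.multinomial(total, [pd_, pv, 1.0 - pd_ - pv])
                for stream, c in zip(("dorsal", "ventral"), counts[:2]):
                    rows.append((subject, seed, hemi, stream, int(c), total))
    return pd.DataFrame(
        rows, columns=["subject", "seed", "hemisphere", "stream", "count", "total"]
    )


def simulate_stream_strengths(
    n_subjects: int = 16,
    cell_means: dict[tuple[str, str], float] | None = None,
    noise_sd: float = 0.05,
    hemispheres: tuple[str, ...] = ("left",),
    rng_seed: int = 0,
) -> pd.DataFrame:
    """ROI-level connectivity-strength tables with a planted seed x stream
    interaction (the EBA-like seed shifted dorsal), as a fast stand-in for
    running the voxelwise pipeline when only the ANOVA stage is exercised.
    """
    if cell_means is None:
        cell_means = {
            ("EBA", "dorsal"): 0.30,
            ("EBA", "ventral"): 0.20,
            ("LOC", "dorsal"): 0.18,
            ("LOC", "ventral"): 0.22,
            ("FBA", "dorsal"): 0.10,
            ("FBA", "ventral"): 0.25,
        }
    rng = np.random.default_rng(
        np.random.SeedSequence(rng_seed, spawn_key=(_KIND_MISC,))
    )
    rows = []
    for subject in range(n_subjects):
        subj_shift = rng.normal(0.0, noise_sd)
        for hemi in hemispheres:
            for (seed, stream), mu in cell_means.items():
                rows.append(
                    (
                        subject,
                        seed,
                        hemi,
                        stream,
                        mu + subj_shift + rng.normal(0.0, noise_sd),
                    )
                )
    return pd.DataFrame(
        rows, columns=["subject", "seed", "hemisphere", "stream", "value"]
    )
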