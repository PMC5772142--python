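"""Pipeline configuration and the end-to-end driver.

The driver runs the full synthetic-cohort analysis — simulate, localize,
connect, fingerprint, classify, tract — writing every stage's outputs as
NIfTI/TSV/JSON under a run directory together with a provenance manifest
(config hash, package version, seed, stage outputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imaging_io import (
    ParcellationVolume,
    RoiSpec,
    StreamTable,
    VolumeImage,
    build_sphere_roi,
    load_stream_table,
    read_volume,
    write_volume,
)
from .localizer_glm import BlockDesign, build_design, contrast_map, fit_glm, localize_seed
from .rs_connectivity import (
    build_nuisance,
    first_eigenvariate,
    pairwise_interaction_anovas,
    repeated_anova,
    screen_motion,
    seed_beta_map,
    stream_strength,
)
from .fingerprint_stats import (
    arm_attribution,
    extract_fingerprint,
    fingerprint_permutation_test,
    fingerprints_to_frame,
)
from .stream_classifier import (
    ClassificationQuery,
    build_training_set,
    compare_outcomes,
    dorsal_probabilities,
    flatten_beta_map,
    k_sweep,
)
from .synthetic_data import (
    SyntheticCohortConfig,
    generate_localizer_run,
    generate_rest_run,
    generate_tract_counts,
    make_block_design,
    make_parcellation,
)
from .tract_strength import pairwise_stream_ttests, strength, tract_anova

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "localize", "connect", "fingerprint", "classify", "tract")

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their standard defaults:
    4 mm ROI spheres, 128 s high-pass, 6 mm FWHM smoothing for group
    maps, 5000 permutations, k from 2 to 8, 20 boundary seed voxels, and
    a 3 mm motion-exclusion threshold."""

    n_subjects: int = 8
    grid_shape: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: float = 2.0
    tr_s: float = 2.0
    n_volumes: int = 200
    localizer_n_volumes: int = 150
    sphere_radius_mm: float = 4.0
    search_radius_mm: float = 15.0
    highpass_s: float = 128.0
    smoothing_fwhm_mm: float = 6.0
    n_perm: int = 5000
    k_min: int = 2
    k_max: int = 8
    boundary_n: int = 20
    motion_threshold_mm: float = 3.0
    tract_total: int = 5000
    # optional override: [name, hemisphere, x, y, z, loading_dorsal,
    # loading_ventral] per site; defaults to the packaged six-site layout
    seed_sites: list | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        for name in (
            "sphere_radius_mm", "search_radius_mm", "highpass_s",
            "motion_threshold_mm", "tr_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (1 <= self.k_min <= self.k_max):
            raise ValueError("invalid k range")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def cohort(self) -> SyntheticCohortConfig:
        kwargs = {}
        if self.seed_sites is not None:
            from .synthetic_data import SeedSite

            kwargs["seed_sites"] = [
                SeedSite(str(n), str(h), (float(x), float(y), float(z)),
                         float(ld), float(lv))
                for n, h, x, y, z, ld, lv in self.seed_sites
            ]
        return SyntheticCohortConfig(
            n_subjects=self.n_subjects,
            grid_shape=self.grid_shape,
            voxel_size_mm=self.voxel_size_mm,
            tr_s=self.tr_s,
            n_volumes=self.n_volumes,
            localizer_n_volumes=self.localizer_n_volumes,
            site_radius_mm=self.sphere_radius_mm,
            rng_seed=self.rng_seed,
            **kwargs,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def _plain_dict(self) -> dict:
        def plain(v):
            if isinstance(v, tuple):
                return [plain(x) for x in v]
            if isinstance(v, list):
                return [plain(x) for x in v]
            return v

        return {k: plain(v) for k, v in asdict(self).items()}

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self._plain_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        payload = yaml.safe_dump(self._plain_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sub_dir(out: Path, subject: int) -> Path:
    d = out / f"sub-{subject:02d}"
    d.mkdir(parents=True, exist_ok=True)
    return d


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _stage_simulate(cfg: PipelineConfig, out: Path) -> list[str]:
    cohort = cfg.cohort()
    streams = load_stream_table()
    parcellation = make_parcellation(cohort, streams)
    outputs = []
    write_volume(
        VolumeImage(parcellation.label_data.astype(np.int16), parcellation.affine),
        out / "parcellation.nii.gz",
    )
    labels_df = pd.DataFrame(
        sorted(parcellation.label_map.items()), columns=["label", "area_name"]
    )
    _write_tsv(labels_df, out / "parcel_labels.tsv")
    outputs += ["parcellation.nii.gz", "parcel_labels.tsv"]

    gt_all = {}
    for s in range(cfg.n_subjects):
        sub = _sub_dir(out, s)
        rest = generate_rest_run(cohort, s, parcellation=parcellation, streams=streams)
        write_volume(rest.volume, sub / "rest.nii.gz")
        _write_tsv(rest.motion, sub / "rest_motion.tsv")
        for name, m in rest.compartments.items():
            write_volume(
                VolumeImage(m.astype(np.uint8), cohort.affine), sub / f"mask_{name}.nii.gz"
            )
        loc = generate_localizer_run(cohort, s)
        write_volume(loc.volume, sub / "localizer.nii.gz")
        _write_tsv(loc.events, sub / "events.tsv")
        _write_tsv(loc.motion, sub / "localizer_motion.tsv")
        gt_all[str(s)] = {
            "rest": {k: v for k, v in rest.ground_truth.items() if k != "latents"},
            "localizer": loc.ground_truth,
        }
    counts = generate_tract_counts(
        n_subjects=cfg.n_subjects, total=cfg.tract_total, rng_seed=cfg.rng_seed
    )
    _write_tsv(counts, out / "tract_counts.tsv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt_all, fh, indent=1)
    outputs += ["tract_counts.tsv", "ground_truth.json", "sub-*/"]
    return outputs


def _load_events(path: Path) -> BlockDesign:
    df = pd.read_csv(path, sep="\t")
    conditions = {}
    for cond, grp in df.groupby("trial_type"):
        conditions[str(cond)] = (
            grp["onset"].to_numpy(float),
            grp["duration"].to_numpy(float),
        )
    return BlockDesign(conditions=conditions)


def _stage_localize(cfg: PipelineConfig, out: Path) -> list[str]:
    cohort = cfg.cohort()
    contrasts = {
        "EBA": ("bodies", "objects"),
        "FBA": ("bodies", "objects"),
        "LOC": ("objects", "scrambled"),
    }
    rows = []
    for s in range(cfg.n_subjects):
        sub = _sub_dir(out, s)
        run = read_volume(sub / "localizer.nii.gz", expect_4d=True)
        design = _load_events(sub / "events.tsv")
        motion = pd.read_csv(sub / "localizer_motion.tsv", sep="\t")
        X = build_design(design, cfg.tr_s, run.n_volumes, motion)
        fit = fit_glm(run, X, tr_s=cfg.tr_s, highpass_s=cfg.highpass_s)
        for site in cohort.seed_sites:
            pos, neg = contrasts[site.name]
            tmap = contrast_map(fit, {pos: 1.0, neg: -1.0})
            search = RoiSpec(
                f"{site.hemisphere}_{site.name}", site.center_mm, cfg.search_radius_mm
            )
            seed = localize_seed(tmap, search, name=site.name,
                                 hemisphere=site.hemisphere)
            rows.append(
                (s, seed.name, seed.hemisphere, *seed.coord_mm, seed.peak_stat)
            )
    seeds = pd.DataFrame(
        rows, columns=["subject", "seed", "hemisphere", "x", "y", "z", "t"]
    )
    _write_tsv(seeds, out / "seed_locations.tsv")
    return ["seed_locations.tsv"]


def _read_compartments(sub: Path) -> dict[str, np.ndarray]:
    out = {}
    for name in ("brain", "white_matter", "csf", "out_of_brain"):
        out[name] = read_volume(sub / f"mask_{name}.nii.gz").data.astype(bool)
    return out


def _stage_connect(cfg: PipelineConfig, out: Path) -> list[str]:
    seeds = pd.read_csv(out / "seed_locations.tsv", sep="\t")
    parcellation = _read_parcellation(out)
    streams = load_stream_table()
    strength_rows = []
    parcel_rows = []
    for s in range(cfg.n_subjects):
        sub = _sub_dir(out, s)
        run = read_volume(sub / "rest.nii.gz", expect_4d=True)
        motion = pd.read_csv(sub / "rest_motion.tsv", sep="\t")
        if not screen_motion(motion, cfg.motion_threshold_mm):
            logger.warning("subject %d excluded for excessive motion", s)
            continue
        comp = _read_compartments(sub)
        nuisance = build_nuisance(motion, run, comp)
        for _, row in seeds[seeds["subject"] == s].iterrows():
            spec = RoiSpec(
                f"{row['hemisphere']}_{row['seed']}",
                (row["x"], row["y"], row["z"]),
                cfg.sphere_radius_mm,
            )
            mask = build_sphere_roi(spec, run.affine, run.shape3d)
            ts = first_eigenvariate(run, mask, name=row["seed"])
            beta = seed_beta_map(
                run, ts, nuisance, highpass_s=cfg.highpass_s,
                subject=s, hemisphere=row["hemisphere"],
            )
            write_volume(
                beta.volume,
                sub / f"beta_{row['hemisphere']}_{row['seed']}.nii.gz",
            )
            st, pc = stream_strength(beta, parcellation, streams)
            strength_rows.append(st)
            parcel_rows.append(pc)
    strengths = pd.concat(strength_rows, ignore_index=True)
    _write_tsv(strengths, out / "stream_strength.tsv")
    _write_tsv(pd.concat(parcel_rows, ignore_index=True), out / "parcel_strength.tsv")

    results = repeated_anova(strengths, within=["seed", "stream"])
    results += repeated_anova(strengths, within=["seed", "stream", "hemisphere"])
    results += pairwise_interaction_anovas(strengths)
    anova_df = pd.DataFrame([asdict(r) for r in results])
    _write_tsv(anova_df, out / "stream_anova.tsv")
    return ["stream_strength.tsv", "parcel_strength.tsv", "stream_anova.tsv"]


def _read_parcellation(out: Path) -> ParcellationVolume:
    vol = read_volume(out / "parcellation.nii.gz")
    labels = pd.read_csv(out / "parcel_labels.tsv", sep="\t")
    label_map = dict(zip(labels["label"].astype(int), labels["area_name"]))
    return ParcellationVolume(vol.data.astype(int), vol.affine, label_map)


def _synthetic_targets(
    parcellation: ParcellationVolume, streams: StreamTable, radius_mm: float
) -> list[RoiSpec]:
    """Synthetic fingerprint target set: centroids of a fixed subset of
    stream parcels (7 dorsal + 6 ventral = 13 arms), standing in for the
    published target coordinates, which lie outside the desk-scale grid."""
    names = streams.areas("dorsal")[:7] + streams.areas("ventral")[:6]
    A = parcellation.affine
    specs = []
    for name in names:
        vox = parcellation.voxels_of(name)
        centroid = (A[:3, :3] @ vox.mean(axis=0)) + A[:3, 3]
        specs.append(RoiSpec(name, tuple(centroid), radius_mm))
    return specs


def _load_betamaps(cfg: PipelineConfig, out: Path, seeds: pd.DataFrame):
    from .rs_connectivity import BetaMap

    maps = {}
    for s in range(cfg.n_subjects):
        sub = _sub_dir(out, s)
        for _, row in seeds[seeds["subject"] == s].iterrows():
            path = sub / f"beta_{row['hemisphere']}_{row['seed']}.nii.gz"
            if not path.exists():
                continue
            maps[(s, row["seed"], row["hemisphere"])] = BetaMap(
                read_volume(path), seed=row["seed"], subject=s,
                hemisphere=row["hemisphere"],
            )
    return maps


def _stage_fingerprint(cfg: PipelineConfig, out: Path) -> list[str]:
    seeds = pd.read_csv(out / "seed_locations.tsv", sep="\t")
    parcellation = _read_parcellation(out)
    streams = load_stream_table()
    targets = _synthetic_targets(parcellation, streams, cfg.sphere_radius_mm)
    maps = _load_betamaps(cfg, out, seeds)
    fps = {
        key: extract_fingerprint(bm, targets, mask_at_zero=True)
        for key, bm in maps.items()
    }
    _write_tsv(fingerprints_to_frame(list(fps.values())), out / "fingerprints.tsv")

    subjects = sorted({k[0] for k in fps})
    seed_names = sorted({k[1] for k in fps})
    hemis = sorted({k[2] for k in fps})

    def arms(seed, hemi):
        return np.stack([fps[(s, seed, hemi)].values for s in subjects])

    tests = []
    for hemi in hemis:
        for i, a in enumerate(seed_names):
            for b in seed_names[i + 1:]:
                res = fingerprint_permutation_test(
                    arms(a, hemi), arms(b, hemi),
                    pair=(f"{hemi}_{a}", f"{hemi}_{b}"),
                    n_perm=cfg.n_perm, rng_seed=cfg.rng_seed,
                )
                tests.append(res)
    attr_rows = []
    if set(hemis) >= {"left", "right"}:
        for name in seed_names:
            res = fingerprint_permutation_test(
                arms(name, "left"), arms(name, "right"),
                pair=(f"left_{name}", f"right_{name}"),
                n_perm=cfg.n_perm, rng_seed=cfg.rng_seed,
            )
            tests.append(res)
            for a in arm_attribution(
                arms(name, "left"), arms(name, "right"),
                targets=[t.name for t in targets],
            ):
                attr_rows.append((name, a.target, a.direction, a.p, a.separated))
    tests_df = pd.DataFrame(
        [
            (t.pair[0], t.pair[1], t.observed_d, t.p, t.n_perm, t.method)
            for t in tests
        ],
        columns=["region_a", "region_b", "observed_d", "p", "n_perm", "method"],
    )
    _write_tsv(tests_df, out / "fingerprint_tests.tsv")
    _write_tsv(
        pd.DataFrame(
            attr_rows, columns=["seed", "target", "direction", "p", "separated"]
        ),
        out / "arm_attribution.tsv",
    )
    return ["fingerprints.tsv", "fingerprint_tests.tsv", "arm_attribution.tsv"]


def _stage_classify(cfg: PipelineConfig, out: Path) -> list[str]:
    seeds = pd.read_csv(out / "seed_locations.tsv", sep="\t")
    parcellation = _read_parcellation(out)
    streams = load_stream_table()
    maps = _load_betamaps(cfg, out, seeds)
    k_hi = min(cfg.k_max, streams.k_max)
    queries = []
    train = {}
    for s in range(cfg.n_subjects):
        sub = _sub_dir(out, s)
        run = read_volume(sub / "rest.nii.gz", expect_4d=True)
        motion = pd.read_csv(sub / "rest_motion.tsv", sep="\t")
        comp = _read_compartments(sub)
        train[s] = build_training_set(
            run, motion, comp, parcellation, streams,
            highpass_s=cfg.highpass_s, in_brain=comp["brain"], subject=s,
        )
        for (subj, seed, hemi), bm in maps.items():
            if subj != s:
                continue
            queries.append(
                ClassificationQuery(
                    s, seed, hemi, flatten_beta_map(bm.volume, comp["brain"])
                )
            )
    outcomes = k_sweep(queries, train, range(cfg.k_min, k_hi + 1))
    _write_tsv(outcomes, out / "classification_outcomes.tsv")
    _write_tsv(dorsal_probabilities(outcomes), out / "dorsal_probability.tsv")
    fr = compare_outcomes(outcomes)
    _write_tsv(pd.DataFrame([asdict(r) for r in fr]), out / "friedman_tests.tsv")
    return [
        "classification_outcomes.tsv", "dorsal_probability.tsv", "friedman_tests.tsv",
    ]


def _stage_tract(cfg: PipelineConfig, out: Path) -> list[str]:
    counts = pd.read_csv(out / "tract_counts.tsv", sep="\t")
    strengths = strength(counts)
    _write_tsv(strengths, out / "tract_strength.tsv")
    results = tract_anova(strengths)
    _write_tsv(
        pd.DataFrame([asdict(r) for r in results]), out / "tract_anova.tsv"
    )
    posthoc = pd.concat(
        [pairwise_stream_ttests(strengths, s) for s in ("dorsal", "ventral")],
        ignore_index=True,
    )
    _write_tsv(posthoc, out / "tract_posthoc.tsv")
    return ["tract_strength.tsv", "tract_anova.tsv", "tract_posthoc.tsv"]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "localize": _stage_localize,
    "connect": _stage_connect,
    "fingerprint": _stage_fingerprint,
    "classify": _stage_classify,
    "tract": _stage_tract,
}


def run_pipeline(
    cfg: PipelineConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] = ALL_STAGES,
) -> Path:
    """Execute the requested stages in order, writing outputs and a
    provenance manifest under ``out_dir``."""
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    manifest = {
        "package": "streamconn",
        "version": __version__,
        "config_sha256": cfg.digest(),
        "rng_seed": cfg.rng_seed,
        "stages": {},
    }
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        logger.info("running stage %s", stage)
        outputs = _STAGE_FN[stage](cfg, out)
        manifest["stages"][stage] = outputs
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
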