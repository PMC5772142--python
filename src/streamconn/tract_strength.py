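"""Tractography path-count statistics.

Tracking itself is out of scope: this module consumes per-seed streamline
count tables (from any probabilistic tracker or the synthetic generator)
and computes the anatomical connection-strength statistic — the
log-transformed, total-normalized path count — plus the diffusion-side
seeding rule (n closest white-matter boundary voxels) and the
seed x stream repeated-measures ANOVA with Bonferroni-corrected paired-t
follow-ups.

Strength formula (isolated here, configurable): value =
log10((count + pseudo) / total) with pseudo-count 1, so zero-count cells
remain finite; rows contributing to the same (subject, seed, hemisphere,
stream) cell are averaged.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .imaging_io import RoiMask
from .rs_connectivity import AnovaResult, pairwise_interaction_anovas, repeated_anova

__all__ = [
    "select_boundary_seeds",
    "strength",
    "tract_anova",
    "pairwise_stream_ttests",
]


def select_boundary_seeds(
    wm_boundary: RoiMask, seed_coord_mm, n: int = 20
) -> RoiMask:
    """The n boundary voxels closest (world-space Euclidean distance) to a
    seed coordinate; ties at the cutoff broken by lexicographic voxel
    index."""
    if len(wm_boundary) < n:
        raise ValueError(
            f"boundary mask has {len(wm_boundary)} voxels, fewer than n={n}"
        )
    centers = wm_boundary.centers_mm()
    d = np.sqrt(((centers - np.asarray(seed_coord_mm, dtype=float)) ** 2).sum(axis=1))
    idx = wm_boundary.voxel_indices
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d))
    chosen = idx[order[:n]]
    return RoiMask(
        chosen, wm_boundary.affine, wm_boundary.shape,
        source=f"{wm_boundary.source}:nearest{n}",
    )


def strength(records: pd.DataFrame, pseudo_count: float = 1.0,
             log_base: float = 10.0) -> pd.DataFrame:
    """Connection strength per (subject, seed, hemisphere, stream) cell."""
    required = {"subject", "seed", "hemisphere", "stream", "count", "total"}
    if not required.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    if (records["total"] <= 0).any():
        raise ValueError("total must be > 0 for every record")
    if ((records["count"] < 0) | (records["count"] > records["total"])).any():
        raise ValueError("count must satisfy 0 <= count <= total")
    vals = np.log(
        (records["count"].to_numpy(float) + pseudo_count)
        / records["total"].to_numpy(float)
    ) / np.log(log_base)
    out = records[["subject", "seed", "hemisphere", "stream"]].copy()
    out["value"] = vals
    return out.groupby(
        ["subject", "seed", "hemisphere", "stream"], observed=True, as_index=False
    )["value"].mean()


def tract_anova(
    strengths: pd.DataFrame, include_hemisphere: bool = False
) -> list[AnovaResult]:
    """Repeated-measures seed x stream ANOVA on strength values (optional
    three-way with hemisphere), with Bonferroni-corrected 2x2 follow-ups.
    """
    within = ["seed", "stream"] + (["hemisphere"] if include_hemisphere else [])
    for w in within:
        if strengths[w].nunique() < 2:
            raise ValueError(f"factor {w!r} needs at least 2 levels")
    results = repeated_anova(strengths, within=within)
    results += pairwise_interaction_anovas(strengths, factor="seed", other="stream")
    return results


def pairwise_stream_ttests(
    strengths: pd.DataFrame, stream: str = "dorsal"
) -> pd.DataFrame:
    """Bonferroni-corrected paired t tests between seeds on one stream's
    strength values (post-hoc follow-ups)."""
    sub = (
        strengths[strengths["stream"] == stream]
        .groupby(["subject", "seed"], observed=True, as_index=False)["value"]
        .mean()
        .pivot(index="subject", columns="seed", values="value")
    )
    pairs = list(combinations(sorted(sub.columns), 2))
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_rel(sub[a], sub[b])
        rows.append(
            (stream, f"{a}-vs-{b}", float(t), len(sub) - 1, min(float(p) * len(pairs), 1.0))
        )
    return pd.DataFrame(rows, columns=["stream", "pair", "t", "df", "p_bonferroni"])
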