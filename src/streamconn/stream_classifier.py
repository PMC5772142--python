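"""Dorsal/ventral classification of whole-brain connectivity patterns.

Each atlas parcel's whole-brain seed-connectivity map, labelled dorsal or
ventral, forms a training item; seed-region maps are classified by a
k-nearest-neighbour rule under the city-block metric, sweeping k from 2
to one less than the ventral class size. Ties at even k are broken by the
label of the single nearest item. Outcomes are compared with Friedman
tests (binary outcomes, midrank ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .imaging_io import ParcellationVolume, RoiMask, StreamTable, VolumeImage
from .rs_connectivity import build_nuisance, first_eigenvariate, seed_beta_map

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingSet",
    "ClassificationQuery",
    "build_training_set",
    "flatten_beta_map",
    "knn_classify",
    "k_sweep",
    "dorsal_probabilities",
    "compare_outcomes",
    "FriedmanResult",
]


@dataclass
class TrainingSet:
    """Labelled, flattened connectivity patterns on a common voxel set."""

    names: list[str]
    labels: list[str]
    X: np.ndarray  # (n_items, n_features)
    voxel_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.names):
            raise ValueError("X must be (n_items, n_features) matching names")
        if len(self.labels) != len(self.names):
            raise ValueError("labels must match names")
        classes = set(self.labels)
        if len(self.names) < 2 or len(classes) < 2:
            raise ValueError("training set needs >= 2 items covering both classes")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class ClassificationQuery:
    subject: int | str
    seed: str
    hemisphere: str
    pattern: np.ndarray


def flatten_beta_map(vol: VolumeImage, in_brain: np.ndarray | None = None) -> np.ndarray:
    data = vol.data if vol.data.ndim == 3 else vol.data[..., 0]
    if in_brain is None:
        return data.ravel().astype(float)
    return data[np.asarray(in_brain, dtype=bool)].astype(float)


def build_training_set(
    run: VolumeImage,
    motion: pd.DataFrame,
    compartments: dict[str, np.ndarray],
    parcellation: ParcellationVolume,
    streams: StreamTable,
    highpass_s: float | None = 128.0,
    in_brain: np.ndarray | None = None,
    subject: int | str = "",
) -> TrainingSet:
    """One subject's training set: a whole-brain connectivity map per
    stream parcel, computed with the same seed-GLM procedure used for the
    localizer seed regions, flattened on a shared in-brain voxel set."""
    missing = parcellation.check_coverage(streams)
    if missing:
        raise ValueError("; ".join(missing))
    nuisance = build_nuisance(motion, run, compartments)
    names, labels, rows = [], [], []
    for _, row in streams.rows.iterrows():
        area, stream = str(row["area_name"]), str(row["stream"])
        vox = parcellation.voxels_of(area)
        mask = RoiMask(vox, parcellation.affine, run.shape3d, source=area)
        ts = first_eigenvariate(run, mask, name=area)
        beta = seed_beta_map(
            run, ts, nuisance, highpass_s=highpass_s, subject=subject
        )
        names.append(area)
        labels.append(stream)
        rows.append(flatten_beta_map(beta.volume, in_brain))
    return TrainingSet(names, labels, np.stack(rows), voxel_mask=in_brain)


def _cityblock_distances(X: np.ndarray, q: np.ndarray) -> np.ndarray:
    return np.abs(X - q[None, :]).sum(axis=1)


def knn_classify(
    query: np.ndarray, train: TrainingSet, k: int, metric: str = "cityblock"
) -> str:
    """Majority label of the k nearest training items under the city-block
    metric; a tied vote (possible at even k) is resolved by the label of
    the single nearest item. Equal distances are ordered by training-item
    index (stable sort), so the outcome is deterministic."""
    if metric != "cityblock":
        raise ValueError("only the city-block metric is supported")
    if not (1 <= k <= len(train)):
        raise ValueError(f"k={k} outside 1..{len(train)}")
    if k == len(train):
        counts = pd.Series(train.labels).value_counts()
        if counts.iloc[0] != counts.min():
            logger.warning(
                "k equals the training-set size; majority class is returned "
                "regardless of the query"
            )
    q = np.asarray(query, dtype=float)
    d = _cityblock_distances(train.X, q)
    order = np.argsort(d, kind="stable")
    top = order[:k]
    votes = pd.Series([train.labels[i] for i in top]).value_counts()
    if len(votes) > 1 and votes.iloc[0] == votes.iloc[1]:
        return train.labels[order[0]]
    return str(votes.index[0])


def k_sweep(
    queries: list[ClassificationQuery],
    train: TrainingSet | dict,
    k_range: range | list[int] = range(2, 9),
) -> pd.DataFrame:
    """Classification outcome per (subject, seed, hemisphere, k).

    ``train`` may be one TrainingSet for all queries or a mapping from
    subject to a subject-specific TrainingSet.
    """
    if len(queries) == 0:
        raise ValueError("empty query set")
    k_list = list(k_range)
    if not k_list or min(k_list) < 1:
        raise ValueError("k_range must contain positive k only")
    rows = []
    for q in queries:
        tr = train[q.subject] if isinstance(train, dict) else train
        if max(k_list) > len(tr):
            raise ValueError(f"k_range exceeds training-set size {len(tr)}")
        for k in k_list:
            label = knn_classify(q.pattern, tr, k)
            rows.append((q.subject, q.seed, q.hemisphere, k, label))
    return pd.DataFrame(
        rows, columns=["subject", "seed", "hemisphere", "k", "label"]
    )


def dorsal_probabilities(
    outcomes: pd.DataFrame, by: list[str] | None = None
) -> pd.DataFrame:
    """Fraction of outcomes labelled dorsal, aggregated over subjects and
    k (default grouping: seed, hemisphere)."""
    if by is None:
        by = ["seed", "hemisphere"]
    out = (
        outcomes.assign(dorsal=(outcomes["label"] == "dorsal").astype(float))
        .groupby(by, observed=True, as_index=False)["dorsal"]
        .mean()
        .rename(columns={"dorsal": "p_dorsal"})
    )
    return out


@dataclass
class FriedmanResult:
    comparison: str
    chi2: float
    df: int
    n_blocks: int
    p: float
    correction: str = "none"


def compare_outcomes(
    outcomes: pd.DataFrame, correct_pairwise: bool = True
) -> list[FriedmanResult]:
    """Friedman test across seed regions, blocking on subject x k
    (binary outcomes coded 0/1, midrank ties), plus pairwise follow-ups.
    """
    df = outcomes.copy()
    df["y"] = (df["label"] == "dorsal").astype(float)
    if "hemisphere" in df.columns and df["hemisphere"].nunique() > 1:
        block_cols = ["subject", "hemisphere", "k"]
    else:
        block_cols = ["subject", "k"]
    wide = df.pivot_table(
        index=block_cols, columns="seed", values="y", aggfunc="mean"
    )
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"unbalanced layout; blocks with missing seeds: {missing}")
    seeds = list(wide.columns)
    if len(seeds) < 2:
        raise ValueError("need at least 2 seed regions")
    cols = [wide[s].to_numpy() for s in seeds]
    out = []
    if len(seeds) >= 3:
        block_var = np.stack(cols).std(axis=0)
        if np.all(block_var == 0):  # every block fully tied
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.friedmanchisquare(*cols)
            if not np.isfinite(stat):
                stat, p = 0.0, 1.0
        out.append(
            FriedmanResult("all-seeds", float(stat), len(seeds) - 1, len(wide), float(p))
        )
    pairs = [
        (a, b) for i, a in enumerate(seeds) for b in seeds[i + 1:]
    ]
    for a, b in pairs:
        diff = wide[a].to_numpy() - wide[b].to_numpy()
        # two-treatment Friedman: rank within block = sign comparison
        nz = diff[diff != 0]
        n_blk = len(wide)
        if nz.size == 0:
            stat, p = 0.0, 1.0
        else:
            n_pos = int((nz > 0).sum())
            stat = (2 * n_pos - nz.size) ** 2 / nz.size
            p = float(stats.chi2.sf(stat, 1))
        out.append(
            FriedmanResult(
                f"{a}-vs-{b}",
                float(stat),
                1,
                n_blk,
                min(p * len(pairs), 1.0) if correct_pairwise else p,
                correction="Bonferroni" if correct_pairwise else "none",
            )
        )
    return out
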