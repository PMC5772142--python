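"""Connectivity fingerprints and fingerprint matching.

A fingerprint is a seed region's vector of mean connectivity betas over a
fixed, ordered set of target ROIs. Two fingerprints are compared by the
city-block distance between their group means after joint min-max
normalization over the combined arms of both. Significance comes from a
permutation null built by independently swapping each subject's pair of
region labels; the joint normalization is recomputed inside every
permutation so the test is not biased by the observed range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .imaging_io import RoiSpec, build_sphere_roi
from .rs_connectivity import BetaMap

logger = logging.getLogger(__name__)

__all__ = [
    "Fingerprint",
    "FingerprintTestResult",
    "ArmAttribution",
    "extract_fingerprint",
    "normalize_pair",
    "cityblock",
    "fingerprint_permutation_test",
    "arm_attribution",
]


@dataclass
class Fingerprint:
    """Ordered (target -> value) connectivity profile of one seed."""

    seed: str
    subject: int | str
    targets: list[str]
    values: np.ndarray
    masked: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.targets) != self.values.size:
            raise ValueError("targets and values must have equal length")
        if self.masked and (self.values < 0).any():
            raise ValueError("masked fingerprint has negative arms")


@dataclass
class FingerprintTestResult:
    pair: tuple[str, str]
    observed_d: float
    null: np.ndarray
    p: float
    n_perm: int
    method: str = "monte-carlo"

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must lie in (0, 1]")


@dataclass
class ArmAttribution:
    target: str
    direction: int
    p: float
    separated: bool = False


def extract_fingerprint(
    beta: BetaMap,
    targets: list[RoiSpec],
    mask_at_zero: bool = True,
) -> Fingerprint:
    """Mean beta within each target sphere; negative arms set to zero when
    ``mask_at_zero``."""
    vol = beta.volume
    values = []
    names = []
    for spec in targets:
        try:
            mask = build_sphere_roi(spec, vol.affine, vol.shape3d)
        except Exception as exc:
            raise ValueError(
                f"target {spec.name!r} not resolvable on the beta grid: {exc}"
            ) from exc
        vals = vol.data[tuple(mask.voxel_indices.T)]
        values.append(float(vals.mean()))
        names.append(spec.name)
    arr = np.asarray(values)
    if mask_at_zero:
        arr = np.maximum(arr, 0.0)
    return Fingerprint(
        seed=beta.seed,
        subject=beta.subject,
        targets=names,
        values=arr,
        masked=mask_at_zero,
    )


def _check_same_arms(a: Fingerprint, b: Fingerprint) -> None:
    if a.targets != b.targets:
        raise ValueError("fingerprints have different arm orders")


def normalize_pair(a: Fingerprint, b: Fingerprint) -> tuple[Fingerprint, Fingerprint]:
    """Affine map sending the minimum over the union of both arm sets to 0
    and the maximum to 1, applied identically to both fingerprints."""
    _check_same_arms(a, b)
    combined = np.concatenate([a.values, b.values])
    lo, hi = combined.min(), combined.max()
    if hi - lo <= 0:
        raise ValueError("degenerate normalization: all arms equal across the pair")
    fa = Fingerprint(a.seed, a.subject, a.targets, (a.values - lo) / (hi - lo))
    fb = Fingerprint(b.seed, b.subject, b.targets, (b.values - lo) / (hi - lo))
    return fa, fb


def cityblock(a: Fingerprint, b: Fingerprint) -> float:
    """Sum of absolute differences over all fingerprint arms."""
    _check_same_arms(a, b)
    return float(np.abs(a.values - b.values).sum())


def _arms_matrix(arms) -> np.ndarray:
    if isinstance(arms, np.ndarray):
        out = np.asarray(arms, dtype=float)
    else:
        out = np.stack([np.asarray(f.values, dtype=float) for f in arms])
    if out.ndim != 2:
        raise ValueError("expected a (subjects x arms) matrix")
    return out


def _normalized_distance(mean_a: np.ndarray, mean_b: np.ndarray) -> float:
    lo = min(mean_a.min(), mean_b.min())
    hi = max(mean_a.max(), mean_b.max())
    if hi - lo <= 0:
        raise ValueError("degenerate normalization: all arms equal across the pair")
    return float(np.abs(mean_a - mean_b).sum() / (hi - lo))


def _null_distances(A: np.ndarray, B: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """City-block distances between jointly renormalized permuted group
    means; ``masks`` is (n_perm, n_subjects) with True = swap that
    subject's labels."""
    n = A.shape[0]
    mean_a = A.mean(axis=0)
    mean_b = B.mean(axis=0)
    shift = masks.astype(float) @ (B - A) / n  # (P, arms)
    pa = mean_a + shift
    pb = mean_b - shift
    lo = np.minimum(pa.min(axis=1), pb.min(axis=1))
    hi = np.maximum(pa.max(axis=1), pb.max(axis=1))
    rng_ = hi - lo
    raw = np.abs(pa - pb).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(rng_ > 0, raw / np.where(rng_ > 0, rng_, 1.0), 0.0)
    return out


def fingerprint_permutation_test(
    arms_a,
    arms_b,
    pair: tuple[str, str] = ("A", "B"),
    n_perm: int = 5000,
    rng_seed: int = 0,
    exact: bool = False,
) -> FingerprintTestResult:
    """Permutation test on the city-block distance between group-mean
    fingerprints.

    The observed statistic is the distance between the jointly normalized
    group means. The null swaps each subject's A/B labels independently,
    recomputes the group means, renormalizes the permuted pair, and
    recomputes the distance. Monte-Carlo p uses the add-one formula
    (1 + #{null >= obs}) / (1 + n_perm); in exact mode all 2^n swap
    assignments (including the identity) are enumerated and
    p = #{null >= obs} / 2^n.
    """
    A = _arms_matrix(arms_a)
    B = _arms_matrix(arms_b)
    if A.shape != B.shape:
        raise ValueError("paired fingerprints must have identical shape")
    n = A.shape[0]
    if n < 2:
        raise ValueError("permutation test needs at least 2 subjects")
    obs = _normalized_distance(A.mean(axis=0), B.mean(axis=0))
    if exact:
        if n > 20:
            raise ValueError("exact enumeration limited to n <= 20 subjects")
        bits = np.arange(2**n)[:, None] >> np.arange(n)[None, :]
        masks = (bits & 1).astype(bool)
        null = _null_distances(A, B, masks)
        p = float((null >= obs - 1e-12).sum() / masks.shape[0])
        return FingerprintTestResult(pair, obs, null, p, masks.shape[0], "exact")
    rng = np.random.default_rng(rng_seed)
    masks = rng.random((n_perm, n)) < 0.5
    null = _null_distances(A, B, masks)
    p = float((1 + (null >= obs - 1e-12).sum()) / (1 + n_perm))
    return FingerprintTestResult(pair, obs, null, p, n_perm, "monte-carlo")


def arm_attribution(
    arms_a,
    arms_b,
    targets: list[str] | None = None,
) -> list[ArmAttribution]:
    """Per-arm logistic regression of the region label on the arm value
    across the stacked per-subject observations (Wald p, uncorrected)."""
    A = _arms_matrix(arms_a)
    B = _arms_matrix(arms_b)
    if A.shape != B.shape:
        raise ValueError("paired fingerprints must have identical shape")
    if targets is None:
        if not isinstance(arms_a, np.ndarray):
            targets = list(arms_a[0].targets)
        else:
            targets = [f"arm{j}" for j in range(A.shape[1])]
    y = np.r_[np.zeros(A.shape[0]), np.ones(B.shape[0])]
    out = []
    for j, name in enumerate(targets):
        x = np.r_[A[:, j], B[:, j]]
        direction = int(np.sign(B[:, j].mean() - A[:, j].mean()))
        if np.ptp(x) == 0:
            out.append(ArmAttribution(name, 0, 1.0, False))
            continue
        X = sm.add_constant(x)
        separated = False
        try:
            import warnings

            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")  # separation handled below
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
                fitted = fit.predict(X)
            if np.all((fitted > 0.999) == (y > 0.5)) and np.all(
                (fitted < 0.001) == (y < 0.5)
            ):
                separated = True
            p = float(fit.pvalues[1])
            if not np.isfinite(p):
                separated, p = True, 0.0
        except Exception:
            separated, p = True, 0.0
        if separated:
            logger.info("arm %r: perfect separation flagged", name)
            p = 0.0
        out.append(ArmAttribution(name, direction, p, separated))
    return out


def fingerprints_to_frame(fps: list[Fingerprint]) -> pd.DataFrame:
    """Long-format export (seed, subject, target, value) for spider plots."""
    rows = [
        (f.seed, f.subject, t, float(v))
        for f in fps
        for t, v in zip(f.targets, f.values)
    ]
    return pd.DataFrame(rows, columns=["seed", "subject", "target", "value"])
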