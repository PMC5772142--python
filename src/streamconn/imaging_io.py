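"""Volume and table I/O, ROI geometry, and packaged coordinate tables.

All world coordinates are RAS+ millimetres (MNI convention); voxel indices
are 0-based. Spherical ROIs are defined between voxel *centres* in world
space with an inclusive boundary (distance <= radius), which on a 2 mm
isotropic grid makes a 4 mm-radius sphere contain exactly 33 voxels.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeImage",
    "RoiSpec",
    "RoiMask",
    "StreamTable",
    "ParcellationVolume",
    "DegenerateMaskError",
    "build_sphere_roi",
    "load_target_table",
    "load_stream_table",
    "read_volume",
    "write_volume",
    "packaged_table_path",
]


class DegenerateMaskError(ValueError):
    """Raised when an ROI resolves to zero voxels on the requested grid."""


@dataclass
class VolumeImage:
    """A 3D or 4D raster with a voxel-to-world affine.

    Parameters
    ----------
    data : ndarray
        Spatial dims first; for 4D data the last axis is time.
    affine : (4, 4) ndarray
        Voxel-index -> world-mm map (RAS+).
    tr_s : float, optional
        Repetition time in seconds (4D data only).
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if self.data.ndim not in (3, 4):
            raise ValueError(f"expected 3D or 4D data, got {self.data.ndim}D")
        if any(s < 1 for s in self.data.shape):
            raise ValueError("all dimensions must be >= 1")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def n_volumes(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ xyz.T).T + inv[:3, 3]


@dataclass(frozen=True)
class RoiSpec:
    """A named spherical ROI in world (MNI) coordinates."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.radius_mm < 0:
            raise ValueError("radius_mm must be >= 0")


@dataclass
class RoiMask:
    """A set of voxel indices on a specific grid."""

    voxel_indices: np.ndarray  # (n, 3) int
    affine: np.ndarray
    shape: tuple[int, int, int]
    source: str = ""

    def __post_init__(self) -> None:
        self.voxel_indices = np.atleast_2d(np.asarray(self.voxel_indices, dtype=int))
        if self.voxel_indices.size and (
            (self.voxel_indices < 0).any()
            or (self.voxel_indices >= np.asarray(self.shape)).any()
        ):
            raise ValueError("voxel indices out of grid bounds")

    def __len__(self) -> int:
        return 0 if self.voxel_indices.size == 0 else self.voxel_indices.shape[0]

    def centers_mm(self) -> np.ndarray:
        A = np.asarray(self.affine)
        return (A[:3, :3] @ self.voxel_indices.T).T + A[:3, 3]

    def as_boolean(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        if len(self):
            out[tuple(self.voxel_indices.T)] = True
        return out


@dataclass
class StreamTable:
    """Parcel names labelled dorsal or ventral."""

    rows: pd.DataFrame  # columns: area_name, stream

    def __post_init__(self) -> None:
        df = self.rows
        required = {"area_name", "stream"}
        if not required.issubset(df.columns):
            raise ValueError(f"stream table needs columns {sorted(required)}")
        bad = set(df["stream"]) - {"dorsal", "ventral"}
        if bad:
            raise ValueError(f"unknown stream value(s): {sorted(bad)}")
        if df["area_name"].duplicated().any():
            dupes = df.loc[df["area_name"].duplicated(), "area_name"].tolist()
            raise ValueError(f"duplicate area name(s): {dupes}")

    def areas(self, stream: str | None = None) -> list[str]:
        if stream is None:
            return self.rows["area_name"].tolist()
        return self.rows.loc[self.rows["stream"] == stream, "area_name"].tolist()

    @property
    def n_dorsal(self) -> int:
        return int((self.rows["stream"] == "dorsal").sum())

    @property
    def n_ventral(self) -> int:
        return int((self.rows["stream"] == "ventral").sum())

    @property
    def k_max(self) -> int:
        """Largest neighbour count used in the k sweep: one less than the
        size of the smaller (ventral) class."""
        return min(self.n_dorsal, self.n_ventral) - 1

    def stream_of(self, area_name: str) -> str:
        hit = self.rows.loc[self.rows["area_name"] == area_name, "stream"]
        if hit.empty:
            raise KeyError(area_name)
        return str(hit.iloc[0])


@dataclass
class ParcellationVolume:
    """Integer label volume plus a label -> area-name map."""

    label_data: np.ndarray
    affine: np.ndarray
    label_map: dict[int, str]
    name_map: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.label_data = np.asarray(self.label_data)
        if self.label_data.ndim != 3:
            raise ValueError("parcellation label data must be 3D")
        self.name_map = {v: k for k, v in self.label_map.items()}

    def voxels_of(self, area_name: str) -> np.ndarray:
        if area_name not in self.name_map:
            raise KeyError(f"area {area_name!r} not in parcellation")
        return np.argwhere(self.label_data == self.name_map[area_name])

    def check_coverage(self, streams: StreamTable) -> list[str]:
        """Return warnings for stream areas resolving to zero voxels."""
        warnings = []
        for area in streams.areas():
            if area not in self.name_map or not (
                self.label_data == self.name_map[area]
            ).any():
                warnings.append(f"area {area!r} has no voxels in parcellation")
        return warnings


def build_sphere_roi(
    spec: RoiSpec, affine: np.ndarray, shape: tuple[int, int, int]
) -> RoiMask:
    """Voxels whose world-space centres lie within ``radius_mm`` of the
    sphere centre (boundary inclusive).

    Distances are computed in world millimetres between voxel centres, so
    anisotropic grids are handled correctly.
    """
    affine = np.asarray(affine, dtype=float)
    inv = np.linalg.inv(affine)
    center = np.asarray(spec.center_mm, dtype=float)
    cvox = inv[:3, :3] @ center + inv[:3, 3]
    # conservative voxel-space bounding box from per-axis voxel extents
    voxel_sizes = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    span = np.ceil(spec.radius_mm / voxel_sizes).astype(int) + 1
    lo = np.maximum(np.floor(cvox).astype(int) - span, 0)
    hi = np.minimum(np.ceil(cvox).astype(int) + span, np.asarray(shape) - 1)
    if (lo > hi).any():
        raise DegenerateMaskError(
            f"sphere {spec.name!r} at {tuple(center)} lies outside the grid"
        )
    grids = np.meshgrid(*(np.arange(l, h + 1) for l, h in zip(lo, hi)), indexing="ij")
    ijk = np.stack([g.ravel() for g in grids], axis=1)
    world = (affine[:3, :3] @ ijk.T).T + affine[:3, 3]
    dist = np.sqrt(((world - center) ** 2).sum(axis=1))
    keep = ijk[dist <= spec.radius_mm + 1e-9]
    if keep.size == 0:
        raise DegenerateMaskError(
            f"sphere {spec.name!r} at {tuple(center)} contains no voxel centres"
        )
    # lexicographic ordering keeps downstream tie-breaks deterministic
    order = np.lexsort((keep[:, 2], keep[:, 1], keep[:, 0]))
    return RoiMask(keep[order], affine, tuple(shape), source=spec.name)


def packaged_table_path(which: str) -> Path:
    """Path to a packaged fixture table: 'targets' or 'streams'."""
    fname = {"targets": "fingerprint_targets.tsv", "streams": "stream_regions.tsv"}[
        which
    ]
    return Path(importlib.resources.files("streamconn.data") / fname)


def load_target_table(
    path: str | Path | None = None,
    hemisphere: str = "left",
    radius_mm: float = 4.0,
) -> list[RoiSpec]:
    """Load fingerprint target ROIs from a TSV with columns
    label, region, x, y, z.

    The stored x column is an unsigned magnitude; ``hemisphere`` resolves
    the sign (left = negative X, right = positive X, 'both' = both sets
    with 'l'/'r' prefixes).
    """
    if hemisphere not in ("left", "right", "both"):
        raise ValueError("hemisphere must be 'left', 'right' or 'both'")
    if path is None:
        path = packaged_table_path("targets")
    df = pd.read_csv(path, sep="\t")
    required = {"label", "region", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"target table needs columns {sorted(required)}")
    if df["label"].duplicated().any():
        dupes = df.loc[df["label"].duplicated(), "label"].tolist()
        raise ValueError(f"duplicate target label(s): {dupes}")
    for i, row in df.iterrows():
        try:
            [float(row[c]) for c in ("x", "y", "z")]
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed coordinate in row {i} ({row['label']})") from exc
    specs: list[RoiSpec] = []
    sides = {"left": [("", -1.0)], "right": [("", +1.0)]}.get(
        hemisphere, [("l", -1.0), ("r", +1.0)]
    )
    for prefix, sign in sides:
        for _, row in df.iterrows():
            name = f"{prefix}{row['label']}" if prefix else str(row["label"])
            specs.append(
                RoiSpec(
                    name=name,
                    center_mm=(
                        sign * abs(float(row["x"])),
                        float(row["y"]),
                        float(row["z"]),
                    ),
                    radius_mm=radius_mm,
                )
            )
    return specs


def load_stream_table(path: str | Path | None = None) -> StreamTable:
    """Load the dorsal/ventral parcel membership table."""
    if path is None:
        path = packaged_table_path("streams")
    df = pd.read_csv(path, sep="\t")
    return StreamTable(df[["area_name", "stream"]].copy())


def read_volume(path: str | Path, expect_4d: bool | None = None) -> VolumeImage:
    """Read a NIfTI-1 volume."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several format errors
        raise ValueError(f"could not read {path} as NIfTI: {exc}") from exc
    data = np.asarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected 3D or 4D image, got {data.ndim}D")
    if expect_4d is True and data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D timeseries, got 3D")
    if expect_4d is False and data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got 4D")
    tr = None
    if data.ndim == 4:
        tr = float(img.header.get_zooms()[3]) or None
    return VolumeImage(data=data, affine=np.asarray(img.affine), tr_s=tr)


def write_volume(vol: VolumeImage, path: str | Path) -> None:
    """Write a volume as NIfTI-1, preserving the affine and TR."""
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    if vol.data.ndim == 4 and vol.tr_s:
        zooms = list(img.header.get_zooms())
        zooms[3] = vol.tr_s
        img.header.set_zooms(zooms)
        img.header["xyzt_units"] = 10  # mm + s
    nib.save(img, str(path))
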