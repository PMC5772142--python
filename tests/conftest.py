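import numpy as np
import pytest

from streamconn.imaging_io import RoiSpec
from streamconn.synthetic_data import SeedSite, SyntheticCohortConfig


@pytest.fixture
def grid2mm():
    """Centred 2 mm isotropic grid large enough for 4 mm spheres."""
    shape = (21, 21, 21)
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = 2.0
    affine[:3, 3] = -20.0
    return affine, shape


@pytest.fixture
def small_cfg():
    """Desk-scale cohort: small grid, short runs, two subjects."""
    sites = []
    for name, (x, y, z), ld, lv in [
        ("EBA", (9.0, -9.0, 5.0), 0.8, 0.4),
        ("LOC", (7.0, -11.0, -5.0), 0.6, 0.6),
        ("FBA", (9.0, 5.0, -7.0), 0.4, 0.8),
    ]:
        sites.append(SeedSite(name, "left", (-x, y, z), ld, lv))
        sites.append(SeedSite(name, "right", (x, y, z), ld, lv))
    return SyntheticCohortConfig(
        n_subjects=2,
        grid_shape=(16, 18, 16),
        n_volumes=120,
        localizer_n_volumes=120,
        seed_sites=sites,
        rng_seed=7,
    )


@pytest.fixture
def clean_cfg():
    """Confound-free single-site cohort for exact-recovery checks."""
    return SyntheticCohortConfig(
        n_subjects=1,
        grid_shape=(12, 12, 12),
        n_volumes=150,
        seed_sites=[SeedSite("EBA", "left", (-4.0, 0.0, 0.0), 1.0, 0.0)],
        noise_sd=0.0,
        motion_gain=0.0,
        compartment_gain=0.0,
        motion_amplitude_mm=0.0,
        rng_seed=3,
    )


def sphere_oracle(affine, shape, center_mm, radius_mm):
    """Brute-force sphere membership over every grid voxel."""
    affine = np.asarray(affine)
    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    d = np.sqrt(((world - np.asarray(center_mm)) ** 2).sum(axis=1))
    return idx[d <= radius_mm + 1e-9]
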