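import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from psmdnet.synthetic import (
    CohortConfig,
    PhantomConfig,
    TractSpec,
    generate_phantom,
)


def straight_tube_config(
    n=32, voxel=1.0, radius=4.0, fa_peak=0.8, scale=2.0, noise=0.0, axis=0
):
    """A single straight tube through the middle of the grid, along ``axis``."""
    mid = n * voxel / 2.0 + voxel / 2.0
    a = [4.5 * voxel] * 3
    b = [4.5 * voxel] * 3
    a[axis] = 4.5 * voxel
    b[axis] = (n - 4.5) * voxel
    for ax in range(3):
        if ax != axis:
            a[ax] = b[ax] = mid
    return PhantomConfig(
        grid_shape=(n, n, n),
        voxel_size=(voxel,) * 3,
        tracts=[
            TractSpec(
                np.array([a, b]), radius=radius, fa_peak=fa_peak,
                fa_profile=("gaussian", scale),
            )
        ],
        csf_regions=[],
        noise_sd_fa=noise,
        noise_sd_md=0.0,
    )


def tiny_null_cohort_config(seed, n_patients=8, n_controls=8):
    """Reduced-size null cohort: 16^3 grid, one tract, all effects off."""
    ph = PhantomConfig(
        grid_shape=(16, 16, 16),
        voxel_size=(2.0, 2.0, 2.0),
        tracts=[
            TractSpec(
                np.array([[5.0, 16.0, 16.0], [27.0, 16.0, 16.0]]),
                radius=3.0, fa_peak=0.7, fa_profile=("gaussian", 3.0),
            )
        ],
        csf_regions=[],
    )
    return CohortConfig(
        n_patients=n_patients, n_controls=n_controls, phantom=ph, seed=seed,
        psmd_effect=1.0, lambda_effect=1.0, eg_effect=1.0,
    )


@pytest.fixture(scope="session")
def tube_subject():
    """Noise-free straight-tube phantom subject (32^3, 1 mm voxels)."""
    cfg = straight_tube_config()
    return cfg, generate_phantom(cfg)
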