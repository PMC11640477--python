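from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ce4dct.phantom import ContrastKinetics, PhantomSpec
from ce4dct.structures import VoxelMask


@pytest.fixture
def small_spec() -> PhantomSpec:
    """A quick-to-generate phantom with dominant SI motion."""
    return PhantomSpec(
        grid_dims=(32, 32, 32),
        spacing=(1.0, 1.0, 2.0),
        lesion_center=(16.0, 16.0, 40.0),
        lesion_radii=(6.0, 6.0, 6.0),
        motion_amplitude=(0.0, 0.0, 10.0),
        n_phases=10,
        aorta_center_xy=(8.0, 16.0),
        aorta_diameter=16.0,
        seed=7,
    )


@pytest.fixture
def default_kinetics() -> ContrastKinetics:
    return ContrastKinetics()


def random_mask(
    rng: np.random.Generator,
    max_dim: int = 24,
    spacing_choices=((1.0, 1.0, 1.0), (1.0, 1.0, 2.0), (0.8, 1.2, 2.5)),
) -> VoxelMask:
    """A random non-empty blob: union of 1-3 random ellipsoids plus salt."""
    dims = tuple(int(d) for d in rng.integers(8, max_dim + 1, size=3))
    spacing = spacing_choices[rng.integers(len(spacing_choices))]
    vox = np.zeros(dims, bool)
    coords = np.meshgrid(
        *[np.arange(dims[a]) * spacing[a] for a in range(3)], indexing="ij"
    )
    for _ in range(rng.integers(1, 4)):
        center = [rng.uniform(0.25, 0.75) * (dims[a] - 1) * spacing[a] for a in range(3)]
        radii = [rng.uniform(1.5, 0.35 * dims[a] * spacing[a]) for a in range(3)]
        val = sum(((coords[a] - center[a]) / radii[a]) ** 2 for a in range(3))
        vox |= val <= 1.0
    # sprinkle a few extra voxels for irregularity
    extra = rng.random(dims) < 0.01
    vox |= extra
    if not vox.any():
        vox[tuple(d // 2 for d in dims)] = True
    return VoxelMask(vox, spacing)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)
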