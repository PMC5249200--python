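"""Shared fixtures.

The full-cup phantom artifacts (voxelization at 0.2 mm, surface meshes,
ground-truth wear volume) are expensive, so they are built once per
session and shared by the wear, registration and acceptance tests.
"""

import numpy as np
import pytest

import cupwear as cw
from cupwear.phantom import make_sphere_geometry

VOXEL = 0.2           # mm, desk-scale phantom resolution
PENETRATION = 0.5     # mm


@pytest.fixture(scope="session")
def cup_spec():
    return cw.CupSpec()


@pytest.fixture(scope="session")
def wear_pattern():
    return cw.WearPattern(PENETRATION)


@pytest.fixture(scope="session")
def cup_volumes(cup_spec, wear_pattern):
    """Clean (noise-free) CT-like volumes of the unworn and worn cup."""
    solid = cw.make_cup_geometry(cup_spec)
    worn = cw.apply_wear(solid, cup_spec, wear_pattern)
    before = cw.voxelize(solid, VOXEL)
    after = cw.voxelize(worn, VOXEL)
    return before, after


@pytest.fixture(scope="session")
def cup_meshes(cup_volumes):
    before, after = cup_volumes
    return cw.extract_surface(before), cw.extract_surface(after)


@pytest.fixture(scope="session")
def true_wear(cup_spec, wear_pattern):
    """Ground-truth wear volume from the fine-grid oracle (mm^3)."""
    return cw.true_wear_volume(cup_spec, wear_pattern, method="grid", grid_step=0.03)


@pytest.fixture(scope="session")
def sphere_volume():
    """Analytic sphere phantom r = 5 mm at 0.2 mm voxels, minimal blur."""
    return cw.voxelize(make_sphere_geometry(5.0), 0.2, blur_sigma=0.2)


@pytest.fixture(scope="session")
def table2_pairs():
    return cw.load_table2_pairs()
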