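"""Shared fixtures: material sets, fake uniform grids, small phantom scenarios."""

import dataclasses

import numpy as np
import pytest

from mwablate.damage import DamageParams
from mwablate.em import AntennaSpec
from mwablate.materials import PropertySet
from mwablate.phantoms import (AntennaPlacement, Label, LabelGrid,
                               generate_tumor_phantom, voxelize)


@pytest.fixture(scope="session")
def props() -> PropertySet:
    return PropertySet()


@pytest.fixture(scope="session")
def no_perfusion_props() -> PropertySet:
    p = PropertySet()
    return dataclasses.replace(p, blood=dataclasses.replace(
        p.blood, perfusion_rate=0.0))


@pytest.fixture(scope="session")
def damage_params() -> DamageParams:
    return DamageParams()


@pytest.fixture(scope="session")
def antenna() -> AntennaSpec:
    return AntennaSpec()


def uniform_grid(shape, spacing=1e-3, label=Label.TUMOR, mesh=None,
                 labels=None):
    """All-tissue block grid with a dummy antenna placement (no antenna voxels)."""
    if labels is None:
        labels = np.full(shape, np.uint8(label))
    return LabelGrid(origin=np.zeros(3), spacing=spacing, labels=labels,
                     mesh=mesh, placement=AntennaPlacement((0.0, 0.0), 0.0),
                     axis_index=(0, 0), slot_z_index=0, antenna=None)


@pytest.fixture(scope="session")
def block_grid():
    return uniform_grid((6, 6, 6))


@pytest.fixture(scope="session")
def sphere_mesh():
    """Sphere of radius 5 mm (synthetic test solid)."""
    return generate_tumor_phantom(semi_axes=(5e-3, 5e-3, 5e-3))


@pytest.fixture(scope="session")
def sphere_grid(sphere_mesh, antenna):
    return voxelize(sphere_mesh, antenna, spacing=1e-3, margin=8e-3)


@pytest.fixture(scope="session")
def small_case(antenna):
    """Small ellipsoid scenario for fast planning-level simulations."""
    mesh = generate_tumor_phantom(semi_axes=(4e-3, 4e-3, 5e-3))
    grid = voxelize(mesh, antenna, spacing=1e-3, margin=6e-3)
    return mesh, grid
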