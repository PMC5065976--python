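"""Shared fixtures.

The two end-to-end stimulation runs (cerebellar montage on the head phantom,
spinal montage on the trunk phantom) dominate the suite's runtime, so they
are session-scoped and shared by every test that needs a solved realistic
field.  Both use 2 mm grids: coarse enough for minutes-scale solves on one
CPU, fine enough to resolve every compartment the metrics touch.
"""

from __future__ import annotations

import numpy as np
import pytest

from voxdcs import (
    GridSpec,
    LabelVolume,
    build_sigma_volume,
    default_catalogue,
    make_calibration_phantom,
    plate_electrodes,
    solve_potential,
)
from voxdcs.pipeline import RunConfig, execute


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def slab_solution():
    """Muscle/Fat slab with plate electrodes: the 1-D series oracle fixture."""
    slab = make_calibration_phantom(
        "slab",
        dict(layers=[("Muscle", 10.0), ("Fat", 10.0)], cross_mm=(40.0, 40.0),
             spacing=1.0),
    )
    vol, anode, cathode = plate_electrodes(slab, axis=2)
    sigma = build_sigma_volume(vol)
    phi = solve_potential(sigma, anode, cathode)
    return dict(labels=vol, sigma=sigma, phi=phi, anode=anode, cathode=cathode)


@pytest.fixture(scope="session")
def head_run():
    """Solved cerebellar (ctDCS) run on the youngest-child head preset, 2 mm."""
    return execute(RunConfig(mode="ctdcs", preset="roberta", spacing=2.0, seed=1))


@pytest.fixture(scope="session")
def trunk_run():
    """Solved spinal (tsDCS) run on a trunk preset with cord in all segments."""
    return execute(RunConfig(mode="tsdcs", preset="thelonious", spacing=2.0, seed=1))


def random_field_fixture(rng, shape=(6, 6, 6), n_tissues=3):
    """Small random labeled lattice + vector field for brute-force oracles."""
    from voxdcs.field_analysis import VectorField

    grid = GridSpec(shape=shape, spacing=1.0)
    labels = rng.integers(1, n_tissues + 1, size=shape).astype(np.int16)
    vol = LabelVolume(grid=grid, labels=labels)
    comps = tuple(rng.normal(size=shape) for _ in range(3))
    mask = np.ones(shape, dtype=bool)
    return vol, VectorField(grid=grid, components=comps, mask=mask)
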