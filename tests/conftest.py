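"""Shared fixtures: meshes, caches and a reusable batch of records.

Session-scoped so the expensive artifacts (Eikonal graphs, template
banks, simulated records) are built once and shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from ecgforge import (AnatomyCache, PathologyLabel, anatomy_pool,
                      build_atrial_mesh, build_slab_mesh,
                      build_ventricular_mesh, generate_records)
from ecgforge.activation import ConductionField


@pytest.fixture(scope="session")
def vent_mesh():
    return build_ventricular_mesh()


@pytest.fixture(scope="session")
def atrial_mesh():
    return build_atrial_mesh()


@pytest.fixture(scope="session")
def slab():
    """40 x 20 x 20 mm slab at 1 mm with fibers along x."""
    return build_slab_mesh((40.0, 20.0, 20.0), 1.0, fiber_axis=0)


@pytest.fixture(scope="session")
def slab_center_source(slab):
    p = slab.node_positions
    src = np.flatnonzero((p[:, 0] == 0) & (p[:, 1] == 10) & (p[:, 2] == 10))
    assert len(src) == 1
    return src


def make_cond(mesh, cv=(0.6, 0.3, 0.15)):
    return ConductionField(cv=np.tile(np.asarray(cv, dtype=float),
                                      (mesh.n_elements, 1)),
                           region=mesh.element_region.copy())


@pytest.fixture(scope="session")
def shared_cache():
    return AnatomyCache()


@pytest.fixture(scope="session")
def anatomies():
    return anatomy_pool(2, seed=42)


@pytest.fixture(scope="session")
def sinus_records(anatomies, shared_cache):
    """A small batch of healthy records reused by synthesis/feature tests."""
    return [rec for _, _, rec in generate_records(
        PathologyLabel("sinus"), 8, 2024, anatomies=anatomies,
        cache=shared_cache)]
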