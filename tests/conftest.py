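"""Shared fixtures: phantoms are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from tibtorsion import PhantomSpec, RunConfig, generate_phantom
from tibtorsion.io import SurfaceMesh


@pytest.fixture(scope="session")
def default_phantom():
    """Default right-leg phantom (construction 3D torsion 25 deg)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_bones(default_phantom):
    return default_phantom[0]


@pytest.fixture(scope="session")
def default_truth(default_phantom):
    return default_phantom[1]


@pytest.fixture(scope="session")
def fast_config():
    """Reduced sample counts for stage-level tests with ~1 degree tolerance."""
    return RunConfig(pta_sample_count=40000, slab_sample_count=80000)


@pytest.fixture()
def tetrahedron():
    """Smallest closed mesh: a regular tetrahedron."""
    v = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    )
    f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return SurfaceMesh(v, f, "tibia")


def make_cylinder(radius=10.0, height=100.0, sections=128, axis="y") -> SurfaceMesh:
    tm = trimesh.creation.cylinder(radius=radius, height=height, sections=sections)
    v = np.asarray(tm.vertices)
    if axis == "y":  # trimesh builds along z; rotate properly about x
        v = np.column_stack([v[:, 0], v[:, 2], -v[:, 1]])
    return SurfaceMesh(v, np.asarray(tm.faces), "tibia")
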