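"""Shared fixtures: small analytic meshes and phantom joints.

Everything is generated at test time; expensive phantom builds are
session-scoped so the geometry suite shares them.
"""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from articmorph.mesh_core import SurfacePatch
from articmorph.phantoms import CapSpec, make_joint_phantom, make_phantom_bone


@pytest.fixture()
def unit_square_patch() -> SurfacePatch:
    """Two triangles tiling [0,1]^2 in the z=0 plane."""
    mesh = trimesh.Trimesh(
        vertices=[[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
        faces=[[0, 1, 2], [0, 2, 3]],
        process=False,
    )
    return SurfacePatch(mesh, np.array([0, 1]))


@pytest.fixture(scope="session")
def small_bone():
    """A quick intermediate-cuneiform-like phantom (coarse mesh)."""
    return make_phantom_bone(
        body_length=16.0,
        cap_specs={
            "distal": CapSpec(0.003, 13.0, 21.0),
            "proximal": CapSpec(0.002, 11.5, 19.0),
        },
        resolution=0.45,
        seed=5,
        bone="intermediate_cuneiform",
        side="right",
    )


@pytest.fixture(scope="session")
def small_joint():
    """A quick TMT2-like joint phantom (coarse mesh)."""
    return make_joint_phantom(
        -0.0025, 0.003, joint="TMT2", side="right", seed=11, resolution=0.45
    )


@pytest.fixture(scope="session")
def mt1_joint():
    """A TMT1-like joint phantom (first ray)."""
    return make_joint_phantom(
        0.0018, -0.0015, joint="TMT1", side="left", seed=17, resolution=0.45
    )
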