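"""Shared fixtures: analytic solids and synthetic spines, generated in-process."""

import numpy as np
import pytest
import trimesh

from spineshape.mesh_core import TriangleMesh
from spineshape.synth import CLASS_DEFAULTS, make_spine


@pytest.fixture(scope="session")
def unit_cube() -> TriangleMesh:
    return TriangleMesh.from_trimesh(trimesh.creation.box(extents=[1.0, 1.0, 1.0]))


@pytest.fixture(scope="session")
def unit_sphere() -> TriangleMesh:
    return TriangleMesh.from_trimesh(trimesh.creation.icosphere(subdivisions=4))


@pytest.fixture(scope="session")
def sphere_r2() -> TriangleMesh:
    return TriangleMesh.from_trimesh(trimesh.creation.icosphere(subdivisions=4, radius=2.0))


@pytest.fixture(scope="session")
def coarse_sphere() -> TriangleMesh:
    return TriangleMesh.from_trimesh(trimesh.creation.icosphere(subdivisions=3))


@pytest.fixture(scope="session")
def mushroom_spine() -> TriangleMesh:
    return make_spine(CLASS_DEFAULTS["mushroom"], seed=11)


@pytest.fixture(scope="session")
def thin_spine() -> TriangleMesh:
    return make_spine(CLASS_DEFAULTS["thin"], seed=12)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_convex_mesh(rng: np.random.Generator, n_points: int = 40) -> TriangleMesh:
    pts = rng.standard_normal((n_points, 3))
    hull = trimesh.convex.convex_hull(pts)
    return TriangleMesh.from_trimesh(hull)
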