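"""Shared fixtures: analytic meshes and synthetic scenes, all generated at test time."""

import numpy as np
import pytest
import trimesh

from samsurf.mesh import SurfaceMesh


def to_surface(tm: trimesh.Trimesh) -> SurfaceMesh:
    return SurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))


def icosphere(radius: float, subdivisions: int = 3) -> SurfaceMesh:
    return to_surface(trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius))


def grid_mesh(n: int = 15, spacing: float = 1.0, height=None) -> SurfaceMesh:
    """Open square-grid height-field mesh with upward normals."""
    xs = np.arange(n) * spacing
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    zz = np.zeros_like(xx) if height is None else height(xx, yy)
    verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = a + n
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return SurfaceMesh(verts, np.asarray(faces, np.int64))


def random_mesh(rng: np.random.Generator, n_pts: int = 30) -> SurfaceMesh:
    """Random planar Delaunay triangulation with random heights."""
    from scipy.spatial import Delaunay

    pts = rng.uniform(0, 10, size=(n_pts, 2))
    tri = Delaunay(pts)
    z = rng.normal(0, 1, size=n_pts)
    verts = np.column_stack([pts, z])
    return SurfaceMesh(verts, tri.simplices.astype(np.int64))


@pytest.fixture
def sphere20() -> SurfaceMesh:
    return icosphere(20.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
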