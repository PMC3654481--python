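import numpy as np
import pytest
import trimesh

from ermdquant.geometry import TriangleMesh
from ermdquant.synthetic import make_plane


def icosphere(radius: float, subdivisions: int = 4, center=(0, 0, 0)) -> TriangleMesh:
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh.create(
        np.asarray(m.vertices) + np.asarray(center, dtype=float),
        np.asarray(m.faces),
        name=f"sphere_r{radius:g}",
    )


def cube(side: float) -> TriangleMesh:
    m = trimesh.creation.box(extents=[side, side, side])
    return TriangleMesh.create(m.vertices, m.faces, name="cube")


def centered_plane(size: float, divisions: int, z: float = 0.0) -> TriangleMesh:
    m = make_plane(size, divisions, z_nm=z)
    return TriangleMesh.create(
        m.vertices - np.array([size / 2, size / 2, 0.0]), m.faces, name=f"plane_z{z:g}"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
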