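"""Mesh geometry primitives against analytic and brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ermdquant.geometry import (
    Centerline,
    GeometryError,
    TriangleMesh,
    closest_points_on_mesh,
    extract_patches,
    local_diameters,
    mesh_surface_area,
    min_distance_point_to_mesh,
    patch_min_distance,
    proximity_map,
    sample_surface_points,
)
from ermdquant.synthetic import sweep_tube

from conftest import centered_plane, cube, icosphere


# ---------------------------------------------------------------------------
# surface area
# ---------------------------------------------------------------------------


class TestSurfaceArea:
    def test_sphere_area_converges_to_analytic(self):
        m = icosphere(100.0, subdivisions=4)
        analytic = 4 * np.pi * 100.0**2
        assert abs(mesh_surface_area(m) - analytic) / analytic < 5e-3

    def test_cube_area_exact(self):
        assert mesh_surface_area(cube(1000.0)) == pytest.approx(6e6, rel=1e-12)

    def test_capped_cylinder_area(self):
        # capped cylinder r=150, L=2000 vs 2*pi*r*L + 2*pi*r^2
        cl = np.column_stack(
            [np.linspace(0, 2000, 81), np.zeros(81), np.zeros(81)]
        )
        tube = sweep_tube(cl, 150.0, n_seg=64, cap="flat")
        analytic = 2 * np.pi * 150 * 2000 + 2 * np.pi * 150**2
        assert abs(mesh_surface_area(tube) - analytic) / analytic < 0.01

    def test_rigid_motion_invariance(self, rng):
        m = icosphere(80.0, subdivisions=3)
        rot = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        moved = m.transformed(rotation=rot, translation=[123.4, -56.7, 89.0])
        assert mesh_surface_area(moved) == pytest.approx(
            mesh_surface_area(m), rel=1e-9
        )

    def test_empty_mesh_rejected(self):
        with pytest.raises(GeometryError, match="empty mesh"):
            TriangleMesh.create(np.empty((0, 3)), np.empty((0, 3)))

    def test_degenerate_faces_dropped_at_load(self):
        verts = [[0, 0, 0], [1000, 0, 0], [0, 1000, 0], [500, 500, 0]]
        faces = [[0, 1, 2], [0, 1, 1], [3, 3, 3]]  # two degenerate
        m = TriangleMesh.create(verts, faces)
        assert m.n_faces() == 1


# ---------------------------------------------------------------------------
# point-to-mesh distance
# ---------------------------------------------------------------------------


class TestPointToMeshDistance:
    def test_point_on_vertex_is_zero(self):
        m = icosphere(100.0, subdivisions=2)
        assert min_distance_point_to_mesh(m.vertices[17], m) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_point_above_plane(self):
        pl = centered_plane(4000.0, 40)
        assert min_distance_point_to_mesh([0, 0, 50.0], pl) == pytest.approx(50.0)

    def test_against_dense_surface_sampling_oracle(self, rng):
        # exact distance must lower-bound, and nearly match, a brute-force
        # minimum over dense random surface samples
        m = icosphere(100.0, subdivisions=3)
        cloud = sample_surface_points(m, 200_000, rng)
        for _ in range(10):
            p = rng.uniform(-250, 250, 3)
            exact = min_distance_point_to_mesh(p, m)
            brute = np.linalg.norm(cloud - p, axis=1).min()
            assert exact <= brute + 1e-9
            assert brute - exact < 2.0  # sampling resolution

    def test_interior_point_distance(self):
        # center of a radius-100 sphere is 100 nm from the surface
        m = icosphere(100.0, subdivisions=3)
        assert min_distance_point_to_mesh([0, 0, 0], m) == pytest.approx(
            100.0, rel=1e-2
        )


# ---------------------------------------------------------------------------
# proximity map
# ---------------------------------------------------------------------------


class TestProximityMap:
    def test_parallel_planes_inside_cutoff_all_flagged(self):
        a = centered_plane(2000.0, 20, z=0.0)
        b = centered_plane(2000.0, 20, z=20.0)
        prox = proximity_map(a, b, cutoff=30.0)
        assert prox.flags.all()
        assert np.allclose(prox.distances, 20.0)

    def test_parallel_planes_outside_cutoff_none_flagged(self):
        a = centered_plane(2000.0, 20, z=0.0)
        b = centered_plane(2000.0, 20, z=50.0)
        assert not proximity_map(a, b, cutoff=30.0).flags.any()

    def test_monotone_in_cutoff(self):
        sphere = icosphere(200.0, subdivisions=3, center=(0, 0, 210.0))
        pl = centered_plane(3000.0, 40)
        prev = None
        for cutoff in (15.0, 30.0, 60.0, 120.0):
            flags = proximity_map(sphere, pl, cutoff).flags
            if prev is not None:
                assert (prev <= flags).all()  # flagged set only grows
            prev = flags

    def test_invalid_cutoff_rejected(self):
        a = centered_plane(1000.0, 5)
        with pytest.raises(GeometryError):
            proximity_map(a, a, cutoff=0.0)

    def test_spherical_cap_area_matches_analytic(self):
        # sphere R=200 with a 10 nm gap above a plane, cutoff 30 nm:
        # flagged region is the spherical cap of height h=20, area 2*pi*R*h
        R, gap, cutoff = 200.0, 10.0, 30.0
        sphere = icosphere(R, subdivisions=4, center=(0, 0, R + gap))
        pl = centered_plane(3000.0, 60)
        prox = proximity_map(sphere, pl, cutoff)
        flagged_area = sphere.face_areas[prox.flags].sum()
        analytic = 2 * np.pi * R * (cutoff - gap)
        assert abs(flagged_area - analytic) / analytic < 0.02


# ---------------------------------------------------------------------------
# patch segmentation
# ---------------------------------------------------------------------------


def _union_find_components(mesh, flagged):
    """Independent union-find oracle over the edge-adjacency graph."""
    flagged = set(int(f) for f in flagged)
    parent = {f: f for f in flagged}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in mesh.face_adjacency:
        a, b = int(a), int(b)
        if a in flagged and b in flagged:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    groups = {}
    for f in flagged:
        groups.setdefault(find(f), set()).add(f)
    return {frozenset(g) for g in groups.values()}


class TestExtractPatches:
    def test_two_disjoint_islands(self):
        pl = centered_plane(2000.0, 10)  # 200 faces in a 10x10 quad grid
        # two islands of 10 and 20 faces: quads 0-4 and quads 30-44
        island1 = list(range(0, 10))
        island2 = list(range(60, 90))[:20]
        patches = extract_patches(pl, island1 + island2)
        assert sorted(p.n_faces for p in patches) == [10, 20]

    def test_fully_flagged_closed_mesh_is_one_patch(self):
        m = icosphere(100.0, subdivisions=2)
        patches = extract_patches(m, np.arange(m.n_faces()))
        assert len(patches) == 1
        assert patches[0].area == pytest.approx(m.area, rel=1e-12)

    def test_empty_input_empty_list(self):
        assert extract_patches(icosphere(50.0, 1), []) == []

    def test_matches_union_find_oracle(self, rng):
        m = icosphere(120.0, subdivisions=3)
        flagged = np.flatnonzero(rng.random(m.n_faces()) < 0.3)
        patches = extract_patches(m, flagged)
        ours = {frozenset(int(i) for i in p.face_indices) for p in patches}
        assert ours == _union_find_components(m, flagged)

    def test_partition_invariants(self, rng):
        m = icosphere(120.0, subdivisions=3)
        flagged = np.flatnonzero(rng.random(m.n_faces()) < 0.4)
        patches = extract_patches(m, flagged)
        all_faces = np.concatenate([p.face_indices for p in patches])
        assert len(all_faces) == len(np.unique(all_faces))  # disjoint
        assert set(all_faces.tolist()) == set(flagged.tolist())  # covering
        assert sum(p.area for p in patches) == pytest.approx(
            m.face_areas[flagged].sum(), rel=1e-9
        )


class TestPatchDistance:
    def _patches_on_plane(self):
        pl = centered_plane(2000.0, 20)
        # quad columns: faces are laid out two per grid cell, row-major
        xs = pl.face_centroids[:, 0]
        left = np.flatnonzero(xs < -200.0)
        right = np.flatnonzero(xs > 300.0)
        pa = extract_patches(pl, left)
        pb = extract_patches(pl, right)
        assert len(pa) == 1 and len(pb) == 1
        return pl, pa[0], pb[0]

    def test_facing_edges_distance(self):
        # patches end on vertex columns at x=-200 and x=300: gap 500
        _, a, b = self._patches_on_plane()
        assert patch_min_distance(a, b) == pytest.approx(500.0)

    def test_adjacent_patches_share_vertex_distance_zero(self):
        pl = centered_plane(1000.0, 10)
        xs = pl.face_centroids[:, 0]
        a = extract_patches(pl, np.flatnonzero(xs < 0))[0]
        b = extract_patches(pl, np.flatnonzero(xs > 0))[0]
        assert patch_min_distance(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_self_distance_rejected(self):
        _, a, _ = self._patches_on_plane()
        with pytest.raises(GeometryError, match="self-distance"):
            patch_min_distance(a, a)

    def test_exhaustive_vertex_pair_oracle_and_symmetry(self, rng):
        m = icosphere(150.0, subdivisions=2)
        zones = [
            np.flatnonzero(m.face_centroids[:, 2] > 100),
            np.flatnonzero(m.face_centroids[:, 2] < -100),
            np.flatnonzero(np.abs(m.face_centroids[:, 2]) < 30),
        ]
        patches = [extract_patches(m, z)[0] for z in zones]
        d = {}
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                dij = patch_min_distance(patches[i], patches[j])
                brute = min(
                    np.linalg.norm(
                        patches[i].vertex_points()[:, None, :]
                        - patches[j].vertex_points()[None, :, :],
                        axis=2,
                    ).min()
                    for _ in (0,)
                )
                assert dij == pytest.approx(brute, rel=1e-12)
                d[(i, j)] = dij
        assert d[(0, 1)] == d[(1, 0)]
        # set-to-set min distances obey the relaxed triangle inequality
        # d(A,B) <= d(A,C) + diam(C) + d(C,B) (the plain form does not hold
        # for set distances)
        vc = patches[2].vertex_points()
        diam_c = np.linalg.norm(vc[:, None, :] - vc[None, :, :], axis=2).max()
        assert d[(0, 1)] <= d[(0, 2)] + diam_c + d[(2, 1)] + 1e-9


# ---------------------------------------------------------------------------
# diameter profiles
# ---------------------------------------------------------------------------


class TestLocalDiameters:
    def test_straight_cylinder_profile(self):
        cl = np.column_stack([np.linspace(0, 2000, 81), np.zeros(81), np.zeros(81)])
        tube = sweep_tube(cl, 150.0, n_seg=64, cap="flat")
        axis = Centerline(points=cl)
        profile = local_diameters(tube, axis, step=50.0)
        inner = profile.diameter[3:-3]  # away from caps
        assert np.isfinite(inner).all()
        assert np.allclose(inner, 300.0, rtol=0.02)

    def test_hourglass_waist_diameter(self):
        z = np.linspace(-500, 500, 101)
        r = 150.0 - 100.0 * np.exp(-((z / 100.0) ** 2))
        cl = np.column_stack([z, np.zeros_like(z), np.zeros_like(z)])
        hour = sweep_tube(cl, r, n_seg=64, cap="flat")
        profile = local_diameters(hour, Centerline(points=cl), step=25.0)
        assert np.nanmin(profile.diameter) == pytest.approx(100.0, rel=0.1)

    def test_sphere_chord_profile(self):
        # centerline along a diameter: diameter(s) = 2*sqrt(R^2 - s^2)
        R = 200.0
        m = icosphere(R, subdivisions=4)
        cl = np.column_stack(
            [np.linspace(-R, R, 41), np.zeros(41), np.zeros(41)]
        )
        profile = local_diameters(m, Centerline(points=cl), step=20.0)
        s = profile.arclength - R  # offset from the center
        expected = 2 * np.sqrt(np.maximum(R**2 - s**2, 0.0))
        sel = np.abs(s) < 0.8 * R
        assert np.isfinite(profile.diameter[sel]).all()
        assert np.allclose(profile.diameter[sel], expected[sel], rtol=0.05)

    def test_samples_outside_mesh_flagged_invalid(self):
        # centerline overshooting the sphere: outer samples have no slab
        # vertices and must come back NaN, not raise
        R = 100.0
        m = icosphere(R, subdivisions=3)
        cl = np.column_stack(
            [np.linspace(-3 * R, 3 * R, 61), np.zeros(61), np.zeros(61)]
        )
        profile = local_diameters(m, Centerline(points=cl), step=20.0)
        assert np.isnan(profile.diameter[0]) and np.isnan(profile.diameter[-1])
        mid = np.abs(profile.arclength - 3 * R) < 0.5 * R
        assert np.isfinite(profile.diameter[mid]).all()
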