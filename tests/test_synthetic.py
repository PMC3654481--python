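"""Scene generator: determinism, geometry oracles, ground-truth contracts."""

import numpy as np
import pytest

from ermdquant.geometry import Centerline, local_diameters, min_distance_point_to_mesh
from ermdquant.kinetics import resolution_time
from ermdquant.synthetic import (
    SceneError,
    SimulationConfig,
    SyntheticScene,
    WrapSpec,
    generate_mito_network,
    generate_ribosomes,
    generate_scene,
    generate_tip_tracks,
    make_contact_scene,
    make_plane,
    place_division_events,
    place_foci,
    render_label_stack,
)
from types import MappingProxyType


SMALL = SimulationConfig(
    seed=11,
    n_tubes=2,
    tube_length_nm=2000.0,
    network_extent_nm=(5000.0, 5000.0, 3000.0),
    ring_spacing_nm=40.0,
    mesh_segments=32,
    n_divisions=20,
)

# coverage granularity needs enough surface per whole focus
BIG = SimulationConfig(
    seed=5,
    n_tubes=8,
    tube_length_nm=3300.0,
    network_extent_nm=(8000.0, 8000.0, 4000.0),
    ring_spacing_nm=60.0,
    mesh_segments=24,
    n_divisions=60,
    p_association=0.6,
)


class TestNetwork:
    def test_deterministic_given_seed(self):
        m1, c1 = generate_mito_network(SMALL)
        m2, c2 = generate_mito_network(SMALL)
        for a, b in zip(m1, m2):
            assert np.array_equal(a.vertices, b.vertices)
            assert np.array_equal(a.faces, b.faces)
        for a, b in zip(c1, c2):
            assert np.array_equal(a.points, b.points)

    def test_straight_tube_diameter_profile(self):
        cfg = SimulationConfig(
            seed=1, n_tubes=1, tube_length_nm=2000.0,
            network_extent_nm=(4000.0, 2000.0, 2000.0),
            ring_spacing_nm=40.0, mesh_segments=48,
        )
        meshes, cls = generate_mito_network(cfg, straight=True)
        profile = local_diameters(meshes[0], cls[0], step=100.0)
        inner = profile.diameter[2:-2]
        assert np.allclose(inner, 2 * cfg.tube_radius_nm, rtol=0.02)

    def test_total_area_matches_swept_cylinder_sum(self):
        meshes, cls = generate_mito_network(SMALL)
        total = sum(m.area for m in meshes)
        analytic = sum(
            2 * np.pi * SMALL.tube_radius_nm * c.length
            + 2 * np.pi * SMALL.tube_radius_nm**2
            for c in cls
        )
        assert abs(total - analytic) / analytic < 0.05

    def test_extent_too_small_rejected(self):
        cfg = SimulationConfig(seed=0, network_extent_nm=(400.0, 400.0, 400.0))
        with pytest.raises(SceneError, match="too small"):
            generate_mito_network(cfg)


class TestFoci:
    def test_target_zero_gives_empty_set(self):
        meshes, _ = generate_mito_network(SMALL)
        cfg = SimulationConfig(
            seed=1, target_focus_coverage=0.0, n_tubes=SMALL.n_tubes
        )
        foci, cov = place_foci(meshes, cfg)
        assert len(foci) == 0 and cov == 0.0

    def test_coverage_on_flat_plane_hits_target_band(self):
        # 4.5% disk coverage on a large flat surface, within +/-0.2 pp
        plane = make_plane(20000.0, 40)
        cfg = SimulationConfig(seed=2)
        foci, cov = place_foci([plane], cfg)
        assert 0.043 <= cov <= 0.047
        n_expected = round(0.045 * plane.area / (np.pi * 205.0**2))
        assert len(foci) == n_expected

    def test_centers_respect_min_separation(self):
        plane = make_plane(20000.0, 40)
        foci, _ = place_foci([plane], SimulationConfig(seed=3))
        d = np.linalg.norm(
            foci.points[:, None, :] - foci.points[None, :, :], axis=2
        )
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2 * 205.0

    def test_doubling_radius_quadruples_coverage_at_fixed_count(self):
        plane = make_plane(30000.0, 30)
        c1 = SimulationConfig(seed=4, focus_radius_nm=205.0)
        c2 = SimulationConfig(seed=4, focus_radius_nm=410.0)
        _, cov1 = place_foci([plane], c1, n_override=30)
        _, cov2 = place_foci([plane], c2, n_override=30)
        assert cov2 / cov1 == pytest.approx(4.0, rel=1e-9)

    def test_unreachable_coverage_names_achieved_value(self):
        plane = make_plane(2000.0, 10)  # far too small for whole foci at 4.5%
        with pytest.raises(SceneError, match="achiev"):
            place_foci([plane], SimulationConfig(seed=5))


class TestDivisionEvents:
    def test_full_association_all_events_near_foci(self):
        meshes, _ = generate_mito_network(BIG)
        foci, _ = place_foci(meshes, BIG)
        cfg = SimulationConfig(**{**BIG.__dict__, "p_association": 1.0})
        events, labels = place_division_events(meshes, foci, cfg)
        assert labels.all()
        for e in events:
            d = np.linalg.norm(foci.points - e.position, axis=1).min()
            assert d < 300.0

    def test_zero_association_all_events_far(self):
        meshes, _ = generate_mito_network(BIG)
        foci, _ = place_foci(meshes, BIG)
        cfg = SimulationConfig(**{**BIG.__dict__, "p_association": 0.0})
        events, labels = place_division_events(meshes, foci, cfg)
        assert not labels.any()
        for e in events:
            d = np.linalg.norm(foci.points - e.position, axis=1).min()
            assert d > 300.0

    def test_labels_reproducible_under_seed(self):
        meshes, _ = generate_mito_network(BIG)
        foci, _ = place_foci(meshes, BIG)
        e1, l1 = place_division_events(meshes, foci, BIG)
        e2, l2 = place_division_events(meshes, foci, BIG)
        assert np.array_equal(l1, l2)
        assert np.allclose(
            [e.position for e in e1], [e.position for e in e2]
        )


class TestErAndRibosomes:
    def test_wrap_gap_and_truth_recorded(self):
        cfg = SimulationConfig(
            seed=9, n_tubes=1, tube_length_nm=2400.0,
            network_extent_nm=(4000.0, 3000.0, 3000.0),
            ring_spacing_nm=15.0, mesh_segments=64,
        )
        scene = make_contact_scene(cfg, [WrapSpec(0, 1200.0, 1.0, 20.0)])
        truth = scene.truth["contacts"][0]
        w = np.sqrt((30.0 + 100.0) ** 2 - (20.0 + 100.0) ** 2)
        band = 2 * np.pi * cfg.tube_radius_nm * 2 * w
        assert truth["area_nm2"] == pytest.approx(band, rel=0.02)
        # closest approach of the ER to the mitochondrial surface ~ gap
        from ermdquant.geometry import closest_points_on_mesh

        d, _, _ = closest_points_on_mesh(
            scene.er_mesh, scene.mito_meshes[0].vertices, exact_within=100.0
        )
        assert d.min() == pytest.approx(20.0, abs=2.0)

    def test_free_er_tubes_keep_clearance(self):
        cfg = SimulationConfig(
            seed=10, n_tubes=1, tube_length_nm=2000.0,
            network_extent_nm=(5000.0, 5000.0, 4000.0),
            ring_spacing_nm=30.0, mesh_segments=32,
        )
        scene = make_contact_scene(
            cfg, [WrapSpec(0, 1000.0, 1.0, 20.0)], n_free_er_tubes=2
        )
        # every mito vertex keeps > 50 nm from free ER; wrap region is the
        # only close approach, so just check the 2nd-smallest cluster
        from ermdquant.geometry import closest_points_on_mesh

        d, _, _ = closest_points_on_mesh(
            scene.er_mesh, scene.mito_meshes[0].vertices, exact_within=200.0
        )
        near = d[d < 45.0]
        # near faces only at the wrap: all within the wrap band
        assert (d.min() > 15.0) and near.size > 0

    def test_ribosomes_excluded_from_organelle_interiors(self):
        cfg = SimulationConfig(
            seed=12, n_tubes=1, tube_length_nm=2000.0,
            network_extent_nm=(4000.0, 3000.0, 3000.0),
            ribosome_density_per_um3=500.0,
        )
        meshes, cls = generate_mito_network(cfg, straight=True)
        excl = cls[0].resample(50.0).points
        ribs = generate_ribosomes(
            cfg,
            exclusion_points=excl,
            exclusion_radii=np.full(len(excl), cfg.tube_radius_nm),
        )
        assert len(ribs) > 0
        from scipy.spatial import cKDTree

        d, _ = cKDTree(excl).query(ribs.points)
        assert (d > cfg.tube_radius_nm + cfg.ribosome_radius_nm).all()


class TestTipTracks:
    def test_point_mass_distribution_recovers_exact_times(self):
        cfg = SimulationConfig(
            seed=20, resolution_time_distribution=("point_mass", (30.0,)),
            censor_fraction=0.0,
        )
        tracks, truth = generate_tip_tracks(cfg, 50)
        for t in tracks:
            out = resolution_time(t)
            assert out.status == "resolved"
            assert out.resolution_time_s == 30.0

    def test_drawn_45s_first_detectable_at_frame_3(self):
        cfg = SimulationConfig(
            seed=21, resolution_time_distribution=("point_mass", (45.0,)),
        )
        tracks, _ = generate_tip_tracks(cfg, 10, onset_frames="zero")
        for t in tracks:
            d = t.tip_distances()
            assert (d[:3] < 500.0).all()
            assert (d[3:] > 500.0).all()
            assert resolution_time(t).resolution_time_s == 45.0

    def test_censored_tracks_never_separate(self):
        cfg = SimulationConfig(seed=22, censor_fraction=1.0)
        tracks, truth = generate_tip_tracks(cfg, 29)
        for t, ts in zip(tracks, truth):
            assert ts is None
            assert (t.tip_distances() < 500.0).all()
            assert resolution_time(t).status == "censored"


class TestLabelStacks:
    def _empty_scene(self, cfg):
        from ermdquant.geometry import PointSet

        return SyntheticScene(
            config=cfg, mito_meshes=[], centerlines=[],
            foci=PointSet(np.empty((0, 3))), divisions=[],
            truth=MappingProxyType({}),
        )

    def test_empty_scene_all_zero(self):
        cfg = SimulationConfig(seed=1, network_extent_nm=(2000.0, 2000.0, 1600.0))
        mito, foci = render_label_stack(self._empty_scene(cfg))
        assert mito.sum() == 0 and foci.sum() == 0
        assert mito.shape == (4, 25, 25)  # (z, y, x) at 400/80/80 nm pitch

    def test_sphere_volume_within_10_percent(self):
        # a degenerate 2-sample centerline of length ~1 nm with radius 400
        # renders as a ball; voxelized volume must match 4/3*pi*R^3
        cfg = SimulationConfig(
            seed=1, network_extent_nm=(2000.0, 2000.0, 2000.0),
            voxel_nm=80.0, z_step_nm=80.0, tube_radius_nm=400.0,
        )
        cl = Centerline(points=np.array([[1000.0, 1000, 1000], [1001.0, 1000, 1000]]))
        scene = self._empty_scene(cfg)
        scene.centerlines = [cl]
        mito, _ = render_label_stack(scene)
        vol = mito.sum() * cfg.voxel_nm**2 * cfg.z_step_nm
        analytic = 4 / 3 * np.pi * 400.0**3
        assert abs(vol - analytic) / analytic < 0.10

    def test_foci_only_on_mitochondria(self):
        scene = generate_scene(BIG, with_nucleoids=False)
        mito, foci = render_label_stack(scene)
        assert foci.sum() > 0
        assert not (foci & ~mito).any()

    def test_voxel_budget_guard(self):
        cfg = SimulationConfig(
            seed=1, network_extent_nm=(6000.0, 6000.0, 3000.0), voxel_nm=80.0
        )
        scene = self._empty_scene(cfg)
        with pytest.raises(SceneError, match="voxel"):
            render_label_stack(scene, max_voxels=100)


class TestSceneTruth:
    def test_truth_complete_and_immutable(self):
        scene = generate_scene(BIG)
        for key in (
            "achieved_coverage",
            "p_association",
            "division_labels",
            "nucleoid_labels",
            "resolution_time_distribution",
        ):
            assert key in scene.truth
        with pytest.raises(TypeError):
            scene.truth["p_association"] = 0.9

    def test_scene_determinism_end_to_end(self):
        s1 = generate_scene(BIG)
        s2 = generate_scene(BIG)
        assert np.array_equal(s1.foci.points, s2.foci.points)
        assert np.array_equal(
            s1.truth["division_labels"], s2.truth["division_labels"]
        )
        assert np.allclose(
            [e.position for e in s1.divisions],
            [e.position for e in s2.divisions],
        )
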