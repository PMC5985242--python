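import numpy as np
import pytest

from erp.cej import cut_at_cej
from erp.io import write_mesh
from erp.mesh import arch_of_fdi
from erp.registration import landmark_register
from erp.synthetic import (
    MovementSpec,
    ScanSpec,
    ToothSpec,
    make_arch,
    make_tooth,
    pick_landmarks,
    simulate_scan,
    simulate_treatment,
)
from erp.transforms import ValidationError


class TestMakeTooth:
    def test_default_incisor_watertight(self, incisor):
        mesh, _ = incisor
        assert mesh.is_watertight
        assert mesh.volume > 0

    def test_extent_along_long_axis(self):
        mesh, _ = make_tooth(ToothSpec(crown_height=8.0, root_length=12.0))
        extent = mesh.bounds[1][2] - mesh.bounds[0][2]
        assert extent == pytest.approx(20.0, rel=0.02)

    def test_deterministic_byte_for_byte(self, tmp_path):
        spec = ToothSpec(tooth_id="23", position=(5.0, -3.0, 1.0))
        a, _ = make_tooth(spec)
        b, _ = make_tooth(spec)
        pa = write_mesh(a, tmp_path / "a.ply")
        pb = write_mesh(b, tmp_path / "b.ply")
        assert pa.read_bytes() == pb.read_bytes()

    def test_cej_plane_separates_crown_and_root(self, incisor):
        mesh, plane = incisor
        heights = plane.signed_height(np.asarray(mesh.vertices))
        assert heights.max() == pytest.approx(ToothSpec().crown_height, rel=0.01)
        assert heights.min() == pytest.approx(-ToothSpec().root_length, rel=0.01)

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(ValidationError):
            ToothSpec(crown_height=0.0)


class TestMakeArch:
    def test_two_teeth_do_not_touch(self):
        case = make_arch(n_teeth=2, arch="mandibular")
        assert len(case.dentition) == 2
        ids = case.dentition.ids()
        a = np.asarray(case.dentition[ids[0]].vertices)
        from erp.registration import NearestSurfaceQuery

        _, dist, _ = NearestSurfaceQuery(case.dentition[ids[1]]).query(a)
        assert dist.min() > 0.1

    def test_fourteen_maxillary_ids(self):
        case = make_arch(n_teeth=14, arch="maxillary")
        quadrants = {t[0] for t in case.dentition.ids()}
        assert quadrants == {"1", "2"}
        assert all(arch_of_fdi(t) == "maxillary" for t in case.dentition.ids())

    def test_pairwise_separation_brute_force(self, small_arch):
        """Every tooth pair keeps > 0.1 mm surface clearance, verified by
        exhaustive point-to-triangle distance on subsampled vertices."""
        import trimesh as tm

        ids = small_arch.dentition.ids()
        for i, left in enumerate(ids):
            for right in ids[i + 1 :]:
                points = np.asarray(small_arch.dentition[left].vertices)[::5]
                triangles = np.asarray(small_arch.dentition[right].triangles)
                best = np.inf
                for tri in triangles:
                    closest = tm.triangles.closest_point(
                        np.tile(tri, (len(points), 1, 1)), points
                    )
                    best = min(best, np.linalg.norm(points - closest, axis=1).min())
                assert best > 0.1

    def test_too_many_teeth_for_arch_rejected(self):
        from erp.synthetic import GenerationError

        with pytest.raises(GenerationError):
            make_arch(n_teeth=16, arch="maxillary", arch_width=40.0, arch_depth=30.0)


class TestSimulateTreatment:
    def test_identity_movements_are_noop(self, small_arch):
        moved, truth = simulate_treatment(small_arch, {})
        for tooth_id in small_arch.dentition.ids():
            assert truth[tooth_id].almost_equal(
                __import__("erp").RigidTransform.identity()
            )
            assert np.array_equal(
                np.asarray(moved.dentition[tooth_id].vertices),
                np.asarray(small_arch.dentition[tooth_id].vertices),
            )

    def test_two_degree_tip_rotates_long_axis(self, small_arch):
        tooth_id = small_arch.dentition.ids()[0]
        moved, truth = simulate_treatment(
            small_arch, {tooth_id: MovementSpec(tip_deg=2.0)}
        )
        t = truth[tooth_id]
        assert t.rotation_angle_deg() == pytest.approx(2.0, abs=1e-9)
        old_axis = small_arch.frames[tooth_id][:, 2]
        new_axis = moved.frames[tooth_id][:, 2]
        angle = np.degrees(np.arccos(np.clip(old_axis @ new_axis, -1, 1)))
        assert angle == pytest.approx(2.0, abs=1e-6)

    def test_ground_truth_round_trip(self, small_arch):
        from erp.synthetic import default_movements

        movements = default_movements(small_arch.dentition.ids(), seed=13)
        moved, truth = simulate_treatment(small_arch, movements)
        for tooth_id in small_arch.dentition.ids():
            back = truth[tooth_id].invert().apply(
                np.asarray(moved.dentition[tooth_id].vertices)
            )
            original = np.asarray(small_arch.dentition[tooth_id].vertices)
            assert np.abs(back - original).max() < 1e-9

    def test_unknown_tooth_rejected(self, small_arch):
        with pytest.raises(ValidationError):
            simulate_treatment(small_arch, {"48": MovementSpec(tip_deg=1.0)})

    def test_collision_flagged_with_warning(self, small_arch):
        ids = small_arch.dentition.ids()
        crash = {ids[0]: MovementSpec(translation=(8.0, 0.0, 0.0))}
        with pytest.warns(UserWarning, match="overlap"):
            moved, _ = simulate_treatment(small_arch, crash)
        assert len(moved.overlaps) >= 1


class TestSimulateScan:
    def test_clean_crop_equals_cej_cut(self, small_arch):
        scan = simulate_scan(small_arch, ScanSpec(crop="crown_only", seed=0))
        for tooth_id in small_arch.dentition.ids():
            expected = cut_at_cej(
                small_arch.dentition[tooth_id], small_arch.cej_planes[tooth_id]
            ).crown
            assert np.array_equal(
                np.asarray(scan[tooth_id].vertices), np.asarray(expected.vertices)
            )

    def test_same_seed_identical(self, small_arch):
        spec = ScanSpec(vertex_noise_sd=0.05, decimation_fraction=0.3, seed=21)
        a = simulate_scan(small_arch, spec)
        b = simulate_scan(small_arch, spec)
        for tooth_id in a.ids():
            assert np.array_equal(
                np.asarray(a[tooth_id].vertices), np.asarray(b[tooth_id].vertices)
            )

    def test_noise_magnitude_matches_half_normal(self):
        """Offsets along normals have |N(0, sd)| magnitude, whose mean is
        sd * sqrt(2/pi)."""
        case = make_arch(n_teeth=2, arch="maxillary", mesh_resolution=2)
        sd = 0.05
        noisy = simulate_scan(
            case, ScanSpec(vertex_noise_sd=sd, crop="full_tooth", seed=3)
        )
        displacements = []
        for tooth_id in case.dentition.ids():
            d = np.linalg.norm(
                np.asarray(noisy[tooth_id].vertices)
                - np.asarray(case.dentition[tooth_id].vertices),
                axis=1,
            )
            displacements.append(d)
        displacements = np.concatenate(displacements)
        assert len(displacements) >= 1000
        expected = sd * np.sqrt(2 / np.pi)
        assert np.mean(displacements) == pytest.approx(expected, rel=0.10)

    def test_overdecimation_rejected(self, small_arch):
        from erp.synthetic import GenerationError

        with pytest.raises(GenerationError):
            simulate_scan(small_arch, ScanSpec(decimation_fraction=0.999, seed=0))


class TestPickLandmarks:
    def test_picks_are_non_collinear(self, incisor):
        mesh, plane = incisor
        source, _ = pick_landmarks(mesh, k=3, seed=0, region_plane=plane)
        assert len(source) == 3  # LandmarkSet construction enforces geometry

    def test_exact_picks_recover_transform(self, incisor, small_arch):
        mesh, plane = incisor
        from conftest import random_rigid

        rng = np.random.default_rng(14)
        true = random_rigid(rng, max_angle_deg=20, max_translation=2.0)
        source, target = pick_landmarks(
            mesh, seed=5, transform=true, perturb_sd=0.0, region_plane=plane
        )
        recovered = landmark_register(source, target)
        assert recovered.almost_equal(true, tol=1e-9)

    def test_k_larger_than_vertices_rejected(self, incisor):
        mesh, _ = incisor
        with pytest.raises(ValidationError):
            pick_landmarks(mesh, k=10**6)
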