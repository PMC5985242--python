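import numpy as np
import pytest
import trimesh

from erp.mesh import apply_transform, make_trimesh
from erp.registration import (
    CorrespondenceStarvationError,
    DegeneracyError,
    ICPParams,
    LandmarkSet,
    NearestSurfaceQuery,
    icp_register,
    landmark_register,
)
from erp.transforms import RigidTransform, ValidationError

from conftest import random_rigid


class TestLandmarkSet:
    def test_requires_three_points(self):
        with pytest.raises(ValidationError):
            LandmarkSet([[0, 0, 0], [1, 0, 0]])

    def test_rejects_collinear(self):
        with pytest.raises(DegeneracyError):
            LandmarkSet([[0, 0, 0], [1, 0, 0], [2, 0, 0]])


class TestLandmarkRegister:
    def test_identity_on_equal_sets(self):
        points = LandmarkSet([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        t = landmark_register(points, points)
        assert t.almost_equal(RigidTransform.identity(), tol=1e-12)

    def test_pure_translation_forced(self):
        source = LandmarkSet([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        target = LandmarkSet(source.points + np.array([1.0, 2.0, 3.0]))
        t = landmark_register(source, target)
        assert np.abs(t.rotation - np.eye(3)).max() < 1e-12
        assert np.allclose(t.translation, [1, 2, 3], atol=1e-12)

    def test_quarter_turn_about_z(self):
        source = LandmarkSet([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        target = LandmarkSet([[0, 1, 0], [-1, 0, 0], [0, 0, 1]])
        t = landmark_register(source, target)
        expected = RigidTransform.from_axis_angle([0, 0, 1], 90.0)
        assert t.almost_equal(expected, tol=1e-9)

    def test_exact_recovery_of_random_transforms(self):
        """Kabsch recovers any noiseless rigid motion of non-collinear
        points to numerical precision."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            points = rng.uniform(-10, 10, (3, 3))
            if np.linalg.svd(points - points.mean(0), compute_uv=False)[1] < 1e-3:
                continue
            true = random_rigid(rng, max_translation=50.0)
            recovered = landmark_register(
                LandmarkSet(points), LandmarkSet(true.apply(points))
            )
            assert np.abs(recovered.rotation - true.rotation).max() < 1e-9
            assert np.linalg.norm(recovered.translation - true.translation) < 1e-9

    def test_mismatched_counts_rejected(self):
        a = LandmarkSet([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        b = LandmarkSet([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 1]])
        with pytest.raises(ValidationError, match="counts"):
            landmark_register(a, b)


class TestNearestSurfaceQuery:
    def brute_force(self, mesh, points):
        triangles = np.asarray(mesh.triangles)
        best_d = np.full(len(points), np.inf)
        best_p = np.zeros((len(points), 3))
        for i, tri in enumerate(triangles):
            closest = trimesh.triangles.closest_point(
                np.tile(tri, (len(points), 1, 1)), points
            )
            dist = np.linalg.norm(points - closest, axis=1)
            better = dist < best_d
            best_d[better] = dist[better]
            best_p[better] = closest[better]
        return best_p, best_d

    def test_matches_brute_force_exactly(self, incisor):
        """The KD-tree-pruned query must equal exhaustive point-to-triangle
        minimization — same distances, bit for bit."""
        mesh, _ = incisor
        small = make_trimesh(mesh.vertices, np.asarray(mesh.faces)[:150])
        rng = np.random.default_rng(5)
        points = rng.uniform(-10, 10, (200, 3)) + np.asarray(small.vertices).mean(0)
        query = NearestSurfaceQuery(small)
        _, dist, _ = query.query(points)
        _, brute_d = self.brute_force(small, points)
        assert np.array_equal(dist, brute_d)

    def test_on_surface_points_have_zero_distance(self, incisor):
        mesh, _ = incisor
        query = NearestSurfaceQuery(mesh)
        _, dist, _ = query.query(np.asarray(mesh.vertices)[::7])
        assert dist.max() < 1e-12


class TestICP:
    def test_fixed_point_when_aligned(self, incisor):
        mesh, _ = incisor
        result = icp_register(mesh, mesh)
        assert result.converged
        assert result.rms < 1e-9
        assert result.transform.rotation_angle_deg() < np.degrees(1e-6)

    def test_recovers_known_translation(self, incisor):
        mesh, _ = incisor
        true = RigidTransform(translation=np.array([0.3, 0.0, 0.0]))
        target = apply_transform(mesh, true)
        result = icp_register(mesh, target)
        assert np.linalg.norm(result.transform.translation - [0.3, 0, 0]) < 0.01
        residual = result.transform @ true.invert()
        moved = residual.apply(np.asarray(target.vertices))
        assert np.linalg.norm(moved - np.asarray(target.vertices), axis=1).max() < 0.02

    def test_sphere_rotation_is_degenerate_but_converges(self):
        """A rotated sphere matches itself at any rotation: rms ~ 0, the
        recovered rotation is non-unique but the fit still converges."""
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=8.0)
        rotated = apply_transform(
            sphere, RigidTransform.from_axis_angle([0, 0, 1], 15.0)
        )
        result = icp_register(
            sphere, rotated, params=ICPParams(sample_count=1000, convergence_tol=1e-5)
        )
        assert result.converged
        # the floor is the faceting sag of the tessellated sphere, not zero
        assert result.rms < 0.05

    def test_rms_monotone_without_rejection(self, incisor):
        mesh, _ = incisor
        init = RigidTransform(translation=np.array([0.5, 0.2, -0.3]))
        target = mesh
        result = icp_register(
            apply_transform(mesh, init),
            target,
            params=ICPParams(correspondence_rejection_dist=None, max_iterations=50),
        )
        history = np.asarray(result.rms_history)
        assert np.all(np.diff(history) <= 1e-12)

    def test_subsampling_deterministic(self, incisor):
        mesh, _ = incisor
        target = apply_transform(mesh, RigidTransform(translation=[0.2, 0, 0]))
        params = ICPParams(sample_count=200, seed=42, max_iterations=20)
        a = icp_register(mesh, target, params=params)
        b = icp_register(mesh, target, params=params)
        assert a.transform.almost_equal(b.transform, tol=0.0)
        assert a.rms == b.rms

    def test_correspondence_starvation(self, incisor):
        mesh, _ = incisor
        far = apply_transform(mesh, RigidTransform(translation=[100.0, 0, 0]))
        with pytest.raises(CorrespondenceStarvationError):
            icp_register(mesh, far, params=ICPParams(correspondence_rejection_dist=0.5))

    def test_result_rotation_is_proper(self, treated_arch):
        case = treated_arch["case"]
        truth = treated_arch["truth"]
        tooth_id = case.dentition.ids()[0]
        target = apply_transform(case.dentition[tooth_id], truth[tooth_id])
        result = icp_register(
            case.dentition[tooth_id], target, params=ICPParams(max_iterations=30)
        )
        rot = result.transform.rotation
        assert np.abs(rot.T @ rot - np.eye(3)).max() < 1e-9
        assert abs(np.linalg.det(rot) - 1) < 1e-9
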