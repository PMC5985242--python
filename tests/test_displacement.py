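import numpy as np
import pandas as pd
import pytest
import trimesh

from erp.displacement import (
    COLOR_RGB,
    ColorMapParams,
    DisplacementField,
    classify_colors,
    colorize_mesh,
    compare_pair_report,
    displacement_histogram,
    displacement_stats,
    signed_displacement,
)
from erp.mesh import apply_transform, make_trimesh
from erp.transforms import RigidTransform, ValidationError

from conftest import random_rigid


def planar_patch(z=0.0, n=6, flip=False):
    """A square grid patch in the z=z plane with +z normals (or -z if
    flipped)."""
    xs = np.linspace(0, 10, n)
    xx, yy = np.meshgrid(xs, xs)
    vertices = np.column_stack([xx.ravel(), yy.ravel(), np.full(n * n, z)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    faces = np.asarray(faces)
    if flip:
        faces = faces[:, ::-1]
    return make_trimesh(vertices, faces)


class TestSignedDisplacement:
    def test_self_comparison_is_zero(self, incisor):
        mesh, _ = incisor
        fld = signed_displacement(mesh, mesh)
        assert np.abs(fld.values).max() < 1e-9

    def test_concentric_spheres(self):
        reference = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        test = trimesh.creation.icosphere(subdivisions=3, radius=10.2)
        fld = signed_displacement(test, reference)
        assert np.abs(fld.values - 0.2).max() < 0.01

    def test_inner_sphere_is_negative(self):
        reference = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        test = trimesh.creation.icosphere(subdivisions=3, radius=9.8)
        fld = signed_displacement(test, reference)
        assert np.abs(fld.values + 0.2).max() < 0.01

    def test_plane_offset_sign(self):
        reference = planar_patch(z=0.0)
        below = planar_patch(z=-1.0)
        fld = signed_displacement(below, reference)
        # interior vertices sit exactly 1 mm on the inward side
        assert np.abs(fld.values + 1.0).max() < 1e-9

    def test_rigid_invariance(self, incisor):
        mesh, plane = incisor
        test = apply_transform(mesh, RigidTransform(translation=[0.1, 0.05, 0.0]))
        base = signed_displacement(test, mesh)
        rng = np.random.default_rng(7)
        frame = random_rigid(rng, max_translation=30.0)
        moved = signed_displacement(
            apply_transform(test, frame), apply_transform(mesh, frame)
        )
        assert np.abs(base.values - moved.values).max() < 1e-6

    def test_empty_field_rejected(self):
        with pytest.raises(ValidationError):
            DisplacementField(values=np.array([]))


class TestColors:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.0, "green"),
            (0.75, "green"),
            (-0.75, "green"),
            (0.76, "red"),
            (-0.76, "blue"),
        ],
    )
    def test_threshold_convention(self, value, expected):
        """Within the 0.75 mm band (inclusive) is green; outward excess red,
        inward excess blue."""
        fld = DisplacementField(values=np.array([value]))
        labels, rgb = classify_colors(fld, ColorMapParams(threshold=0.75))
        assert labels[0] == expected
        assert tuple(rgb[0]) == COLOR_RGB[expected]

    def test_partition_is_total(self):
        rng = np.random.default_rng(8)
        fld = DisplacementField(values=rng.normal(0, 1, 5000))
        labels, _ = classify_colors(fld)
        assert set(labels) <= {"green", "blue", "red"}
        counts = sum((labels == c).sum() for c in ("green", "blue", "red"))
        assert counts == len(fld)

    def test_colorize_mesh_paints_every_vertex(self, incisor):
        mesh, _ = incisor
        fld = signed_displacement(mesh, mesh)
        colored = colorize_mesh(mesh, fld)
        rgb = np.asarray(colored.visual.vertex_colors)[:, :3]
        assert np.all(rgb == COLOR_RGB["green"])

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValidationError):
            ColorMapParams(threshold=0.0)


class TestStats:
    def test_all_zero_field(self):
        stats = displacement_stats(DisplacementField(values=np.zeros(3)))
        assert stats.as_tuple() == (0.0, 0.0, 0.0)

    def test_plus_minus_one_closed_form(self):
        stats = displacement_stats(DisplacementField(values=np.array([1.0, -1.0])))
        assert stats.mean == 0.0
        assert stats.sd == 1.0  # population SD
        assert stats.max_abs == 1.0
        assert stats.n_vertices == 2

    def test_max_is_absolute(self):
        stats = displacement_stats(DisplacementField(values=np.array([0.1, -2.5])))
        assert stats.max_abs == 2.5


class TestHistogram:
    def test_point_mass_lands_in_zero_bin(self):
        fld = DisplacementField(values=np.zeros(3))
        edges, counts = displacement_histogram(fld, bin_width=0.5, range=(-2, 2))
        bin_of_zero = np.searchsorted(edges, 0.0, side="right") - 1
        assert counts[bin_of_zero] == 3
        assert counts.sum() == 3

    def test_counts_match_direct_binning_oracle(self):
        rng = np.random.default_rng(9)
        values = rng.normal(0, 0.8, 4000)
        fld = DisplacementField(values=values)
        edges, counts = displacement_histogram(fld, bin_width=0.25, range=(-2, 2))
        clipped = np.clip(values, -2, np.nextafter(2, -np.inf))
        oracle = np.array(
            [((clipped >= lo) & (clipped < hi)).sum() for lo, hi in zip(edges[:-1], edges[1:])]
        )
        oracle[-1] += (clipped == edges[-1]).sum()
        assert np.array_equal(counts, oracle)

    def test_out_of_range_values_clipped_into_end_bins(self):
        fld = DisplacementField(values=np.array([-10.0, 10.0, 0.0]))
        edges, counts = displacement_histogram(fld, bin_width=1.0, range=(-2, 2))
        assert counts[0] >= 1 and counts[-1] >= 1
        assert counts.sum() == 3

    def test_inverted_range_rejected(self):
        with pytest.raises(ValidationError):
            displacement_histogram(DisplacementField(values=np.zeros(1)), range=(2, -2))


class TestPairReport:
    def test_identical_pairs_give_zero_rows(self, small_arch):
        pairs = {
            t: (small_arch.dentition[t], small_arch.dentition[t])
            for t in small_arch.dentition.ids()
        }
        report = compare_pair_report(pairs, cej_planes=small_arch.cej_planes)
        assert set(report.stats["analysis"]) == {"crowns", "roots"}
        assert np.abs(report.stats[["mean_mm", "sd_mm", "max_mm"]].to_numpy()).max() < 1e-9

    def test_outward_root_displacement_detected(self, incisor):
        """Moving only the root surface outward by 0.5 mm must show in the
        root rows and leave the crown rows at zero."""
        mesh, plane = incisor
        vertices = np.asarray(mesh.vertices).copy()
        heights = plane.signed_height(vertices)
        normals = np.asarray(mesh.vertex_normals)
        ramp = np.clip(-heights / 1.0, 0.0, 1.0)  # full offset 1 mm below CEJ
        test = make_trimesh(vertices + (0.5 * ramp)[:, None] * normals, mesh.faces)
        report = compare_pair_report(
            {"11": (test, mesh)}, cej_planes={"11": plane}
        )
        stats = report.stats.set_index("analysis")
        assert abs(stats.loc["crowns", "mean_mm"]) < 0.02
        assert stats.loc["roots", "mean_mm"] == pytest.approx(0.5, abs=0.08)

    def test_missing_cej_planes_rejected(self, incisor):
        mesh, plane = incisor
        with pytest.raises(ValidationError, match="CEJ"):
            compare_pair_report({"11": (mesh, mesh)}, cej_planes={"21": plane})

    def test_csv_round_trip(self, tmp_path, small_arch):
        pairs = {
            t: (small_arch.dentition[t], small_arch.dentition[t])
            for t in small_arch.dentition.ids()
        }
        report = compare_pair_report(pairs, cej_planes=small_arch.cej_planes)
        report.write(tmp_path)
        frame = pd.read_csv(tmp_path / "displacement_stats.csv")
        assert list(frame.columns) == [
            "analysis", "arch", "mean_mm", "sd_mm", "max_mm", "n_vertices",
        ]
        assert (tmp_path / "histogram_crowns_maxillary.csv").exists()
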