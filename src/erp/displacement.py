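"""Signed surface-displacement fields, color maps and summary statistics.

A :class:`DisplacementField` holds, for every vertex of a *test* mesh, its
signed distance to the nearest point on a *reference* surface: positive when
the test vertex lies on the outward-normal side of the reference surface at
the nearest point (outside), negative when inside.

The three-color classification follows the convention used for clinical
displacement maps: values within +/- ``threshold`` (default 0.75 mm,
boundary inclusive) are green, inward excess (< -threshold) blue, outward
excess (> +threshold) red.

Statistics per field are the signed mean, the population standard deviation
and the maximum absolute displacement — the row schema of a clinical
displacement-map analysis table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .mesh import LabeledDentition, make_trimesh, validate_mesh
from .registration import NearestSurfaceQuery
from .transforms import ValidationError

__all__ = [
    "DisplacementField",
    "ColorMapParams",
    "DisplacementStats",
    "signed_displacement",
    "classify_colors",
    "displacement_stats",
    "displacement_histogram",
    "compare_pair_report",
    "PairReport",
    "COLOR_RGB",
]

#: uchar RGB for the three displacement classes
COLOR_RGB = {
    "green": (0, 255, 0),
    "blue": (0, 0, 255),
    "red": (255, 0, 0),
}


@dataclass(frozen=True)
class DisplacementField:
    """Per-vertex signed distances (mm) of a test mesh vs a reference."""

    values: np.ndarray
    test_id: str = "test"
    reference_id: str = "reference"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).reshape(-1)
        if len(values) == 0:
            raise ValidationError("displacement field must have >= 1 value")
        if not np.all(np.isfinite(values)):
            raise ValidationError("displacement field contains non-finite values")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ColorMapParams:
    """Only knob: the green band half-width in mm (default 0.75)."""

    threshold: float = 0.75

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("color threshold must be > 0")


@dataclass(frozen=True)
class DisplacementStats:
    mean: float
    sd: float
    max_abs: float
    n_vertices: int

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.mean, self.sd, self.max_abs)


def signed_displacement(
    test: trimesh.Trimesh,
    reference: trimesh.Trimesh,
    test_id: str = "test",
    reference_id: str = "reference",
    query: NearestSurfaceQuery | None = None,
) -> DisplacementField:
    """Signed distance of every test vertex to the reference surface.

    Distance is point-to-triangle (exact nearest point on the surface, never
    nearest vertex); the sign is the side of the reference surface at the
    nearest point, taken from that triangle's outward normal.  Pass a
    prebuilt ``query`` to amortize the reference spatial index across calls.
    """
    validate_mesh(test, name="test mesh")
    if query is None:
        validate_mesh(reference, name="reference mesh")
        if np.asarray(reference.area_faces).max() <= 0:
            raise ValidationError("reference mesh has only zero-area triangles")
        query = NearestSurfaceQuery(reference)
    points = np.asarray(test.vertices)
    closest, dist, tri = query.query(points)
    side = np.einsum("ij,ij->i", points - closest, query.face_normals[tri])
    signs = np.where(side < 0, -1.0, 1.0)
    return DisplacementField(values=signs * dist, test_id=test_id, reference_id=reference_id)


def classify_colors(
    fld: DisplacementField, params: ColorMapParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Classify each vertex as green / blue / red.

    ``|d| <= threshold`` is green (the band is inclusive), ``d < -threshold``
    blue (inward), ``d > +threshold`` red (outward).  Returns
    ``(labels, rgb)`` where labels is an array of strings and rgb an
    (n, 3) uint8 array.
    """
    params = params or ColorMapParams()
    values = fld.values
    labels = np.full(len(values), "green", dtype=object)
    labels[values < -params.threshold] = "blue"
    labels[values > params.threshold] = "red"
    rgb = np.array([COLOR_RGB[label] for label in labels], dtype=np.uint8)
    return labels, rgb


def colorize_mesh(
    test: trimesh.Trimesh, fld: DisplacementField, params: ColorMapParams | None = None
) -> trimesh.Trimesh:
    """Copy of the test mesh with the three-class colors painted per vertex."""
    if len(fld) != len(test.vertices):
        raise ValidationError(
            f"field length {len(fld)} != vertex count {len(test.vertices)}"
        )
    _, rgb = classify_colors(fld, params)
    return make_trimesh(test.vertices, test.faces, vertex_colors=rgb)


def displacement_stats(fld: DisplacementField) -> DisplacementStats:
    """Signed mean, population SD and maximum absolute displacement."""
    values = fld.values
    return DisplacementStats(
        mean=float(values.mean()),
        sd=float(values.std(ddof=0)),
        max_abs=float(np.abs(values).max()),
        n_vertices=len(values),
    )


def displacement_histogram(
    fld: DisplacementField,
    bin_width: float = 0.25,
    range: tuple[float, float] = (-2.0, 2.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of signed displacements; values beyond the range are
    clipped into the end bins so counts always sum to the vertex count.

    Returns ``(bin_edges, counts)`` with ``len(edges) == len(counts) + 1``.
    """
    lo, hi = range
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    if hi <= lo:
        raise ValidationError(f"inverted histogram range ({lo}, {hi})")
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-12)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi)
    clipped = np.clip(fld.values, lo, np.nextafter(hi, -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    return edges, counts


# ----------------------------------------------------------------------
# paired-dentition reports


@dataclass
class PairReport:
    """Displacement analysis of paired dentitions, crowns and roots pooled
    per arch (per-tooth breakdown kept as a supplement)."""

    stats: pd.DataFrame
    per_tooth_stats: pd.DataFrame
    fields: dict = field(default_factory=dict)          # (analysis, arch) -> DisplacementField
    histograms: dict = field(default_factory=dict)      # (analysis, arch) -> (edges, counts)
    colored: dict = field(default_factory=dict)         # (analysis, arch) -> LabeledDentition

    def write(self, out_dir) -> None:
        """Write stats CSV, per-tooth CSV, histogram CSVs and colored PLYs."""
        from pathlib import Path

        from .io import write_dentition

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.stats.to_csv(out_dir / "displacement_stats.csv", index=False)
        self.per_tooth_stats.to_csv(out_dir / "displacement_stats_per_tooth.csv", index=False)
        for (analysis, arch), (edges, counts) in self.histograms.items():
            pd.DataFrame(
                {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
            ).to_csv(out_dir / f"histogram_{analysis}_{arch}.csv", index=False)
        for (analysis, arch), dentition in self.colored.items():
            write_dentition(
                dentition, out_dir / f"colormap_{analysis}_{arch}", with_colors=True
            )


def compare_pair_report(
    pairs: dict,
    cej_planes: dict | None = None,
    params: ColorMapParams | None = None,
    bin_width: float = 0.25,
    hist_range: tuple[float, float] = (-2.0, 2.0),
    arch_of: dict | None = None,
) -> PairReport:
    """Crown and root displacement analysis over paired tooth meshes.

    Parameters
    ----------
    pairs
        ``tooth_id -> (test_mesh, reference_mesh)`` in one common frame
        (e.g. the output of indirect superimposition: ERP tooth vs control
        CBCT tooth).
    cej_planes
        ``tooth_id -> CEJPlane`` in the same frame.  Required for the roots
        scenario; with planes present each pair is analyzed twice, once for
        the crown parts and once for the root parts.  Without planes only a
        whole-tooth "crowns" analysis is produced.
    arch_of
        ``tooth_id -> arch``; inferred from FDI codes when omitted.

    Per arch and scenario, per-vertex signed displacements of all teeth are
    pooled unweighted into one field, summarized (signed mean, population SD,
    max |d|), histogrammed, and painted onto a colored copy of the test part.
    """
    from .cej import cut_at_cej
    from .mesh import arch_of_fdi

    if not pairs:
        raise ValidationError("no tooth pairs to compare")
    params = params or ColorMapParams()
    scenarios = ["crowns", "roots"] if cej_planes is not None else ["crowns"]
    if cej_planes is not None:
        missing = sorted(set(pairs) - set(cej_planes))
        if missing:
            raise ValidationError(f"missing CEJ planes for teeth: {missing}")
    if arch_of is None:
        arch_of = {tooth_id: arch_of_fdi(tooth_id) for tooth_id in pairs}

    pooled: dict = {}
    per_tooth_rows = []
    colored: dict = {}

    for tooth_id in sorted(pairs):
        test, reference = pairs[tooth_id]
        arch = arch_of[tooth_id]
        parts: dict[str, tuple[trimesh.Trimesh, trimesh.Trimesh] | None] = {}
        if cej_planes is None:
            parts["crowns"] = (test, reference)
        else:
            plane = cej_planes[tooth_id]
            cut_test = cut_at_cej(test, plane)
            cut_ref = cut_at_cej(reference, plane)
            parts["crowns"] = (
                (cut_test.crown, cut_ref.crown)
                if cut_test.crown is not None and cut_ref.crown is not None
                else None
            )
            parts["roots"] = (
                (cut_test.root, cut_ref.root)
                if cut_test.root is not None and cut_ref.root is not None
                else None
            )
        for analysis in scenarios:
            pair = parts.get(analysis)
            if pair is None:
                continue
            test_part, ref_part = pair
            fld = signed_displacement(
                test_part, ref_part, test_id=f"{tooth_id}", reference_id=f"{tooth_id}"
            )
            pooled.setdefault((analysis, arch), []).append(fld.values)
            stats = displacement_stats(fld)
            per_tooth_rows.append(
                {
                    "analysis": analysis,
                    "arch": arch,
                    "tooth": tooth_id,
                    "mean_mm": stats.mean,
                    "sd_mm": stats.sd,
                    "max_mm": stats.max_abs,
                    "n_vertices": stats.n_vertices,
                }
            )
            colored.setdefault((analysis, arch), LabeledDentition()).add(
                tooth_id, colorize_mesh(test_part, fld, params), arch
            )

    fields = {}
    histograms = {}
    rows = []
    arches_present = [a for a in ("maxillary", "mandibular") if a in set(arch_of.values())]
    for analysis in scenarios:
        for arch in arches_present:
            chunks = pooled.get((analysis, arch))
            if not chunks:
                continue
            fld = DisplacementField(
                np.concatenate(chunks),
                test_id=f"{analysis}:{arch}",
                reference_id=f"{analysis}:{arch}",
            )
            fields[(analysis, arch)] = fld
            histograms[(analysis, arch)] = displacement_histogram(
                fld, bin_width=bin_width, range=hist_range
            )
            stats = displacement_stats(fld)
            rows.append(
                {
                    "analysis": analysis,
                    "arch": arch,
                    "mean_mm": stats.mean,
                    "sd_mm": stats.sd,
                    "max_mm": stats.max_abs,
                    "n_vertices": stats.n_vertices,
                }
            )

    return PairReport(
        stats=pd.DataFrame(rows),
        per_tooth_stats=pd.DataFrame(per_tooth_rows),
        fields=fields,
        histograms=histograms,
        colored=colored,
    )


def plot_histogram(fld: DisplacementField, ax=None, bin_width: float = 0.25,
                   range: tuple[float, float] = (-2.0, 2.0)):
    """Bar plot of a displacement histogram (requires matplotlib)."""
    import matplotlib.pyplot as plt

    edges, counts = displacement_histogram(fld, bin_width=bin_width, range=range)
    if ax is None:
        _, ax = plt.subplots()
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", edgecolor="black")
    ax.set_xlabel("signed displacement (mm)")
    ax.set_ylabel("vertex count")
    return ax
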