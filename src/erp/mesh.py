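"""Mesh containers and validation.

The canonical triangle-mesh container throughout the package is
:class:`trimesh.Trimesh` (vertices in mm, integer face triples, optional
per-vertex uchar RGB colors).  :func:`validate_mesh` enforces the structural
invariants every pipeline stage assumes: finite coordinates, at least one
face, in-range face indices and no degenerate (repeated-index) faces.

A :class:`LabeledDentition` maps FDI two-digit tooth codes to meshes and
records which arch (maxillary / mandibular) each tooth belongs to.  FDI
quadrants 1 and 2 are maxillary, 3 and 4 mandibular.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import trimesh

from .transforms import RigidTransform, ValidationError

__all__ = [
    "EmptyMeshError",
    "LabeledDentition",
    "apply_transform",
    "make_trimesh",
    "validate_mesh",
    "arch_of_fdi",
    "VALID_FDI",
]

#: all 32 permanent-dentition FDI codes
VALID_FDI = frozenset(
    f"{quadrant}{pos}" for quadrant in (1, 2, 3, 4) for pos in range(1, 9)
)


class EmptyMeshError(ValidationError):
    """Mesh has no faces."""


def arch_of_fdi(tooth_id: str) -> str:
    """Arch membership implied by an FDI code: quadrants 1,2 -> maxillary,
    3,4 -> mandibular.  Rejects anything outside codes 11-48."""
    if tooth_id not in VALID_FDI:
        raise ValidationError(f"not a valid FDI tooth code: {tooth_id!r}")
    return "maxillary" if tooth_id[0] in "12" else "mandibular"


def validate_mesh(mesh: trimesh.Trimesh, name: str = "mesh") -> trimesh.Trimesh:
    """Check structural invariants; return the mesh unchanged if valid."""
    vertices = np.asarray(mesh.vertices)
    faces = np.asarray(mesh.faces)
    if len(faces) == 0:
        raise EmptyMeshError(f"{name}: mesh has no faces")
    if not np.all(np.isfinite(vertices)):
        raise ValidationError(f"{name}: non-finite vertex coordinates")
    if faces.min() < 0 or faces.max() >= len(vertices):
        raise ValidationError(
            f"{name}: face index out of range (max {faces.max()}, "
            f"{len(vertices)} vertices)"
        )
    degenerate = (
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )
    if degenerate.any():
        raise ValidationError(
            f"{name}: {int(degenerate.sum())} degenerate faces (repeated indices)"
        )
    return mesh


def make_trimesh(
    vertices: np.ndarray,
    faces: np.ndarray,
    vertex_colors: np.ndarray | None = None,
    validate: bool = True,
) -> trimesh.Trimesh:
    """Build a Trimesh without any of trimesh's automatic processing
    (no merging, no winding fixes) so vertex order and count are preserved."""
    mesh = trimesh.Trimesh(
        vertices=np.asarray(vertices, dtype=float),
        faces=np.asarray(faces, dtype=np.int64),
        process=False,
    )
    if vertex_colors is not None:
        mesh.visual.vertex_colors = vertex_colors
    if validate:
        validate_mesh(mesh)
    return mesh


def apply_transform(mesh: trimesh.Trimesh, transform: RigidTransform) -> trimesh.Trimesh:
    """Return a copy with every vertex mapped through ``transform``;
    connectivity (and colors, if any) unchanged."""
    out = mesh.copy()
    out.vertices = transform.apply(np.asarray(mesh.vertices))
    return out


@dataclass
class LabeledDentition:
    """A set of labeled tooth meshes with per-tooth arch membership.

    ``teeth`` maps FDI codes to meshes; ``arch`` maps the same codes to
    ``"maxillary"`` or ``"mandibular"``.  When an arch entry is omitted at
    insertion it is inferred from the FDI quadrant.
    """

    teeth: dict[str, trimesh.Trimesh] = field(default_factory=dict)
    arch: dict[str, str] = field(default_factory=dict)

    def add(self, tooth_id: str, mesh: trimesh.Trimesh, arch: str | None = None) -> None:
        if tooth_id in self.teeth:
            raise ValidationError(f"duplicate tooth ID {tooth_id!r}")
        if arch is None:
            arch = arch_of_fdi(tooth_id)
        elif arch not in ("maxillary", "mandibular"):
            raise ValidationError(f"unknown arch {arch!r}")
        validate_mesh(mesh, name=f"tooth {tooth_id}")
        self.teeth[tooth_id] = mesh
        self.arch[tooth_id] = arch

    def __contains__(self, tooth_id: str) -> bool:
        return tooth_id in self.teeth

    def __len__(self) -> int:
        return len(self.teeth)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.teeth))

    def __getitem__(self, tooth_id: str) -> trimesh.Trimesh:
        return self.teeth[tooth_id]

    def ids(self) -> list[str]:
        return sorted(self.teeth)

    def arch_ids(self, arch: str) -> list[str]:
        """Tooth IDs belonging to one arch, sorted."""
        return sorted(t for t, a in self.arch.items() if a == arch)

    def arches(self) -> list[str]:
        """Arches actually present, maxillary first."""
        present = set(self.arch.values())
        return [a for a in ("maxillary", "mandibular") if a in present]

    def transformed(
        self, transforms: "dict[str, RigidTransform] | RigidTransform"
    ) -> "LabeledDentition":
        """Copy with per-tooth transforms (a dict) or one global transform
        applied to every tooth."""
        out = LabeledDentition()
        for tooth_id in self:
            if isinstance(transforms, RigidTransform):
                t = transforms
            else:
                t = transforms.get(tooth_id, RigidTransform.identity())
            out.add(tooth_id, apply_transform(self.teeth[tooth_id], t), self.arch[tooth_id])
        return out

    def subset(self, tooth_ids) -> "LabeledDentition":
        out = LabeledDentition()
        for tooth_id in tooth_ids:
            out.add(tooth_id, self.teeth[tooth_id], self.arch[tooth_id])
        return out
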