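"""Crown/root separation at the cemento-enamel junction (CEJ).

Clinically the CEJ is the anatomical boundary between crown enamel and root
cementum.  The cut here is plane-based: a :class:`CEJPlane` (point + unit
normal oriented crown-ward) is fitted to >= 3 user-picked CEJ landmarks, or
known by construction for synthetic teeth.  :func:`cut_at_cej` partitions a
tooth mesh into crown and root parts, splitting triangles that cross the
plane so both halves terminate exactly at it; boundaries are left open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import trimesh
from trimesh.intersections import slice_mesh_plane

from .mesh import validate_mesh
from .registration import DegeneracyError, LandmarkSet
from .transforms import RigidTransform, ValidationError

__all__ = ["CEJPlane", "CutResult", "cut_at_cej", "fit_cej_plane"]


@dataclass(frozen=True)
class CEJPlane:
    """Cutting plane with the normal pointing toward the crown."""

    point: np.ndarray
    normal: np.ndarray
    tooth_id: str | None = None

    def __post_init__(self) -> None:
        point = np.asarray(self.point, dtype=float).reshape(3)
        normal = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            raise ValidationError("CEJ plane normal must be non-zero")
        object.__setattr__(self, "point", point)
        object.__setattr__(self, "normal", normal / norm)

    def signed_height(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of points from the plane; positive = crown side."""
        return (np.atleast_2d(points) - self.point) @ self.normal

    def transformed(self, transform: RigidTransform) -> "CEJPlane":
        return CEJPlane(
            point=transform.apply(self.point),
            normal=transform.rotation @ self.normal,
            tooth_id=self.tooth_id,
        )

    def to_dict(self) -> dict:
        out = {"point": self.point.tolist(), "normal": self.normal.tolist()}
        if self.tooth_id is not None:
            out["tooth"] = self.tooth_id
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "CEJPlane":
        return cls(
            point=np.asarray(data["point"], dtype=float),
            normal=np.asarray(data["normal"], dtype=float),
            tooth_id=data.get("tooth"),
        )


class CutResult(NamedTuple):
    crown: trimesh.Trimesh | None
    root: trimesh.Trimesh | None
    crown_empty: bool
    root_empty: bool


def fit_cej_plane(
    landmarks: LandmarkSet | np.ndarray,
    crownward_hint: np.ndarray,
    tooth_id: str | None = None,
) -> CEJPlane:
    """Least-squares plane through >= 3 non-collinear CEJ landmark points.

    The plane normal is the smallest principal direction of the centered
    points; its sign is chosen so that ``crownward_hint`` (any point known to
    lie on the crown side, e.g. a cusp tip) has positive signed height.
    """
    if isinstance(landmarks, LandmarkSet):
        points = landmarks.points
        tooth_id = tooth_id or landmarks.tooth_id
    else:
        points = np.asarray(landmarks, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3 or len(points) < 3:
            raise ValidationError("need an (n>=3, 3) array of CEJ points")
    centroid = points.mean(axis=0)
    centered = points - centroid
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-9:
        raise DegeneracyError("CEJ landmarks are collinear")
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    hint = np.asarray(crownward_hint, dtype=float).reshape(3)
    if (hint - centroid) @ normal < 0:
        normal = -normal
    return CEJPlane(point=centroid, normal=normal, tooth_id=tooth_id)


def _half(mesh: trimesh.Trimesh, plane: CEJPlane, crown_side: bool) -> trimesh.Trimesh | None:
    normal = plane.normal if crown_side else -plane.normal
    part = slice_mesh_plane(
        mesh, plane_normal=normal, plane_origin=plane.point, cap=False
    )
    if part is None or len(part.faces) == 0:
        return None
    return part


def cut_at_cej(tooth: trimesh.Trimesh, plane: CEJPlane) -> CutResult:
    """Split a tooth mesh into (crown, root) at the CEJ plane.

    Triangles crossing the plane are split along it, so the two parts
    together conserve the input surface area; the cut boundary is left open
    (no capping).  A plane missing the mesh entirely is not an error: the
    empty side is ``None`` and flagged in the result.
    """
    validate_mesh(tooth, name="tooth to cut")
    crown = _half(tooth, plane, crown_side=True)
    root = _half(tooth, plane, crown_side=False)
    return CutResult(
        crown=crown,
        root=root,
        crown_empty=crown is None,
        root_empty=root is None,
    )
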