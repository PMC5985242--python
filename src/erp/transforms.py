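"""Rigid transforms (rotation + translation, no scaling).

All geometry in this package lives in millimetres.  A :class:`RigidTransform`
maps a point ``v`` to ``R @ v + t`` where ``R`` is a proper rotation
(orthonormal, det = +1) and ``t`` a translation vector.  CBCT volumes render
dentofacial structures at a 1:1 scale, so no scale factor is ever estimated
or applied anywhere in the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform", "ValidationError"]

#: tolerance for orthonormality / unit-determinant checks
_ORTHO_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_rotation(rotation: np.ndarray, tol: float = _ORTHO_TOL) -> None:
    if rotation.shape != (3, 3):
        raise ValidationError(f"rotation must be 3x3, got {rotation.shape}")
    if not np.all(np.isfinite(rotation)):
        raise ValidationError("rotation contains non-finite entries")
    err = np.abs(rotation.T @ rotation - np.eye(3)).max()
    if err > tol:
        raise ValidationError(f"rotation not orthonormal (max error {err:.3e})")
    det = np.linalg.det(rotation)
    if abs(det - 1.0) > tol:
        raise ValidationError(f"rotation determinant {det:.12f} != +1 (improper)")


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion of 3-space, ``v -> rotation @ v + translation``.

    Parameters
    ----------
    rotation
        3x3 orthonormal matrix with determinant +1 (checked to 1e-9).
    translation
        Length-3 vector in mm.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        rotation = np.asarray(self.rotation, dtype=float)
        translation = np.asarray(self.translation, dtype=float).reshape(3)
        _check_rotation(rotation)
        if not np.all(np.isfinite(translation)):
            raise ValidationError("translation contains non-finite entries")
        object.__setattr__(self, "rotation", rotation)
        object.__setattr__(self, "translation", translation)

    # ------------------------------------------------------------------
    # constructors
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix (row-major convention)."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise ValidationError(f"expected 4x4 matrix, got {matrix.shape}")
        if not np.allclose(matrix[3], [0, 0, 0, 1], atol=1e-9):
            raise ValidationError("last row of homogeneous matrix must be [0,0,0,1]")
        return cls(rotation=matrix[:3, :3], translation=matrix[:3, 3])

    @classmethod
    def from_axis_angle(
        cls,
        axis: np.ndarray,
        angle_deg: float,
        center: np.ndarray | None = None,
    ) -> "RigidTransform":
        """Rotation of ``angle_deg`` about ``axis`` through ``center`` (origin
        if omitted)."""
        from scipy.spatial.transform import Rotation

        axis = np.asarray(axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValidationError("axis must be non-zero")
        rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / norm).as_matrix()
        if center is None:
            return cls(rotation=rot)
        center = np.asarray(center, dtype=float).reshape(3)
        return cls(rotation=rot, translation=center - rot @ center)

    # ------------------------------------------------------------------
    # algebra
    def matrix(self) -> np.ndarray:
        """Return the 4x4 homogeneous matrix."""
        out = np.eye(4)
        out[:3, :3] = self.rotation
        out[:3, 3] = self.translation
        return out

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) array of points (or a single point)."""
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Composition ``self ∘ other``: ``other`` is applied first.

        The accumulated rotation is re-orthonormalized (nearest rotation by
        SVD) so long chains never drift away from SO(3).
        """
        rotation = _nearest_rotation(self.rotation @ other.rotation)
        translation = self.rotation @ other.translation + self.translation
        return RigidTransform(rotation=rotation, translation=translation)

    def invert(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rotation=rot_inv, translation=-rot_inv @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation in degrees."""
        cos = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def almost_equal(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return (
            np.abs(self.rotation - other.rotation).max() <= tol
            and np.abs(self.translation - other.translation).max() <= tol
        )

    # ------------------------------------------------------------------
    # serialization (JSON with a 4x4 row-major "matrix" key)
    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"matrix": self.matrix().tolist()}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            data = json.load(fh)
        if "matrix" not in data:
            raise ValidationError(f"{path}: missing 'matrix' key")
        return cls.from_matrix(np.asarray(data["matrix"], dtype=float))


def _nearest_rotation(matrix: np.ndarray) -> np.ndarray:
    """Project a near-rotation onto SO(3) via SVD (polar decomposition)."""
    u, _, vt = np.linalg.svd(matrix)
    rot = u @ vt
    if np.linalg.det(rot) < 0:
        u[:, -1] = -u[:, -1]
        rot = u @ vt
    return rot
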