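"""Synthetic dentitions with known ground truth.

Every stage of the root-prediction pipeline is testable without patient data
by generating parametric-idealized teeth whose CEJ planes, local axes and
rigid movements are known by construction:

* :func:`make_tooth` — a watertight tooth: a superellipsoid-profile crown
  joined to a tapered-paraboloid root along an exactly planar CEJ.
* :func:`make_arch` — teeth placed along a parabolic arch form with FDI
  codes assigned by position, non-intersecting by construction (verified).
* :func:`simulate_treatment` — applies known per-tooth rigid movements
  (tip / torque / rotation about tooth-local axes through the crown
  centroid, plus translation) and returns the ground-truth transforms.
* :func:`simulate_scan` — degrades a dentition the way real acquisitions
  do: crown-only cropping (laser scan of a cast), Gaussian vertex noise
  along normals (surface-measurement error), random face decimation.
* :func:`pick_landmarks` — deterministic farthest-point landmark picks with
  optional click-imprecision noise, standing in for manual point selection.

The geometry is idealized, not anatomical: what matters for testing is that
CEJ planes and movements are known exactly, not crown morphology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .cej import CEJPlane, cut_at_cej
from .mesh import LabeledDentition, make_trimesh, validate_mesh
from .registration import LandmarkSet, NearestSurfaceQuery
from .transforms import RigidTransform, ValidationError

__all__ = [
    "ToothSpec",
    "MovementSpec",
    "ScanSpec",
    "ArchCase",
    "make_tooth",
    "make_arch",
    "simulate_treatment",
    "simulate_scan",
    "pick_landmarks",
    "default_movements",
]


class GenerationError(RuntimeError):
    """Synthetic geometry could not be generated under the given parameters."""


@dataclass(frozen=True)
class ToothSpec:
    """Parameters of one idealized tooth.

    ``position`` is the CEJ center; ``long_axis`` points crown-ward.
    ``crown_widths`` are the (mesiodistal, buccolingual) diameters at the
    CEJ in mm.  ``root_taper`` is the exponent of the paraboloid-like taper
    profile ``(1 - u)**root_taper`` from CEJ (u=0) to apex (u=1).
    ``mesh_resolution`` scales ring/segment counts.
    """

    tooth_id: str = "11"
    crown_height: float = 10.0
    crown_widths: tuple[float, float] = (8.0, 7.0)
    root_length: float = 13.0
    root_taper: float = 0.5
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    long_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    mesiodistal_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    mesh_resolution: int = 1
    crown_bulge: float = 0.08
    cross_exponent: float = 2.4

    def __post_init__(self) -> None:
        if min(self.crown_height, self.root_length, *self.crown_widths) <= 0:
            raise ValidationError("all tooth dimensions must be > 0")
        if self.root_taper <= 0:
            raise ValidationError("root_taper must be > 0")
        axis = np.asarray(self.long_axis, dtype=float)
        if np.linalg.norm(axis) < 1e-12:
            raise ValidationError("long_axis must be non-zero")


@dataclass(frozen=True)
class MovementSpec:
    """A clinical tooth movement about tooth-local axes through the crown
    centroid: tip (rotation about the buccolingual axis), torque (about the
    mesiodistal axis), rotation (about the long axis), plus a translation in
    mm (global frame)."""

    tip_deg: float = 0.0
    torque_deg: float = 0.0
    rotation_deg: float = 0.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ScanSpec:
    """Degradation model for an acquired mesh: vertex noise sd along
    normals (mm), fraction of faces randomly removed, crown-only cropping or
    full-tooth retention, RNG seed."""

    vertex_noise_sd: float = 0.0
    decimation_fraction: float = 0.0
    crop: str = "crown_only"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vertex_noise_sd < 0:
            raise ValidationError("vertex_noise_sd must be >= 0")
        if not (0 <= self.decimation_fraction < 1):
            raise ValidationError("decimation_fraction must be in [0, 1)")
        if self.crop not in ("crown_only", "full_tooth"):
            raise ValidationError(f"unknown crop mode {self.crop!r}")


@dataclass
class ArchCase:
    """A generated arch: dentition plus everything known by construction.

    ``overlaps`` lists tooth pairs flagged as touching/colliding after a
    simulated treatment (clinical crowding is allowed, merely flagged).
    """

    dentition: LabeledDentition
    cej_planes: dict[str, CEJPlane] = field(default_factory=dict)
    frames: dict[str, np.ndarray] = field(default_factory=dict)  # columns: md, bl, long axes
    specs: dict[str, ToothSpec] = field(default_factory=dict)
    overlaps: list[tuple[str, str]] = field(default_factory=list)


def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    tri = vertices[faces]
    return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)


def _superellipse_ring(a: float, b: float, exponent: float, n_theta: int) -> np.ndarray:
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    c, s = np.cos(theta), np.sin(theta)
    p = 2.0 / exponent
    x = a * np.sign(c) * np.abs(c) ** p
    y = b * np.sign(s) * np.abs(s) ** p
    return np.column_stack([x, y])


def make_tooth(spec: ToothSpec) -> tuple[trimesh.Trimesh, CEJPlane]:
    """Generate a watertight tooth mesh and its (exact) CEJ plane.

    The surface is a loft of superellipse rings along the long axis: the
    root tapers to an apex pole following ``(1-u)**root_taper``; the crown
    bulges by ``crown_bulge`` mid-height and closes at a rounded tip pole.
    Deterministic: the same spec always yields the identical mesh.
    """
    res = max(1, int(spec.mesh_resolution))
    n_theta = 20 + 8 * res
    n_root = 6 + 4 * res
    n_crown = 8 + 4 * res

    a0 = spec.crown_widths[0] / 2.0
    b0 = spec.crown_widths[1] / 2.0
    base_ring = _superellipse_ring(a0, b0, spec.cross_exponent, n_theta)

    # z-levels and radial scale factors, apex -> tip
    levels: list[tuple[float, float]] = []
    for u in np.linspace(1.0, 0.0, n_root + 1)[1:]:  # skip apex pole level
        levels.append((-spec.root_length * u, (1.0 - u) ** spec.root_taper))
    for v in np.linspace(0.0, 1.0, n_crown + 1)[1:-1]:  # CEJ ring already added
        profile = (1.0 - v**3) ** (1.0 / 3.0)
        bulge = 1.0 + spec.crown_bulge * np.sin(np.pi * v)
        levels.append((spec.crown_height * v, profile * bulge))

    rings = []
    for z, scale in levels:
        ring = np.column_stack([base_ring * scale, np.full(n_theta, z)])
        rings.append(ring)
    n_rings = len(rings)

    apex = np.array([0.0, 0.0, -spec.root_length])
    tip = np.array([0.0, 0.0, spec.crown_height])
    vertices = np.vstack([apex[None, :], np.vstack(rings), tip[None, :]])

    def rv(ring_i: int, j: int) -> int:
        return 1 + ring_i * n_theta + (j % n_theta)

    faces = []
    for j in range(n_theta):  # apex fan
        faces.append([0, rv(0, j + 1), rv(0, j)])
    for i in range(n_rings - 1):  # lofted quads
        for j in range(n_theta):
            faces.append([rv(i, j), rv(i, j + 1), rv(i + 1, j + 1)])
            faces.append([rv(i, j), rv(i + 1, j + 1), rv(i + 1, j)])
    tip_idx = len(vertices) - 1
    for j in range(n_theta):  # tip fan
        faces.append([tip_idx, rv(n_rings - 1, j), rv(n_rings - 1, j + 1)])
    faces = np.asarray(faces, dtype=np.int64)
    if _signed_volume(vertices, faces) < 0:
        faces = faces[:, ::-1]

    # orient into the requested frame: local x -> mesiodistal, z -> long axis
    axis = np.asarray(spec.long_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    md = np.asarray(spec.mesiodistal_axis, dtype=float)
    md = md - (md @ axis) * axis
    if np.linalg.norm(md) < 1e-9:
        md = np.array([1.0, 0.0, 0.0]) - axis[0] * axis
    md = md / np.linalg.norm(md)
    bl = np.cross(axis, md)
    rotation = np.column_stack([md, bl, axis])
    if np.linalg.det(rotation) < 0:  # enforce a proper rotation
        bl = -bl
        rotation = np.column_stack([md, bl, axis])
    position = np.asarray(spec.position, dtype=float)
    vertices = vertices @ rotation.T + position

    mesh = make_trimesh(vertices, faces)
    plane = CEJPlane(point=position, normal=axis, tooth_id=spec.tooth_id)
    return mesh, plane


# ----------------------------------------------------------------------
# arch generation

# (crown_height, mesiodistal, buccolingual, root_length) in mm per tooth
# position 1..8 from the midline; idealized adult dimensions
_TOOTH_DIMS = {
    1: (10.5, 8.5, 7.0, 13.0),  # central incisor
    2: (9.5, 6.5, 6.0, 13.0),   # lateral incisor
    3: (10.0, 7.5, 8.0, 16.0),  # canine
    4: (8.5, 7.0, 9.0, 14.0),   # first premolar
    5: (8.0, 6.8, 9.0, 14.0),   # second premolar
    6: (7.5, 10.0, 11.0, 13.0), # first molar
    7: (7.0, 9.5, 11.0, 13.0),  # second molar
    8: (6.5, 9.0, 11.0, 11.0),  # third molar
}


def _fdi_sequence(n_teeth: int, arch: str) -> list[str]:
    """FDI codes for n teeth of one arch, ordered around the arch from the
    patient's right to left (e.g. 17..11, 21..27 for 14 maxillary teeth)."""
    if not 1 <= n_teeth <= 16:
        raise ValidationError("n_teeth must be in 1..16")
    right_q, left_q = (1, 2) if arch == "maxillary" else (4, 3)
    per_side = n_teeth // 2
    extra = n_teeth % 2
    right = [f"{right_q}{p}" for p in range(per_side + extra, 0, -1)]
    left = [f"{left_q}{p}" for p in range(1, per_side + 1)]
    return right + left


def make_arch(
    n_teeth: int = 14,
    arch: str = "maxillary",
    arch_width: float = 68.0,
    arch_depth: float = 54.0,
    gap: float = 0.6,
    mesh_resolution: int = 1,
    min_gap_check: float = 0.1,
) -> ArchCase:
    """Place idealized teeth along a parabolic arch form.

    The arch curve is ``y = arch_depth * (1 - (2x / arch_width)**2)``; teeth
    are spaced by mesiodistal width plus ``gap`` along arc length, centered
    on the midline.  Maxillary crowns point down (occlusal plane z=0 between
    the arches), mandibular crowns point up.  Pairwise surface separation of
    neighbors is verified to exceed ``min_gap_check`` mm.
    """
    if arch not in ("maxillary", "mandibular"):
        raise ValidationError(f"unknown arch {arch!r}")
    ids = _fdi_sequence(n_teeth, arch)
    dims = [_TOOTH_DIMS[int(t[1])] for t in ids]

    # dense parabola parametrized by arc length, patient's right (x<0) first
    x_dense = np.linspace(-arch_width / 2, arch_width / 2, 4001)
    y_dense = arch_depth * (1.0 - (2.0 * x_dense / arch_width) ** 2)
    seg = np.hypot(np.diff(x_dense), np.diff(y_dense))
    s_dense = np.concatenate([[0.0], np.cumsum(seg)])

    # effective width includes the mid-crown bulge of the tooth profile
    bulge = 1.0 + ToothSpec().crown_bulge
    widths = np.array([d[1] for d in dims]) * bulge
    pitch = widths + gap
    centers = np.concatenate([[0.0], np.cumsum(pitch)])[:-1] + widths / 2.0
    total = centers[-1] + widths[-1] / 2.0 + gap / 2.0
    offset = (s_dense[-1] - total) / 2.0
    if offset < 0:
        raise GenerationError(
            f"{n_teeth} teeth need {total:.1f} mm of arch; "
            f"only {s_dense[-1]:.1f} mm available"
        )

    crown_dir = -1.0 if arch == "maxillary" else 1.0

    case = ArchCase(dentition=LabeledDentition())
    for tooth_id, (ch, md_w, bl_w, rl), s_center in zip(ids, dims, centers + offset):
        x = np.interp(s_center, s_dense, x_dense)
        y = np.interp(s_center, s_dense, y_dense)
        # tangent of the arch curve = mesiodistal direction
        dydx = -8.0 * arch_depth * x / arch_width**2
        tangent = np.array([1.0, dydx, 0.0])
        tangent /= np.linalg.norm(tangent)
        long_axis = np.array([0.0, 0.0, crown_dir])
        # CEJ placed so crowns end ~2 mm short of the occlusal plane z=0
        position = np.array([x, y, -crown_dir * (ch + 2.0)])
        spec = ToothSpec(
            tooth_id=tooth_id,
            crown_height=ch,
            crown_widths=(md_w, bl_w),
            root_length=rl,
            position=tuple(position),
            long_axis=tuple(long_axis),
            mesiodistal_axis=tuple(tangent),
            mesh_resolution=mesh_resolution,
        )
        mesh, plane = make_tooth(spec)
        case.dentition.add(tooth_id, mesh, arch)
        case.cej_planes[tooth_id] = plane
        bl_axis = np.cross(long_axis, tangent)
        case.frames[tooth_id] = np.column_stack([tangent, bl_axis, long_axis])
        case.specs[tooth_id] = spec

    _check_separation(case, ids, min_gap_check)
    return case


def _check_separation(case: ArchCase, ids: list[str], min_gap: float) -> None:
    for left, right in zip(ids[:-1], ids[1:]):
        query = NearestSurfaceQuery(case.dentition[right])
        _, dist, _ = query.query(np.asarray(case.dentition[left].vertices))
        if dist.min() <= min_gap:
            raise GenerationError(
                f"teeth {left} and {right} are {dist.min():.3f} mm apart "
                f"(need > {min_gap} mm)"
            )


# ----------------------------------------------------------------------
# treatment simulation


def _crown_centroid(mesh: trimesh.Trimesh, plane: CEJPlane) -> np.ndarray:
    vertices = np.asarray(mesh.vertices)
    crown_mask = plane.signed_height(vertices) > 0
    if not crown_mask.any():
        return vertices.mean(axis=0)
    return vertices[crown_mask].mean(axis=0)


def movement_to_transform(
    movement: MovementSpec, frame: np.ndarray, center: np.ndarray
) -> RigidTransform:
    """Compose tip, torque and long-axis rotation (in that order) about
    ``center`` along the tooth-local ``frame`` axes, then translate."""
    md_axis, bl_axis, long_axis = frame.T
    t = RigidTransform.from_axis_angle(long_axis, movement.rotation_deg, center)
    t = RigidTransform.from_axis_angle(md_axis, movement.torque_deg, center) @ t
    t = RigidTransform.from_axis_angle(bl_axis, movement.tip_deg, center) @ t
    return RigidTransform(
        rotation=t.rotation,
        translation=t.translation + np.asarray(movement.translation, dtype=float),
    )


def simulate_treatment(
    case: ArchCase, movements: dict[str, MovementSpec]
) -> tuple[ArchCase, dict[str, RigidTransform]]:
    """Apply known per-tooth movements; return the moved arch (meshes, CEJ
    planes and frames co-transformed) and the ground-truth transforms."""
    unknown = sorted(set(movements) - set(case.dentition.teeth))
    if unknown:
        raise ValidationError(f"movements refer to unknown teeth: {unknown}")
    moved = ArchCase(dentition=LabeledDentition())
    truth: dict[str, RigidTransform] = {}
    for tooth_id in case.dentition:
        movement = movements.get(tooth_id, MovementSpec())
        frame = case.frames[tooth_id]
        center = _crown_centroid(case.dentition[tooth_id], case.cej_planes[tooth_id])
        transform = movement_to_transform(movement, frame, center)
        truth[tooth_id] = transform
        moved.dentition.add(
            tooth_id,
            case.dentition[tooth_id].copy().apply_transform(transform.matrix()),
            case.dentition.arch[tooth_id],
        )
        moved.cej_planes[tooth_id] = case.cej_planes[tooth_id].transformed(transform)
        moved.frames[tooth_id] = transform.rotation @ frame
        moved.specs[tooth_id] = case.specs.get(tooth_id)
    moved.overlaps = _flag_overlaps(moved.dentition)
    return moved, truth


def _flag_overlaps(
    dentition: LabeledDentition, touch_dist: float = 0.05
) -> list[tuple[str, str]]:
    """Flag tooth pairs whose surfaces come within ``touch_dist`` mm.

    Cheap screen on axis-aligned bounding boxes first; only overlapping
    boxes get an exact surface-distance query.  Collisions are allowed
    (crowding exists clinically) — they are warned about, not rejected.
    """
    ids = dentition.ids()
    bounds = {t: dentition[t].bounds for t in ids}
    overlaps = []
    for i, left in enumerate(ids):
        for right in ids[i + 1 :]:
            lo = np.maximum(bounds[left][0], bounds[right][0])
            hi = np.minimum(bounds[left][1], bounds[right][1])
            if np.any(lo - hi > touch_dist):
                continue
            query = NearestSurfaceQuery(dentition[right])
            _, dist, _ = query.query(np.asarray(dentition[left].vertices))
            if dist.min() < touch_dist:
                overlaps.append((left, right))
                warnings.warn(
                    f"teeth {left} and {right} overlap after movement "
                    f"(min surface distance {dist.min():.3f} mm)",
                    stacklevel=3,
                )
    return overlaps


def default_movements(
    tooth_ids, seed: int = 0, max_tip: float = 4.0, max_torque: float = 3.0,
    max_rotation: float = 4.0, max_translation: float = 0.8,
) -> dict[str, MovementSpec]:
    """Random small clinical movements, deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    out = {}
    for tooth_id in sorted(tooth_ids):
        out[tooth_id] = MovementSpec(
            tip_deg=float(rng.uniform(-max_tip, max_tip)),
            torque_deg=float(rng.uniform(-max_torque, max_torque)),
            rotation_deg=float(rng.uniform(-max_rotation, max_rotation)),
            translation=tuple(rng.uniform(-max_translation, max_translation, 3)),
        )
    return out


# ----------------------------------------------------------------------
# scan simulation


def simulate_scan(
    case: ArchCase, spec: ScanSpec
) -> LabeledDentition:
    """Emulate an acquired mesh set from a ground-truth arch.

    ``crop="crown_only"`` keeps only geometry crown-side of each CEJ plane
    (a cast laser scan shows no roots); ``"full_tooth"`` keeps everything
    (a CBCT segmentation).  Gaussian noise of ``vertex_noise_sd`` mm is
    applied along vertex normals, then ``decimation_fraction`` of the faces
    is removed at random.  Fully deterministic given ``spec.seed``.
    """
    out = LabeledDentition()
    for tooth_id in case.dentition:
        mesh = case.dentition[tooth_id]
        if spec.crop == "crown_only":
            cut = cut_at_cej(mesh, case.cej_planes[tooth_id])
            if cut.crown is None:
                raise GenerationError(f"tooth {tooth_id}: CEJ plane misses the crown")
            mesh = cut.crown
        else:
            mesh = mesh.copy()
        # per-tooth substream: independent of dentition ordering
        rng = np.random.default_rng([spec.seed, int(tooth_id)])
        if spec.vertex_noise_sd > 0:
            normals = np.asarray(mesh.vertex_normals)
            offsets = rng.normal(0.0, spec.vertex_noise_sd, len(mesh.vertices))
            mesh = make_trimesh(
                np.asarray(mesh.vertices) + offsets[:, None] * normals, mesh.faces
            )
        if spec.decimation_fraction > 0:
            n_faces = len(mesh.faces)
            n_keep = n_faces - int(round(spec.decimation_fraction * n_faces))
            if n_keep < 10:
                raise GenerationError(
                    f"tooth {tooth_id}: decimation leaves {n_keep} faces (< 10)"
                )
            keep = np.sort(rng.choice(n_faces, size=n_keep, replace=False))
            mesh = make_trimesh(np.asarray(mesh.vertices), np.asarray(mesh.faces)[keep])
            mesh.remove_unreferenced_vertices()
        out.add(tooth_id, mesh, case.dentition.arch[tooth_id])
    return out


# ----------------------------------------------------------------------
# landmark picking


def pick_landmarks(
    mesh: trimesh.Trimesh,
    k: int = 3,
    seed: int = 0,
    transform: RigidTransform | None = None,
    perturb_sd: float = 0.0,
    region_plane: CEJPlane | None = None,
    region_margin: float = 0.5,
    tooth_id: str | None = None,
) -> tuple[LandmarkSet, LandmarkSet | None]:
    """Deterministic well-separated surface landmarks via farthest-point
    sampling from a seed-chosen start vertex.

    With ``region_plane`` set, candidates are restricted to vertices at
    least ``region_margin`` mm crown-side of the plane (so picks survive
    crown-only cropping).  When a ground-truth ``transform`` is given, the
    matching target landmarks are the transformed picks, optionally
    perturbed by ``perturb_sd`` mm of isotropic Gaussian noise to emulate
    imprecise clicking.  Returns ``(source, target_or_None)``.
    """
    validate_mesh(mesh, name="landmark mesh")
    vertices = np.asarray(mesh.vertices)
    if region_plane is not None:
        mask = region_plane.signed_height(vertices) >= region_margin
        candidates = vertices[mask]
    else:
        candidates = vertices
    if len(candidates) < k:
        raise ValidationError(
            f"only {len(candidates)} candidate vertices for k={k} landmarks"
        )
    rng = np.random.default_rng(seed)
    start = int(rng.integers(len(candidates)))
    picked = [start]
    dist = np.linalg.norm(candidates - candidates[start], axis=1)
    while len(picked) < k:
        nxt = int(np.argmax(dist))
        picked.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(candidates - candidates[nxt], axis=1))
    points = candidates[picked]
    source = LandmarkSet(points, tooth_id=tooth_id)
    if transform is None:
        return source, None
    target_points = transform.apply(points)
    if perturb_sd > 0:
        target_points = target_points + rng.normal(0.0, perturb_sd, target_points.shape)
    return source, LandmarkSet(target_points, tooth_id=tooth_id)


def add_bracket(
    mesh: trimesh.Trimesh, plane: CEJPlane, size: float = 3.0, height: float = 1.5
) -> trimesh.Trimesh:
    """Fuse a small box to the buccal crown surface, emulating an
    orthodontic bracket artifact (off by default everywhere)."""
    vertices = np.asarray(mesh.vertices)
    heights = plane.signed_height(vertices)
    crown = vertices[heights > 0]
    centroid = crown.mean(axis=0)
    # buccal = outward in the plane, away from the crown centroid axis
    outward = crown - centroid
    outward[:, 2] = 0 if abs(plane.normal[2]) > 0.9 else outward[:, 2]
    idx = int(np.argmax(np.linalg.norm(outward, axis=1)))
    anchor = crown[idx]
    normal_dir = outward[idx] / (np.linalg.norm(outward[idx]) + 1e-12)
    box = trimesh.creation.box(extents=(size, size, height))
    rot = trimesh.geometry.align_vectors([0, 0, 1], normal_dir)
    box.apply_transform(rot)
    box.apply_translation(anchor + normal_dir * height / 2.0)
    return trimesh.util.concatenate([mesh, box])
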