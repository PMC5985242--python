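"""Reference synthetic studies measuring pipeline accuracy.

These routines generate ground-truth dentitions, run the registration
pipeline on them, and measure recovery error against the known transforms.
They are the package's own accuracy benchmarks — used by the test suite and
by the reproduction script — and define one canonical set of study
conditions each, so results are comparable across runs.

All randomness flows from an integer ``seed``; derived substreams use
``numpy.random.default_rng`` seed sequences, so every study is fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .cej import cut_at_cej
from .displacement import (
    DisplacementField,
    displacement_stats,
    signed_displacement,
)
from .pipeline import ERPModel, indirect_superimpose
from .registration import ICPParams, LandmarkSet, landmark_register
from .synthetic import (
    ScanSpec,
    default_movements,
    make_arch,
    make_tooth,
    pick_landmarks,
    simulate_scan,
    simulate_treatment,
    ToothSpec,
)
from .transforms import RigidTransform

__all__ = [
    "landmark_exactness",
    "root_recovery_study",
    "RecoveryStudy",
    "sphere_displacement_check",
    "cej_area_conservation",
    "indirect_consistency_check",
]


def landmark_exactness(n_trials: int = 1000, seed: int = 0) -> dict[str, float]:
    """Recover random proper rigid transforms from exact 3-point
    correspondences; report the worst rotation / translation error.

    Rotation error is the max absolute entry difference between recovered
    and true rotation matrices; translation error the Euclidean norm of the
    translation difference (mm).  For noiseless non-collinear points both
    should sit at numerical zero (< 1e-9).
    """
    rng = np.random.default_rng(seed)
    max_rot = 0.0
    max_trans = 0.0
    done = 0
    while done < n_trials:
        points = rng.uniform(-10.0, 10.0, (3, 3))
        s = np.linalg.svd(points - points.mean(axis=0), compute_uv=False)
        if s[1] <= 1e-6:  # nearly collinear draw: re-sample
            continue
        true = RigidTransform(
            rotation=Rotation.random(random_state=rng).as_matrix(),
            translation=rng.uniform(-50.0, 50.0, 3),
        )
        recovered = landmark_register(
            LandmarkSet(points), LandmarkSet(true.apply(points))
        )
        max_rot = max(max_rot, float(np.abs(recovered.rotation - true.rotation).max()))
        max_trans = max(
            max_trans, float(np.linalg.norm(recovered.translation - true.translation))
        )
        done += 1
    return {
        "n_trials": n_trials,
        "max_rotation_error": max_rot,
        "max_translation_error_mm": max_trans,
    }


@dataclass
class RecoveryStudy:
    """Outcome of one synthetic root-recovery study."""

    per_tooth_error: dict[str, float] = field(default_factory=dict)
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def max_vertex_error(self) -> float:
        return max(self.per_tooth_error.values())

    @property
    def mean_vertex_error(self) -> float:
        return float(np.mean(list(self.per_tooth_error.values())))


def root_recovery_study(
    seed: int = 0,
    n_teeth: int = 14,
    arches: tuple[str, ...] = ("maxillary",),
    movement_limits: dict | None = None,
    landmark_sd: float = 0.3,
    noise_sd: float = 0.0,
    decimation: float = 0.0,
    icp_params: ICPParams | None = None,
) -> RecoveryStudy:
    """The canonical end-to-end benchmark: simulate treatment, fit the ERP
    setup from crown-only scans, compare predicted against true positions.

    Per arch: an ``n_teeth`` arch is generated, each tooth moved by a random
    clinical movement (bounded by ``movement_limits`` kwargs of
    :func:`~erp.synthetic.default_movements`), the moved arch is scanned
    crown-only with ``noise_sd`` / ``decimation`` degradation, landmarks are
    picked with ``landmark_sd`` mm click noise, and the ERP model is fitted.

    Measures, per tooth, the max vertex distance between the ERP tooth and
    the ground-truth moved tooth; and per arch, pooled signed-displacement
    statistics of the ERP crown and root surfaces against the ground-truth
    surfaces (cut at the true CEJ planes).
    """
    movement_limits = movement_limits or {}
    study = RecoveryStudy()
    stats_rows = []
    diag_frames = []
    for arch_index, arch in enumerate(arches):
        rng = np.random.default_rng([seed, arch_index])
        case = make_arch(n_teeth=n_teeth, arch=arch)
        ids = case.dentition.ids()
        movements = default_movements(
            ids, seed=int(rng.integers(2**31)), **movement_limits
        )
        moved, truth = simulate_treatment(case, movements)
        crowns = simulate_scan(
            moved,
            ScanSpec(
                vertex_noise_sd=noise_sd,
                decimation_fraction=decimation,
                crop="crown_only",
                seed=int(rng.integers(2**31)),
            ),
        )
        landmarks = {}
        for tooth_id in ids:
            source, target = pick_landmarks(
                case.dentition[tooth_id],
                transform=truth[tooth_id],
                seed=int(rng.integers(2**31)),
                perturb_sd=landmark_sd,
                region_plane=case.cej_planes[tooth_id],
                tooth_id=tooth_id,
            )
            landmarks[tooth_id] = (source, target)
        result = ERPModel(
            case.dentition,
            crowns,
            landmarks,
            cej_planes=case.cej_planes,
            icp_params=icp_params,
        ).fit()
        diag_frames.append(result.diagnostics)

        pooled: dict[str, list[np.ndarray]] = {"crowns": [], "roots": []}
        for tooth_id in result.erp_teeth.ids():
            erp_tooth = result.erp_teeth[tooth_id]
            true_tooth = moved.dentition[tooth_id]
            err = np.linalg.norm(
                np.asarray(erp_tooth.vertices) - np.asarray(true_tooth.vertices),
                axis=1,
            ).max()
            study.per_tooth_error[tooth_id] = float(err)
            plane = moved.cej_planes[tooth_id]
            cut_erp = cut_at_cej(erp_tooth, plane)
            cut_true = cut_at_cej(true_tooth, plane)
            for analysis, erp_part, true_part in (
                ("crowns", cut_erp.crown, cut_true.crown),
                ("roots", cut_erp.root, cut_true.root),
            ):
                if erp_part is None or true_part is None:
                    continue
                fld = signed_displacement(erp_part, true_part)
                pooled[analysis].append(fld.values)
        for analysis in ("crowns", "roots"):
            if not pooled[analysis]:
                continue
            fld = DisplacementField(np.concatenate(pooled[analysis]))
            stats = displacement_stats(fld)
            stats_rows.append(
                {
                    "analysis": analysis,
                    "arch": arch,
                    "mean_mm": stats.mean,
                    "sd_mm": stats.sd,
                    "max_mm": stats.max_abs,
                    "n_vertices": stats.n_vertices,
                }
            )
    study.stats = pd.DataFrame(stats_rows)
    study.diagnostics = pd.concat(diag_frames, ignore_index=True)
    return study


def sphere_displacement_check(
    radius: float = 10.0, offset: float = 0.2, subdivisions: int = 4
) -> dict[str, float]:
    """Concentric-sphere oracle: every vertex of a sphere of radius
    ``radius + offset`` lies ``offset`` mm outside a reference sphere of
    ``radius`` (up to tessellation sag).  Returns the worst deviation."""
    import trimesh

    reference = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    test = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius + offset)
    fld = signed_displacement(test, reference)
    return {
        "expected_mm": offset,
        "max_abs_deviation_mm": float(np.abs(fld.values - offset).max()),
        "n_vertices": len(fld),
    }


def cej_area_conservation(n_teeth: int = 100, seed: int = 0) -> dict[str, float]:
    """Cut random synthetic teeth at their CEJ planes and measure the worst
    relative error between input area and crown + root area."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_teeth):
        spec = ToothSpec(
            crown_height=float(rng.uniform(6.0, 12.0)),
            crown_widths=(float(rng.uniform(5.0, 11.0)), float(rng.uniform(5.0, 11.0))),
            root_length=float(rng.uniform(9.0, 17.0)),
            root_taper=float(rng.uniform(0.3, 0.8)),
            position=tuple(rng.uniform(-30.0, 30.0, 3)),
            long_axis=tuple(rng.normal(size=3)),
        )
        mesh, plane = make_tooth(spec)
        cut = cut_at_cej(mesh, plane)
        total = (cut.crown.area if cut.crown is not None else 0.0) + (
            cut.root.area if cut.root is not None else 0.0
        )
        worst = max(worst, abs(total - mesh.area) / mesh.area)
    return {"n_teeth": n_teeth, "max_relative_area_error": worst}


def indirect_consistency_check(seed: int = 0, n_teeth: int = 4) -> dict[str, float]:
    """Displacement statistics must not depend on the common frame used for
    the comparison: compute ERP-vs-control stats in the laser-scan frame and
    again after a shared rigid change of frame, and report the worst
    difference across all statistics."""
    from .displacement import compare_pair_report

    rng = np.random.default_rng(seed)
    case = make_arch(n_teeth=n_teeth, arch="maxillary")
    movements = default_movements(case.dentition.ids(), seed=int(rng.integers(2**31)))
    moved, truth = simulate_treatment(case, movements)
    crowns = simulate_scan(moved, ScanSpec(crop="crown_only", seed=0))
    landmarks = {
        tooth_id: pick_landmarks(
            case.dentition[tooth_id],
            transform=truth[tooth_id],
            seed=int(rng.integers(2**31)),
            perturb_sd=0.3,
            region_plane=case.cej_planes[tooth_id],
            tooth_id=tooth_id,
        )
        for tooth_id in case.dentition.ids()
    }
    result = ERPModel(
        case.dentition, crowns, landmarks, cej_planes=case.cej_planes
    ).fit()
    control = moved.dentition  # ground truth, already in the laser frame

    def stats_in_frame(frame_change: RigidTransform) -> pd.DataFrame:
        erp_frame = result.erp_teeth.transformed(frame_change)
        control_frame = control.transformed(frame_change)
        planes = {
            t: moved.cej_planes[t].transformed(frame_change)
            for t in moved.cej_planes
        }
        pairs = indirect_superimpose(erp_frame, control_frame)
        report = compare_pair_report(
            pairs, cej_planes=planes, arch_of=dict(erp_frame.arch)
        )
        return report.stats

    direct = stats_in_frame(RigidTransform.identity())
    reframed = stats_in_frame(
        RigidTransform(
            rotation=Rotation.random(random_state=rng).as_matrix(),
            translation=rng.uniform(-20.0, 20.0, 3),
        )
    )
    diff = (
        direct[["mean_mm", "sd_mm", "max_mm"]].to_numpy()
        - reframed[["mean_mm", "sd_mm", "max_mm"]].to_numpy()
    )
    return {
        "max_stats_difference_mm": float(np.abs(diff).max()),
        "n_rows": len(direct),
    }
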