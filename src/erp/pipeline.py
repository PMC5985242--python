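"""Expected-root-position (ERP) estimation and indirect superimposition.

The clinical problem: during orthodontic treatment, root position can only
be imaged radiographically, but crowns can be scanned harmlessly at any
visit.  Because each tooth is rigid, a rigid transform fitted on the crown
alone moves the root along with it.  The ERP method registers each
pre-treatment CBCT-segmented tooth (crown + root) onto the matching
progress-stage crown-only scan using crown geometry only; applying the
fitted transform to the full tooth predicts the current root position
without new radiographs.

:class:`ERPModel` is the modelling entry point: constructed from the
pre-treatment dentition, the target crown scans and per-tooth landmark
pairs, its :meth:`~ERPModel.fit` runs the three-stage registration per tooth
(landmark pre-alignment, optional manual correction, ICP refinement) and
returns an :class:`ERPResult` holding the per-tooth transforms, the ERP
dentition, and registration diagnostics with a ``summary()`` table.

Validation against a ground-truth progress CBCT uses *indirect*
superimposition: both the ERP setup and the control CBCT teeth are mapped
into the laser-scan frame (the common intermediary), the scan is discarded,
and the paired teeth are compared by signed surface displacement
(:func:`erp.displacement.compare_pair_report`).  The control dentition is
registered as one rigid body per arch ("combined crowns"), in contrast to
the per-tooth fitting of the ERP setup.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .cej import CEJPlane, cut_at_cej
from .mesh import LabeledDentition, apply_transform
from .registration import (
    ICPParams,
    ICPResult,
    LandmarkSet,
    icp_register,
    landmark_register,
)
from .transforms import RigidTransform, ValidationError

__all__ = [
    "ERPModel",
    "ERPResult",
    "ERPSetup",
    "generate_erp_setup",
    "superimpose_control",
    "indirect_superimpose",
]

logger = logging.getLogger("erp")


@dataclass
class ERPSetup:
    """The fitted ERP setup: full CBCT teeth moved into the target frame."""

    per_tooth_transforms: dict[str, RigidTransform] = field(default_factory=dict)
    erp_teeth: LabeledDentition = field(default_factory=LabeledDentition)
    registration_diagnostics: dict[str, ICPResult] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)


class ERPModel:
    """Per-tooth rigid registration model for expected root position.

    Parameters
    ----------
    pretx
        Pre-treatment dentition of full (crown + root) tooth meshes.
    target_crowns
        Crown-only meshes at the progress stage (e.g. a cast laser scan,
        segmented per tooth), sharing FDI IDs with ``pretx``.  Teeth present
        in only one dentition are skipped with a warning.
    landmarks
        ``tooth_id -> (source_landmarks, target_landmarks)``, three or more
        matched points picked on the pre-treatment crown and on the target
        crown.  Required for every shared tooth.
    cej_planes
        Optional ``tooth_id -> CEJPlane`` on the pre-treatment teeth.  When
        given, ICP uses only the crown side of each tooth as the moving
        point set (the crown-only target cannot provide root
        correspondences); without planes all vertices are used and the
        rejection distance must do the work.
    manual_pre
        Optional ``tooth_id -> RigidTransform`` applied after landmark
        registration, standing in for interactive translation/rotation
        corrections of gross tip/torque errors.
    icp_params
        :class:`~erp.registration.ICPParams`; defaults are crown-scale.
    """

    def __init__(
        self,
        pretx: LabeledDentition,
        target_crowns: LabeledDentition,
        landmarks: dict[str, tuple[LandmarkSet, LandmarkSet]],
        cej_planes: dict[str, CEJPlane] | None = None,
        manual_pre: dict[str, RigidTransform] | None = None,
        icp_params: ICPParams | None = None,
    ):
        self.pretx = pretx
        self.target_crowns = target_crowns
        self.landmarks = landmarks
        self.cej_planes = cej_planes or {}
        self.manual_pre = manual_pre or {}
        self.icp_params = icp_params or ICPParams()

        shared = sorted(set(pretx.teeth) & set(target_crowns.teeth))
        for tooth_id in sorted(
            set(pretx.teeth) ^ set(target_crowns.teeth)
        ):
            warnings.warn(
                f"tooth {tooth_id} present in only one dentition; skipped",
                stacklevel=2,
            )
        if not shared:
            raise ValidationError("no shared teeth between dentitions")
        self.shared_ids = shared

    def fit(self) -> "ERPResult":
        """Fit the per-tooth transforms and build the ERP dentition.

        Per tooth: (1) Kabsch on the landmark pair gives the initial
        transform; (2) the optional manual pre-transform is composed on top;
        (3) ICP refines the crown fit; (4) the final transform is applied to
        the *full* tooth, crown and root alike.  Teeth whose landmarks are
        missing or whose ICP starves are recorded as per-tooth errors and
        excluded, never fatal.
        """
        setup = ERPSetup()
        skipped_shared = sorted(
            set(self.pretx.teeth) ^ set(self.target_crowns.teeth)
        )
        setup.skipped = skipped_shared
        for tooth_id in self.shared_ids:
            try:
                transform, diag = self._fit_tooth(tooth_id)
            except Exception as exc:  # noqa: BLE001 - per-tooth isolation
                logger.warning("tooth %s failed: %s", tooth_id, exc)
                setup.errors[tooth_id] = str(exc)
                continue
            setup.per_tooth_transforms[tooth_id] = transform
            setup.registration_diagnostics[tooth_id] = diag
            setup.erp_teeth.add(
                tooth_id,
                apply_transform(self.pretx[tooth_id], transform),
                self.pretx.arch[tooth_id],
            )
            logger.info(
                "tooth %s: rms=%.4f mm, %d iterations, converged=%s",
                tooth_id, diag.rms, diag.iterations_run, diag.converged,
            )
        if not setup.per_tooth_transforms:
            raise ValidationError(
                f"every tooth failed to register: {setup.errors}"
            )
        return ERPResult(self, setup)

    def _fit_tooth(self, tooth_id: str) -> tuple[RigidTransform, ICPResult]:
        if tooth_id not in self.landmarks:
            raise ValidationError(f"no landmarks for tooth {tooth_id}")
        source_lm, target_lm = self.landmarks[tooth_id]
        init = landmark_register(source_lm, target_lm)
        if tooth_id in self.manual_pre:
            init = self.manual_pre[tooth_id] @ init

        moving = self.pretx[tooth_id]
        if tooth_id in self.cej_planes:
            crown = cut_at_cej(moving, self.cej_planes[tooth_id]).crown
            if crown is not None:
                moving = crown
        result = icp_register(
            moving, self.target_crowns[tooth_id], init=init, params=self.icp_params
        )
        return result.transform, result


class ERPResult:
    """Fitted ERP setup with diagnostics.

    Attributes
    ----------
    transforms
        ``tooth_id -> RigidTransform`` mapping pre-treatment coordinates
        into the target (laser-scan) frame.
    erp_teeth
        The ERP dentition: full teeth in the target frame; their roots are
        the expected root positions.
    """

    def __init__(self, model: ERPModel, setup: ERPSetup):
        self.model = model
        self.setup = setup
        self.transforms = setup.per_tooth_transforms
        self.erp_teeth = setup.erp_teeth
        self.errors = setup.errors

    @property
    def diagnostics(self) -> pd.DataFrame:
        """Per-tooth registration diagnostics as a DataFrame."""
        rows = []
        for tooth_id, diag in sorted(self.setup.registration_diagnostics.items()):
            t = self.transforms[tooth_id]
            rows.append(
                {
                    "tooth": tooth_id,
                    "arch": self.erp_teeth.arch[tooth_id],
                    "rms_mm": diag.rms,
                    "iterations": diag.iterations_run,
                    "converged": diag.converged,
                    "n_correspondences": diag.n_correspondences,
                    "rotation_deg": t.rotation_angle_deg(),
                    "translation_mm": float(np.linalg.norm(t.translation)),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit report."""
        frame = self.diagnostics
        lines = [
            "Expected Root Position — registration summary",
            "=" * 60,
            f"teeth fitted:     {len(frame)}",
            f"teeth failed:     {len(self.errors)}"
            + (f"  ({sorted(self.errors)})" if self.errors else ""),
            f"mean crown RMS:   {frame['rms_mm'].mean():.4f} mm",
            f"max crown RMS:    {frame['rms_mm'].max():.4f} mm",
            f"all converged:    {bool(frame['converged'].all())}",
            "-" * 60,
            frame.to_string(
                index=False,
                float_format=lambda v: f"{v:.4f}",
                columns=[
                    "tooth", "arch", "rms_mm", "iterations",
                    "converged", "rotation_deg", "translation_mm",
                ],
            ),
        ]
        return "\n".join(lines)

    def compare_roots(
        self,
        control_aligned: LabeledDentition,
        cej_planes: dict[str, CEJPlane],
        **report_kwargs,
    ):
        """Displacement report (crowns + roots scenarios) of the ERP setup
        against a control dentition already in the same frame."""
        from .displacement import compare_pair_report

        pairs = indirect_superimpose(self.setup, control_aligned)
        arch_of = {t: self.erp_teeth.arch[t] for t in pairs}
        return compare_pair_report(
            pairs, cej_planes=cej_planes, arch_of=arch_of, **report_kwargs
        )

    def save(self, out_dir) -> None:
        """Write per-tooth transform JSONs, ERP dentition PLYs and a
        diagnostics CSV under ``out_dir``."""
        from pathlib import Path

        from .io import write_dentition, write_transform

        out_dir = Path(out_dir)
        (out_dir / "transforms").mkdir(parents=True, exist_ok=True)
        for tooth_id, t in self.transforms.items():
            write_transform(t, out_dir / "transforms" / f"{tooth_id}.json")
        write_dentition(self.erp_teeth, out_dir / "erp_teeth")
        self.diagnostics.to_csv(out_dir / "diagnostics.csv", index=False)


def generate_erp_setup(
    pretx: LabeledDentition,
    target_crowns: LabeledDentition,
    landmarks: dict[str, tuple[LandmarkSet, LandmarkSet]],
    manual_pre: dict[str, RigidTransform] | None = None,
    icp_params: ICPParams | None = None,
    cej_planes: dict[str, CEJPlane] | None = None,
) -> ERPSetup:
    """Functional wrapper around :class:`ERPModel` returning the raw setup."""
    result = ERPModel(
        pretx,
        target_crowns,
        landmarks,
        cej_planes=cej_planes,
        manual_pre=manual_pre,
        icp_params=icp_params,
    ).fit()
    return result.setup


def _combined_mesh(dentition: LabeledDentition, tooth_ids) -> trimesh.Trimesh:
    return trimesh.util.concatenate(
        [dentition[tooth_id] for tooth_id in tooth_ids]
    )


def superimpose_control(
    control: LabeledDentition,
    target_crowns: LabeledDentition,
    arch_landmarks: dict[str, tuple[LandmarkSet, LandmarkSet]] | None = None,
    icp_params: ICPParams | None = None,
    cej_planes: dict[str, CEJPlane] | None = None,
) -> tuple[dict[str, RigidTransform], LabeledDentition]:
    """Register a control dentition onto the laser-scan crowns, one rigid
    transform per arch.

    The *combined* crown surfaces of each arch are fitted as a single rigid
    body — deliberately different from the per-tooth fitting of the ERP
    setup, because the control CBCT already has correct relative tooth
    positions and only its global pose differs.  When ``cej_planes`` are
    given, only crown-side geometry of the control teeth feeds the fit;
    otherwise the ICP rejection distance excludes root points, which have no
    counterpart on the crown-only target.

    Returns ``(arch -> transform, aligned control dentition)``.
    """
    icp_params = icp_params or ICPParams()
    if len(control) == 0 or len(target_crowns) == 0:
        raise ValidationError("control and target dentitions must be non-empty")
    arch_transforms: dict[str, RigidTransform] = {}
    aligned = LabeledDentition()
    for arch in control.arches():
        control_ids = control.arch_ids(arch)
        target_ids = [t for t in target_crowns.arch_ids(arch) if t in target_crowns]
        if not control_ids or not target_ids:
            raise ValidationError(f"empty {arch} arch in control or target")
        if cej_planes:
            crowns = []
            for tooth_id in control_ids:
                if tooth_id in cej_planes:
                    part = cut_at_cej(control[tooth_id], cej_planes[tooth_id]).crown
                    crowns.append(part if part is not None else control[tooth_id])
                else:
                    crowns.append(control[tooth_id])
            source = trimesh.util.concatenate(crowns)
        else:
            source = _combined_mesh(control, control_ids)
        target = _combined_mesh(target_crowns, target_ids)
        if arch_landmarks and arch in arch_landmarks:
            init = landmark_register(*arch_landmarks[arch])
        else:
            # no landmarks: align centroids so ICP starts in the right basin
            init = RigidTransform(
                translation=np.asarray(target.vertices).mean(axis=0)
                - np.asarray(source.vertices).mean(axis=0)
            )
        result = icp_register(source, target, init=init, params=icp_params)
        arch_transforms[arch] = result.transform
        logger.info(
            "%s arch: rms=%.4f mm, %d iterations", arch, result.rms, result.iterations_run
        )
        for tooth_id in control_ids:
            aligned.add(tooth_id, apply_transform(control[tooth_id], result.transform), arch)
    return arch_transforms, aligned


def indirect_superimpose(
    erp: ERPSetup | LabeledDentition,
    control_aligned: LabeledDentition,
) -> dict[str, tuple[trimesh.Trimesh, trimesh.Trimesh]]:
    """Pair ERP teeth with control teeth in the shared laser-scan frame.

    Both dentitions must already be expressed in the laser-scan frame (the
    common intermediary); the scan itself plays no further part.  Returns
    ``tooth_id -> (erp_mesh, control_mesh)``; teeth present in only one
    dentition are excluded with a warning.
    """
    erp_teeth = erp.erp_teeth if isinstance(erp, ERPSetup) else erp
    shared = sorted(set(erp_teeth.teeth) & set(control_aligned.teeth))
    missing = sorted(set(erp_teeth.teeth) ^ set(control_aligned.teeth))
    for tooth_id in missing:
        warnings.warn(
            f"tooth {tooth_id} present in only one dentition; excluded from pairs",
            stacklevel=2,
        )
    if not shared:
        raise ValidationError("no shared teeth to pair")
    return {t: (erp_teeth[t], control_aligned[t]) for t in shared}
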