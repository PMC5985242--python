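import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from erp.synthetic import ScanSpec, ToothSpec, default_movements, make_arch, make_tooth
from erp.transforms import RigidTransform


def random_rigid(rng, max_angle_deg=180.0, max_translation=10.0) -> RigidTransform:
    """A random proper rigid transform bounded in angle and translation."""
    axis = rng.normal(size=3)
    angle = rng.uniform(-max_angle_deg, max_angle_deg)
    rotation = Rotation.from_rotvec(
        np.deg2rad(angle) * axis / np.linalg.norm(axis)
    ).as_matrix()
    return RigidTransform(
        rotation=rotation, translation=rng.uniform(-max_translation, max_translation, 3)
    )


@pytest.fixture(scope="session")
def incisor():
    """One default incisor mesh with its CEJ plane."""
    return make_tooth(ToothSpec())


@pytest.fixture(scope="session")
def small_arch():
    """A 4-tooth maxillary arch (session-scoped; treat as read-only)."""
    return make_arch(n_teeth=4, arch="maxillary")


@pytest.fixture(scope="session")
def treated_arch(small_arch):
    """The small arch after known random movements, plus crown-only scans
    and matched landmark pairs — the standard small pipeline scenario."""
    from erp.synthetic import pick_landmarks, simulate_scan, simulate_treatment

    movements = default_movements(small_arch.dentition.ids(), seed=11)
    moved, truth = simulate_treatment(small_arch, movements)
    crowns = simulate_scan(moved, ScanSpec(crop="crown_only", seed=0))
    landmarks = {
        tooth_id: pick_landmarks(
            small_arch.dentition[tooth_id],
            transform=truth[tooth_id],
            seed=17,
            perturb_sd=0.3,
            region_plane=small_arch.cej_planes[tooth_id],
            tooth_id=tooth_id,
        )
        for tooth_id in small_arch.dentition.ids()
    }
    return {
        "case": small_arch,
        "moved": moved,
        "truth": truth,
        "crowns": crowns,
        "landmarks": landmarks,
    }
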