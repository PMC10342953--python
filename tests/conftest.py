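import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rootmotion import (
    DeformationParams,
    PhantomParams,
    apply_deformation,
    compute_root_metrics,
    make_root_phantom,
    plane_at_ostia,
)


@pytest.fixture(scope="session")
def default_phantom():
    """Reference phantom: 15 mm root, 4 mm three-lobed sinus bulge, 128 circ."""
    params = PhantomParams(
        root_radius=15.0,
        sinus_bulge_amplitude=4.0,
        circumferential_resolution=128,
        axial_resolution=64,
    )
    mesh, centerline, landmarks = make_root_phantom(params)
    plane = plane_at_ostia(
        centerline,
        landmarks["left_coronary_ostium"],
        landmarks["right_coronary_ostium"],
    )
    return params, mesh, centerline, landmarks, plane


@pytest.fixture(scope="session")
def run_phantom_pipeline(default_phantom):
    """Deform the reference phantom and recover metrics in one call."""
    _, mesh, centerline, landmarks, plane = default_phantom

    def run(dparams: DeformationParams, pulse_pressure: float = 56.0):
        field, truth = apply_deformation(
            mesh, centerline, landmarks, dparams, plane,
            pulse_pressure=pulse_pressure,
        )
        metrics = compute_root_metrics(
            mesh, field, centerline, landmarks, pulse_pressure
        )
        return metrics, truth

    return run


def random_rigid_transform(rng: np.random.Generator):
    """Random rotation matrix + translation, for invariance checks."""
    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    trans = rng.uniform(-50.0, 50.0, 3)
    return rot, trans
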