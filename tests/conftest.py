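"""Shared fixtures: packaged geometry, toy paths, and a reference subject."""

import numpy as np
import pytest

from elbowext import load_geometry
from elbowext.geometry import MusclePath, PathPoint
from elbowext.optimize import optimization_grid
from elbowext.pipeline import build_subject_model
from elbowext.synthetic import NO_NOISE, generate_subject
from elbowext.torque import predict_extension_torque


@pytest.fixture(scope="session")
def default_geometry():
    return load_geometry()


@pytest.fixture(scope="session")
def grid46():
    return optimization_grid()


@pytest.fixture
def two_point_path():
    """A 3-4-5 triangle, both points humerus-fixed: length 5 at any angle."""
    return MusclePath(
        muscle_id="toy",
        origin=PathPoint(np.array([0.0, 0.0, 0.0])),
        insertion=PathPoint(np.array([3.0, 4.0, 0.0])),
    )


@pytest.fixture(scope="session")
def reference_subject():
    """One noise-free synthetic control subject with its hidden truth."""
    record, truth = generate_subject("control", 42, noise=NO_NOISE)
    return record, truth


@pytest.fixture(scope="session")
def reference_model(reference_subject):
    record, _ = reference_subject
    return build_subject_model(record)


@pytest.fixture(scope="session")
def reference_curve(reference_subject, reference_model, grid46):
    """Noise-free forward torque at the reference subject's true forces."""
    _, truth = reference_subject
    model = reference_model.with_forces(truth.F_z)
    return predict_extension_torque(model, grid46)
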