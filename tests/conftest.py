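"""Shared fixtures and builders for the test suite.

All synthetic inputs are generated programmatically; nothing is read from
disk except files the tests themselves write to tmp_path.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from vftrial.grid import FieldLocation, native_locations
from vftrial.model import IntegratedField, MonocularExam, PointData, field_from_maps

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_exam(
    patient_id: str = "P001",
    visit: str = "baseline",
    eye: str = "OD",
    sensitivity: float = 25.0,
    td: float | None = None,
    prob: float = 100.0,
) -> MonocularExam:
    """Exam with a spatially uniform value triple."""
    td = sensitivity - 30.0 if td is None else td
    values = {
        loc: PointData(sensitivity, td, prob) for loc in native_locations(eye)
    }
    return MonocularExam(patient_id=patient_id, eye=eye, visit=visit, values=values)


def make_field(
    sensitivity,
    patient_id: str = "P001",
    visit: str = "baseline",
    td=None,
    prob=None,
) -> IntegratedField:
    """Integrated field from per-location maps or scalars."""
    from vftrial.grid import common_frame_locations

    locs = common_frame_locations()
    if np.isscalar(sensitivity):
        sensitivity = {loc: float(sensitivity) for loc in locs}
    if td is not None and np.isscalar(td):
        td = {loc: float(td) for loc in locs}
    if prob is not None and np.isscalar(prob):
        prob = {loc: float(prob) for loc in locs}
    return field_from_maps(patient_id, visit, sensitivity, td=td, td_prob=prob)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
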