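"""Exam data model: monocular Humphrey 24-2 exams and binocular integrated fields.

A :class:`MonocularExam` holds, for each of the 52 eye-native locations, the
measured luminance sensitivity (dB), the total deviation (TD, dB — sensitivity
minus the age-normative value) and the TD probability category.  Probability
categories follow the perimeter's convention: a point is printed with the
tightest percentile level at which its TD is abnormal (0.5, 1, 2 or 5), and
100 encodes "within normal limits" (TD not below the 5% percentile of the
normative distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

from .grid import (
    Eye,
    EYES,
    FieldLocation,
    VISITS,
    common_frame_locations,
    native_locations,
)

#: Valid TD probability categories (percent). 100 = within normal limits.
PROB_CATEGORIES = (0.5, 1.0, 2.0, 5.0, 100.0)

SENSITIVITY_MIN_DB = 0.0   # "<0 dB" on the printout is floored at 0
SENSITIVITY_MAX_DB = 50.0


class PointData(NamedTuple):
    """Per-location measurement triple."""

    sensitivity_db: float
    td_db: float
    td_prob_pct: float


def _check_point(loc: FieldLocation, data: PointData) -> None:
    if not SENSITIVITY_MIN_DB <= data.sensitivity_db <= SENSITIVITY_MAX_DB:
        raise ValueError(
            f"sensitivity {data.sensitivity_db} dB at {tuple(loc)} outside "
            f"[{SENSITIVITY_MIN_DB}, {SENSITIVITY_MAX_DB}]"
        )
    if data.td_prob_pct not in PROB_CATEGORIES:
        raise ValueError(
            f"TD probability category {data.td_prob_pct} at {tuple(loc)} not in "
            f"{PROB_CATEGORIES}"
        )


@dataclass
class MonocularExam:
    """One eye's 24-2 exam at one visit."""

    patient_id: str
    eye: Eye
    visit: str
    values: dict[FieldLocation, PointData]

    def __post_init__(self) -> None:
        if self.eye not in EYES:
            raise ValueError(f"unknown eye code {self.eye!r}")
        if self.visit not in VISITS:
            raise ValueError(f"unknown visit code {self.visit!r}")
        self.values = {
            FieldLocation(*k): PointData(*v) for k, v in self.values.items()
        }
        expected = set(native_locations(self.eye))
        got = set(self.values)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ValueError(
                f"exam {self.patient_id}/{self.eye}/{self.visit}: locations do not "
                f"form the {self.eye} native 24-2 grid "
                f"(missing {missing[:4]}{'...' if len(missing) > 4 else ''}, "
                f"extra {extra[:4]}{'...' if len(extra) > 4 else ''})"
            )
        for loc, data in self.values.items():
            _check_point(loc, data)


@dataclass
class IntegratedField:
    """Binocular-integrated field on the 52-location common frame.

    ``provenance`` records, per location, which eye supplied the value
    ("OD" or "OS").
    """

    patient_id: str
    visit: str
    values: dict[FieldLocation, PointData]
    provenance: dict[FieldLocation, Eye] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.visit not in VISITS:
            raise ValueError(f"unknown visit code {self.visit!r}")
        self.values = {
            FieldLocation(*k): PointData(*v) for k, v in self.values.items()
        }
        expected = set(common_frame_locations())
        if set(self.values) != expected:
            raise ValueError(
                f"integrated field {self.patient_id}/{self.visit}: expected the "
                f"52 common-frame locations, got {len(self.values)}"
            )
        for loc, data in self.values.items():
            _check_point(loc, data)

    def sensitivity(self, loc: FieldLocation) -> float:
        return self.values[FieldLocation(*loc)].sensitivity_db

    def td(self, loc: FieldLocation) -> float:
        return self.values[FieldLocation(*loc)].td_db


def field_from_maps(
    patient_id: str,
    visit: str,
    sensitivity: Mapping[FieldLocation, float],
    td: Mapping[FieldLocation, float] | None = None,
    td_prob: Mapping[FieldLocation, float] | None = None,
) -> IntegratedField:
    """Convenience constructor for tests and examples.

    Missing TD defaults to sensitivity - 30 (a flat normative surface);
    missing probability defaults to "within normal limits".
    """
    values = {}
    for loc, s in sensitivity.items():
        loc = FieldLocation(*loc)
        t = td[loc] if td is not None else s - 30.0
        p = td_prob[loc] if td_prob is not None else 100.0
        values[loc] = PointData(s, t, p)
    return IntegratedField(patient_id=patient_id, visit=visit, values=values)
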