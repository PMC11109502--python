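"""Binocular integration: one field per patient/visit from the two monocular exams.

The integrated sensitivity at each common-frame location is the maximum over
the eyes tested there ("best location" integration).  48 locations are seen
by both eyes; at each blind-spot location (+/-15, +/-3) only the fellow eye
contributes and its value stands in unchanged.  Total deviation and the TD
probability category are carried over from the eye that supplied the winning
sensitivity (ties go to OD), so that defect masks defined on TD probability
live directly on the integrated map.  The single-eye nasal-extension points
at |x| = 27 are outside the common frame and are dropped.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .grid import FieldLocation, common_frame_locations
from .model import IntegratedField, MonocularExam

logger = logging.getLogger(__name__)


def integrate(od: MonocularExam, os_: MonocularExam) -> IntegratedField:
    """Build the binocular-integrated field from an OD/OS exam pair."""
    if od.eye != "OD" or os_.eye != "OS":
        raise ValueError(f"expected an (OD, OS) pair, got ({od.eye}, {os_.eye})")
    if od.patient_id != os_.patient_id or od.visit != os_.visit:
        raise ValueError(
            f"exam pair mismatch: {od.patient_id}/{od.visit} vs "
            f"{os_.patient_id}/{os_.visit}"
        )
    values: dict[FieldLocation, object] = {}
    provenance = {}
    for loc in common_frame_locations():
        in_od, in_os = loc in od.values, loc in os_.values
        if in_od and in_os:
            # tie -> OD, so strict '>' for OS to win
            if os_.values[loc].sensitivity_db > od.values[loc].sensitivity_db:
                eye = "OS"
            else:
                eye = "OD"
        elif in_od:
            eye = "OD"
        elif in_os:
            eye = "OS"
        else:  # unreachable for valid exams: every common point is in >=1 eye
            raise ValueError(f"location {tuple(loc)} missing from both exams")
        values[loc] = (od if eye == "OD" else os_).values[loc]
        provenance[loc] = eye
    return IntegratedField(
        patient_id=od.patient_id, visit=od.visit,
        values=values, provenance=provenance,
    )


def integrate_cohort(exams: Sequence[MonocularExam]) -> list[IntegratedField]:
    """Integrate every complete (patient, visit) OD/OS pair in a cohort.

    Incomplete pairs are logged and skipped; duplicate (patient, visit, eye)
    records raise.
    """
    by_key: dict[tuple[str, str], dict[str, MonocularExam]] = {}
    for exam in exams:
        key = (exam.patient_id, exam.visit)
        eyes = by_key.setdefault(key, {})
        if exam.eye in eyes:
            raise ValueError(
                f"duplicate exam for patient {exam.patient_id}, visit "
                f"{exam.visit}, eye {exam.eye}"
            )
        eyes[exam.eye] = exam
    fields = []
    for key in sorted(by_key):
        eyes = by_key[key]
        if "OD" in eyes and "OS" in eyes:
            fields.append(integrate(eyes["OD"], eyes["OS"]))
        else:
            logger.warning(
                "skipping patient %s visit %s: only %s exam present",
                key[0], key[1], next(iter(eyes)),
            )
    return fields
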