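"""CSV I/O for exam data.

One row per test location::

    patient_id,visit,eye,x_deg,y_deg,sensitivity_db,td_db,td_prob_pct

with ``visit`` in {baseline, week12}, ``eye`` in {OD, OS} (or BIN for
integrated fields), decimal point '.', UTF-8, header required.  Reading is
strict: rows violating the schema are reported with their file row number
and the whole read is rejected.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .grid import EYES, FieldLocation, VISITS, is_valid_grid_point
from .model import (
    IntegratedField,
    MonocularExam,
    PointData,
    PROB_CATEGORIES,
    SENSITIVITY_MAX_DB,
    SENSITIVITY_MIN_DB,
)

logger = logging.getLogger(__name__)

EXAM_COLUMNS = [
    "patient_id", "visit", "eye", "x_deg", "y_deg",
    "sensitivity_db", "td_db", "td_prob_pct",
]


class ExamSchemaError(ValueError):
    """Raised when an exam CSV violates the schema; message lists row numbers."""


def _validate_rows(df: pd.DataFrame, allowed_eyes: Sequence[str]) -> list[str]:
    problems = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based, after the header line
        if row["visit"] not in VISITS:
            problems.append(f"row {rowno}: unknown visit {row['visit']!r}")
        if row["eye"] not in allowed_eyes:
            problems.append(f"row {rowno}: unknown eye {row['eye']!r}")
        try:
            x, y = int(row["x_deg"]), int(row["y_deg"])
            if not is_valid_grid_point(x, y):
                problems.append(
                    f"row {rowno}: ({x}, {y}) is not on the 6-degree 24-2 grid "
                    "(coordinates must be odd multiples of 3)"
                )
        except (TypeError, ValueError):
            problems.append(f"row {rowno}: non-integer coordinates")
        s = row["sensitivity_db"]
        if not SENSITIVITY_MIN_DB <= s <= SENSITIVITY_MAX_DB:
            problems.append(f"row {rowno}: sensitivity {s} outside [0, 50]")
        if float(row["td_prob_pct"]) not in PROB_CATEGORIES:
            problems.append(
                f"row {rowno}: td_prob_pct {row['td_prob_pct']} not in "
                f"{PROB_CATEGORIES}"
            )
    return problems


def read_exams(path: str | Path) -> list[MonocularExam]:
    """Read monocular exams from CSV; returns one exam per (patient, visit, eye)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        logger.warning("exam file %s contains no data rows", path)
        return []
    missing = [c for c in EXAM_COLUMNS if c not in df.columns]
    if missing:
        raise ExamSchemaError(f"{path}: missing columns {missing}")
    problems = _validate_rows(df, allowed_eyes=EYES)
    if problems:
        raise ExamSchemaError(f"{path}: invalid rows:\n" + "\n".join(problems))

    exams = []
    for (pid, visit, eye), grp in df.groupby(
        ["patient_id", "visit", "eye"], sort=True
    ):
        values = {
            FieldLocation(int(r.x_deg), int(r.y_deg)): PointData(
                float(r.sensitivity_db), float(r.td_db), float(r.td_prob_pct)
            )
            for r in grp.itertuples()
        }
        exams.append(
            MonocularExam(patient_id=str(pid), eye=eye, visit=visit, values=values)
        )
    return exams


def _rows(patient_id: str, visit: str, eye: str, values) -> Iterable[dict]:
    for loc in sorted(values, key=lambda p: (-p.y_deg, p.x_deg)):
        d = values[loc]
        yield {
            "patient_id": patient_id, "visit": visit, "eye": eye,
            "x_deg": loc.x_deg, "y_deg": loc.y_deg,
            "sensitivity_db": d.sensitivity_db, "td_db": d.td_db,
            "td_prob_pct": d.td_prob_pct,
        }


def write_exams(exams: Sequence[MonocularExam], path: str | Path) -> None:
    """Write monocular exams to CSV (lossless round-trip with :func:`read_exams`)."""
    records = []
    for exam in exams:
        records.extend(_rows(exam.patient_id, exam.visit, exam.eye, exam.values))
    pd.DataFrame(records, columns=EXAM_COLUMNS).to_csv(path, index=False)


def write_integrated(fields: Sequence[IntegratedField], path: str | Path) -> None:
    """Write binocular-integrated fields in the exam schema with eye=BIN."""
    records = []
    for f in fields:
        records.extend(_rows(f.patient_id, f.visit, "BIN", f.values))
    pd.DataFrame(records, columns=EXAM_COLUMNS).to_csv(path, index=False)


def read_integrated(path: str | Path) -> list[IntegratedField]:
    """Read integrated fields (eye=BIN rows) written by :func:`write_integrated`."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        logger.warning("integrated-field file %s contains no data rows", path)
        return []
    problems = _validate_rows(df, allowed_eyes=("BIN",))
    if problems:
        raise ExamSchemaError(f"{path}: invalid rows:\n" + "\n".join(problems))
    fields = []
    for (pid, visit), grp in df.groupby(["patient_id", "visit"], sort=True):
        values = {
            FieldLocation(int(r.x_deg), int(r.y_deg)): PointData(
                float(r.sensitivity_db), float(r.td_db), float(r.td_prob_pct)
            )
            for r in grp.itertuples()
        }
        fields.append(IntegratedField(patient_id=str(pid), visit=visit, values=values))
    return fields
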