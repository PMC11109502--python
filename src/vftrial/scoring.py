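"""Visual-field-defect classification and per-patient outcome scoring.

The trial's outcome definitions, applied to binocular-integrated fields:

* **defect mask** — baseline locations whose total-deviation probability
  category is below the 5% level;
* **VFD classification** — side (hemifield holding the strict majority of
  mask points) and type (hemianopia if both quadrants of that hemifield are
  each at least 25% defective, else quadrantanopia in the dominant quadrant);
* **improved visual area** (primary outcome) — 36 deg^2 per location whose
  sensitivity gained at least 6 dB from baseline within a region, counting
  only locations that were below the 30 dB normal threshold at baseline;
* **mean total deviation (MTD)** (secondary outcome) — arithmetic mean of
  the per-location total deviations over a region, in dB;
* **responder** — strictly positive MTD change in the region.

The "defective hemifield" used for outcomes is the full 26-point hemifield
on the classified side, not the defect mask alone, so boundary points count
toward both improved area and MTD.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import (
    FieldLocation,
    POINT_AREA_DEG2,
    Quadrant,
    RegionSpec,
    Side,
    hemifield_of,
    quadrant_of,
    region_members,
)
from .model import IntegratedField

#: Sensitivity gain (dB) counted as training-induced improvement.
IMPROVEMENT_THRESHOLD_DB = 6.0
#: Baseline sensitivity at/above this is considered normal and not improvable.
NORMAL_CAP_DB = 30.0
#: TD probability categories strictly below this flag a defective location.
DEFECT_ALPHA_PCT = 5.0
#: Minimum defective fraction of both quadrants for a hemianopia call.
HEMIANOPIA_QUADRANT_FRACTION = 0.25


@dataclass(frozen=True)
class VfdClassification:
    """Side and type of a visual field defect, with its defining mask."""

    side: Side
    vfd_type: str  # "hemianopia" | "quadrantanopia"
    quadrant: Quadrant | None
    defect_mask: RegionSpec

    def __post_init__(self) -> None:
        if self.vfd_type not in ("hemianopia", "quadrantanopia"):
            raise ValueError(f"unknown VFD type {self.vfd_type!r}")
        if (self.quadrant is not None) != (self.vfd_type == "quadrantanopia"):
            raise ValueError("quadrant must be present iff type is quadrantanopia")


@dataclass
class OutcomeRecord:
    """Per-patient trial outcomes on the integrated field."""

    patient_id: str
    arm: str
    vfd_side: Side
    vfd_type: str
    improved_area_hemi_deg2: float
    improved_area_whole_deg2: float
    mtd_pre_hemi: float
    mtd_post_hemi: float
    mtd_delta_hemi: float
    mtd_pre_whole: float
    mtd_post_whole: float
    mtd_delta_whole: float
    responder_hemi: bool
    responder_whole: bool


def defect_mask(
    baseline: IntegratedField, alpha_pct: float = DEFECT_ALPHA_PCT
) -> RegionSpec:
    """Mask of baseline locations with TD probability category < ``alpha_pct``."""
    locs = [
        loc for loc, d in baseline.values.items() if d.td_prob_pct < alpha_pct
    ]
    locs.sort(key=lambda p: (-p.y_deg, p.x_deg))
    return RegionSpec.mask(locs)


def classify_vfd(
    mask: RegionSpec,
    hemianopia_fraction: float = HEMIANOPIA_QUADRANT_FRACTION,
) -> VfdClassification:
    """Classify a defect mask as left/right hemianopia or quadrantanopia.

    Side is the hemifield holding the strict majority of mask points (an
    exact tie is an un-lateralized defect and raises).  The defect is called
    hemianopia when both quadrants of that hemifield are each at least
    ``hemianopia_fraction`` defective (of their 13-point capacity); otherwise
    quadrantanopia in the dominant quadrant (tie broken to the upper one).
    """
    locs = region_members(mask)
    if not locs:
        raise ValueError("cannot classify an empty defect mask")
    n_left = sum(1 for p in locs if hemifield_of(p) == "left")
    n_right = len(locs) - n_left
    if n_left == n_right:
        raise ValueError(
            f"un-lateralized defect: {n_left} left vs {n_right} right mask points"
        )
    side: Side = "left" if n_left > n_right else "right"
    quads = ("UL", "LL") if side == "left" else ("UR", "LR")
    counts = {
        q: sum(1 for p in locs if quadrant_of(p) == q) for q in quads
    }
    capacity = len(region_members(RegionSpec.quadrant(quads[0])))  # 13
    if all(counts[q] / capacity >= hemianopia_fraction for q in quads):
        return VfdClassification(
            side=side, vfd_type="hemianopia", quadrant=None, defect_mask=mask
        )
    dominant = max(quads, key=lambda q: (counts[q], q == quads[0]))
    return VfdClassification(
        side=side, vfd_type="quadrantanopia", quadrant=dominant, defect_mask=mask
    )


def improved_area(
    pre: IntegratedField,
    post: IntegratedField,
    region: RegionSpec,
    delta_db: float = IMPROVEMENT_THRESHOLD_DB,
    normal_cap_db: float | None = NORMAL_CAP_DB,
) -> float:
    """Improved visual area (deg^2) in ``region`` between two visits.

    Counts locations whose sensitivity gained at least ``delta_db`` and whose
    baseline sensitivity was below ``normal_cap_db`` (pass ``None`` to count
    already-normal locations too), at 36 deg^2 per location.
    """
    if pre.patient_id != post.patient_id:
        raise ValueError(
            f"patient mismatch: {pre.patient_id} vs {post.patient_id}"
        )
    n = 0
    for loc in region_members(region):
        gain = post.sensitivity(loc) - pre.sensitivity(loc)
        if gain >= delta_db and (
            normal_cap_db is None or pre.sensitivity(loc) < normal_cap_db
        ):
            n += 1
    return n * POINT_AREA_DEG2


def mtd(field: IntegratedField, region: RegionSpec) -> float:
    """Mean total deviation (dB) over the region's locations."""
    locs = region_members(region)
    if not locs:
        raise ValueError("MTD over an empty region is undefined")
    return float(np.mean([field.td(loc) for loc in locs]))


def score_patient(
    pre: IntegratedField,
    post: IntegratedField,
    arm: str,
    delta_db: float = IMPROVEMENT_THRESHOLD_DB,
    alpha_pct: float = DEFECT_ALPHA_PCT,
    normal_cap_db: float | None = NORMAL_CAP_DB,
) -> OutcomeRecord:
    """Score one patient: classify the baseline defect, then compute the
    improved areas, regional MTD changes and responder flags."""
    cls = classify_vfd(defect_mask(pre, alpha_pct=alpha_pct))
    hemi = RegionSpec.hemifield(cls.side)
    whole = RegionSpec.whole()
    mtd_pre_h, mtd_post_h = mtd(pre, hemi), mtd(post, hemi)
    mtd_pre_w, mtd_post_w = mtd(pre, whole), mtd(post, whole)
    return OutcomeRecord(
        patient_id=pre.patient_id,
        arm=arm,
        vfd_side=cls.side,
        vfd_type=cls.vfd_type,
        improved_area_hemi_deg2=improved_area(
            pre, post, hemi, delta_db=delta_db, normal_cap_db=normal_cap_db
        ),
        improved_area_whole_deg2=improved_area(
            pre, post, whole, delta_db=delta_db, normal_cap_db=normal_cap_db
        ),
        mtd_pre_hemi=mtd_pre_h,
        mtd_post_hemi=mtd_post_h,
        mtd_delta_hemi=mtd_post_h - mtd_pre_h,
        mtd_pre_whole=mtd_pre_w,
        mtd_post_whole=mtd_post_w,
        mtd_delta_whole=mtd_post_w - mtd_pre_w,
        responder_hemi=mtd_post_h - mtd_pre_h > 0,
        responder_whole=mtd_post_w - mtd_pre_w > 0,
    )


OUTCOME_COLUMNS = [
    "patient_id", "arm", "vfd_side", "vfd_type",
    "improved_area_hemi_deg2", "improved_area_whole_deg2",
    "mtd_pre_hemi", "mtd_post_hemi", "mtd_delta_hemi",
    "mtd_pre_whole", "mtd_post_whole", "mtd_delta_whole",
    "responder_hemi", "responder_whole",
]


def outcomes_to_frame(outcomes: Sequence[OutcomeRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(o) for o in outcomes], columns=OUTCOME_COLUMNS)


def write_outcomes(outcomes: Sequence[OutcomeRecord], path: str | Path) -> None:
    outcomes_to_frame(outcomes).to_csv(path, index=False)


def read_outcomes(path: str | Path) -> list[OutcomeRecord]:
    df = pd.read_csv(path)
    return [
        OutcomeRecord(**{k: row[k] for k in OUTCOME_COLUMNS})
        for _, row in df.iterrows()
    ]
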