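"""Synthetic two-arm trial cohorts with known ground truth.

The generator emulates the data the scoring pipeline consumes — hemianopic
or quadrantanopic sensitivity maps on the 24-2 grid, age-normative
deviations, per-point test-retest noise, permuted-block arm assignment,
arm-specific training-induced improvement and per-arm dropout — while
recording every patient's ground truth so that parameter-recovery tests can
check the pipeline end to end.

Key defaults follow the trial being emulated: completer counts 40/35,
left-sided defects 56%, hemianopia 53.3%, ages ~ Normal(52, 15) truncated to
[19, 80], dropout probabilities 1/41 and 3/38, and a per-point test-retest
standard deviation of 3 dB (half the 6 dB change threshold, which is chosen
to roughly double the test-to-test variability).  The normative-sensitivity
surface, defect depths and the TD-probability quantile mapping are modelling
conventions of this package, parameterised in :class:`CohortConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats as sps

from .grid import (
    Eye,
    FieldLocation,
    Quadrant,
    RegionSpec,
    Side,
    common_frame_locations,
    native_locations,
    region_members,
)
from .model import (
    MonocularExam,
    PointData,
    SENSITIVITY_MAX_DB,
    SENSITIVITY_MIN_DB,
)
from .scoring import VfdClassification

ARMS = ("NV", "NV-C")

#: Lower-tail normal quantiles defining the TD probability categories.
_PROB_LEVELS = (0.5, 1.0, 2.0, 5.0)
_PROB_Z = {c: float(sps.norm.ppf(c / 100.0)) for c in _PROB_LEVELS}


class EffectModel(BaseModel):
    """Training effect for one arm: each defective-hemifield point truly
    improves with probability ``p_improve`` by a Normal(gain_mean, gain_sd)
    dB gain (negative draws floored at zero)."""

    p_improve: float = Field(ge=0.0, le=1.0)
    gain_mean_db: float = 8.0
    gain_sd_db: float = Field(default=2.0, ge=0.0)


class CohortConfig(BaseModel):
    """All tunable parameters of the synthetic trial."""

    seed: int
    n_per_arm: tuple[int, int] = (40, 35)
    block_size: int = 4
    p_left: float = Field(default=0.56, ge=0.0, le=1.0)
    p_hemianopia: float = Field(default=0.5333, ge=0.0, le=1.0)
    age_mean: float = 52.0
    age_sd: float = 15.0
    age_range: tuple[float, float] = (19.0, 80.0)
    noise_sd_db: float = Field(default=3.0, gt=0.0)
    #: SD of the normative population used for TD probability categories.
    normative_sd_db: float = Field(default=3.0, gt=0.0)
    defect_depth_range_db: tuple[float, float] = (0.0, 8.0)
    transition_range_db: tuple[float, float] = (8.0, 18.0)
    effects: dict[str, EffectModel] = Field(
        default_factory=lambda: {
            "NV": EffectModel(p_improve=0.10),
            "NV-C": EffectModel(p_improve=0.08),
        }
    )
    dropout: tuple[float, float] = (1 / 41, 3 / 38)

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if self.block_size % 2 != 0 or self.block_size < 2:
            raise ValueError("block_size must be a positive even integer")
        if any(n < 0 for n in self.n_per_arm):
            raise ValueError("n_per_arm must be nonnegative")
        if any(not 0 <= p <= 1 for p in self.dropout):
            raise ValueError("dropout probabilities must be in [0, 1]")
        if set(self.effects) != set(ARMS):
            raise ValueError(f"effects must be specified for arms {ARMS}")
        return self


@dataclass
class PatientTruth:
    """Ground truth for one simulated patient."""

    patient_id: str
    arm: str
    age: float
    classification: VfdClassification
    baseline_truth: dict[FieldLocation, float]
    gain_map: dict[FieldLocation, float]
    dropped: bool


@dataclass
class CohortData:
    exams: list[MonocularExam]
    truths: list[PatientTruth]
    meta: pd.DataFrame


def normative_sensitivity(loc: FieldLocation, age: float) -> float:
    """Age-normative sensitivity (dB) at a common-frame location.

    33 dB at the innermost ring for a 45-year-old, falling by 0.5 dB per
    eccentricity ring and 0.1 dB per year beyond age 45, clamped to [20, 40].
    """
    if not 18.0 <= age <= 100.0:
        raise ValueError(f"age {age} outside the supported range [18, 100]")
    loc = FieldLocation(*loc)
    value = 33.0 - 0.5 * loc.ring - 0.1 * max(0.0, age - 45.0)
    return float(np.clip(value, 20.0, 40.0))


def apply_vfd_template(
    truth_map: dict[FieldLocation, float],
    classification: VfdClassification,
    rng: np.random.Generator,
    depth_range: tuple[float, float] = (0.0, 8.0),
    transition_range: tuple[float, float] = (8.0, 18.0),
) -> dict[FieldLocation, float]:
    """Impose a deep defect on the classified hemifield or quadrant.

    Affected points are redrawn from Uniform(*depth_range*); the ring of
    affected points adjacent to the vertical meridian (|x| = 3) forms a
    shallower transition band drawn from Uniform(*transition_range*).
    """
    if classification.vfd_type == "hemianopia":
        region = RegionSpec.hemifield(classification.side)
    else:
        region = RegionSpec.quadrant(classification.quadrant)
    out = dict(truth_map)
    for loc in region_members(region):
        lo, hi = (transition_range if abs(loc.x_deg) == 3 else depth_range)
        out[loc] = float(rng.uniform(lo, hi))
    return out


def _nearest_common(loc: FieldLocation) -> FieldLocation:
    common = common_frame_locations()
    return min(
        common,
        key=lambda c: ((c.x_deg - loc.x_deg) ** 2 + (c.y_deg - loc.y_deg) ** 2,
                       -c.y_deg, c.x_deg),
    )


def td_probability_category(td_db: float, normative_sd_db: float) -> float:
    """Map a total deviation to its probability category.

    Returns the smallest level c in {0.5, 1, 2, 5} whose lower-tail normal
    quantile (z_c * normative_sd) still exceeds the TD, or 100 ("within
    normal limits") when the TD is not below the 5% quantile.
    """
    for c in _PROB_LEVELS:
        if td_db < _PROB_Z[c] * normative_sd_db:
            return c
    return 100.0


def measure_exam(
    truth_map: dict[FieldLocation, float],
    age: float,
    eye: Eye,
    rng: np.random.Generator,
    noise_sd: float,
    patient_id: str = "P000",
    visit: str = "baseline",
    normative_sd_db: float = 3.0,
) -> MonocularExam:
    """Simulate one perimetry exam of a true sensitivity map.

    Measured sensitivity is truth plus Normal(0, noise_sd) noise, clamped to
    [0, 50] dB; TD is measured sensitivity minus the age-normative value;
    the TD probability category follows the quantile mapping.  The eye-native
    grid is produced: nasal-extension points take the truth (and normative
    value) of their nearest common-frame neighbour.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    values = {}
    for loc in native_locations(eye):
        src = loc if loc in truth_map else _nearest_common(loc)
        truth = truth_map[src]
        norm = normative_sensitivity(src, age)
        sens = float(
            np.clip(truth + rng.normal(0.0, noise_sd),
                    SENSITIVITY_MIN_DB, SENSITIVITY_MAX_DB)
        )
        td = sens - norm
        values[loc] = PointData(sens, td, td_probability_category(td, normative_sd_db))
    return MonocularExam(patient_id=patient_id, eye=eye, visit=visit, values=values)


def permuted_block_randomize(
    n: int,
    block_size: int,
    rng: np.random.Generator,
    arms: tuple[str, str] = ARMS,
) -> list[str]:
    """1:1 permuted-block arm assignment for ``n`` patients.

    Every complete block contains exactly half of each arm; a final partial
    block is a truncated shuffled block (sampling without replacement).
    """
    if n < 1:
        raise ValueError("need at least one patient")
    if block_size % 2 != 0 or block_size < 2:
        raise ValueError("block_size must be a positive even integer")
    half = block_size // 2
    labels: list[str] = []
    while len(labels) < n:
        block = [arms[0]] * half + [arms[1]] * half
        rng.shuffle(block)
        labels.extend(block)
    return labels[:n]


def _quota_block_sequence(
    quotas: tuple[int, int],
    block_size: int,
    rng: np.random.Generator,
) -> list[str]:
    """Permuted-block sequence with exact final per-arm counts.

    Blocks stay 1:1 balanced until one arm's quota is exhausted, after which
    the remaining slots fill with the other arm (as when enrolment in one
    arm closes first).
    """
    half = block_size // 2
    rem = list(quotas)
    seq: list[str] = []
    while sum(rem) > 0:
        take = [min(half, rem[0]), min(half, rem[1])]
        block = [ARMS[0]] * take[0] + [ARMS[1]] * take[1]
        rng.shuffle(block)
        seq.extend(block)
        rem[0] -= take[0]
        rem[1] -= take[1]
    return seq


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _draw_classification(
    config: CohortConfig, rng: np.random.Generator
) -> VfdClassification:
    side: Side = "left" if rng.random() < config.p_left else "right"
    if rng.random() < config.p_hemianopia:
        region = RegionSpec.hemifield(side)
        return VfdClassification(
            side=side, vfd_type="hemianopia", quadrant=None,
            defect_mask=RegionSpec.mask(region_members(region)),
        )
    quads: tuple[Quadrant, Quadrant] = (
        ("UL", "LL") if side == "left" else ("UR", "LR")
    )
    quad = quads[int(rng.integers(2))]
    region = RegionSpec.quadrant(quad)
    return VfdClassification(
        side=side, vfd_type="quadrantanopia", quadrant=quad,
        defect_mask=RegionSpec.mask(region_members(region)),
    )


def generate_cohort(config: CohortConfig) -> CohortData:
    """Generate a full synthetic trial: exams, ground truths and metadata.

    Each patient gets one true baseline map shared by both eyes (homonymous
    defects), an arm-specific improvement map added for the week-12 visit,
    and four independently noisy exams (2 eyes x 2 visits); dropouts omit
    the week-12 exams.
    """
    rng = np.random.default_rng(config.seed)
    arms = _quota_block_sequence(config.n_per_arm, config.block_size, rng)
    dropout = dict(zip(ARMS, config.dropout))

    exams: list[MonocularExam] = []
    truths: list[PatientTruth] = []
    meta_rows = []
    common = common_frame_locations()
    for i, arm in enumerate(arms, start=1):
        pid = f"P{i:03d}"
        age = _truncated_normal(
            rng, config.age_mean, config.age_sd, *config.age_range
        )
        cls = _draw_classification(config, rng)
        baseline = {loc: normative_sensitivity(loc, age) for loc in common}
        baseline = apply_vfd_template(
            baseline, cls, rng,
            depth_range=config.defect_depth_range_db,
            transition_range=config.transition_range_db,
        )
        effect = config.effects[arm]
        hemi = region_members(RegionSpec.hemifield(cls.side))
        gains = {}
        for loc in hemi:
            if rng.random() < effect.p_improve:
                gains[loc] = max(
                    0.0, float(rng.normal(effect.gain_mean_db, effect.gain_sd_db))
                )
        post_truth = {
            loc: baseline[loc] + gains.get(loc, 0.0) for loc in common
        }
        dropped = bool(rng.random() < dropout[arm])
        truths.append(PatientTruth(
            patient_id=pid, arm=arm, age=age, classification=cls,
            baseline_truth=baseline, gain_map=gains, dropped=dropped,
        ))
        visits = [("baseline", baseline)]
        if not dropped:
            visits.append(("week12", post_truth))
        for visit, truth in visits:
            for eye in ("OD", "OS"):
                exams.append(measure_exam(
                    truth, age, eye, rng,
                    noise_sd=config.noise_sd_db,
                    patient_id=pid, visit=visit,
                    normative_sd_db=config.normative_sd_db,
                ))
        meta_rows.append({
            "patient_id": pid, "arm": arm, "age": age,
            "vfd_side": cls.side, "vfd_type": cls.vfd_type,
            "dropped": dropped,
        })
    return CohortData(exams=exams, truths=truths, meta=pd.DataFrame(meta_rows))


def write_cohort(data: CohortData, outdir: str | Path) -> dict[str, Path]:
    """Write exams.csv (exam schema), truth.csv and meta.csv to a directory."""
    from .io import write_exams  # local import to avoid a cycle at import time

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exams": outdir / "exams.csv",
        "truth": outdir / "truth.csv",
        "meta": outdir / "meta.csv",
    }
    write_exams(data.exams, paths["exams"])
    truth_rows = []
    for t in data.truths:
        for loc in sorted(t.baseline_truth, key=lambda p: (-p.y_deg, p.x_deg)):
            truth_rows.append({
                "patient_id": t.patient_id,
                "x_deg": loc.x_deg, "y_deg": loc.y_deg,
                "baseline_db": t.baseline_truth[loc],
                "gain_db": t.gain_map.get(loc, 0.0),
            })
    pd.DataFrame(truth_rows).to_csv(paths["truth"], index=False)
    data.meta.to_csv(paths["meta"], index=False)
    return paths
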