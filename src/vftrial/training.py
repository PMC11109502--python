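"""Headless simulator of the two visual-perceptual-learning programs.

Both arms train a same/different discrimination between a central and a
peripheral stimulus (orientation, rotation or depth), 64 trials x 6 blocks
per day, 5 days a week for 12 weeks (60 sessions, 23,040 trials).  The arms
differ in where the peripheral stimulus lands:

* **NV** — large stimuli placed peripherally (ring eccentricity 5-21 deg),
  4.3 times more often in the defective hemifield than in the intact one;
* **NV-C** — small stimuli within 5 deg of fixation, 4.3 times more often
  in the *intact* hemifield.

A simulated observer answers through a psychometric function of the true
sensitivity at the stimulated location, so program-level logs can exercise
the performance-summary and performance-vs-outcome analyses end to end.
The observer model is plumbing for tests, not a claim about patients.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .grid import FieldLocation, Quadrant, common_frame_locations
from .scoring import OutcomeRecord, VfdClassification
from .stats import TestResult

logger = logging.getLogger(__name__)

TASKS = ("orientation", "rotation", "depth")


class TrainingConfig(BaseModel):
    """Parameters of the training protocol (defaults = the deployed programs)."""

    trials_per_block: int = Field(default=64, gt=0)
    blocks_per_day: int = Field(default=6, gt=0)
    days_per_week: int = Field(default=5, gt=0)
    weeks: int = Field(default=12, gt=0)
    #: Sampling odds toward the favoured hemifield (defective for NV,
    #: intact for NV-C).
    allocation_ratio: float = Field(default=4.3, gt=0.0)
    pre_blank_ms: int = 700
    stimulus_ms: int = 150
    response_window_ms: int = 3000
    nv_stimulus_deg: tuple[float, float, float] = (10.0, 10.0, 0.6)
    nvc_stimulus_deg: tuple[float, float, float] = (0.6, 0.6, 0.6)
    #: NV peripheral placements span this ring-eccentricity range (deg).
    nv_ecc_range_deg: tuple[float, float] = (5.0, 21.0)
    #: NV-C placements stay within this eccentricity of fixation (deg).
    nvc_max_ecc_deg: float = 5.0
    tasks: tuple[str, ...] = TASKS

    @property
    def trials_per_day(self) -> int:
        return self.trials_per_block * self.blocks_per_day

    @property
    def n_sessions(self) -> int:
        return self.days_per_week * self.weeks

    @property
    def total_trials(self) -> int:
        return self.trials_per_day * self.n_sessions


@dataclass(frozen=True)
class ObserverModel:
    """Psychometric stand-in for a patient.

    P(correct) = 0.5 + (0.5 - lapse/2) * logistic(beta * (S - theta)), where
    S is the true sensitivity (dB) at the stimulated location; with
    probability lapse/2 no button is pressed at all (scored incorrect).
    """

    sensitivity: dict[FieldLocation, float]
    beta: float = 0.4
    theta_db: float = 15.0
    lapse: float = 0.02
    #: Optional learning: dB added per week at locations trained that week.
    learning_db_per_week: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse rate must be in [0, 0.1]")

    def p_correct(self, sensitivity_db: float) -> float:
        logistic = 1.0 / (1.0 + math.exp(-self.beta * (sensitivity_db - self.theta_db)))
        return 0.5 + (0.5 - self.lapse / 2.0) * logistic


@dataclass(frozen=True)
class TrialRecord:
    session_idx: int
    block_idx: int
    trial_idx: int
    task: str
    hemifield: str          # "defective" | "intact"
    quadrant: Quadrant
    x_deg: float
    y_deg: float
    match: bool
    response: str           # "same" | "different" | "none"
    correct: bool
    rt_ms: float            # NaN when no response

    def __post_init__(self) -> None:
        if self.response == "none" and self.correct:
            raise ValueError("a missed response cannot be correct")


@dataclass
class SessionLog:
    arm: str
    records: list[TrialRecord] = field(default_factory=list)
    n_sessions_scheduled: int = 0
    sessions_completed: int = 0

    @property
    def compliance(self) -> float:
        if self.n_sessions_scheduled == 0:
            return float("nan")
        return self.sessions_completed / self.n_sessions_scheduled

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def schedule_program(
    config: TrainingConfig, rng: np.random.Generator
) -> list[list[str]]:
    """Session calendar: one task per block, chosen uniformly at random
    (patients chose freely among the three tasks; modelled as uniform)."""
    return [
        [config.tasks[int(rng.integers(len(config.tasks)))]
         for _ in range(config.blocks_per_day)]
        for _ in range(config.n_sessions)
    ]


def _quadrant_cells(quad: Quadrant, ecc_range: tuple[float, float]):
    lo, hi = ecc_range
    return [
        p for p in common_frame_locations()
        if (("U" in quad) == (p.y_deg > 0))
        and (("L" in quad[1]) == (p.x_deg < 0))
        and lo <= max(abs(p.x_deg), abs(p.y_deg)) <= hi
    ]


def sample_placement(
    arm: str,
    vfd: VfdClassification,
    config: TrainingConfig,
    rng: np.random.Generator,
) -> tuple[str, Quadrant, float, float]:
    """Draw one peripheral-stimulus placement.

    Returns (hemifield label, quadrant, x_deg, y_deg).  The hemifield is
    drawn with odds ``allocation_ratio : 1`` toward the defective side (NV)
    or the intact side (NV-C); the quadrant is uniform within the chosen
    hemifield.  NV placements are uniform over the quadrant's grid cells in
    the 5-21 deg eccentricity ring; NV-C placements are uniform over the
    quadrant sector within 5 deg of fixation.
    """
    if arm not in ("NV", "NV-C"):
        raise ValueError(f"unknown arm {arm!r}")
    r = config.allocation_ratio
    p_defective = r / (r + 1.0) if arm == "NV" else 1.0 / (r + 1.0)
    hemifield = "defective" if rng.random() < p_defective else "intact"
    side = vfd.side if hemifield == "defective" else (
        "right" if vfd.side == "left" else "left"
    )
    upper = bool(rng.integers(2))
    quad: Quadrant = ("U" if upper else "L") + ("L" if side == "left" else "R")  # type: ignore

    if arm == "NV":
        cells = _quadrant_cells(quad, config.nv_ecc_range_deg)
        loc = cells[int(rng.integers(len(cells)))]
        x, y = float(loc.x_deg), float(loc.y_deg)
    else:
        # uniform over the quarter-disc of radius nvc_max_ecc in that quadrant
        radius = config.nvc_max_ecc_deg * math.sqrt(rng.random())
        angle = rng.uniform(0.0, math.pi / 2.0)
        x = radius * math.cos(angle) * (-1.0 if side == "left" else 1.0)
        y = radius * math.sin(angle) * (1.0 if upper else -1.0)
    return hemifield, quad, x, y


def _nearest_grid(x: float, y: float) -> FieldLocation:
    return min(
        common_frame_locations(),
        key=lambda p: ((p.x_deg - x) ** 2 + (p.y_deg - y) ** 2, -p.y_deg, p.x_deg),
    )


def run_trial(
    observer: ObserverModel,
    session_idx: int,
    block_idx: int,
    trial_idx: int,
    task: str,
    placement: tuple[str, Quadrant, float, float],
    rng: np.random.Generator,
    sensitivity: dict[FieldLocation, float] | None = None,
) -> TrialRecord:
    """Simulate one same/different discrimination trial.

    Sensitivity at the stimulated location is looked up at the nearest
    common-frame grid point.  The unconditional probability of a correct
    response equals the observer's psychometric value; no-response events
    (probability lapse/2) are always incorrect.
    """
    hemifield, quad, x, y = placement
    smap = sensitivity if sensitivity is not None else observer.sensitivity
    s = smap[_nearest_grid(x, y)]
    p_correct = observer.p_correct(s)
    match = bool(rng.integers(2))
    u = rng.random()
    if u < observer.lapse / 2.0:
        response, correct, rt = "none", False, float("nan")
    else:
        p_given_response = p_correct / (1.0 - observer.lapse / 2.0)
        correct = bool(rng.random() < p_given_response)
        answered_same = match if correct else not match
        response = "same" if answered_same else "different"
        rt = float(rng.uniform(300.0, 3000.0))
    return TrialRecord(
        session_idx=session_idx, block_idx=block_idx, trial_idx=trial_idx,
        task=task, hemifield=hemifield, quadrant=quad, x_deg=x, y_deg=y,
        match=match, response=response, correct=correct, rt_ms=rt,
    )


def run_program(
    observer: ObserverModel,
    arm: str,
    vfd: VfdClassification,
    config: TrainingConfig,
    seed: int,
    skip_session_prob: float = 0.0,
) -> SessionLog:
    """Simulate the full 60-session program for one observer.

    Deterministic given ``seed``.  ``skip_session_prob`` models imperfect
    compliance (each session independently skipped with that probability).
    With a positive observer ``learning_db_per_week``, sensitivity at the
    locations stimulated during a week increases by that amount at the end
    of the week.
    """
    rng = np.random.default_rng(seed)
    calendar = schedule_program(config, rng)
    smap = dict(observer.sensitivity)
    log = SessionLog(arm=arm, n_sessions_scheduled=config.n_sessions)
    week_locations: set[FieldLocation] = set()
    for s_idx, session_tasks in enumerate(calendar, start=1):
        if rng.random() < skip_session_prob:
            continue
        log.sessions_completed += 1
        for b_idx, task in enumerate(session_tasks, start=1):
            for t_idx in range(1, config.trials_per_block + 1):
                placement = sample_placement(arm, vfd, config, rng)
                rec = run_trial(
                    observer, s_idx, b_idx, t_idx, task, placement, rng,
                    sensitivity=smap,
                )
                week_locations.add(_nearest_grid(rec.x_deg, rec.y_deg))
                log.records.append(rec)
        if s_idx % config.days_per_week == 0 and observer.learning_db_per_week:
            for loc in week_locations:
                smap[loc] = smap[loc] + observer.learning_db_per_week
            week_locations.clear()
    return log


def performance_summary(
    log: SessionLog, days_per_week: int = 5
) -> pd.DataFrame:
    """Per-task, per-week accuracy table (columns: task, week, n_trials, accuracy)."""
    if not log.records:
        raise ValueError("empty session log")
    df = log.to_frame()
    df["week"] = (df["session_idx"] - 1) // days_per_week + 1
    out = (
        df.groupby(["task", "week"], as_index=False)
        .agg(n_trials=("correct", "size"), accuracy=("correct", "mean"))
    )
    return out


def performance_vs_outcome(
    summaries: dict[str, pd.DataFrame],
    outcomes: Sequence[OutcomeRecord],
    task: str = "orientation",
) -> TestResult | None:
    """Spearman correlation between per-patient accuracy change on a task
    (last week minus first week) and improved hemifield area.

    Returns None (with a warning) when fewer than 3 patients have both
    measures or either variable has zero variance.
    """
    from scipy import stats as sps

    area_by_pid = {o.patient_id: o.improved_area_hemi_deg2 for o in outcomes}
    gains, areas = [], []
    for pid, summary in summaries.items():
        if pid not in area_by_pid:
            continue
        rows = summary[summary["task"] == task]
        if rows.empty:
            logger.warning("patient %s has no %s trials; omitted", pid, task)
            continue
        first = rows.loc[rows["week"].idxmin(), "accuracy"]
        last = rows.loc[rows["week"].idxmax(), "accuracy"]
        gains.append(float(last - first))
        areas.append(float(area_by_pid[pid]))
    if len(gains) < 3:
        logger.warning("performance_vs_outcome: fewer than 3 usable patients")
        return None
    if np.ptp(gains) == 0 or np.ptp(areas) == 0:
        logger.warning(
            "performance_vs_outcome: zero variance in %s; correlation undefined",
            "accuracy changes" if np.ptp(gains) == 0 else "improved areas",
        )
        return None
    rho, p = sps.spearmanr(gains, areas)
    return TestResult("spearman", float(rho), float(p), n=len(gains))


LOG_COLUMNS = [
    "patient_id", "session_idx", "block_idx", "trial_idx", "task",
    "hemifield", "quadrant", "x_deg", "y_deg", "match", "response",
    "correct", "rt_ms",
]


def write_session_log(
    log: SessionLog, patient_id: str, path: str | Path
) -> None:
    df = log.to_frame()
    df.insert(0, "patient_id", patient_id)
    df[LOG_COLUMNS].to_csv(path, index=False)
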