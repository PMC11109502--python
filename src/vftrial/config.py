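"""Combined YAML configuration for the pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .cohort import CohortConfig
from .training import TrainingConfig


class AnalysisConfig(BaseModel):
    """Scoring thresholds (see the scoring module for their meaning)."""

    delta_db: float = Field(default=6.0, gt=0.0)
    alpha_pct: float = Field(default=5.0, gt=0.0)
    normal_cap_db: float | None = 30.0


class PipelineConfig(BaseModel):
    cohort: CohortConfig
    training: TrainingConfig = Field(default_factory=TrainingConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def save_pipeline_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)


def config_hash(config: BaseModel) -> str:
    """Short stable hash of a config, for run provenance in logs."""
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
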