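"""Run configuration: one validated object covering every stage threshold.

Defaults equal the published operating point of the pipeline: 0.5-15 Hz
3rd-order Butterworth band-pass, 20-s windows with 50% overlap, SQI gate at
0.75, reference-variability gate at 0.10, 80/20 subject-stratified split,
20% relative change threshold and 3-min timespan bin for trending.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator


class PreprocessConfig(BaseModel):
    lp_cut: float = Field(15.0, gt=0)
    hp_cut: float = Field(0.5, gt=0)
    order: int = Field(3, ge=1)
    win: float = Field(20.0, gt=0)
    overlap: float = Field(0.5, ge=0, lt=1)
    sqi_min: float = Field(0.75, ge=0, le=1)
    var_max: float = Field(0.10, ge=0)
    pulse_length: int = Field(256, ge=16)
    align: bool = False
    max_lag: float = Field(5.0, gt=0)

    @model_validator(mode="after")
    def _cuts(self):
        if self.hp_cut >= self.lp_cut:
            raise ValueError("high-pass cut-off must lie below low-pass cut-off")
        return self


class PwaConfig(BaseModel):
    aix_hr_slope: float = 0.48
    inflection_point: str = "apg.d"


class SynthConfigModel(BaseModel):
    n_subjects: int = Field(40, ge=1)
    fs: float = Field(125.0, gt=30)
    duration_min: float = Field(540.0, gt=60)
    duration_max: float = Field(1140.0, gt=60)
    noise_sd: float = Field(0.02, ge=0)
    corrupt_frac: float = Field(0.02, ge=0, le=1)


class ModelsConfig(BaseModel):
    kinds: list[str] = ["lasso", "svr", "flat"]
    cv_folds: int = Field(10, ge=2)
    svr_budget: int = Field(30, ge=3)
    max_tune_samples: int = Field(800, ge=100)
    max_train_samples: int = Field(3000, ge=100)


class EvaluateConfig(BaseModel):
    rel_threshold: float = Field(0.20, gt=0, lt=1)
    bin_edge: float = Field(180.0, gt=0)
    angular_limit: float = Field(30.0, gt=0)


class RunConfig(BaseModel):
    """Top-level configuration; a single seed fans out to all stages."""

    seed: int = 0
    train_fraction: float = Field(0.8, gt=0, lt=1)
    n_permutations: int = Field(100, ge=0)
    preprocess: PreprocessConfig = PreprocessConfig()
    pwa: PwaConfig = PwaConfig()
    synth: SynthConfigModel = SynthConfigModel()
    models: ModelsConfig = ModelsConfig()
    evaluate: EvaluateConfig = EvaluateConfig()

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the run seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
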