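"""Structured experiment configuration: YAML in, validated sections out.

A single file configures every stage (cohort simulation, movement model,
dataset/windowing, training, CAM) plus a global seed from which per-stage
seeds are derived by stable hashing, so stages can be rerun independently
and an identical file reproduces every number.
"""

from __future__ import annotations

import hashlib
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .cohort import ACTIVITY_CLASSES, SLEEP_CLASSES, CohortConfig, MovementModelParams
from .models import ModelConfig
from .prep import DatasetSpec
from .training import TrainConfig


class CohortSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    cell_counts: dict[str, dict[str, int]] = Field(
        default_factory=lambda: {
            "sitting": {"sleep_9h": 22, "sleep_5h": 22},
            "breaking_up_sitting": {"sleep_9h": 20, "sleep_5h": 20},
        }
    )
    effect_size_activity: float = Field(default=1.0, ge=0)
    effect_size_sleep: float = Field(default=1.0, ge=0)
    sample_rate: float = Field(default=20.0, gt=0)
    drive_duration: float = Field(default=1200.0, gt=0)
    days: int = Field(default=5, ge=1)
    drives_per_day: int = Field(default=2, ge=1, le=2)

    @model_validator(mode="after")
    def _check_cells(self):
        for act, inner in self.cell_counts.items():
            if act not in ACTIVITY_CLASSES:
                raise ValueError(f"cohort.cell_counts: unknown activity class {act!r}")
            for slp, count in inner.items():
                if slp not in SLEEP_CLASSES:
                    raise ValueError(f"cohort.cell_counts.{act}: unknown sleep class {slp!r}")
                if count < 0:
                    raise ValueError(f"cohort.cell_counts.{act}.{slp}: count must be non-negative")
        return self

    def to_cohort_config(self, seed: int) -> CohortConfig:
        counts = {
            (act, slp): self.cell_counts.get(act, {}).get(slp, 0)
            for act in ACTIVITY_CLASSES
            for slp in SLEEP_CLASSES
        }
        return CohortConfig(
            cell_counts=counts,
            seed=seed,
            effect_size_activity=self.effect_size_activity,
            effect_size_sleep=self.effect_size_sleep,
            sample_rate=self.sample_rate,
            drive_duration=self.drive_duration,
            days=self.days,
            drives_per_day=self.drives_per_day,
        )


class MovementSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    pedal_event_rate: float = Field(default=8.0, ge=0)
    pedal_event_amplitude: float = Field(default=0.6, ge=0, le=3.0)
    pedal_event_amplitude_sd: float = Field(default=0.2, ge=0)
    pedal_event_duration: float = Field(default=0.8, ge=0)
    postural_shift_rate: float = Field(default=0.5, ge=0)
    postural_shift_angle_change: float = Field(default=8.0, ge=0)
    inactivity_bout_probability: float = Field(default=0.3, ge=0, le=1)
    noise_sd: float = Field(default=0.02, ge=0)

    def to_params(self) -> MovementModelParams:
        return MovementModelParams(**self.model_dump())


class DatasetSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    window_length: int = Field(default=4096, ge=1)
    eval_stride: int = Field(default=1024, ge=1)
    split_mode: Literal["window_level", "participant_level"] = "window_level"
    k: int = Field(default=5, ge=2)

    def to_spec(self, task: str, seed: int) -> DatasetSpec:
        return DatasetSpec(task=task, seed=seed, **self.model_dump())


class TrainingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    batch_size: int = Field(default=64, ge=1)
    initial_lr: float = Field(default=1e-4, gt=0)
    lr_factor: float = Field(default=10.0, gt=1)
    patience: int = Field(default=10, ge=1)
    improvement_tol: float = Field(default=1e-4, ge=0)
    max_epochs: int = Field(default=100, ge=1)
    windows_per_epoch: int | None = Field(default=None, ge=1)
    min_lr: float = Field(default=1e-7, gt=0)
    threshold: float = Field(default=0.5, gt=0, lt=1)

    def to_config(self, seed: int) -> TrainConfig:
        return TrainConfig(seed=seed, **self.model_dump())


class CamSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_exemplars: int = Field(default=5, ge=1)
    upsample: Literal["linear", "nearest"] = "linear"


class ExperimentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "results"
    tasks: list[Literal["sitting_history", "sleep_history"]] = Field(
        default_factory=lambda: ["sitting_history", "sleep_history"]
    )
    architectures: list[Literal["dixonnet", "resnet18_1d", "resnet10_1d"]] = Field(
        default_factory=lambda: ["dixonnet", "resnet18_1d"]
    )
    dixonnet_width: int = Field(default=100, ge=1)
    dropout_p: float = Field(default=0.5, ge=0, lt=1)
    cohort: CohortSection = Field(default_factory=CohortSection)
    movement: MovementSection = Field(default_factory=MovementSection)
    dataset: DatasetSection = Field(default_factory=DatasetSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    cam: CamSection = Field(default_factory=CamSection)

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    def model_config_for(self, architecture: str, seed: int) -> ModelConfig:
        return ModelConfig(
            architecture=architecture,
            window_length=self.dataset.window_length,
            dropout_p=self.dropout_p,
            width=self.dixonnet_width,
            seed=seed,
        )

    def content_hash(self) -> str:
        """Hash of the scientific settings (the output directory is excluded)."""
        canonical = yaml.safe_dump(self.model_dump(exclude={"out_dir"}), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def derive_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage seed (< 2**31) from the global seed."""
    digest = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def validate_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment file.

    Raises ``ValueError`` listing every violation with its field path;
    unknown keys are rejected.
    """
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValueError(f"unparseable configuration file: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    try:
        return ExperimentConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            ".".join(str(part) for part in err["loc"]) + ": " + err["msg"] for err in exc.errors()
        ]
        raise ValueError("invalid configuration:\n  " + "\n  ".join(lines)) from exc
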