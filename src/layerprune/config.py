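"""Run configuration: a versioned YAML schema for end-to-end experiments.

Unknown keys are errors, not warnings — a silently ignored typo in a
threshold name would change the rule semantics. Validation aggregates
every problem into one :class:`~layerprune.errors.ConfigError` whose
message names the offending keys.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

from .errors import ConfigError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MotifSpec(_Strict):
    causal_motif: str = "TATAAT"
    placement_window: int = Field(2, ge=0)
    background_gc: float = Field(0.5, ge=0.0, le=1.0)
    decoy_motifs: list[str] = []
    label_noise: float = Field(0.0, ge=0.0, le=1.0)


class SyntheticSpec(_Strict):
    n_train: int = Field(2000, ge=2)
    n_val: int = Field(200, ge=2)
    n_test: int = Field(400, ge=2)
    L: int = Field(64, ge=8)
    seed: int = 0
    motif: MotifSpec = MotifSpec()


class BenchmarkSpec(_Strict):
    accession: str = "InstaDeepAI/genomics-long-range-benchmark"
    task: str = "variant_effect_causal_eqtl"
    cache_dir: Optional[str] = None
    subsample: Optional[int] = Field(None, ge=2)


class DatasetSource(_Strict):
    synthetic: Optional[SyntheticSpec] = None
    path: Optional[str] = None
    benchmark: Optional[BenchmarkSpec] = None

    @model_validator(mode="after")
    def _exactly_one(self):
        set_count = sum(x is not None for x in (self.synthetic, self.path, self.benchmark))
        if set_count != 1:
            raise ValueError(
                "dataset: exactly one of synthetic / path / benchmark must be set"
            )
        return self


class TinyModelSpec(_Strict):
    n_layers: int = Field(4, ge=1)
    d_model: int = Field(32, ge=4)
    n_heads: int = Field(4, ge=1)
    d_ff: int = Field(64, ge=4)
    max_len: int = Field(128, ge=2)
    pooling: Literal["first-token", "mean"] = "first-token"
    head_dims: list[int] = [2]
    seed: int = 0


class ModelSource(_Strict):
    tiny: Optional[TinyModelSpec] = None
    checkpoint: Optional[str] = None

    @model_validator(mode="after")
    def _exactly_one(self):
        if (self.tiny is None) == (self.checkpoint is None):
            raise ValueError("model: exactly one of tiny / checkpoint must be set")
        return self


class TrainSpec(_Strict):
    mode: Literal["to_convergence", "fixed_epochs"] = "to_convergence"
    max_epochs: int = Field(50, ge=1)
    patience: int = Field(5, ge=1)
    fixed_epochs: int = Field(5, ge=1)
    learning_rate: float = Field(1e-3, gt=0)
    batch_size: int = Field(32, ge=1)
    threshold: float = Field(0.5, gt=0, lt=1)
    convergence_tol: float = Field(1e-4, ge=0)
    reinit_head: bool = True


class ClassifySpec(_Strict):
    metrics_used: list[str] = ["accuracy", "auroc", "f1", "pct_tp"]
    min_criteria: int = Field(3, ge=1)
    cornerstone_drop: float = Field(0.05, gt=0)
    drop_mode: Literal["relative", "absolute_points"] = "relative"
    tolerance_source: Literal["layer_sd", "baseline_sd", "pooled_sd"] = "layer_sd"

    @model_validator(mode="after")
    def _criteria_bound(self):
        if self.min_criteria > len(self.metrics_used):
            raise ValueError(
                f"min_criteria={self.min_criteria} exceeds the "
                f"{len(self.metrics_used)} metrics in metrics_used"
            )
        return self


class RunConfig(_Strict):
    """Validated end-to-end experiment configuration."""

    schema_version: int = 1
    output_dir: str
    seeds: list[int] = Field([0, 1, 2], min_length=1)
    dataset: DatasetSource
    model: ModelSource
    pretrain: TrainSpec = TrainSpec()
    finetune: TrainSpec = TrainSpec(mode="fixed_epochs", fixed_epochs=5)
    classification: ClassifySpec = ClassifySpec()
    deterministic: bool = True

    @field_validator("seeds")
    @classmethod
    def _seeds_ok(cls, v):
        if len(set(v)) != len(v):
            raise ValueError("seeds must be distinct")
        if any(s < 0 for s in v):
            raise ValueError("seeds must be non-negative")
        return v

    @field_validator("schema_version")
    @classmethod
    def _version_ok(cls, v):
        if v != 1:
            raise ValueError(f"unsupported schema_version {v}")
        return v


def _format_errors(exc: ValidationError) -> str:
    msgs = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        msgs.append(f"{loc}: {err['msg']}")
    return "; ".join(msgs)


def parse_config(data: dict) -> RunConfig:
    """Validate a config mapping; aggregate all errors into ConfigError."""
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(f"invalid configuration: {_format_errors(exc)}") from exc


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return parse_config(data)
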