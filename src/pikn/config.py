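"""Run configuration: a strict YAML schema for end-to-end CLI runs.

Unknown keys are rejected (typos should fail loudly), and a fully resolved
copy of the configuration is written next to every run's outputs so results
stay reproducible from the output directory alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["RunConfig", "ModelConfig", "TrainBlock", "load_run_config"]


class TrainBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    epochs: int = Field(default=200, ge=0)
    batch_size: int = Field(default=32, ge=1)
    learning_rate: float = Field(default=1e-3, gt=0)
    beta: float = Field(default=0.999, ge=0, lt=1)
    weight_decay: float = Field(default=1e-3, ge=0)
    seed: int = 0
    anchor_init_seed: int = 0
    standardize: bool = True


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", protected_namespaces=())

    type: str = "pooling"                 # pooling | attention | multiomics
    q: int = Field(default=30, ge=1)      # anchor points per pathway
    attention_dim: int = Field(default=128, ge=1)
    fusion_dim: int = Field(default=16, ge=1)
    fusion_attention_dim: int = Field(default=4, ge=1)
    gated: bool = True
    epsilon: float = Field(default=0.1, ge=0)  # Gram ridge, fraction of mean eigenvalue

    @field_validator("type")
    @classmethod
    def _known_type(cls, v: str) -> str:
        if v not in ("pooling", "attention", "multiomics"):
            raise ValueError(f"model type must be pooling, attention or multiomics, got {v!r}")
        return v


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", protected_namespaces=())

    # data: one path for single-omics, a {modality: path} map for multi-omics
    data: Union[str, dict[str, str]]
    labels: Optional[str] = None
    pathways: Optional[str] = None        # GMT file
    edge_dir: Optional[str] = None        # per-pathway edge lists (optional)
    laplacian_dir: Optional[str] = None   # precomputed Laplacian TSVs (alternative)
    missing_policy: str = "zero-fill"
    model: ModelConfig = Field(default_factory=ModelConfig)
    train: TrainBlock = Field(default_factory=TrainBlock)
    output_dir: str = "pikn_run"

    @field_validator("missing_policy")
    @classmethod
    def _known_policy(cls, v: str) -> str:
        if v not in ("zero-fill", "drop-node"):
            raise ValueError(f"missing_policy must be zero-fill or drop-node, got {v!r}")
        return v

    def write_resolved(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "resolved_config.json"
        with open(path, "w") as fh:
            json.dump(self.model_dump(), fh, indent=1)
        return path


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)
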