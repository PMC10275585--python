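"""Pipeline configuration: schema-validated before any stage runs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .simulate import SimConfig


class PipelineConfig(BaseModel):
    """End-to-end pipeline settings.

    Either ``input_dir`` (an on-disk dataset) or ``sim`` (a simulation
    config) supplies the input; when both are absent the study-condition
    default simulation is used with the pipeline seed.
    """

    seed: int = 0
    input_dir: Optional[str] = None
    sim: Optional[SimConfig] = None
    output_dir: str = "clonostate_out"

    # normalization / scoring
    target_sum: float = Field(default=1e4, gt=0)
    signature_file: Optional[str] = None
    n_bins: int = Field(default=25, ge=1)
    n_ctrl: int = Field(default=50, ge=1)

    # repertoire statistics
    size_threshold: int = Field(default=10, ge=1)
    expansion_threshold: int = Field(default=500, ge=0)
    top_n: int = Field(default=30, ge=0)

    # clone bias
    bias_pseudocount: float = Field(default=0.5, gt=0)
    min_clone_size: int = Field(default=3, ge=1)

    # markers / modules
    n_modules: int = Field(default=12, ge=1)
    marker_min_fc: float = 0.25
    marker_alpha: float = 0.05
    marker_min_frac: float = 0.1
    gzm_pseudocount: float = Field(default=1.0, gt=0)

    label_column: str = "cluster"

    @model_validator(mode="after")
    def _check_paths(self) -> "PipelineConfig":
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise ValueError(f"input_dir {self.input_dir!r} does not exist")
        if self.signature_file is not None and not Path(self.signature_file).is_file():
            raise ValueError(f"signature_file {self.signature_file!r} does not exist")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        """Deterministic short hash of the full configuration."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
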