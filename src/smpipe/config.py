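"""Run configuration for the specific-moment pipeline.

The defaults encode the analysis conditions: a window grid of 60–210 s with
50% overlap for the heart-rate branch, 1 fps facial-expression frames, a
two-component GMM, and a fused decision that gives heart rate precedence
over facial expression (w_hr >= w_efe).
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Tuple

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class PipelineConfig(BaseModel):
    """Validated pipeline parameters; unknown fields are rejected."""

    window_lengths_s: List[int] = Field(default=[60, 90, 120, 150, 180, 210])
    overlap_fraction: float = 0.5
    efe_fps: float = 1.0
    gmm_seed: int = 0
    gmm_components: int = 2
    fusion_weights: Tuple[float, float] = (0.7, 0.3)  # (w_hr, w_efe)
    fusion_threshold: float = 0.3
    iou_resolution_s: int = 1
    efe_merge_gap_s: float = 2.0
    efe_min_duration_s: float = 3.0
    obs_match_min_overlap_s: float = 1.0
    hr_nominal_rate_hz: float = 1.0
    standardize_hr_features: bool = True
    standardize_efe_features: bool = False
    per_session_clustering: bool = False

    model_config = {"extra": "forbid"}

    @field_validator("window_lengths_s")
    @classmethod
    def _windows_positive(cls, v: List[int]) -> List[int]:
        if not v or any(t < 2 for t in v):
            raise ValueError("window_lengths_s must be positive and span >= 2 samples at 1 Hz")
        return sorted(set(int(t) for t in v))

    @field_validator("overlap_fraction")
    @classmethod
    def _overlap_open_interval(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError("overlap_fraction must lie strictly between 0 and 1")
        return v

    @field_validator("efe_fps", "iou_resolution_s", "hr_nominal_rate_hz")
    @classmethod
    def _strictly_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be strictly positive")
        return v

    @field_validator("efe_merge_gap_s", "efe_min_duration_s", "fusion_threshold")
    @classmethod
    def _nonnegative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("must be nonnegative")
        return v

    @field_validator("obs_match_min_overlap_s")
    @classmethod
    def _min_overlap_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("obs_match_min_overlap_s must be positive")
        return v

    @field_validator("gmm_components")
    @classmethod
    def _two_components(cls, v: int) -> int:
        if v != 2:
            raise ValueError("gmm_components is fixed at 2 (normal vs specific)")
        return v

    @model_validator(mode="after")
    def _hr_precedence(self) -> "PipelineConfig":
        w_hr, w_efe = self.fusion_weights
        if w_hr < 0 or w_efe < 0:
            raise ValueError("fusion_weights must be nonnegative")
        if w_hr < w_efe:
            raise ValueError("fusion_weights: w_hr must be >= w_efe (heart-rate precedence)")
        return self


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML mapping into a :class:`PipelineConfig`, filling defaults.

    An empty file yields the documented defaults.  Validation failures raise
    with the offending field named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a YAML mapping")
    return PipelineConfig(**raw)
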