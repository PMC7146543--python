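"""Run configuration: a validated schema with every numeric default of the
pipeline in one place (stage code carries no hard-coded defaults)."""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigurationError


class FilterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fc_hz: float = Field(10.0, gt=0)
    order: int = Field(2, ge=1)
    method: Literal["fft", "filtfilt"] = "fft"


class SegmentationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    threshold_frac: float = Field(0.05, gt=0, lt=1)
    smooth_fc_hz: float = Field(3.0, gt=0)
    min_run: int = Field(3, ge=1)
    use_markers: bool = False  # take event markers from trial metadata verbatim


class SvmConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    C: float = Field(1.0, gt=0)
    kernels: tuple[str, ...] = ("linear", "quadratic", "cubic", "gaussian")
    group_by_subject: bool = False  # leave-one-subject-out instead of per-sample


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_subjects: int = Field(26, ge=1)
    tasks: tuple[str, ...] = ("LL", "RL")
    loads_kg: tuple[float, ...] = (1.0, 2.0, 5.0)
    repetitions: int = Field(3, ge=1)
    orientation_noise_deg: float = Field(0.3, ge=0)
    misalignment_deg: float = Field(3.0, ge=0)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    fs_hz: float = Field(40.0, gt=0)
    filter: FilterConfig = FilterConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    normalization: Literal["fold", "global"] = "fold"
    svm: SvmConfig = SvmConfig()
    simulate: Optional[SimulateConfig] = SimulateConfig()

    def validate_rates(self) -> None:
        if self.fs_hz <= 2.0 * self.filter.fc_hz:
            raise ConfigurationError(
                f"filter cutoff {self.filter.fc_hz} Hz requires fs > {2 * self.filter.fc_hz} Hz"
            )

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def load_config(data: dict | None = None) -> RunConfig:
    """Build and validate a RunConfig from a plain dict (unknown keys rejected)."""
    try:
        cfg = RunConfig(**(data or {}))
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc
    cfg.validate_rates()
    return cfg
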