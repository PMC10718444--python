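"""JSON run configuration: validated blocks with documented defaults.

The defaults reproduce the reference study conditions: a 50-oscillator
population at 8 Hz (coupling 0.8, stimulation intensity 30), the 58 s
optimization-step protocol (8 s stimulation window, 25 s baseline window),
12 burn-in samples, and a 360-point candidate phase grid.  Unknown keys are
rejected with an error naming the key.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .drift import DRIFT_KINDS
from .gp import KERNEL_KINDS

__all__ = ["RunConfig", "parse_config", "config_error_message"]

MODES = ("tv", "static", "scheduler")
OBJECTIVES = ("kuramoto", "toy")


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ModelBlock(_Block):
    n_oscillators: int = 50
    f0: float = 8.0
    sigma_rel: float = 0.0075
    gamma: float = 0.8
    intensity: float = 30.0
    dt: float = 1e-3
    freq_clip: float | None = 0.15
    sigma_mode: str = "relative"

    @field_validator("n_oscillators")
    @classmethod
    def _n(cls, v):
        if v < 1:
            raise ValueError("n_oscillators must be >= 1")
        return v

    @field_validator("f0", "dt")
    @classmethod
    def _pos(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0")
        return v

    @field_validator("sigma_rel", "gamma", "intensity")
    @classmethod
    def _nonneg(cls, v, info):
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0")
        return v


class ProtocolBlock(_Block):
    step_duration_s: float = 58.0
    stim_window_s: float = 8.0
    baseline_window_s: float = 25.0
    pulse_width_s: float = 1e-3
    refractory: float = 0.5

    @model_validator(mode="after")
    def _windows(self):
        if self.stim_window_s + self.baseline_window_s > self.step_duration_s:
            raise ValueError("stim_window_s + baseline_window_s must be <= step_duration_s")
        if self.pulse_width_s <= 0:
            raise ValueError("pulse_width_s must be > 0")
        return self


class GPBlock(_Block):
    l_x: float = 1.0
    T_x: float = 2.0 * np.pi
    epsilon: float = 0.1
    T_t: float = 100.0
    l_tp: float = 1.0
    sigma_n2: float = 1e-2
    kernel_kind: str | None = None  # None -> resolved from mode/scenario
    window: int | None = 500
    normalize_y: bool = True

    @field_validator("epsilon")
    @classmethod
    def _eps(cls, v):
        if not 0.0 <= v < 1.0:
            raise ValueError("epsilon must be in [0, 1)")
        return v

    @field_validator("l_x", "T_x", "T_t", "l_tp")
    @classmethod
    def _pos(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0")
        return v

    @field_validator("sigma_n2")
    @classmethod
    def _noise(cls, v):
        if v < 0:
            raise ValueError("sigma_n2 must be >= 0")
        return v

    @field_validator("kernel_kind")
    @classmethod
    def _kind(cls, v):
        if v is not None and v not in KERNEL_KINDS:
            raise ValueError(f"kernel_kind must be one of {KERNEL_KINDS}")
        return v


class AcquisitionBlock(_Block):
    kappa: float = 1.0
    grid_size: int = 360
    tie_break: str = "smallest_phase"

    @field_validator("kappa")
    @classmethod
    def _kappa(cls, v):
        if v < 0:
            raise ValueError("kappa must be >= 0")
        return v

    @field_validator("grid_size")
    @classmethod
    def _grid(cls, v):
        if v < 2:
            raise ValueError("grid_size must be >= 2")
        return v


class ScenarioBlock(_Block):
    scenario: str = "none"
    period_steps: int = 100
    amplitude: float = float(np.pi)
    noise_std: float = 0.0

    @field_validator("scenario")
    @classmethod
    def _scenario(cls, v):
        if v not in DRIFT_KINDS:
            raise ValueError(f"scenario must be one of {DRIFT_KINDS}")
        return v

    @field_validator("period_steps")
    @classmethod
    def _period(cls, v):
        if v < 1:
            raise ValueError("period_steps must be >= 1")
        return v


class RunConfig(_Block):
    schema_version: int = 1
    model: ModelBlock = ModelBlock()
    protocol: ProtocolBlock = ProtocolBlock()
    gp: GPBlock = GPBlock()
    acquisition: AcquisitionBlock = AcquisitionBlock()
    scenario: ScenarioBlock = ScenarioBlock()
    mode: str = "tv"
    objective: str = "kuramoto"
    n_steps: int = 3000
    n_init: int = 12
    burn_in_s: float = 200.0
    toy_amplitude: float = 1.0
    toy_noise_std: float = 0.0
    seed: int = 0
    out: str | None = None

    @field_validator("mode")
    @classmethod
    def _mode(cls, v):
        if v not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        return v

    @field_validator("objective")
    @classmethod
    def _objective(cls, v):
        if v not in OBJECTIVES:
            raise ValueError(f"objective must be one of {OBJECTIVES}")
        return v

    @field_validator("n_steps", "n_init")
    @classmethod
    def _steps(cls, v, info):
        if v < 1:
            raise ValueError(f"{info.field_name} must be >= 1")
        return v

    def to_json(self, **kwargs) -> str:
        return self.model_dump_json(indent=2, **kwargs)

    def hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()
        ).hexdigest()[:12]


def parse_config(source: str | Path | dict | None = None) -> RunConfig:
    """Parse a JSON config from a path, inline JSON text, dict, or nothing.

    An empty/absent document yields all defaults.  Malformed JSON,
    out-of-range values, and unknown keys raise ``ValueError`` with a
    descriptive message.
    """
    if source is None:
        return RunConfig()
    if isinstance(source, dict):
        data = source
    else:
        def _is_path(s):
            if isinstance(s, Path):
                return True
            try:
                return "\n" not in s and Path(s).is_file()
            except OSError:
                return False

        text = Path(source).read_text() if _is_path(source) else str(source)
        text = text.strip() or "{}"
        try:
            data = json.loads(text)
        except json.JSONDecodeError as err:
            raise ValueError(f"malformed JSON configuration: {err}") from err
    try:
        return RunConfig.model_validate(data)
    except Exception as err:  # pydantic.ValidationError
        raise ValueError(f"invalid configuration: {err}") from err


def config_error_message(err: Exception) -> str:
    return str(err)
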