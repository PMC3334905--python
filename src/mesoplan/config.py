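"""Run configuration: a validated, file-loadable description of a campaign.

A :class:`RunConfig` captures everything the pipeline needs — protein,
plate format, screens (an explicit list or a grid recipe), dilution
scheme, calibration constants, optional phase-map override, an optional
measured assay CSV — and is validated before any computation.  The JSON
schema is available from :func:`config_schema` for external tooling.
Files may be JSON or YAML (a JSON superset here, so either dialect loads).
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .hydration import CalibrationParams
from .phasemap import DEFAULT_PHASE_MAP, PhaseMap
from .screens import Additive, ProteinSample, ScreenSolution

__all__ = ["GridScreenSpec", "ScreensSpec", "RunConfig", "load_config", "config_schema"]


class GridScreenSpec(BaseModel):
    """Recipe for a pH × precipitant-concentration grid screen."""

    model_config = ConfigDict(frozen=True)

    ph_min: float
    ph_max: float
    conc_min: float
    conc_max: float
    n_ph: int = Field(ge=2)
    n_conc: int = Field(ge=2)
    precipitant: str = "Na/K phosphate"


class ScreensSpec(BaseModel):
    """Either an explicit screen list or a grid recipe (exactly one)."""

    model_config = ConfigDict(frozen=True)

    grid: GridScreenSpec | None = None
    solutions: tuple[ScreenSolution, ...] | None = None
    additive: Additive | None = None
    additive_fraction: float = 0.10

    def is_valid(self) -> bool:
        return (self.grid is None) != (self.solutions is None)


class RunConfig(BaseModel):
    """Validated top-level configuration for :func:`mesoplan.pipeline.run_pipeline`."""

    model_config = ConfigDict(frozen=True)

    protein: ProteinSample
    plate_format: str = "MO132"
    screens: ScreensSpec
    dilutions: tuple[float, ...] = (1.0, 2.0, 4.0, 7.0)
    calibration: CalibrationParams = CalibrationParams()
    phase_map: PhaseMap = DEFAULT_PHASE_MAP
    assay_csv: str | None = None  # measured depletion assay to estimate K from
    bootstrap_resamples: int = 2000
    seed: int = 0
    out_dir: str | None = None
    include_timestamp: bool = False
    verbosity: int = Field(default=1, ge=0, le=2)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or YAML config file."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    return RunConfig.model_validate(data)


def config_schema() -> dict:
    """The published JSON schema for config files."""
    return RunConfig.model_json_schema()


def schema_json() -> str:
    return json.dumps(config_schema(), indent=2, sort_keys=True)
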