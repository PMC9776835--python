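"""Run configuration: a validated YAML schema tying the stages together.

Unknown keys are rejected so typos fail loudly; every effective value is
printed into the run log by the CLI.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .model import ElectrodeModel, FrequencyGrid

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ElectrodeSettings(_Strict):
    cpe_magnitude: float = 5.0e4
    cpe_exponent: float = Field(0.95, gt=0, le=1)
    series_resistance: float = Field(300.0, ge=0)
    electrode_area: float = Field(3.9e-3, gt=0)

    def build(self) -> ElectrodeModel:
        return ElectrodeModel(cpe_magnitude=self.cpe_magnitude,
                              cpe_exponent=self.cpe_exponent,
                              series_resistance=self.series_resistance,
                              electrode_area=self.electrode_area)


class SimSettings(_Strict):
    dt_h: float = Field(0.25, gt=0)
    horizon_h: float = Field(30.0, gt=0)
    frequencies_hz: list[float] | None = None  # None -> default 9-point grid
    noise_sd: float = Field(0.01, ge=0)
    n_wells: int = Field(6, ge=2)

    def grid(self) -> FrequencyGrid:
        if self.frequencies_hz is None:
            return FrequencyGrid.default()
        return FrequencyGrid(tuple(self.frequencies_hz))


class FitSettings(_Strict):
    eps_rb: float = Field(0.05, ge=0)
    xtol: float = 1e-12
    ftol: float = 1e-14


class AnalysisSettings(_Strict):
    windows_h: list[tuple[float, float]] = [(0.0, 2.5), (0.0, 3.6), (0.0, 30.0)]
    frequency_resistance_hz: float = 4000.0
    frequency_capacitance_hz: float = 64000.0
    confluence_threshold_nf: float = 20.0
    plateau_span_h: float = 5.0


class StatsSettings(_Strict):
    posthoc: str = Field("tukey", pattern="^(tukey|bonferroni)$")
    vehicle_label: str = "vehicle"


class RunConfig(_Strict):
    """Complete configuration of a synthetic-study run."""

    seed: int = 0
    sim: SimSettings = SimSettings()
    electrode: ElectrodeSettings = ElectrodeSettings()
    fit: FitSettings = FitSettings()
    analysis: AnalysisSettings = AnalysisSettings()
    stats: StatsSettings = StatsSettings()


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config (or the documented defaults when path is None)."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
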