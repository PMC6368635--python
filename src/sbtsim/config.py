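"""Configuration blocks for one bench condition, with strict validation.

A run is defined by four physical blocks (lung / apparatus / ventilator /
effort) plus a numerics block.  Configurations are read and written as YAML
with unknown keys rejected, so a config file is always a complete, auditable
record of a condition.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .gas import CONDUITS, ConduitGeometry

#: Default effective Rohrer coefficients (k1 cmH2O/(L/s), k2 cmH2O/(L/s)^2)
#: per tube, covering the clinically curved tube plus the 9-mm adapter duct
#: and connectors.  Calibrated against the bench's printed T-piece mean-flow
#: band (3.1-3.3 L/min at 36/min) and its qualitative sweep behaviour; see
#: docs/methods.md.
DEFAULT_ROHRER: dict[str, tuple[float, float]] = {
    "ETT-3.0": (20.0, 850.0),
    "ETT-3.5": (15.0, 850.0),
}


class LungModel(BaseModel):
    """Single-compartment respiratory system: C, R, and patient weight."""

    model_config = ConfigDict(extra="forbid")

    compliance: float = Field(1.5, gt=0, description="total compliance, mL/cmH2O")
    resistance: float = Field(40.0, ge=0, description="airway resistance, cmH2O/(L/s)")
    weight: float = Field(3.0, gt=0, description="patient weight, kg")

    @classmethod
    def for_weight(cls, weight: float, compliance_per_kg: float = 0.5,
                   resistance: float = 40.0) -> "LungModel":
        """Scale compliance by weight (default 0.5 mL/cmH2O/kg)."""
        return cls(compliance=compliance_per_kg * weight, resistance=resistance,
                   weight=weight)


class AirwayApparatus(BaseModel):
    """What sits between the airway opening and the atmosphere/ventilator.

    ``intubated`` and ``t_piece`` modes breathe through an endotracheal tube
    whose pressure-flow relation is the Rohrer form
    dP = k1*q + k2*q*|q|; ``bare`` mode is the lung chamber open to
    atmosphere through its wide inlet port (no apparatus drop).
    """

    model_config = ConfigDict(extra="forbid")

    mode: Literal["intubated", "t_piece", "bare"] = "intubated"
    tube_label: Optional[Literal["ETT-3.0", "ETT-3.5"]] = "ETT-3.5"
    rohrer_k1: Optional[float] = Field(None, ge=0)
    rohrer_k2: Optional[float] = Field(None, ge=0)

    @model_validator(mode="after")
    def _fill_defaults(self) -> "AirwayApparatus":
        if self.mode == "bare":
            if self.tube_label is not None and (
                self.rohrer_k1 not in (None, 0.0) or self.rohrer_k2 not in (None, 0.0)
            ):
                raise ValueError("bare mode has no tube; do not set Rohrer coefficients")
            object.__setattr__(self, "tube_label", None)
            object.__setattr__(self, "rohrer_k1", 0.0)
            object.__setattr__(self, "rohrer_k2", 0.0)
            return self
        if self.tube_label is None:
            raise ValueError(f"{self.mode} mode requires a tube_label")
        k1_def, k2_def = DEFAULT_ROHRER[self.tube_label]
        if self.rohrer_k1 is None:
            object.__setattr__(self, "rohrer_k1", k1_def)
        if self.rohrer_k2 is None:
            object.__setattr__(self, "rohrer_k2", k2_def)
        return self

    @property
    def tube(self) -> Optional[ConduitGeometry]:
        return CONDUITS[self.tube_label] if self.tube_label else None

    @property
    def conduit(self) -> ConduitGeometry:
        """Conduit used for Reynolds numbers: tube if present, else the
        22-mm inlet port of the lung simulator."""
        return self.tube if self.tube else CONDUITS["adapter-port-22mm"]


class VentilatorSettings(BaseModel):
    """Pressure-support ventilator model settings.

    ``mode="none"`` (T-piece / bare breathing) fixes the source pressure at
    atmospheric and disables triggering.  In PSV the source pressure relaxes
    toward PEEP+PS while pressurizing and toward PEEP while exhaling, with
    first-order time constant ``rise_time_constant``.  Triggering is
    flow-based: a patient-induced inspiratory flow exceeding
    ``trigger_deviation`` of the circuit bias flow starts pressurization
    after ``actuation_delay``.  ``exp_resistance`` is the effective linear
    resistance of the expiratory limb and exhalation valve, seen only by
    expiratory flow in PSV.
    """

    model_config = ConfigDict(extra="forbid")

    mode: Literal["psv", "none"] = "psv"
    pressure_support: float = Field(10.0, ge=0, le=30, description="PS above PEEP, cmH2O")
    peep: float = Field(4.0, ge=0, le=20, description="set PEEP, cmH2O")
    bias_flow: float = Field(0.5, ge=0, description="circuit bias flow, L/min")
    trigger_deviation: float = Field(0.25, gt=0, description="flow-trigger threshold, L/min")
    insp_fraction: float = Field(0.45, gt=0, lt=1, description="inspiratory-time cap, fraction of cycle")
    rise_time_constant: float = Field(0.05, gt=0, description="pressurization time constant, s")
    cycle_off_fraction: float = Field(0.30, gt=0, lt=1, description="flow-cycling threshold, fraction of peak")
    actuation_delay: float = Field(0.04, ge=0, description="trigger-to-pressurization delay, s")
    exp_resistance: float = Field(180.0, ge=0, description="expiratory limb + valve resistance, cmH2O/(L/s)")

    @classmethod
    def none(cls) -> "VentilatorSettings":
        """Unassisted breathing (T-piece or bare): atmospheric source."""
        return cls(mode="none", pressure_support=0.0, peep=0.0, exp_resistance=0.0)


class EffortProfile(BaseModel):
    """Active muscle-pressure driver in constant-tidal-volume mode.

    Pmus is a half-wave per cycle: half-sine descent to -amplitude over
    ``rise_fraction`` of the cycle, optional hold, then passive exponential
    release over ``release_fraction``; zero for the rest of the cycle.  The
    amplitude is normally set by :func:`sbtsim.mechanics.calibrate_constant_vt`
    so each breath delivers ``tidal_volume_target``.
    """

    model_config = ConfigDict(extra="forbid")

    rate: float = Field(24.0, gt=0, le=120, description="respiratory rate, /min")
    tidal_volume_target: float = Field(30.0, ge=0, description="target VT, mL")
    rise_fraction: float = Field(0.30, gt=0, lt=1)
    hold_fraction: float = Field(0.0, ge=0, lt=1)
    release_fraction: float = Field(0.30, gt=0, lt=1)
    amplitude: float = Field(0.0, ge=0, description="peak |Pmus|, cmH2O")

    @model_validator(mode="after")
    def _check_fractions(self) -> "EffortProfile":
        if self.rise_fraction + self.hold_fraction + self.release_fraction > 1.0:
            raise ValueError("rise+hold+release fractions must sum to <= 1")
        return self

    @property
    def cycle_time(self) -> float:
        return 60.0 / self.rate


class NumericsConfig(BaseModel):
    """Integration and sampling settings plus the optional noise layer."""

    model_config = ConfigDict(extra="forbid")

    dt: float = Field(5.0e-4, gt=0, le=1.0e-3, description="integration step, s")
    n_breaths: int = Field(10, ge=1, description="steady-state breaths retained")
    discard_breaths: int = Field(4, ge=2, description="transient breaths discarded")
    vt_tolerance: float = Field(0.1, gt=0, description="constant-VT calibration tolerance, mL")
    noise_rel_sd: float = Field(0.0, ge=0, description="optional relative measurement noise SD")
    seed: Optional[int] = Field(None, ge=0, description="noise seed; None = deterministic")


class RunConfig(BaseModel):
    """One bench condition: the four physical blocks plus numerics."""

    model_config = ConfigDict(extra="forbid")

    lung: LungModel = Field(default_factory=LungModel)
    apparatus: AirwayApparatus = Field(default_factory=AirwayApparatus)
    ventilator: VentilatorSettings = Field(default_factory=VentilatorSettings)
    effort: EffortProfile = Field(default_factory=EffortProfile)
    numerics: NumericsConfig = Field(default_factory=NumericsConfig)

    @model_validator(mode="after")
    def _cross_checks(self) -> "RunConfig":
        if self.ventilator.mode == "psv" and self.apparatus.mode != "intubated":
            raise ValueError("PSV requires an intubated apparatus")
        return self


def bench_condition(
    setting: Literal["bare", "t_piece", "psv"],
    rate: float = 24.0,
    ps: float = 10.0,
    tube: str = "ETT-3.5",
    **overrides,
) -> RunConfig:
    """Build one of the three bench breathing conditions.

    ``bare``   - lung simulator alone, open to atmosphere.
    ``t_piece``- breathing through the tube, open to atmosphere.
    ``psv``    - intubated, pressure-support ventilation at ``ps`` cmH2O
                 above 4 cmH2O PEEP.
    """
    if setting == "bare":
        apparatus = AirwayApparatus(mode="bare", tube_label=None)
        vent = VentilatorSettings.none()
    elif setting == "t_piece":
        apparatus = AirwayApparatus(mode="t_piece", tube_label=tube)
        vent = VentilatorSettings.none()
    elif setting == "psv":
        apparatus = AirwayApparatus(mode="intubated", tube_label=tube)
        vent = VentilatorSettings(mode="psv", pressure_support=ps)
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown setting {setting!r}")
    effort = EffortProfile(rate=rate)
    return RunConfig(apparatus=apparatus, ventilator=vent, effort=effort, **overrides)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return RunConfig.model_validate(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration as YAML; ``load_config`` round-trips it."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
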