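"""Gas properties, conduit geometry, and Reynolds-number flow-regime analysis.

All computations here are in SI units: flow in m^3/s, lengths in m, density
in kg/m^3, dynamic viscosity in kg/(m*s).  For a circular conduit of inner
radius ``r`` carrying volumetric flow ``Q`` the Reynolds number is

    Re = rho * v * D / eta = 2 * rho * Q / (pi * r * eta)

using the mean velocity v = Q / (pi r^2) and diameter D = 2 r.  The lower
critical Reynolds number below which turbulence cannot be self-sustained in
a pipe is ~1760; above ~2000 flow is treated as turbulent, with the closed
band [1760, 2000] reported as transitional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidGeometryError, InvalidInputError

#: Lower critical Reynolds number: below this, induced turbulence decays.
RE_LOWER_CRITICAL: float = 1760.0
#: Conventional upper threshold for fully turbulent pipe flow.
RE_TURBULENT: float = 2000.0


@dataclass(frozen=True)
class GasProperties:
    """Density and viscosity of the breathing gas.

    Parameters
    ----------
    density:
        Mass density rho in kg/m^3.
    dynamic_viscosity:
        Dynamic viscosity eta in kg/(m*s) (1 poise = 0.1 kg/(m*s)).
    """

    density: float
    dynamic_viscosity: float

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise InvalidInputError(
                "gas density and dynamic viscosity must be strictly positive, "
                f"got rho={self.density}, eta={self.dynamic_viscosity}"
            )

    @property
    def kinematic_viscosity(self) -> float:
        """nu = eta / rho in m^2/s."""
        return self.dynamic_viscosity / self.density


#: Dry FiO2 0.4 gas at 20 degC (the bench gas: no humidifier in line).
DRY_GAS_FIO2_04 = GasProperties(density=1.231, dynamic_viscosity=18.72e-6)


@dataclass(frozen=True)
class ConduitGeometry:
    """A circular flow conduit identified by its inner diameter."""

    inner_diameter: float  # m
    label: str = field(default="conduit")

    def __post_init__(self) -> None:
        if self.inner_diameter <= 0:
            raise InvalidGeometryError(
                f"conduit inner diameter must be > 0, got {self.inner_diameter}"
            )

    @property
    def inner_radius(self) -> float:
        return self.inner_diameter / 2.0


#: 3.0-mm inner-diameter endotracheal tube.
ETT_30 = ConduitGeometry(inner_diameter=3.0e-3, label="ETT-3.0")
#: 3.5-mm inner-diameter endotracheal tube.
ETT_35 = ConduitGeometry(inner_diameter=3.5e-3, label="ETT-3.5")
#: 22-mm port of the 22/19-mm adapter on the lung-simulator inlet.
ADAPTER_PORT_22MM = ConduitGeometry(inner_diameter=22.0e-3, label="adapter-port-22mm")
#: 9-mm built-in duct of the 22/19-mm adapter.
ADAPTER_DUCT_9MM = ConduitGeometry(inner_diameter=9.0e-3, label="adapter-duct-9mm")

CONDUITS: dict[str, ConduitGeometry] = {
    c.label: c for c in (ETT_30, ETT_35, ADAPTER_PORT_22MM, ADAPTER_DUCT_9MM)
}


def reynolds_number(
    flow: float,
    conduit: ConduitGeometry,
    gas: GasProperties = DRY_GAS_FIO2_04,
) -> float:
    """Reynolds number for volumetric flow through a circular conduit.

    Parameters
    ----------
    flow:
        Volumetric flow in m^3/s; must be >= 0.
    conduit:
        Conduit carrying the flow.
    gas:
        Gas properties; defaults to dry FiO2 0.4 at 20 degC.

    Returns
    -------
    float
        Re = 2 * rho * flow / (pi * r * eta); dimensionless, linear in flow.
    """
    if conduit.inner_radius <= 0:
        raise InvalidGeometryError("conduit radius must be positive")
    if gas.dynamic_viscosity <= 0:
        raise InvalidGeometryError("gas viscosity must be positive")
    if flow < 0:
        raise InvalidInputError(f"flow must be >= 0, got {flow}")
    return 2.0 * gas.density * flow / (math.pi * conduit.inner_radius * gas.dynamic_viscosity)


def reynolds_number_lpm(
    flow_lpm: float,
    conduit: ConduitGeometry,
    gas: GasProperties = DRY_GAS_FIO2_04,
) -> float:
    """Convenience wrapper taking flow in L/min (clinical interface unit)."""
    return reynolds_number(flow_lpm / 60_000.0, conduit, gas)


def humidification_re_change(nu_dry: float, nu_humid: float) -> float:
    """Percent change in Re when kinematic viscosity changes at fixed flow.

    Re is proportional to 1/nu at fixed volumetric flow and geometry, so
    the percent *decrease* going from ``nu_dry`` to ``nu_humid`` is
    ``100 * (1 - nu_dry / nu_humid)``.  A positive return value therefore
    means Re decreased with humidification.
    """
    if nu_dry <= 0 or nu_humid <= 0:
        raise InvalidInputError(
            f"kinematic viscosities must be > 0, got {nu_dry}, {nu_humid}"
        )
    return 100.0 * (1.0 - nu_dry / nu_humid)


def classify_flow_regime(re: float) -> str:
    """Classify a Reynolds number as laminar, transitional, or turbulent.

    The band [1760, 2000] is reported as ``"transitional"`` (closed band:
    both boundaries are included in it).
    """
    if re < 0:
        raise InvalidInputError(f"Reynolds number must be >= 0, got {re}")
    if re < RE_LOWER_CRITICAL:
        return "laminar"
    if re <= RE_TURBULENT:
        return "transitional"
    return "turbulent"
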