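"""Closed-form physico-chemical conversions for particle characterization.

Stokes-Einstein converts a measured diffusion coefficient into a
hydrodynamic radius; Smoluchowski converts an electrophoretic mobility
into a zeta potential.  SI units throughout; convenience helpers convert
to nm and mV at reporting boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.constants import Boltzmann

__all__ = [
    "SolventConditions",
    "WATER_25C",
    "hydrodynamic_radius",
    "zeta_from_mobility",
    "m_to_nm",
    "v_to_mv",
]


@dataclass(frozen=True)
class SolventConditions:
    """Solvent state: temperature (K), dynamic viscosity (Pa s) and
    absolute permittivity (F/m)."""

    temperature: float = 298.15
    viscosity: float = 8.9e-4
    permittivity: float = 6.93e-10

    def __post_init__(self) -> None:
        if min(self.temperature, self.viscosity, self.permittivity) <= 0:
            raise ValueError("all solvent parameters must be strictly positive")


WATER_25C = SolventConditions()


def hydrodynamic_radius(D: float, cond: SolventConditions = WATER_25C) -> float:
    """Stokes-Einstein: R_H = k_B T / (6 pi eta D), in metres (D in m^2/s)."""
    if D <= 0:
        raise ValueError("diffusion coefficient must be positive")
    from math import pi
    return Boltzmann * cond.temperature / (6.0 * pi * cond.viscosity * D)


def zeta_from_mobility(u: float, cond: SolventConditions = WATER_25C) -> float:
    """Smoluchowski: zeta = u * eta / epsilon, in volts (u in m^2/(V s))."""
    return u * cond.viscosity / cond.permittivity


def m_to_nm(x: float) -> float:
    return x * 1e9


def v_to_mv(x: float) -> float:
    return x * 1e3
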