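"""Unit systems and physical-quantity conversion.

NeuroML v1.x documents declare exactly one of two unit systems, *SI Units*
or *Physiological Units*, and every dimensional attribute in the file is
interpreted in that system.  This module is the single authoritative place
where the two systems are defined.

The Physiological system used throughout this package is the mV/ms family
conventional in compartmental modelling:

========================  ==============  ==================
dimension                 SI unit         Physiological unit
========================  ==============  ==================
voltage                   V               mV
time                      s               ms
length                    m               um
specific-capacitance      F/m^2           uF/cm^2
specific-conductance      S/m^2           mS/cm^2
conductance               S               uS
current                   A               nA
concentration             mol/m^3 (mM)    mM
temperature               degC            degC
resistivity               Ohm*m           kOhm*cm
dimensionless             1               1
========================  ==============  ==================

All in-memory model objects in this package store magnitudes in the
Physiological system; conversion happens only at the XML boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class UnitSystem(enum.Enum):
    """The two unit systems a NeuroML document may declare."""

    SI = "SI Units"
    PHYSIOLOGICAL = "Physiological Units"

    @classmethod
    def from_string(cls, text: str) -> "UnitSystem":
        t = text.strip().lower()
        if t in ("si units", "si"):
            return cls.SI
        if t in ("physiological units", "physiological"):
            return cls.PHYSIOLOGICAL
        raise ValueError(f"unknown unit system: {text!r}")


class Dimension(enum.Enum):
    VOLTAGE = "voltage"
    TIME = "time"
    LENGTH = "length"
    SPECIFIC_CAPACITANCE = "specific-capacitance"
    SPECIFIC_CONDUCTANCE = "specific-conductance"
    CONDUCTANCE = "conductance"
    CURRENT = "current"
    CONCENTRATION = "concentration"
    TEMPERATURE = "temperature"
    RESISTIVITY = "resistivity"
    DIMENSIONLESS = "dimensionless"


#: multiplicative factor taking an SI magnitude to a Physiological magnitude
SI_TO_PHYSIOLOGICAL: dict[Dimension, float] = {
    Dimension.VOLTAGE: 1e3,                 # V -> mV
    Dimension.TIME: 1e3,                    # s -> ms
    Dimension.LENGTH: 1e6,                  # m -> um
    Dimension.SPECIFIC_CAPACITANCE: 1e2,    # F/m^2 -> uF/cm^2
    Dimension.SPECIFIC_CONDUCTANCE: 1e-1,   # S/m^2 -> mS/cm^2
    Dimension.CONDUCTANCE: 1e6,             # S -> uS
    Dimension.CURRENT: 1e9,                 # A -> nA
    Dimension.CONCENTRATION: 1.0,           # mol/m^3 == mmol/l
    Dimension.TEMPERATURE: 1.0,             # degC in both systems
    Dimension.RESISTIVITY: 1e-1,            # Ohm*m -> kOhm*cm
    Dimension.DIMENSIONLESS: 1.0,
}

#: number of um^2 in one cm^2 (handy for densities quoted per um^2)
UM2_PER_CM2 = 1e8


def convert(magnitude: float, dimension: Dimension,
            from_system: UnitSystem, to_system: UnitSystem) -> float:
    """Convert ``magnitude`` of ``dimension`` between unit systems.

    The conversion is a group action: SI -> Physiological -> SI is the
    identity up to floating-point rounding (each direction is a single
    multiplication by an exact power of ten).
    """
    if from_system is to_system:
        return magnitude
    factor = SI_TO_PHYSIOLOGICAL[dimension]
    if from_system is UnitSystem.SI:
        return magnitude * factor
    return magnitude / factor


@dataclass(frozen=True)
class PhysicalQuantity:
    """A magnitude tagged with its dimension and unit system."""

    magnitude: float
    dimension: Dimension
    system: UnitSystem = UnitSystem.PHYSIOLOGICAL

    def to(self, system: UnitSystem) -> "PhysicalQuantity":
        return PhysicalQuantity(
            convert(self.magnitude, self.dimension, self.system, system),
            self.dimension, system)

    @property
    def physiological(self) -> float:
        """Magnitude in the package-internal (Physiological) system."""
        return self.to(UnitSystem.PHYSIOLOGICAL).magnitude
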