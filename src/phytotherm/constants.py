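"""Physical constants and temperature handling.

A single, overridable set of physical constants feeds every formula in the
package.  The defaults are deliberately the rounded textbook values the
radiometric reference table was computed with (h = 6.626e-34 J s,
c = 2.998e8 m/s, k_B = 1.381e-23 J/K) rather than full-precision CODATA
values, so that the tabulated golden irradiances reproduce to their printed
precision.  Pass a custom :class:`PhysicalConstants` to any radiometry
function to work with other values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any, Mapping, Union

import yaml

__all__ = ["PhysicalConstants", "Temperature", "DEFAULT_CONSTANTS", "as_temperature"]


@dataclass(frozen=True)
class PhysicalConstants:
    """The six constants driving black-body and solar radiometry.

    Attributes
    ----------
    planck_h : float
        Planck's constant, J s.
    light_speed_c : float
        Speed of light in vacuum, m/s.
    boltzmann_kB : float
        Boltzmann's constant, J/K.
    sun_radius : float
        Radius of the sun, m.
    orbit_radius : float
        Mean radius of the earth's orbit, m.
    sun_temperature : float
        Effective black-body temperature of the sun, K.
    """

    planck_h: float = 6.626e-34
    light_speed_c: float = 2.998e8
    boltzmann_kB: float = 1.381e-23
    sun_radius: float = 6.95e8
    orbit_radius: float = 1.50e11
    sun_temperature: float = 5778.0

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not value > 0:
                raise ValueError(f"{f.name} must be strictly positive, got {value!r}")

    @property
    def hc(self) -> float:
        """Product h*c, J m (appears in every Planck exponent)."""
        return self.planck_h * self.light_speed_c

    @property
    def stefan_boltzmann_sigma(self) -> float:
        """Stefan-Boltzmann constant sigma = 2 pi^5 k_B^4 / (15 h^3 c^2), W m^-2 K^-4."""
        import math

        h, c, kB = self.planck_h, self.light_speed_c, self.boltzmann_kB
        return 2.0 * math.pi**5 * kB**4 / (15.0 * h**3 * c**2)

    @property
    def solar_dilution(self) -> float:
        """Geometric dilution factor (R_sun / R_orbit)^2 of sunlight at the orbit."""
        return (self.sun_radius / self.orbit_radius) ** 2

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "PhysicalConstants":
        """Build constants from a dict; absent keys keep their defaults."""
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise KeyError(f"unknown constant name(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PhysicalConstants":
        """Load a YAML or JSON constants block (a flat mapping, possibly partial)."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            return cls()
        if not isinstance(data, Mapping):
            raise TypeError(f"constants file {path} must contain a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


DEFAULT_CONSTANTS = PhysicalConstants()

_CELSIUS_OFFSET = 273.15


@dataclass(frozen=True, order=True)
class Temperature:
    """An absolute temperature in kelvin.

    Construct from Celsius with :meth:`from_celsius` (exact +273.15 offset,
    so 22 degC -> 295.15 K).
    """

    kelvin: float

    def __post_init__(self) -> None:
        if not self.kelvin > 0:
            raise ValueError(f"absolute temperature must be positive, got {self.kelvin} K")

    @classmethod
    def from_celsius(cls, celsius: float) -> "Temperature":
        return cls(kelvin=celsius + _CELSIUS_OFFSET)

    @property
    def celsius(self) -> float:
        return self.kelvin - _CELSIUS_OFFSET

    def __float__(self) -> float:
        return float(self.kelvin)


def as_temperature(value: Union[Temperature, float], *, celsius: bool = False) -> Temperature:
    """Coerce a bare number (kelvin by default) or Temperature to Temperature."""
    if isinstance(value, Temperature):
        return value
    return Temperature.from_celsius(value) if celsius else Temperature(float(value))
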