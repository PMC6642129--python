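"""Black-body radiometry for plant light and temperature environments.

Everything here follows from Planck's law.  The spectral energy density of
thermal radiation at wavelength ``lambda`` and absolute temperature ``T`` is

    rho_T(lambda) = 8 pi h c / lambda^5 * 1 / (exp(hc / lambda k_B T) - 1)

Irradiance relates to energy density as E = c * rho, and under the isotropic
(black-body) assumption the plane irradiance through a surface is E_d = E / 4,
giving the spectral plane irradiance

    E_dT(lambda) = 2 pi h c^2 / lambda^5 * 1 / (exp(hc / lambda k_B T) - 1).

Sunlight at the earth's orbit is the same expression at the sun's effective
temperature, diluted geometrically by (R_sun / R_orbit)^2.  For a leaf surface
in thermal equilibrium with its surroundings the distance factor is 1 and the
environment radiates directly at the ambient temperature: plant-physiological
temperatures (4-37 degC) peak near 10 um, in the thermal infra-red, which is
why the IR photon flux at 10 um serves as the temperature signal throughout
the package.

Unit conventions: wavelengths are metres everywhere; spectral irradiances are
returned per nanometre of wavelength (W m^-2 nm^-1), the unit plant
photobiology tables use.  The per-metre value is 1e9 times larger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Union

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .constants import DEFAULT_CONSTANTS, PhysicalConstants, Temperature, as_temperature

__all__ = [
    "PER_NM",
    "IR_WAVELENGTH",
    "RED_WAVELENGTH",
    "PhotonFlux",
    "Spectrum",
    "SpectrumSource",
    "spectral_energy_density",
    "spectral_plane_irradiance",
    "solar_spectral_irradiance",
    "peak_wavelength",
    "total_irradiance",
    "photon_flux",
    "ir_photon_flux",
    "relative_r_ir_ratio",
]

#: Conversion from per-metre to per-nanometre spectral quantities.
PER_NM = 1e-9

#: Nominal thermal infra-red wavelength (m): the environmental Planck peak.
IR_WAVELENGTH = 10e-6

#: Nominal red wavelength (m) absorbed by the Pr phytochrome.
RED_WAVELENGTH = 660e-9

# exp argument beyond which 1/expm1(x) is numerically exp(-x); avoids overflow
# deep in the Wien tail (e.g. UV wavelengths at leaf temperatures).
_EXP_SWITCH = 500.0


def _check_wavelength(wavelength) -> np.ndarray:
    lam = np.asarray(wavelength, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be strictly positive (metres)")
    return lam


def _bose_factor(x: np.ndarray) -> np.ndarray:
    """1 / (exp(x) - 1), stable for both small and very large x."""
    x = np.asarray(x, dtype=float)
    tail = x > _EXP_SWITCH
    with np.errstate(under="ignore"):
        # Wien tail: 1/expm1(x) ~ exp(-x), flushed to exactly 0 past underflow
        tail_val = np.where(x > 745.0, 0.0, np.exp(-np.minimum(x, 745.0)))
        out = np.where(tail, tail_val, 1.0 / np.expm1(np.minimum(x, _EXP_SWITCH)))
    return out


def spectral_energy_density(
    wavelength,
    temperature: Union[Temperature, float],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Planck spectral energy density rho_T(lambda), J m^-4.

    Parameters
    ----------
    wavelength : float or array
        Wavelength(s) in metres, > 0.
    temperature : Temperature or float
        Absolute temperature (bare floats are kelvin).
    constants : PhysicalConstants
        Constant set to evaluate with.
    """
    lam = _check_wavelength(wavelength)
    T = as_temperature(temperature).kelvin
    x = constants.hc / (lam * constants.boltzmann_kB * T)
    value = 8.0 * math.pi * constants.hc / lam**5 * _bose_factor(x)
    return value if value.ndim else float(value)


def spectral_plane_irradiance(
    wavelength,
    temperature: Union[Temperature, float],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Spectral plane irradiance E_dT(lambda) of a black body, W m^-2 nm^-1.

    E_d = E/4 = (c/4) * rho, i.e. 2 pi h c^2 / lambda^5 / (exp(hc/lambda kB T) - 1),
    converted to per-nm.
    """
    lam = _check_wavelength(wavelength)
    T = as_temperature(temperature).kelvin
    x = constants.hc / (lam * constants.boltzmann_kB * T)
    per_m = 2.0 * math.pi * constants.planck_h * constants.light_speed_c**2 / lam**5 * _bose_factor(x)
    value = per_m * PER_NM
    return value if value.ndim else float(value)


def solar_spectral_irradiance(
    wavelength,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Solar spectral irradiance at the earth's orbit, W m^-2 nm^-1.

    The sun's black-body spectrum at T_sun diluted by (R_sun / R_orbit)^2.
    """
    base = spectral_plane_irradiance(wavelength, constants.sun_temperature, constants)
    return constants.solar_dilution * base


def wien_displacement_x(rtol: float = 1e-12) -> float:
    """Root x* of x e^x / (e^x - 1) = 5, defining the Planck peak lambda*T = hc/(x* kB)."""
    return brentq(lambda x: x * math.exp(x) / math.expm1(x) - 5.0, 1.0, 20.0, xtol=rtol)


_WIEN_X = wien_displacement_x()


def peak_wavelength(
    temperature: Union[Temperature, float],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Wavelength (m) maximising the per-wavelength Planck irradiance at ``temperature``.

    Solves the Wien displacement condition x e^x/(e^x - 1) = 5 by bracketed
    root finding, so lambda_max * T = hc / (x* k_B) holds to machine precision.
    """
    T = as_temperature(temperature).kelvin
    return constants.hc / (_WIEN_X * constants.boltzmann_kB * T)


def total_irradiance(
    temperature: Union[Temperature, float],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    lam_lo: float = 1e-8,
    lam_hi: float = 1e-3,
) -> float:
    """Band-integrated plane irradiance, W m^-2.

    Adaptive quadrature of the per-metre spectral plane irradiance over
    [lam_lo, lam_hi].  The default band (10 nm to 1 mm) captures the full
    Stefan-Boltzmann total sigma T^4 to well within 0.1% for any temperature
    between deep winter and the solar photosphere.
    """
    if not (0 < lam_lo < lam_hi):
        raise ValueError(f"need 0 < lam_lo < lam_hi, got [{lam_lo}, {lam_hi}]")
    T = as_temperature(temperature)

    def integrand(lam: float) -> float:
        return spectral_plane_irradiance(lam, T, constants) / PER_NM

    peak = peak_wavelength(T, constants)
    points = [p for p in (peak, 2.0 * peak, 5.0 * peak) if lam_lo < p < lam_hi]
    value, _ = quad(integrand, lam_lo, lam_hi, points=points or None, limit=200, epsrel=1e-10)
    return value


@dataclass(frozen=True)
class PhotonFlux:
    """Monochromatic photon flux, photons m^-2 s^-1 nm^-1, at a nominal wavelength."""

    value: float
    wavelength: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("photon flux cannot be negative")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")


def photon_flux(
    irradiance: float,
    wavelength: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> PhotonFlux:
    """Convert a spectral irradiance (W m^-2 nm^-1) to photon flux at one wavelength.

    Each photon carries hc/lambda joules, so N = E * lambda / (h c), in
    photons m^-2 s^-1 nm^-1.  Monochromatic by design: the kinetics model
    drives phytochrome with the flux at a nominal band wavelength (660 nm for
    red, 10 um for thermal IR), not with a band integral.
    """
    if irradiance < 0:
        raise ValueError("irradiance cannot be negative")
    lam = float(_check_wavelength(wavelength))
    return PhotonFlux(value=irradiance * lam / constants.hc, wavelength=lam)


def ir_photon_flux(
    temperature: Union[Temperature, float],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    wavelength: float = IR_WAVELENGTH,
) -> PhotonFlux:
    """Thermal IR photon flux of the environment at ``temperature`` (default 10 um)."""
    E = spectral_plane_irradiance(wavelength, temperature, constants)
    return photon_flux(E, wavelength, constants)


def relative_r_ir_ratio(
    temp_ref: Union[Temperature, float],
    temp_query: Union[Temperature, float],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    wavelength: float = IR_WAVELENGTH,
) -> float:
    """Relative R:IR ratio r(T_ref, T_query) = N_IR(T_ref) / N_IR(T_query).

    Under constant illumination the red photon flux N_R is fixed while the
    thermal IR flux tracks temperature, so the R:IR ratio at T_query relative
    to the reference reduces to the ratio of IR photon fluxes.  Equals 1 when
    the two temperatures coincide and falls below 1 for warmer queries.
    """
    n_ref = ir_photon_flux(temp_ref, constants, wavelength).value
    n_query = ir_photon_flux(temp_query, constants, wavelength).value
    return n_ref / n_query


class SpectrumSource(str, Enum):
    SOLAR = "solar"
    ENVIRONMENT = "environment"


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectral plane irradiance curve at one temperature.

    wavelengths are metres on a strictly increasing grid; irradiance is
    W m^-2 nm^-1 per grid point.
    """

    wavelengths: np.ndarray
    irradiance: np.ndarray
    temperature: Temperature
    source: SpectrumSource

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths, dtype=float)
        irr = np.asarray(self.irradiance, dtype=float)
        if lam.shape != irr.shape or lam.ndim != 1:
            raise ValueError("wavelengths and irradiance must be matching 1-D arrays")
        if np.any(lam <= 0) or np.any(np.diff(lam) <= 0):
            raise ValueError("wavelength grid must be positive and strictly increasing")
        if np.any(irr < 0):
            raise ValueError("irradiance values must be non-negative")
        object.__setattr__(self, "wavelengths", lam)
        object.__setattr__(self, "irradiance", irr)
        object.__setattr__(self, "source", SpectrumSource(self.source))

    @classmethod
    def environment(
        cls,
        temperature: Union[Temperature, float],
        wavelengths=None,
        constants: PhysicalConstants = DEFAULT_CONSTANTS,
    ) -> "Spectrum":
        """Thermal spectrum of surroundings at ``temperature`` on a log grid."""
        T = as_temperature(temperature)
        lam = default_grid() if wavelengths is None else np.asarray(wavelengths, float)
        return cls(lam, spectral_plane_irradiance(lam, T, constants), T, SpectrumSource.ENVIRONMENT)

    @classmethod
    def solar(
        cls,
        wavelengths=None,
        constants: PhysicalConstants = DEFAULT_CONSTANTS,
    ) -> "Spectrum":
        """Diluted solar spectrum at the earth's orbit on a log grid."""
        lam = default_grid() if wavelengths is None else np.asarray(wavelengths, float)
        T = Temperature(constants.sun_temperature)
        return cls(lam, solar_spectral_irradiance(lam, constants), T, SpectrumSource.SOLAR)

    def grid_peak(self) -> tuple[float, float]:
        """(wavelength, irradiance) at the grid argmax — a coarse check on peak_wavelength."""
        i = int(np.argmax(self.irradiance))
        return float(self.wavelengths[i]), float(self.irradiance[i])

    def to_csv(self, path: Union[str, Path]) -> Path:
        """Write wavelength_nm, irradiance_W_m2_nm, temperature_K, source rows."""
        import pandas as pd

        path = Path(path)
        frame = pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths / PER_NM,
                "irradiance_W_m2_nm": self.irradiance,
                "temperature_K": self.temperature.kelvin,
                "source": self.source.value,
            }
        ).sort_values("wavelength_nm")
        frame.to_csv(path, index=False)
        return path


def default_grid(lam_lo: float = 1e-8, lam_hi: float = 1e-3, n: int = 4000) -> np.ndarray:
    """Log-spaced wavelength grid (m) spanning UV to the far thermal infra-red."""
    return np.logspace(math.log10(lam_lo), math.log10(lam_hi), n)
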