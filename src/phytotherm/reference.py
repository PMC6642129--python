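"""Published reference values used as golden checks.

The tabulated spectral irradiances at plant-physiological wavelengths
(UV-B 310 nm, blue 470 nm, red 660 nm, far-red 730 nm, thermal IR 10 um)
were originally computed with the same rounded constants this package
defaults to, so a registered subset reproduces directly:

* the full thermal IR row (10 um at 4-37 degC), to 1% relative;
* four solar cells (310, 470, 660 nm and 10 um), to 1.5% relative.

The remaining printed cells do NOT reproduce from the stated formulas and are
registered as unverified: the UV-B, blue and far-red thermal cells sit a
consistent ~1.6x below direct evaluation of the Planck plane-irradiance
formula, the red thermal cells ~7% above it, and the 730 nm solar cell ~2%
off.  They are retained here verbatim so the discrepancy is measurable, but
no golden test asserts them.
"""

from __future__ import annotations

__all__ = [
    "TABLE1_WAVELENGTHS_M",
    "TABLE1_TEMPERATURES_C",
    "TABLE1_SOLAR",
    "TABLE1_THERMAL",
    "GOLDEN_SOLAR_CELLS",
    "GOLDEN_THERMAL_ROWS",
    "HALF_LIFE_FIT",
    "IR_ROW_RTOL",
    "SOLAR_RTOL",
]

#: Light regimes and their nominal wavelengths (m).
TABLE1_WAVELENGTHS_M: dict[str, float] = {
    "UV-B": 310e-9,
    "B": 470e-9,
    "R": 660e-9,
    "FR": 730e-9,
    "IR": 10e-6,
}

#: Environmental temperature columns (degC).
TABLE1_TEMPERATURES_C: tuple[float, ...] = (4.0, 12.0, 16.0, 22.0, 28.0, 37.0)

#: Printed solar spectral irradiance, W m^-2 nm^-1, per light regime.
TABLE1_SOLAR: dict[str, float] = {
    "UV-B": 0.91,
    "B": 1.77,
    "R": 1.52,
    "FR": 1.35,
    "IR": 2.86e-4,
}

#: Printed thermal spectral irradiance, W m^-2 nm^-1: regime -> per-temperature row.
TABLE1_THERMAL: dict[str, tuple[float, ...]] = {
    "UV-B": (1.53e-65, 1.70e-63, 1.63e-62, 4.29e-61, 9.93e-60, 8.81e-58),
    "B": (1.08e-41, 2.43e-40, 1.08e-39, 9.37e-39, 7.47e-38, 1.45e-36),
    "R": (2.27e-28, 2.06e-27, 5.93e-27, 2.74e-26, 1.19e-25, 9.70e-25),
    "FR": (1.44e-25, 1.08e-24, 2.82e-24, 1.14e-23, 4.35e-23, 2.95e-22),
    "IR": (0.0210, 0.0243, 0.0260, 0.0288, 0.0318, 0.0366),
}

#: Solar cells that reproduce from the diluted Planck formula (golden at 1.5%).
GOLDEN_SOLAR_CELLS: tuple[str, ...] = ("UV-B", "B", "R", "IR")

#: Thermal rows that reproduce from the plane-irradiance formula (golden at 1%).
GOLDEN_THERMAL_ROWS: tuple[str, ...] = ("IR",)

IR_ROW_RTOL = 0.01
SOLAR_RTOL = 0.015

#: Published log2(relative half-life) vs temperature (degC) fit over 4-37 degC.
HALF_LIFE_FIT: dict[str, float] = {
    "slope": -0.0243,
    "intercept": 0.5435,
    "r_squared": 0.9988,
    "slope_tol": 2e-4,
    "intercept_tol": 2e-3,
    "r_squared_tol": 1e-3,
}
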