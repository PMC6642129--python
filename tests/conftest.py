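import numpy as np
import pytest

from phytotherm import DEFAULT_CONSTANTS, Temperature

#: The six environmental growth temperatures (degC) used throughout.
GROWTH_TEMPS_C = (4.0, 12.0, 16.0, 22.0, 28.0, 37.0)

#: Warm window where every genotype archetype's mean length clears the
#: 0.1 mm truncation floor by > 3 noise SD (see docs/methods.md).
WARM_TEMPS_C = (16.0, 22.0, 28.0, 37.0)


@pytest.fixture(scope="session")
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def growth_temperatures():
    return tuple(Temperature.from_celsius(t) for t in GROWTH_TEMPS_C)


def planck_plane_irradiance_oracle(lam_m: float, T_k: float) -> float:
    """Independent arithmetic of the Planck plane irradiance (W m^-2 nm^-1).

    Written out long-hand from the defining formula so implementation tests
    do not share code with the module under test.
    """
    h, c, kB = 6.626e-34, 2.998e8, 1.381e-23
    x = h * c / (lam_m * kB * T_k)
    return 2.0 * np.pi * h * c**2 / lam_m**5 / np.expm1(x) * 1e-9
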