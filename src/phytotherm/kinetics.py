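"""Pfr/Pr phytochrome kinetics under red, far-red and thermal infra-red drive.

Phytochrome interconverts between the red-absorbing Pr form and the
far-red-absorbing, physiologically active Pfr form.  Photoconversion under a
photon flux N with photoconversion cross-section sigma (= 2.3 * epsilon * phi,
extinction coefficient times quantum yield) is first order, and the classic
two-term photoequilibrium model extends with an infra-red term that drives the
spontaneous Pfr-to-Pr "dark reversion" as a thermal photoconversion:

    d[Pfr]/dt = N_R sigma_R [Pr] - N_FR sigma_FR [Pfr] - N_IR k_IR [Pfr]

In darkness (N_R = N_FR = 0) this integrates to exponential decay,
[Pfr](t) = [Pfr]_0 exp(-N_IR k_IR t), with half-life t_1/2 = ln2 / (N_IR k_IR)
and an accumulating Pr/Pfr ratio exp(N_IR k_IR t) - 1.  Because only the
product N_IR * k_IR is identifiable, time is expressed in relative units: the
default calibration fixes the dark half-life at the 22 degC reference to 1,
so N_IR(22 degC) * k_IR = ln 2.  Relative half-lives across temperatures then
depend only on the ratio of thermal IR photon fluxes at 10 um, which is pure
radiometry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants, Temperature, as_temperature
from .radiometry import IR_WAVELENGTH, ir_photon_flux

__all__ = [
    "LightEnvironment",
    "PfrState",
    "PfrTrajectory",
    "pfr_rate",
    "simulate_pfr",
    "dark_half_life",
    "relative_half_life",
    "pr_pfr_ratio",
    "photostationary_pfr_fraction",
]

REFERENCE_CELSIUS = 22.0


@dataclass(frozen=True)
class LightEnvironment:
    """Photon fluxes and conversion coefficients driving Pfr dynamics.

    Fluxes are photons m^-2 s^-1 nm^-1; sigma_r / sigma_fr are photoconversion
    cross-sections (m^2 per photon); k_ir is the effective IR conversion
    coefficient with the same units contract, folding in the efficiency of
    thermal photons at driving the Pfr-to-Pr isomerisation.
    """

    n_r: float = 0.0
    n_fr: float = 0.0
    n_ir: float = 0.0
    sigma_r: float = 0.0
    sigma_fr: float = 0.0
    k_ir: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_r", "n_fr", "n_ir", "sigma_r", "sigma_fr", "k_ir"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def is_dark(self) -> bool:
        """True when no visible drive acts (pure thermal reversion)."""
        return self.n_r * self.sigma_r == 0.0 and self.n_fr * self.sigma_fr == 0.0

    @property
    def ir_rate(self) -> float:
        """First-order IR reversion rate N_IR * k_IR (reciprocal relative time)."""
        return self.n_ir * self.k_ir

    @property
    def total_rate(self) -> float:
        return self.n_r * self.sigma_r + self.n_fr * self.sigma_fr + self.ir_rate

    @classmethod
    def dark_thermal(
        cls,
        temperature: Union[Temperature, float],
        constants: PhysicalConstants = DEFAULT_CONSTANTS,
        reference: Union[Temperature, float, None] = None,
        wavelength: float = IR_WAVELENGTH,
    ) -> "LightEnvironment":
        """Dark environment at ``temperature`` with the relative-time calibration.

        n_ir is the thermal IR photon flux at ``wavelength``; k_ir is chosen so
        that the dark half-life at the reference temperature (22 degC unless
        overridden) equals exactly 1 relative time unit.
        """
        ref = Temperature.from_celsius(REFERENCE_CELSIUS) if reference is None else as_temperature(reference)
        n_ir = ir_photon_flux(temperature, constants, wavelength).value
        n_ref = ir_photon_flux(ref, constants, wavelength).value
        return cls(n_ir=n_ir, k_ir=math.log(2.0) / n_ref)


@dataclass(frozen=True)
class PfrState:
    """Amounts of the two phytochrome forms (arbitrary concentration units)."""

    pfr: float
    pr: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.pfr < 0 or self.pr < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def total(self) -> float:
        return self.pfr + self.pr

    @property
    def pfr_fraction(self) -> float:
        return self.pfr / self.total


def pfr_rate(state: PfrState, env: LightEnvironment) -> float:
    """d[Pfr]/dt: red drive forward, far-red and thermal IR backward."""
    return (
        env.n_r * env.sigma_r * state.pr
        - env.n_fr * env.sigma_fr * state.pfr
        - env.n_ir * env.k_ir * state.pfr
    )


@dataclass(frozen=True)
class PfrTrajectory:
    """A Pfr/Pr time course under a constant light environment."""

    times: np.ndarray
    pfr: np.ndarray
    pr: np.ndarray
    environment: LightEnvironment

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "pfr", np.asarray(self.pfr, dtype=float))
        object.__setattr__(self, "pr", np.asarray(self.pr, dtype=float))

    @property
    def total(self) -> np.ndarray:
        return self.pfr + self.pr

    @property
    def pr_over_pfr(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return self.pr / self.pfr

    def to_csv(self, path: Union[str, Path]) -> Path:
        import pandas as pd

        path = Path(path)
        pd.DataFrame(
            {
                "time": self.times,
                "pfr": self.pfr,
                "pr": self.pr,
                "pr_over_pfr": self.pr_over_pfr,
            }
        ).to_csv(path, index=False)
        return path

    def summary(self) -> dict:
        env = self.environment
        out = {
            "half_life": dark_half_life(env) if env.is_dark else None,
            "photostationary_pfr_fraction": (
                photostationary_pfr_fraction(env) if env.total_rate > 0 else None
            ),
            "n_points": int(self.times.size),
            "time_span": [float(self.times[0]), float(self.times[-1])],
        }
        if out["half_life"] == math.inf:
            out["half_life"] = "inf"
        return out

    def summary_json(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.summary(), indent=2) + "\n")
        return path


def _closed_form_dark(env: LightEnvironment, initial: PfrState, times: np.ndarray):
    decay = np.exp(-env.ir_rate * (times - initial.time))
    pfr = initial.pfr * decay
    return pfr, initial.total - pfr


def simulate_pfr(
    env: LightEnvironment,
    initial: PfrState,
    times,
    method: str = "auto",
) -> PfrTrajectory:
    """Integrate the Pfr rate equation at the requested times.

    For a constant dark environment the exact exponential solution is used
    (``method="auto"``); otherwise, or when ``method="rk4"`` is forced, a
    fixed-step classic 4th-order Runge-Kutta scheme integrates [Pfr] with a
    step no larger than one hundredth of the fastest characteristic half-life.
    [Pr] is recovered from conservation, so pfr + pr is exact along the
    trajectory.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(t) <= 0) or t[0] < initial.time:
        raise ValueError("times must be strictly increasing, starting at or after initial.time")
    if method not in ("auto", "rk4", "closed_form"):
        raise ValueError(f"unknown method {method!r}")
    if method == "closed_form" and not env.is_dark:
        raise ValueError("closed-form solution only applies to a dark environment")

    if env.is_dark and method != "rk4":
        pfr, pr = _closed_form_dark(env, initial, t)
        return PfrTrajectory(t, pfr, pr, env)

    total = initial.total
    k = env.total_rate
    # linear relaxation toward the photostationary state at rate k
    dt_max = math.log(2.0) / k / 100.0 if k > 0 else math.inf

    def rate(pfr: float) -> float:
        return env.n_r * env.sigma_r * (total - pfr) - (env.n_fr * env.sigma_fr + env.ir_rate) * pfr

    pfr_out = np.empty_like(t)
    pfr_now, t_now = initial.pfr, initial.time
    for i, t_target in enumerate(t):
        span = t_target - t_now
        n_steps = max(1, int(math.ceil(span / dt_max))) if span > 0 and math.isfinite(dt_max) else 1
        h = span / n_steps if n_steps else 0.0
        for _ in range(n_steps):
            if h == 0.0:
                break
            k1 = rate(pfr_now)
            k2 = rate(pfr_now + 0.5 * h * k1)
            k3 = rate(pfr_now + 0.5 * h * k2)
            k4 = rate(pfr_now + h * k3)
            pfr_now += h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t_now = t_target
        pfr_out[i] = pfr_now
    return PfrTrajectory(t, pfr_out, total - pfr_out, env)


def dark_half_life(env: LightEnvironment) -> float:
    """Half-life ln2 / (N_IR k_IR) of Pfr in the dark; inf when there is no IR drive."""
    if not env.is_dark:
        raise ValueError("dark_half_life requires a dark environment (no R/FR drive)")
    if env.ir_rate == 0.0:
        return math.inf
    return math.log(2.0) / env.ir_rate


def relative_half_life(
    temp_query: Union[Temperature, float],
    temp_ref: Union[Temperature, float, None] = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    wavelength: float = IR_WAVELENGTH,
) -> float:
    """Dark-reversion half-life at ``temp_query`` relative to the 22 degC reference.

    Because t_1/2 = ln2 / (N_IR k_IR) and k_IR is a molecular constant, the
    ratio of half-lives between two temperatures is the inverse ratio of their
    thermal IR photon fluxes: t_1/2(T) / t_1/2(ref) = N_IR(ref) / N_IR(T).
    Warmer environments radiate more IR and revert Pfr faster.
    """
    ref = Temperature.from_celsius(REFERENCE_CELSIUS) if temp_ref is None else as_temperature(temp_ref)
    n_ref = ir_photon_flux(ref, constants, wavelength).value
    n_query = ir_photon_flux(temp_query, constants, wavelength).value
    return n_ref / n_query


def pr_pfr_ratio(t: float, env: LightEnvironment) -> float:
    """Pr/Pfr ratio after dark time t from an all-Pfr start: exp(N_IR k_IR t) - 1."""
    if t < 0:
        raise ValueError("time must be non-negative")
    if not env.is_dark:
        raise ValueError("pr_pfr_ratio applies to dark reversion only")
    return math.expm1(env.ir_rate * t)


def photostationary_pfr_fraction(env: LightEnvironment) -> float:
    """Steady-state Pfr fraction N_R sigma_R / (N_R sigma_R + N_FR sigma_FR + N_IR k_IR)."""
    denom = env.total_rate
    if denom == 0.0:
        raise ValueError("photostationary state undefined: all drive terms are zero")
    return env.n_r * env.sigma_r / denom
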