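"""Synthetic hypocotyl-length datasets for testing the regression stage.

The generator emulates the statistical structure the photothermal analysis
assumes: for each genotype, mean hypocotyl length is linear in the relative
R:IR ratio r(T) = N_IR(22 degC)/N_IR(T), and individual seedlings scatter
around that mean with additive Gaussian noise.  Seven built-in genotype
archetypes carry published slope/intercept pairs (mm per unit r, mm) spanning
wild-type-like controls, the phytochrome-null *phyABCDE* quintuple mutant, a
phyB overexpressor, the constitutively active YHB phyB variant and the
chromophore-deficient *hy1* mutant.  Defaults mirror the source experiments:
six growth temperatures (4, 12, 16, 22, 28, 37 degC) and 15 seedlings per
condition.  Replicate noise is sigma = 0.5 mm — the experiments publish no
replicate variance, and half a millimetre gives plausible scatter on
hypocotyls of a few to ~20 mm while keeping slope recovery a non-trivial
statistical exercise.  Draws below 0.1 mm are truncated up to 0.1 mm so no
seedling has a non-physical length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysicalConstants, Temperature
from .kinetics import REFERENCE_CELSIUS
from .radiometry import relative_r_ir_ratio

__all__ = [
    "GenotypeArchetype",
    "HypocotylDataset",
    "builtin_archetypes",
    "generate",
    "DEFAULT_TEMPERATURES_C",
    "DEFAULT_N_PER_TEMP",
    "DEFAULT_NOISE_SD",
    "MIN_LENGTH_MM",
]

DEFAULT_TEMPERATURES_C = (4.0, 12.0, 16.0, 22.0, 28.0, 37.0)
DEFAULT_N_PER_TEMP = 15
DEFAULT_NOISE_SD = 0.5
MIN_LENGTH_MM = 0.1


@dataclass(frozen=True)
class GenotypeArchetype:
    """Generative linear response of one genotype: length = intercept + slope * r."""

    name: str
    slope: float
    intercept: float
    noise_sd: float = DEFAULT_NOISE_SD

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def mean_length(self, relative_r: float) -> float:
        return self.intercept + self.slope * relative_r

    def with_noise(self, noise_sd: float) -> "GenotypeArchetype":
        return replace(self, noise_sd=noise_sd)


# Published per-genotype fit equations, length (mm) vs relative R:IR ratio.
# The wild-type control was refit in each experiment, hence three Col-0-like
# presets with slightly different coefficients (kept separate on purpose).
_ARCHETYPES = (
    GenotypeArchetype("control", slope=-16.177, intercept=20.27),
    GenotypeArchetype("phyABCDE", slope=-7.2727, intercept=19.762),
    GenotypeArchetype("phyB-GFP", slope=-14.489, intercept=18.397),
    GenotypeArchetype("Col-0-YHB", slope=-14.879, intercept=18.705),
    GenotypeArchetype("YHB", slope=-1.5748, intercept=2.9523),
    GenotypeArchetype("Col-0", slope=-14.853, intercept=18.662),
    GenotypeArchetype("hy1", slope=-8.2234, intercept=18.489),
)


def builtin_archetypes() -> dict[str, GenotypeArchetype]:
    """The seven built-in genotype presets, keyed by name."""
    return {a.name: a for a in _ARCHETYPES}


@dataclass(frozen=True)
class HypocotylDataset:
    """Replicate hypocotyl lengths for one genotype across temperatures.

    Backed by a tidy frame with columns genotype, temperature_C, relative_r,
    replicate_index, length_mm; the generating seed rides along so any file
    written from the dataset is self-describing.
    """

    genotype: str
    data: pd.DataFrame
    seed: Optional[int] = None

    _COLUMNS = ("genotype", "temperature_C", "relative_r", "replicate_index", "length_mm")

    def __post_init__(self) -> None:
        missing = [c for c in self._COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"dataset frame missing column(s): {missing}")
        if (self.data["length_mm"] < MIN_LENGTH_MM - 1e-12).any():
            raise ValueError(f"lengths must be >= {MIN_LENGTH_MM} mm after truncation")

    def to_dataframe(self) -> pd.DataFrame:
        return self.data.copy()

    @property
    def temperatures_c(self) -> np.ndarray:
        return np.unique(self.data["temperature_C"].to_numpy())

    def mean_lengths(self) -> pd.DataFrame:
        """Per-temperature mean length with its relative R:IR ratio."""
        return (
            self.data.groupby(["temperature_C", "relative_r"], as_index=False)["length_mm"]
            .mean()
            .sort_values("temperature_C", ignore_index=True)
        )

    def to_csv(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        out = self.data.copy()
        out["seed"] = self.seed if self.seed is not None else ""
        out.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "HypocotylDataset":
        frame = pd.read_csv(path, float_precision="round_trip")
        seed_col = frame.pop("seed") if "seed" in frame.columns else None
        seed = None
        if seed_col is not None and seed_col.notna().any():
            seed = int(seed_col.iloc[0])
        genotypes = frame["genotype"].unique()
        if len(genotypes) != 1:
            raise ValueError(f"expected a single genotype per dataset file, got {list(genotypes)}")
        return cls(genotype=str(genotypes[0]), data=frame, seed=seed)


def generate(
    archetype: GenotypeArchetype,
    temperatures_c: Sequence[float] = DEFAULT_TEMPERATURES_C,
    n_per_temp: int = DEFAULT_N_PER_TEMP,
    seed: Optional[int] = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> HypocotylDataset:
    """Draw a seeded synthetic dataset for one genotype archetype.

    For each temperature T the relative R:IR ratio r = N_IR(22 degC)/N_IR(T)
    comes from the radiometry; ``n_per_temp`` lengths are drawn from
    Normal(intercept + slope * r, noise_sd^2), truncated below at 0.1 mm.
    Identical arguments and seed give an identical dataset.
    """
    if n_per_temp < 1:
        raise ValueError("n_per_temp must be at least 1")
    temps = [float(t) for t in temperatures_c]
    if not temps:
        raise ValueError("temperatures_c must be non-empty")
    rng = np.random.default_rng(seed)
    ref = Temperature.from_celsius(REFERENCE_CELSIUS)
    rows = []
    for temp_c in temps:
        r = relative_r_ir_ratio(ref, Temperature.from_celsius(temp_c), constants)
        mean = archetype.mean_length(r)
        draws = rng.normal(mean, archetype.noise_sd, size=n_per_temp)
        lengths = np.maximum(draws, MIN_LENGTH_MM)
        for i, length in enumerate(lengths):
            rows.append((archetype.name, temp_c, r, i, float(length)))
    frame = pd.DataFrame(rows, columns=list(HypocotylDataset._COLUMNS))
    return HypocotylDataset(genotype=archetype.name, data=frame, seed=seed)
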