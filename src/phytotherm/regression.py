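"""Linear regression stages of the photothermal analysis.

Two fits connect the physics to the biology:

* the log2 relative dark-reversion half-life of Pfr against temperature in
  degC, which is close to linear across the physiological range because the
  thermal IR photon flux at 10 um grows almost exponentially with T there;
* per-genotype hypocotyl length against the relative R:IR ratio
  r = N_IR(22 degC) / N_IR(T), the statistic phytochromes are proposed to
  monitor.  Wild-type seedlings elongate strongly as r falls (warm, IR-rich
  environments); phytochrome-null, constitutively-active-phyB and
  chromophore-deficient genotypes show reduced |slope|, i.e. reduced
  sensitivity to the ratio.

The hypocotyl stage follows the model/results idiom: build a
:class:`HypocotylResponseModel` from a tidy data frame (or generated
datasets), call :meth:`~HypocotylResponseModel.fit`, and read estimates,
standard errors and the sensitivity ranking off the returned
:class:`HypocotylResponseResults`, whose ``summary()`` prints a per-genotype
coefficient table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .constants import DEFAULT_CONSTANTS, PhysicalConstants, Temperature
from .kinetics import REFERENCE_CELSIUS, relative_half_life
from .radiometry import relative_r_ir_ratio

__all__ = [
    "RegressionResult",
    "HalfLifeSeries",
    "SensitivityReport",
    "fit_linear",
    "half_life_series",
    "half_life_regression",
    "HypocotylResponseModel",
    "HypocotylResponseResults",
    "hypocotyl_response_fit",
    "sensitivity_comparison",
]


@dataclass(frozen=True)
class RegressionResult:
    """Slope, intercept, coefficient of determination and size of a linear fit."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    slope_se: float = float("nan")

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a linear fit needs at least two points")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
            "slope_se": self.slope_se,
        }


def fit_linear(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares y = a + b x with R^2 as squared Pearson correlation.

    A constant predictor is a degenerate design and raises; a constant
    response returns slope 0 with R^2 = 0 by convention (and a warning),
    since the correlation is undefined there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if x.size < 2:
        raise ValueError("need at least two points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: predictor is constant")
    if np.ptp(y) == 0:
        warnings.warn("constant response: slope 0, R^2 defined as 0", stacklevel=2)
        return RegressionResult(0.0, float(y[0]), 0.0, int(x.size), 0.0)
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n=int(x.size),
        slope_se=float(res.stderr),
    )


@dataclass(frozen=True)
class HalfLifeSeries:
    """Relative Pfr dark-reversion half-lives across temperatures (22 degC == 1)."""

    temperatures_c: np.ndarray
    relative_half_lives: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "temperatures_c", np.asarray(self.temperatures_c, float))
        object.__setattr__(self, "relative_half_lives", np.asarray(self.relative_half_lives, float))

    @property
    def log2_values(self) -> np.ndarray:
        return np.log2(self.relative_half_lives)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature_C": self.temperatures_c,
                "relative_half_life": self.relative_half_lives,
                "log2_relative_half_life": self.log2_values,
            }
        )


DEFAULT_TEMPERATURES_C = (4.0, 12.0, 16.0, 22.0, 28.0, 37.0)


def half_life_series(
    temperatures_c: Sequence[float] = DEFAULT_TEMPERATURES_C,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> HalfLifeSeries:
    """Relative half-life at each temperature, referenced to 22 degC."""
    temps = np.asarray(temperatures_c, dtype=float)
    rel = np.array(
        [relative_half_life(Temperature.from_celsius(t), constants=constants) for t in temps]
    )
    return HalfLifeSeries(temps, rel)


def half_life_regression(
    temperatures_c: Sequence[float] = DEFAULT_TEMPERATURES_C,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> RegressionResult:
    """OLS of log2(relative half-life) on temperature in degC.

    The reference 22 degC must be among the temperatures, anchoring the
    relative scale at exactly 1 (log2 value 0).
    """
    temps = np.asarray(temperatures_c, dtype=float)
    if not np.any(np.isclose(temps, REFERENCE_CELSIUS)):
        raise ValueError(f"temperatures must include the {REFERENCE_CELSIUS} degC reference")
    series = half_life_series(temps, constants)
    return fit_linear(series.temperatures_c, series.log2_values)


# ---------------------------------------------------------------------------
# Hypocotyl response model


class HypocotylResponseModel:
    """Per-genotype linear response of hypocotyl length to the relative R:IR ratio.

    Parameters
    ----------
    data : pandas.DataFrame
        Tidy seedling table with columns ``genotype``, ``temperature_C``,
        ``relative_r`` and ``length_mm`` (one row per seedling).
    """

    REQUIRED_COLUMNS = ("genotype", "temperature_C", "relative_r", "length_mm")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"data is missing column(s): {missing}")
        if data.empty:
            raise ValueError("data is empty")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "HypocotylResponseModel":
        return cls(data)

    @classmethod
    def from_datasets(cls, datasets: Iterable) -> "HypocotylResponseModel":
        """Build from one or more :class:`~phytotherm.synthetic.HypocotylDataset`."""
        frames = [ds.to_dataframe() for ds in datasets]
        if not frames:
            raise ValueError("no datasets given")
        return cls(pd.concat(frames, ignore_index=True))

    @classmethod
    def from_temperatures(
        cls,
        lengths: Mapping[str, Mapping[float, Sequence[float]]],
        constants: PhysicalConstants = DEFAULT_CONSTANTS,
    ) -> "HypocotylResponseModel":
        """Build from ``{genotype: {temperature_C: [lengths_mm, ...]}}``,
        computing each temperature's relative R:IR ratio from the radiometry."""
        rows = []
        for genotype, by_temp in lengths.items():
            for temp_c, reps in by_temp.items():
                r = relative_r_ir_ratio(
                    Temperature.from_celsius(REFERENCE_CELSIUS),
                    Temperature.from_celsius(temp_c),
                    constants,
                )
                for length in reps:
                    rows.append((genotype, float(temp_c), r, float(length)))
        return cls(pd.DataFrame(rows, columns=list(cls.REQUIRED_COLUMNS)))

    def fit(self, aggregate: str = "mean") -> "HypocotylResponseResults":
        """Fit each genotype's length-vs-ratio line by OLS.

        aggregate="mean" (default) fits the per-temperature mean lengths, as
        response curves are usually plotted; "replicates" fits every seedling.
        """
        if aggregate not in ("mean", "replicates"):
            raise ValueError(f"unknown aggregate mode {aggregate!r}")
        fits: dict[str, RegressionResult] = {}
        for genotype, group in self.data.groupby("genotype", sort=True):
            if group["temperature_C"].nunique() < 2:
                raise ValueError(f"genotype {genotype!r} has fewer than two temperatures")
            if aggregate == "mean":
                per_temp = (
                    group.groupby(["temperature_C", "relative_r"], sort=True)["length_mm"]
                    .mean()
                    .reset_index()
                )
                x = per_temp["relative_r"].to_numpy()
                y = per_temp["length_mm"].to_numpy()
            else:
                x, y = group["relative_r"].to_numpy(), group["length_mm"].to_numpy()
            fits[str(genotype)] = fit_linear(x, y)
        return HypocotylResponseResults(model=self, fits=fits, aggregate=aggregate)


@dataclass
class HypocotylResponseResults:
    """Per-genotype OLS estimates of hypocotyl sensitivity to the R:IR ratio."""

    model: HypocotylResponseModel
    fits: Mapping[str, RegressionResult]
    aggregate: str

    def __getitem__(self, genotype: str) -> RegressionResult:
        return self.fits[genotype]

    def summary(self) -> pd.DataFrame:
        """Coefficient table: slope (mm per unit r), intercept (mm), R^2, n, slope SE."""
        rows = [
            {"genotype": g, **res.to_dict()} for g, res in sorted(self.fits.items())
        ]
        return pd.DataFrame(rows).set_index("genotype")

    def __str__(self) -> str:
        table = self.summary().to_string(float_format=lambda v: f"{v:.4f}")
        return (
            "Hypocotyl response to relative R:IR ratio "
            f"(OLS on {self.aggregate})\n{table}"
        )

    def sensitivity(
        self, reference: Optional[str] = None, threshold: float = 0.5
    ) -> "SensitivityReport":
        return sensitivity_comparison(self.fits, reference=reference, threshold=threshold)

    def to_json(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        payload = {g: res.to_dict() for g, res in sorted(self.fits.items())}
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path

    def to_csv(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        self.summary().to_csv(path)
        return path


def hypocotyl_response_fit(
    data, aggregate: str = "mean"
) -> Mapping[str, RegressionResult]:
    """One-call fit: accepts a DataFrame, a dataset, or an iterable of datasets."""
    if isinstance(data, pd.DataFrame):
        model = HypocotylResponseModel(data)
    elif hasattr(data, "to_dataframe"):
        model = HypocotylResponseModel(data.to_dataframe())
    else:
        model = HypocotylResponseModel.from_datasets(data)
    return model.fit(aggregate=aggregate).fits


@dataclass(frozen=True)
class SensitivityReport:
    """Genotypes ranked by |slope|, with reduced-sensitivity flags.

    A genotype is flagged when its |slope| falls below ``threshold`` times the
    reference genotype's |slope| (default: half of the steepest genotype).
    The cutoff is a reporting convention, not a biological constant.
    """

    ranking: tuple[str, ...]
    reference: str
    threshold: float
    reduced: tuple[str, ...]
    slopes: Mapping[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ranking": list(self.ranking),
            "reference": self.reference,
            "threshold": self.threshold,
            "reduced_sensitivity": list(self.reduced),
            "slopes": dict(self.slopes),
        }


def sensitivity_comparison(
    results: Mapping[str, RegressionResult],
    reference: Optional[str] = None,
    threshold: float = 0.5,
) -> SensitivityReport:
    """Rank genotypes by |slope| and flag those below ``threshold`` x reference |slope|."""
    if len(results) < 2:
        raise ValueError("sensitivity comparison needs at least two genotypes")
    slopes = {g: res.slope for g, res in results.items()}
    # stable, deterministic order: descending |slope|, name breaks ties
    ranking = tuple(sorted(slopes, key=lambda g: (-abs(slopes[g]), g)))
    ref = ranking[0] if reference is None else reference
    if ref not in slopes:
        raise KeyError(f"reference genotype {ref!r} not among results")
    cutoff = threshold * abs(slopes[ref])
    reduced = tuple(g for g in ranking if g != ref and abs(slopes[g]) < cutoff)
    return SensitivityReport(
        ranking=ranking, reference=ref, threshold=threshold, reduced=reduced, slopes=slopes
    )
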