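"""Core record and series containers shared across the estimation pipeline.

Rates are always deaths per 1000 livebirths; observation reference dates are
mid-year decimal years (e.g. 2004.5); estimate and death tables use those same
mid-year grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SOURCE_TYPES = ("VR", "SRS", "survey_FBH", "census_SBH")
INDICATORS = ("U5MR", "NMR")


@dataclass(frozen=True)
class ObservationRecord:
    """One country-year mortality datapoint with its error metadata.

    ``se_log`` is the sampling standard error on the log-rate scale; the
    systematic and non-sampling error components are what the estimation
    model infers per source type.
    """

    country: str
    reference_year: float
    value: float
    se_log: float
    series_id: str
    source_type: str
    indicator: str = "U5MR"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"{self.country} {self.reference_year}: value must be > 0")
        if self.se_log < 0:
            raise ValueError(f"{self.country} {self.reference_year}: se_log must be >= 0")
        if self.source_type not in SOURCE_TYPES:
            raise ValueError(f"unknown source_type {self.source_type!r}")
        if self.indicator not in INDICATORS:
            raise ValueError(f"unknown indicator {self.indicator!r}")
        if not 1900.0 <= self.reference_year <= 2100.0:
            raise ValueError(f"implausible reference_year {self.reference_year}")


@dataclass
class EstimateSeries:
    """Posterior summary of one country's rate trajectory (per 1000)."""

    country: str
    years: np.ndarray
    median: np.ndarray
    lower90: np.ndarray
    upper90: np.ndarray
    indicator: str = "U5MR"

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        self.median = np.asarray(self.median, dtype=float)
        self.lower90 = np.asarray(self.lower90, dtype=float)
        self.upper90 = np.asarray(self.upper90, dtype=float)
        if not (len(self.years) == len(self.median) == len(self.lower90) == len(self.upper90)):
            raise ValueError("years/median/lower90/upper90 lengths differ")
        if np.any(self.lower90 > self.median + 1e-12) or np.any(self.median > self.upper90 + 1e-12):
            raise ValueError("interval must bracket the median")
        if np.any(self.lower90 <= 0):
            raise ValueError("rates must be positive")

    def at(self, year: float) -> float:
        """Median rate at ``year`` (interpolated on the log scale)."""
        return float(np.exp(np.interp(year, self.years, np.log(self.median))))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "country": self.country,
                "indicator": self.indicator,
                "year": self.years,
                "median": self.median,
                "lower90": self.lower90,
                "upper90": self.upper90,
            }
        )


@dataclass
class LivebirthsSeries:
    """Annual livebirth counts for one country (calendar years)."""

    country: str
    years: np.ndarray
    births: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.births = np.asarray(self.births, dtype=float)
        if len(self.years) != len(self.births):
            raise ValueError("years/births lengths differ")
        if np.any(self.births <= 0):
            raise ValueError("births must be positive")

    def at(self, year: int) -> float:
        idx = np.where(self.years == int(year))[0]
        if len(idx) == 0:
            raise KeyError(f"{self.country}: no livebirths for {year}")
        return float(self.births[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"country": self.country, "year": self.years, "births": self.births})


def observations_to_frame(records: list[ObservationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "country": [r.country for r in records],
            "year": [r.reference_year for r in records],
            "indicator": [r.indicator for r in records],
            "value": [r.value for r in records],
            "se_log": [r.se_log for r in records],
            "series_id": [r.series_id for r in records],
            "source_type": [r.source_type for r in records],
        }
    )
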