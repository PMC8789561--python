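"""CSV and YAML interchange for the estimation pipeline.

All tables are plain CSV: observations (country, year, indicator, value,
se_log, series_id, source_type), livebirths (country, year, births),
estimates (country, indicator, year, median, lower90, upper90) and deaths
(country, year, age_group, median, lower90, upper90).  Rates are per 1000
livebirths; observation years are mid-year decimals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import EstimateSeries, LivebirthsSeries, ObservationRecord

OBS_COLUMNS = ["country", "year", "indicator", "value", "se_log", "series_id", "source_type"]


class ObservationFileError(ValueError):
    """Malformed observation file; message lists offending lines."""


def read_observations(path: str | Path) -> list[ObservationRecord]:
    """Read and validate an observation CSV.

    Malformed rows are reported with their (1-based, header-inclusive) line
    numbers; any malformed row fails the whole read.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ObservationFileError(f"{path}: missing columns {missing}")
    records, problems = [], []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            records.append(
                ObservationRecord(
                    country=str(row["country"]),
                    reference_year=float(row["year"]),
                    value=float(row["value"]),
                    se_log=float(row["se_log"]),
                    series_id=str(row["series_id"]),
                    source_type=str(row["source_type"]),
                    indicator=str(row["indicator"]),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise ObservationFileError(f"{path}: " + "; ".join(problems))
    return records


def write_observations(records: list[ObservationRecord], path: str | Path) -> None:
    from .records import observations_to_frame

    observations_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_livebirths(path: str | Path) -> dict[str, LivebirthsSeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = {}
    for c, sub in df.groupby("country"):
        sub = sub.sort_values("year")
        out[str(c)] = LivebirthsSeries(
            country=str(c), years=sub["year"].to_numpy(), births=sub["births"].to_numpy()
        )
    return out


def write_livebirths(series: dict[str, LivebirthsSeries], path: str | Path) -> None:
    pd.concat([s.to_frame() for s in series.values()], ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_estimates(path: str | Path) -> dict[str, EstimateSeries]:
    """Read an estimates CSV into per-country series (one indicator per file)."""
    df = pd.read_csv(path, float_precision="round_trip")
    out = {}
    for c, sub in df.groupby("country"):
        sub = sub.sort_values("year")
        out[str(c)] = EstimateSeries(
            country=str(c),
            years=sub["year"].to_numpy(),
            median=sub["median"].to_numpy(),
            lower90=sub["lower90"].to_numpy(),
            upper90=sub["upper90"].to_numpy(),
            indicator=str(sub["indicator"].iloc[0]),
        )
    return out


def write_estimates(series: dict[str, EstimateSeries], path: str | Path) -> None:
    pd.concat([s.to_frame() for s in series.values()], ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


@dataclass
class RunConfig:
    """One pipeline run: paths are derived from ``out_dir``; the seed feeds
    every stage's randomness and is recorded in output metadata."""

    out_dir: str = "run"
    seed: int = 0
    n_countries: int = 25
    estimate_years: tuple[float, float] = (1985.5, 2019.5)
    chains: int = 4
    warmup: int = 400
    samples: int = 500
    level: float = 0.90
    scenario: str = "all"
    report_precision: int = 1

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "estimate_years" in raw:
            raw["estimate_years"] = tuple(raw["estimate_years"])
        return cls(**raw)
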