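"""SDG progress classification and regional/global aggregation.

Countries are classified against a 2030 target from their 2019 estimate and
their 2010-19 annual rate of reduction (ARR): *achieved* if the 2019 rate is
already at or below the target, *on track* if the current-trends projection
reaches the target by 2030, otherwise *acceleration needed*, with the
acceleration factor (required ARR over current ARR) banded at the doubling
and tripling thresholds.  Death aggregates are computed on posterior draws
(sum the draws, then take quantiles — never sum quantiles), and group rates
are births-weighted means of member rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenarios import required_arr

#: floor on the current ARR when forming acceleration factors, so stagnating
#: countries get a finite factor (and land in the highest band)
ARR_EPS = 1e-6


@dataclass(frozen=True)
class ProgressStatus:
    country: str
    indicator: str
    status: str  # achieved | on_track | acceleration_needed
    acceleration_factor: float
    band: str  # "<2" | ">=2" | ">=3"
    achievement_year: str  # e.g. "2026" or ">2099"


@dataclass
class RegionMap:
    """Total partitions of the country set into regions and income groups."""

    region: dict[str, str]
    income: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.region) != set(self.income):
            raise ValueError("region and income maps must cover the same countries")

    def validate(self, countries: list[str]) -> None:
        missing = [c for c in countries if c not in self.region]
        if missing:
            raise KeyError(f"unmapped countries: {missing}")

    def groups(self, kind: str = "region") -> dict[str, list[str]]:
        mapping = self.region if kind == "region" else self.income
        out: dict[str, list[str]] = {}
        for c, g in mapping.items():
            out.setdefault(g, []).append(c)
        return out


def classify_progress(
    est_2019: float,
    arr_2010_19: float,
    target: float,
    country: str = "",
    indicator: str = "U5MR",
    horizon_year: int = 2030,
) -> ProgressStatus:
    """Classify one country-indicator against its 2030 target."""
    if not (np.isfinite(est_2019) and np.isfinite(arr_2010_19)):
        raise ValueError("inputs must be finite")
    span = horizon_year - 2019
    req = required_arr(est_2019, target, span=span) if est_2019 > target else 0.0
    if est_2019 <= target:
        status, factor = "achieved", 0.0
        year = str(2019)
    elif est_2019 * math.exp(-arr_2010_19 * span) <= target:
        status = "on_track"
        factor = req / max(arr_2010_19, ARR_EPS)
        year = str(2019 + math.ceil(math.log(est_2019 / target) / arr_2010_19))
    else:
        status = "acceleration_needed"
        factor = req / max(arr_2010_19, ARR_EPS)
        if arr_2010_19 <= 0:
            year = ">2099"
        else:
            horizon = math.log(est_2019 / target) / arr_2010_19
            year = str(2019 + math.ceil(horizon)) if horizon <= 80 else ">2099"
    band = ">=3" if factor >= 3 else (">=2" if factor >= 2 else "<2")
    return ProgressStatus(
        country=country,
        indicator=indicator,
        status=status,
        acceleration_factor=factor,
        band=band,
        achievement_year=year,
    )


def progress_table(statuses: list[ProgressStatus]) -> pd.DataFrame:
    df = pd.DataFrame([s.__dict__ for s in statuses])
    return df


def aggregate_deaths(
    deaths_draws: dict[str, np.ndarray],
    grouping: dict[str, str],
    level: float = 0.90,
) -> dict[str, dict[str, np.ndarray]]:
    """Aggregate per-country death draws to groups.

    ``deaths_draws`` maps country to an (n_draws, ...) array; draws are
    summed within each group cell-wise and quantiles are taken on the summed
    draws.  Returns per group: ``{"median": ..., "lower90": ..., "upper90":
    ..., "draws": summed draws}``.
    """
    unmapped = [c for c in deaths_draws if c not in grouping]
    if unmapped:
        raise KeyError(f"unmapped countries: {unmapped}")
    a = (1 - level) / 2
    sums: dict[str, np.ndarray] = {}
    for c, d in deaths_draws.items():
        g = grouping[c]
        sums[g] = sums.get(g, 0) + np.asarray(d, dtype=float)
    out = {}
    for g, d in sums.items():
        out[g] = {
            "median": np.quantile(d, 0.5, axis=0),
            "lower90": np.quantile(d, a, axis=0),
            "upper90": np.quantile(d, 1 - a, axis=0),
            "draws": d,
        }
    return out


def aggregate_rate(
    rates: dict[str, np.ndarray], births: dict[str, np.ndarray]
) -> np.ndarray:
    """Births-weighted group rate.

    A convex combination of member rates, so the group rate always lies
    between the member minimum and maximum; it approximates the rate that
    would reproduce the group's cohort deaths from the group's births (exact
    when member rates are equal, and within the cohort model's nonlinearity —
    a relative error below ~u5mr/1000 — otherwise).
    """
    countries = sorted(rates)
    r = np.array([np.asarray(rates[c], dtype=float) for c in countries])
    b = np.array([np.asarray(births[c], dtype=float) for c in countries])
    return (r * b).sum(axis=0) / b.sum(axis=0)


def percent_decline(v_start: float, v_end: float) -> int:
    """Percent decrease between two values, display-rounded to an integer."""
    if v_start <= 0:
        raise ValueError("v_start must be positive")
    return int(round(100.0 * (1.0 - v_end / v_start)))


def share_percent(part: float, total: float) -> int:
    """Integer percent share of a total."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(round(100.0 * part / total))


def one_in_n(rate_per_1000: float) -> int:
    """'One in N children' equivalent of a rate per 1000."""
    if rate_per_1000 <= 0:
        raise ValueError("rate must be positive")
    return int(round(1000.0 / rate_per_1000))


def fold_ratio(rate_a: float, rate_b: float) -> int:
    """How many times larger rate_a is than rate_b, display-rounded."""
    if rate_b <= 0:
        raise ValueError("rate_b must be positive")
    return int(round(rate_a / rate_b))
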