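"""Scenario-based projection of mortality rates and deaths, 2020-2030.

Four scenarios are projected from the 2019 estimates:

* ``constant_2019`` — rates held flat at their 2019 level;
* ``current_trends`` — exponential decline at each country's 2010-19 annual
  rate of reduction (ARR), held flat instead if that ARR is negative, and
  clamped at the lowest observed rates (U5MR 1.7, NMR 0.85 per 1000) once
  reached;
* ``achieve_sdg`` — countries not already at or on track for the SDG targets
  (U5MR 25, NMR 12 per 1000 by 2030) follow the constant required ARR that
  lands exactly on the target in 2030; the rest keep their current-trends
  path;
* ``achieve_hic`` — likewise with the 2019 high-income-country average
  levels (U5MR 5.0, NMR 2.9 per 1000) as the target.

Projected NMR is additionally capped at 0.79 times projected U5MR each year
(the highest ratio observed in a country with reliable vital registration).
Deaths are computed with the birth-week cohort method using one shared
livebirths projection, so differences between scenarios are attributable to
mortality alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import build_mortality_schedule, compute_cohort_deaths, schedules_from_estimates
from .records import EstimateSeries, LivebirthsSeries

SCENARIO_NAMES = ("constant_2019", "current_trends", "achieve_sdg", "achieve_hic")


@dataclass(frozen=True)
class ScenarioConfig:
    """All floors, caps, targets and windows driving one scenario."""

    name: str
    arr_window: tuple[int, int] = (2010, 2019)
    u5mr_floor: float = 1.7
    nmr_floor: float = 0.85
    ratio_cap: float = 0.79
    sdg_u5mr: float = 25.0
    sdg_nmr: float = 12.0
    hic_u5mr: float = 5.0
    hic_nmr: float = 2.9
    horizon: tuple[int, int] = (2020, 2030)

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}; one of {SCENARIO_NAMES}")
        if not 0.0 < self.ratio_cap < 1.0:
            raise ValueError("ratio_cap must be in (0, 1)")
        if not (self.u5mr_floor < self.sdg_u5mr and self.nmr_floor < self.sdg_nmr):
            raise ValueError("floors must lie below targets")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.horizon[0], self.horizon[1] + 1)

    def target(self, indicator: str) -> float | None:
        if self.name == "achieve_sdg":
            return self.sdg_u5mr if indicator == "U5MR" else self.sdg_nmr
        if self.name == "achieve_hic":
            return self.hic_u5mr if indicator == "U5MR" else self.hic_nmr
        return None

    def floor(self, indicator: str) -> float:
        return self.u5mr_floor if indicator == "U5MR" else self.nmr_floor


def scenario(name: str, **overrides) -> ScenarioConfig:
    return ScenarioConfig(name=name, **overrides)


def compute_arr(rate_t1: float, rate_t2: float, t1: float, t2: float) -> float:
    """Annual rate of reduction, ln(rate_t1 / rate_t2) / (t2 - t1).

    Positive when the rate declines between t1 and t2 (t1 < t2).
    """
    if rate_t1 <= 0 or rate_t2 <= 0:
        raise ValueError("rates must be positive")
    if not t1 < t2:
        raise ValueError("t1 must precede t2")
    return float(np.log(rate_t1 / rate_t2) / (t2 - t1))


def required_arr(rate_2019: float, target: float, span: float = 11.0) -> float:
    """Constant ARR needed to reach ``target`` by 2030 from the 2019 level
    (zero if the target is already achieved)."""
    if rate_2019 <= 0:
        raise ValueError("rate_2019 must be positive")
    if rate_2019 <= target:
        return 0.0
    return float(np.log(rate_2019 / target) / span)


def _exp_path(est_2019: float, arr: float, years: np.ndarray, floor: float) -> np.ndarray:
    path = est_2019 * np.exp(-arr * (years - 2019))
    return np.maximum(path, floor)


def project_u5mr(
    est_2019: float, arr_2010_19: float, config: ScenarioConfig, indicator: str = "U5MR"
) -> np.ndarray:
    """Yearly projected rates over the horizon under ``config``'s rules."""
    if est_2019 <= 0:
        raise ValueError("est_2019 must be positive")
    years = config.years
    floor = config.floor(indicator)
    if config.name == "constant_2019":
        return np.full(len(years), est_2019)
    arr_eff = max(arr_2010_19, 0.0)
    current = _exp_path(est_2019, arr_eff, years, floor)
    if config.name == "current_trends":
        return current
    target = config.target(indicator)
    on_track = est_2019 <= target or current[-1] <= target
    if on_track:
        return current
    req = required_arr(est_2019, target, span=config.horizon[1] - 2019)
    return _exp_path(est_2019, req, years, floor)


def project_nmr(
    est_2019_nmr: float,
    arr_2010_19_nmr: float,
    u5mr_projection: np.ndarray,
    config: ScenarioConfig,
) -> np.ndarray:
    """NMR projection under the same rules, then capped at
    ``ratio_cap * U5MR`` year by year."""
    u5mr_projection = np.asarray(u5mr_projection, dtype=float)
    if len(u5mr_projection) != len(config.years):
        raise ValueError("u5mr projection misaligned with horizon")
    nmr = project_u5mr(est_2019_nmr, arr_2010_19_nmr, config, indicator="NMR")
    return np.minimum(nmr, config.ratio_cap * u5mr_projection)


@dataclass
class CountryProjection:
    country: str
    scenario: str
    years: np.ndarray
    u5mr: np.ndarray
    nmr: np.ndarray


def project_country(
    u5mr_est: EstimateSeries,
    nmr_est: EstimateSeries,
    config: ScenarioConfig,
    arr_adjustment: dict[int, float] | None = None,
) -> CountryProjection:
    """Project one country from its fitted estimate series.

    The 2010-19 ARR is computed from posterior-median rates; an optional
    ``arr_adjustment`` maps calendar years to rate decrements (per 1000)
    removed before the ARR is taken — the hook for excluding crisis mortality
    from the trend without modelling it here.
    """
    t1, t2 = config.arr_window

    def rate_at(est: EstimateSeries, year: int) -> float:
        r = est.at(year + 0.5)
        if arr_adjustment:
            r = max(r - arr_adjustment.get(year, 0.0), 1e-6)
        return r

    arr_u = compute_arr(rate_at(u5mr_est, t1), rate_at(u5mr_est, t2), t1, t2)
    arr_n = compute_arr(rate_at(nmr_est, t1), rate_at(nmr_est, t2), t1, t2)
    u_path = project_u5mr(u5mr_est.at(t2 + 0.5), arr_u, config)
    n_path = project_nmr(nmr_est.at(t2 + 0.5), arr_n, u_path, config)
    return CountryProjection(
        country=u5mr_est.country,
        scenario=config.name,
        years=config.years,
        u5mr=u_path,
        nmr=n_path,
    )


def project_deaths(
    projections: dict[str, CountryProjection],
    livebirths: dict[str, LivebirthsSeries],
    u5mr_estimates: dict[str, EstimateSeries],
    nmr_estimates: dict[str, EstimateSeries],
) -> pd.DataFrame:
    """Death counts 2020-2030 per country for one scenario.

    Pre-horizon exposure (cohorts born 2015-2019) uses the fitted estimate
    medians; the horizon uses the projected rates.  All scenarios must be
    given the same ``livebirths``, so averted-death comparisons isolate
    mortality.  Returns a tidy frame (country, year, age-group columns).
    """
    if set(projections) - set(livebirths):
        raise ValueError(f"countries without livebirths: {sorted(set(projections) - set(livebirths))}")
    frames = []
    for c, proj in projections.items():
        years_pre = np.arange(proj.years[0] - 5, proj.years[0])
        sched = schedules_from_estimates(u5mr_estimates[c], nmr_estimates[c], years_pre)
        sched += [
            build_mortality_schedule(float(u), float(n), year=int(y))
            for y, u, n in zip(proj.years, proj.u5mr, proj.nmr)
        ]
        table = compute_cohort_deaths(livebirths[c], sched, proj.years)
        table.insert(0, "country", c)
        table.insert(1, "scenario", proj.scenario)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def averted_deaths(deaths_a: pd.DataFrame, deaths_b: pd.DataFrame) -> float:
    """Cumulative under-5 deaths in scenario A minus scenario B over the
    common years (positive when B averts deaths relative to A)."""
    ya = deaths_a.groupby("year")["deaths_under5"].sum()
    yb = deaths_b.groupby("year")["deaths_under5"].sum()
    common = ya.index.intersection(yb.index)
    return float(ya[common].sum() - yb[common].sum())
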