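"""Birth-week cohort computation of death counts by age group.

Each annual birth cohort is split into 52 equal birth-week cohorts seeded at
week midpoints.  Every weekly cohort is stepped through its first five years
of life in 1/52-year increments against a piecewise-constant hazard schedule
with two age segments — neonatal (ages below 28/365.25 years) and
post-neonatal (up to exact age 5) — that varies by calendar year.  Any step
that crosses a calendar-year boundary or the neonatal age boundary is split
exactly at the boundary, so survival decrements integrate the hazard exactly
and deaths are allocated to the calendar year and age group in which they
occur.  Summing allocated deaths over cohorts gives the annual death counts;
the bookkeeping conserves each cohort (deaths + survivors at age 5 = cohort
size) to floating-point accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .records import EstimateSeries, LivebirthsSeries

#: neonatal age boundary, years
NEONATAL_YEARS = 28.0 / 365.25
WEEKS = 52
AGE_END = 5.0

AGE_GROUPS = ("neonatal", "1_59m", "under5")


@dataclass(frozen=True)
class AgeSchedule:
    """Piecewise-constant hazards (per year of exposure) for one calendar year."""

    year: int
    hazard_neonatal: float
    hazard_postneonatal: float

    def __post_init__(self) -> None:
        if self.hazard_neonatal < 0 or self.hazard_postneonatal < 0:
            raise ValueError("hazards must be non-negative")


def build_mortality_schedule(u5mr: float, nmr: float, year: int = 0) -> AgeSchedule:
    """Invert cohort probabilities (per 1000) into the two-segment hazards.

    Under a constant schedule a cohort exposed from birth dies by day 28 with
    probability nmr/1000 and by age 5 with probability u5mr/1000; the
    piecewise-constant hazards reproducing that are

        h_neo  = -ln(1 - nmr/1000) / (28/365.25)
        h_post = -ln((1 - u5mr/1000) / (1 - nmr/1000)) / (5 - 28/365.25)
    """
    if not 0.0 < nmr < u5mr < 1000.0:
        raise ValueError("need 0 < nmr < u5mr < 1000 (per 1000 livebirths)")
    h_neo = -np.log1p(-nmr / 1000.0) / NEONATAL_YEARS
    h_post = -np.log((1.0 - u5mr / 1000.0) / (1.0 - nmr / 1000.0)) / (AGE_END - NEONATAL_YEARS)
    return AgeSchedule(year=int(year), hazard_neonatal=float(h_neo),
                       hazard_postneonatal=float(h_post))


def hazard_array(u5mr: np.ndarray, nmr: np.ndarray) -> np.ndarray:
    """Vectorised schedule builder: (..., n_years) rates -> (..., n_years, 2)."""
    u5mr = np.asarray(u5mr, dtype=float)
    nmr = np.asarray(nmr, dtype=float)
    if np.any(nmr >= u5mr) or np.any(nmr <= 0) or np.any(u5mr >= 1000):
        raise ValueError("need 0 < nmr < u5mr < 1000")
    h_neo = -np.log1p(-nmr / 1000.0) / NEONATAL_YEARS
    h_post = -np.log((1.0 - u5mr / 1000.0) / (1.0 - nmr / 1000.0)) / (AGE_END - NEONATAL_YEARS)
    return np.stack([h_neo, h_post], axis=-1)


@lru_cache(maxsize=4)
def _segmentation(weeks: int = WEEKS) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-week exact segmentation of the first five years of life.

    Returns (durations, year_offsets, age_groups), each (weeks, n_seg):
    segments are the 1/52-year age steps split at calendar-year boundaries
    and at the neonatal age boundary.  The relative structure is identical
    for every birth year, so it is computed once.
    """
    grid = np.arange(weeks * 5 + 1) / weeks
    durs, offs, grps = [], [], []
    for w in range(1, weeks + 1):
        mid = (w - 0.5) / weeks  # birth time within the calendar year
        year_breaks = np.arange(1, 6) - mid  # ages at which the year increments
        breaks = np.union1d(grid, np.union1d(year_breaks, [NEONATAL_YEARS]))
        d = np.diff(breaks)
        m = (breaks[:-1] + breaks[1:]) / 2.0
        durs.append(d)
        offs.append(np.floor(mid + m).astype(np.int64))
        grps.append((m >= NEONATAL_YEARS).astype(np.int64))
    return np.array(durs), np.array(offs), np.array(grps)


def _deaths_engine(
    hazards: np.ndarray,
    sched_years: np.ndarray,
    births: dict[int, float],
    report_years: np.ndarray,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Core allocation loop.

    hazards: (n_draws, n_sched_years, 2); cohorts born in
    [min(report)-5, max(report)] are exposed; schedule years beyond the last
    available one are clamped to it (end-of-horizon truncation rule).
    Returns (deaths[(n_draws, n_report, 3)], per-cohort ledger DataFrame for
    draw 0 with deaths and survivors per birth cohort).
    """
    hazards = np.asarray(hazards, dtype=float)
    if hazards.ndim == 2:
        hazards = hazards[None]
    n_draws = hazards.shape[0]
    sched_years = np.asarray(sched_years, dtype=int)
    y0, y1 = int(sched_years[0]), int(sched_years[-1])
    if np.any(np.diff(sched_years) != 1):
        raise ValueError("schedule years must be consecutive")
    report_years = np.asarray(report_years, dtype=int)
    rep_index = {int(y): i for i, y in enumerate(report_years)}

    durs, offs, grps = _segmentation()
    out = np.zeros((n_draws, len(report_years), 3))
    ledger_rows = []
    birth_lo = int(report_years[0]) - 5
    birth_hi = int(report_years[-1])
    for Y in range(birth_lo, birth_hi + 1):
        if Y not in births:
            raise ValueError(f"missing livebirths for cohort year {Y}")
        cal = Y + offs  # (weeks, nseg) calendar year of each segment
        if cal.min() < y0:
            raise ValueError(f"missing mortality schedule for year {cal.min()}")
        yi = np.minimum(cal, y1) - y0
        h = hazards[:, yi, grps]  # (n_draws, weeks, nseg)
        cum = np.cumsum(h * durs, axis=-1)
        n0 = births[Y] / WEEKS
        surv = n0 * np.exp(-cum)
        prev = np.concatenate([np.full((n_draws, WEEKS, 1), n0), surv[..., :-1]], axis=-1)
        deaths = prev - surv
        # allocate to (report year, age group)
        in_rep = (cal >= report_years[0]) & (cal <= report_years[-1])
        ridx = np.searchsorted(report_years, cal)
        flat = (np.where(in_rep, ridx, 0) * 2 + grps).ravel()
        w_sel = in_rep.ravel()
        for d in range(n_draws):
            dd = deaths[d].ravel()
            binned = np.bincount(flat[w_sel], weights=dd[w_sel],
                                 minlength=len(report_years) * 2)
            binned = binned.reshape(len(report_years), 2)
            out[d, :, 0] += binned[:, 0]
            out[d, :, 1] += binned[:, 1]
        ledger_rows.append(
            {
                "birth_year": Y,
                "cohort_size": births[Y],
                "deaths": float(deaths[0].sum()),
                "survivors_age5": float(surv[0, :, -1].sum()),
            }
        )
    out[:, :, 2] = out[:, :, 0] + out[:, :, 1]
    return out, pd.DataFrame(ledger_rows)


def compute_cohort_deaths(
    livebirths: LivebirthsSeries,
    schedules: list[AgeSchedule],
    report_years: np.ndarray,
    return_ledger: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Annual deaths by age group for ``report_years``.

    ``schedules`` must cover every calendar year from five years before the
    first report year up to (at least) the last schedule year; later exposure
    years reuse the final schedule (truncation rule).  Livebirths must cover
    all contributing cohort years.  With ``return_ledger=True`` also returns
    the per-cohort conservation ledger (deaths + survivors per birth cohort).
    """
    report_years = np.asarray(report_years, dtype=int)
    sched = sorted(schedules, key=lambda s: s.year)
    years = np.array([s.year for s in sched])
    hz = np.array([[s.hazard_neonatal, s.hazard_postneonatal] for s in sched])
    births = {int(y): livebirths.at(int(y))
              for y in range(int(report_years[0]) - 5, int(report_years[-1]) + 1)}
    deaths, ledger = _deaths_engine(hz[None], years, births, report_years)
    table = pd.DataFrame(
        {
            "year": report_years,
            "deaths_neonatal": deaths[0, :, 0],
            "deaths_1_59m": deaths[0, :, 1],
            "deaths_under5": deaths[0, :, 2],
        }
    )
    return (table, ledger) if return_ledger else table


def deaths_uncertainty(
    u5mr_draws: np.ndarray,
    nmr_draws: np.ndarray,
    years: np.ndarray,
    livebirths: LivebirthsSeries,
    report_years: np.ndarray,
    level: float = 0.90,
    max_draws: int | None = 200,
    chunk: int = 50,
) -> pd.DataFrame:
    """Death-count uncertainty from rate posterior draws.

    Applies the birth-week cohort computation to each (U5MR, NMR) draw pair
    (livebirths held fixed, mirroring the convention that death intervals
    reflect rate uncertainty only) and summarises each year/age-group cell by
    its median and equal-tailed interval.  ``max_draws`` caps the number of
    draws used (evenly thinned) to bound runtime.
    """
    u5mr_draws = np.asarray(u5mr_draws, dtype=float)
    nmr_draws = np.asarray(nmr_draws, dtype=float)
    if u5mr_draws.shape != nmr_draws.shape:
        raise ValueError("draw matrices must be aligned")
    years = np.asarray(years, dtype=int)
    n = u5mr_draws.shape[0]
    if max_draws and n > max_draws:
        idx = np.linspace(0, n - 1, max_draws).astype(int)
        u5mr_draws, nmr_draws = u5mr_draws[idx], nmr_draws[idx]
        n = max_draws
    report_years = np.asarray(report_years, dtype=int)
    births = {int(y): livebirths.at(int(y))
              for y in range(int(report_years[0]) - 5, int(report_years[-1]) + 1)}
    hz = hazard_array(u5mr_draws, nmr_draws)  # (n, n_years, 2)
    pieces = []
    for i0 in range(0, n, chunk):
        d, _ = _deaths_engine(hz[i0 : i0 + chunk], years, births, report_years)
        pieces.append(d)
    deaths = np.concatenate(pieces, axis=0)  # (n, n_report, 3)
    a = (1 - level) / 2
    rows = []
    for gi, group in enumerate(AGE_GROUPS):
        for yi, yr in enumerate(report_years):
            cell = deaths[:, yi, gi]
            rows.append(
                {
                    "year": int(yr),
                    "age_group": group,
                    "median": float(np.quantile(cell, 0.5)),
                    "lower90": float(np.quantile(cell, a)),
                    "upper90": float(np.quantile(cell, 1 - a)),
                }
            )
    return pd.DataFrame(rows)


def schedules_from_estimates(
    u5mr: EstimateSeries, nmr: EstimateSeries, years: np.ndarray
) -> list[AgeSchedule]:
    """Median-rate schedules for the given calendar years (mid-year lookup)."""
    return [
        build_mortality_schedule(u5mr.at(y + 0.5), nmr.at(y + 0.5), year=int(y))
        for y in np.asarray(years, dtype=int)
    ]
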