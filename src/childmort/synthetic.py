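"""Synthetic multi-country worlds for exercising the estimation pipeline.

The generator emulates the statistical structure of a multi-source child
mortality database: each country has a smooth true under-5 mortality
trajectory (an exponential-decline mean path with spline-level random-walk
wiggle), a true neonatal trajectory derived through the global
ratio-versus-level relation, annual livebirths, and several overlapping
observation series whose values are the truth times a source-type-specific
error multiplier — a systematic bias component shared by the source type, a
per-series jitter, and log-normal sampling noise.  Some countries' series end
years before the estimation endpoint so that extrapolation is exercised.

Because the truth is drawn from the same model family the estimator assumes
(exp of a spline with random-walk coefficient increments), parameter-recovery
and interval-coverage experiments on these worlds are well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import LivebirthsSeries, ObservationRecord
from .splines import SplineBasis, build_spline_basis

#: neonatal age boundary in years
NEONATAL_YEARS = 28.0 / 365.25

# Global ratio relation log R = a + b log(U5MR) used to place true NMR below
# true U5MR; coefficients calibrated once to the published global rate pairs
# (93.0, 36.6) in 1990 and (37.7, 17.5) in 2019.
RATIO_INTERCEPT = 1.01
RATIO_SLOPE = -0.32

#: per-source-type error signatures: (mean bias multiplier, per-series bias
#: jitter SD on the log scale, sampling SD on the log scale, extra
#: non-sampling SD on the log scale)
SOURCE_SIGNATURES: dict[str, tuple[float, float, float, float]] = {
    "VR": (1.00, 0.000, 0.025, 0.010),
    "SRS": (1.00, 0.020, 0.040, 0.020),
    "survey_FBH": (0.97, 0.040, 0.070, 0.030),
    "census_SBH": (0.90, 0.060, 0.100, 0.050),
}


@dataclass(frozen=True)
class SourceSpec:
    """Error signature and coverage of one observation series."""

    source_type: str
    bias_multiplier: float
    extra_sd_log: float
    sampling_sd_log: float
    coverage_years: np.ndarray
    series_id: str = ""
    indicator: str = "U5MR"

    def __post_init__(self) -> None:
        if self.bias_multiplier <= 0:
            raise ValueError("bias_multiplier must be > 0")
        if self.extra_sd_log < 0 or self.sampling_sd_log < 0:
            raise ValueError("error SDs must be >= 0")
        if self.source_type == "VR" and abs(self.bias_multiplier - 1.0) > 1e-12:
            raise ValueError("VR series are unbiased by convention")


@dataclass
class TrueSchedule:
    """True mortality trajectories for one country (rates per 1000)."""

    country: str
    years: np.ndarray
    u5mr_true: np.ndarray
    nmr_true: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.u5mr_true <= 0) or np.any(self.nmr_true <= 0):
            raise ValueError("true rates must be positive")
        if np.any(self.nmr_true >= self.u5mr_true):
            raise ValueError("NMR must lie strictly below U5MR")

    def u5mr_at(self, year: float | np.ndarray) -> np.ndarray:
        return np.exp(np.interp(year, self.years, np.log(self.u5mr_true)))

    def nmr_at(self, year: float | np.ndarray) -> np.ndarray:
        return np.exp(np.interp(year, self.years, np.log(self.nmr_true)))


def ratio_from_u5mr(u5mr: np.ndarray, intercept: float = RATIO_INTERCEPT,
                    slope: float = RATIO_SLOPE) -> np.ndarray:
    """Expected ratio NMR/(U5MR−NMR) at a given U5MR level."""
    return np.exp(intercept + slope * np.log(u5mr))


def generate_true_trajectory(
    seed: int,
    country: str = "C01",
    years: np.ndarray | None = None,
    u5mr_start: float = 180.0,
    arr: float = 0.03,
    coef_noise_sd: float = 0.04,
    knot_spacing: float = 2.5,
    ratio_multiplier: float = 1.0,
    ratio_noise_sd: float = 0.02,
) -> TrueSchedule:
    """Draw one smooth true (U5MR, NMR) trajectory.

    The mean path is exponential decline from ``u5mr_start`` at the first year
    at annual rate ``arr``; spline coefficients are perturbed by independent
    increments of SD ``coef_noise_sd`` (random walk on the log scale).  With
    ``coef_noise_sd = 0`` the path is the exact exponential.  NMR is placed
    via the ratio relation, guaranteeing NMR < U5MR at every year.
    """
    if years is None:
        years = np.arange(1985.5, 2020.0)
    years = np.asarray(years, dtype=float)
    if years[-1] - years[0] < 20.0:
        raise ValueError("year range must span at least 20 years")
    rng = np.random.default_rng(seed)
    basis = build_spline_basis(years[0], years[-1], knot_spacing=knot_spacing)
    grev = basis.greville
    mean_coef = np.log(u5mr_start) - arr * (grev - years[0])
    coefs = mean_coef + np.cumsum(rng.normal(0.0, coef_noise_sd, size=len(grev)))
    # recentre so the starting level stays at u5mr_start on average
    coefs -= coefs[0] - mean_coef[0]
    log_u5mr = basis.design_matrix(years) @ coefs
    u5mr = np.exp(log_u5mr)
    log_p = np.cumsum(rng.normal(0.0, ratio_noise_sd, size=len(years)))
    log_p -= log_p.mean()
    ratio = ratio_from_u5mr(u5mr) * ratio_multiplier * np.exp(log_p)
    nmr = u5mr * ratio / (1.0 + ratio)
    return TrueSchedule(country=country, years=years, u5mr_true=u5mr, nmr_true=nmr)


def generate_observations(
    schedule: TrueSchedule,
    specs: list[SourceSpec],
    seed: int,
) -> list[ObservationRecord]:
    """Observe a true schedule through a set of error-prone series.

    Each observation is ``truth × bias_multiplier × exp(ε)`` with
    ``ε ~ Normal(0, sampling_sd² + extra_sd²)`` on the log scale; the reported
    ``se_log`` is the sampling component only, mirroring databases where
    sampling errors are published but non-sampling errors are not.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    rng = np.random.default_rng(seed)
    records: list[ObservationRecord] = []
    for j, spec in enumerate(specs):
        sid = spec.series_id or f"{schedule.country}-{spec.source_type}-{j}"
        truth = (
            schedule.nmr_at(spec.coverage_years)
            if spec.indicator == "NMR"
            else schedule.u5mr_at(spec.coverage_years)
        )
        total_sd = float(np.hypot(spec.sampling_sd_log, spec.extra_sd_log))
        eps = rng.normal(0.0, total_sd, size=len(spec.coverage_years)) if total_sd else 0.0
        values = truth * spec.bias_multiplier * np.exp(eps)
        for year, value in zip(np.atleast_1d(spec.coverage_years), np.atleast_1d(values)):
            records.append(
                ObservationRecord(
                    country=schedule.country,
                    reference_year=float(year),
                    value=float(value),
                    se_log=spec.sampling_sd_log,
                    series_id=sid,
                    source_type=spec.source_type,
                    indicator=spec.indicator,
                )
            )
    return records


def generate_livebirths(
    seed: int,
    country: str = "C01",
    years: np.ndarray | None = None,
    base: float = 100_000.0,
    growth: float = 0.01,
    noise_sd: float = 0.0,
) -> LivebirthsSeries:
    """Smoothly varying annual livebirths (compound growth plus optional
    random-walk wiggle), rounded to whole births."""
    if years is None:
        years = np.arange(1985, 2031)
    years = np.asarray(years, dtype=int)
    rng = np.random.default_rng(seed)
    wiggle = np.cumsum(rng.normal(0.0, noise_sd, size=len(years))) if noise_sd else 0.0
    births = np.round(base * np.exp(growth * (years - years[0]) + wiggle))
    return LivebirthsSeries(country=country, years=years, births=np.maximum(births, 1.0))


@dataclass
class World:
    """A full synthetic study area: truth, observations, livebirths."""

    schedules: dict[str, TrueSchedule]
    observations: list[ObservationRecord]
    livebirths: dict[str, LivebirthsSeries]
    specs: dict[str, list[SourceSpec]]

    @property
    def countries(self) -> list[str]:
        return sorted(self.schedules)

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for sched in self.schedules.values():
            rows.append(
                pd.DataFrame(
                    {
                        "country": sched.country,
                        "year": sched.years,
                        "u5mr_true": sched.u5mr_true,
                        "nmr_true": sched.nmr_true,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _country_series_plan(rng: np.random.Generator, u5mr_start: float,
                         years: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Decide which series observe a country: (source_type, coverage_years).

    Low-mortality countries are VR-only; higher-mortality countries mix
    sample registration, full-birth-history surveys and summary-birth-history
    censuses, with some series ending several years before the endpoint.
    """
    first, last = years[0], years[-1]
    plan: list[tuple[str, np.ndarray]] = []
    if u5mr_start < 25.0:
        plan.append(("VR", years.copy()))
        if rng.random() < 0.5:
            plan.append(("VR", years[: len(years) // 2].copy()))
        return plan
    # gap before the endpoint for ~40% of survey-reliant countries
    gap = float(rng.choice([0, 0, 0, 2, 4, 6, 8]))
    data_end = last - gap
    if rng.random() < 0.35:
        plan.append(("VR", years[years <= data_end].copy()))
    else:
        plan.append(("SRS", years[years <= data_end].copy()))
    n_surveys = rng.integers(1, 3)
    for _ in range(int(n_surveys)):
        svy_year = float(rng.uniform(first + 12, data_end))
        # retrospective direct estimates: annual points for ~12 years back
        pts = svy_year - np.arange(1.0, 13.0)
        plan.append(("survey_FBH", pts[pts >= first]))
    if rng.random() < 0.6:
        census_year = float(rng.uniform(first + 10, data_end))
        pts = census_year - np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        plan.append(("census_SBH", pts[pts >= first]))
    return plan


def generate_world(
    seed: int = 0,
    n_countries: int = 25,
    years: np.ndarray | None = None,
    birth_years: np.ndarray | None = None,
) -> World:
    """Generate the default study world.

    25 countries observed over mid-years 1985.5–2019.5 with 2–4 series each;
    U5MR starting levels span ~10–220 per 1000 and annual reduction rates
    0.5–5%/yr, covering the range over which the ratio relation and the
    scenario rules operate.  Deterministic given ``seed``.
    """
    if years is None:
        years = np.arange(1985.5, 2020.0)
    if birth_years is None:
        birth_years = np.arange(1985, 2031)
    root = np.random.SeedSequence(seed)
    country_seeds = root.spawn(n_countries)
    schedules: dict[str, TrueSchedule] = {}
    livebirths: dict[str, LivebirthsSeries] = {}
    specs: dict[str, list[SourceSpec]] = {}
    observations: list[ObservationRecord] = []
    for i, ss in enumerate(country_seeds):
        name = f"C{i + 1:02d}"
        rng = np.random.default_rng(ss)
        u5mr_start = float(np.exp(rng.uniform(np.log(10.0), np.log(220.0))))
        arr = float(rng.uniform(0.005, 0.05))
        ratio_mult = float(np.exp(rng.normal(0.0, 0.1)))
        sched = generate_true_trajectory(
            seed=rng.integers(2**31),
            country=name,
            years=years,
            u5mr_start=u5mr_start,
            arr=arr,
            ratio_multiplier=ratio_mult,
        )
        schedules[name] = sched
        livebirths[name] = generate_livebirths(
            seed=rng.integers(2**31),
            country=name,
            years=birth_years,
            base=float(np.exp(rng.uniform(np.log(2e4), np.log(2e6)))),
            growth=float(rng.uniform(-0.005, 0.025)),
        )
        plan = _country_series_plan(rng, u5mr_start, years)
        country_specs: list[SourceSpec] = []
        for j, (stype, cov) in enumerate(plan):
            mean_bias, jitter, samp_sd, extra_sd = SOURCE_SIGNATURES[stype]
            bias = 1.0 if stype == "VR" else float(mean_bias * np.exp(rng.normal(0.0, jitter)))
            country_specs.append(
                SourceSpec(
                    source_type=stype,
                    bias_multiplier=bias,
                    extra_sd_log=extra_sd,
                    sampling_sd_log=samp_sd,
                    coverage_years=np.asarray(cov, dtype=float),
                    series_id=f"{name}-{stype}-{j}",
                )
            )
            # NMR series ride along with every direct-estimation series
            # (summary birth histories cannot yield NMR)
            if stype != "census_SBH":
                country_specs.append(
                    SourceSpec(
                        source_type=stype,
                        bias_multiplier=bias,
                        extra_sd_log=extra_sd,
                        sampling_sd_log=samp_sd * 1.2,
                        coverage_years=np.asarray(cov, dtype=float),
                        series_id=f"{name}-{stype}-{j}-nmr",
                        indicator="NMR",
                    )
                )
        specs[name] = country_specs
        observations.extend(
            generate_observations(sched, country_specs, seed=int(rng.integers(2**31)))
        )
    return World(schedules=schedules, observations=observations,
                 livebirths=livebirths, specs=specs)
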