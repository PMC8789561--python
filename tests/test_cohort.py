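import numpy as np
import pytest

import childmort as cm
from childmort.cohort import (
    AGE_END,
    NEONATAL_YEARS,
    build_mortality_schedule,
    compute_cohort_deaths,
    deaths_uncertainty,
    hazard_array,
)
from childmort.records import LivebirthsSeries


def _const_world(u5mr, nmr, years=range(1980, 2021), births=100_000.0):
    lb = LivebirthsSeries("X", np.array(list(years)),
                          np.full(len(list(years)), births))
    sched = [build_mortality_schedule(u5mr, nmr, year=y) for y in years]
    return lb, sched


def test_schedule_inverts_cohort_probabilities():
    # constant exposure to the schedule reproduces the input probabilities
    s = build_mortality_schedule(37.7, 17.5)
    p_neo = 1.0 - np.exp(-s.hazard_neonatal * NEONATAL_YEARS)
    p_u5 = 1.0 - np.exp(
        -s.hazard_neonatal * NEONATAL_YEARS
        - s.hazard_postneonatal * (AGE_END - NEONATAL_YEARS)
    )
    assert p_neo == pytest.approx(0.0175, abs=1e-12)
    assert p_u5 == pytest.approx(0.0377, abs=1e-12)


def test_schedule_limits_and_domain():
    s = build_mortality_schedule(20.0 + 1e-9, 20.0, year=0)
    assert s.hazard_postneonatal == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        build_mortality_schedule(20.0, 20.0)
    with pytest.raises(ValueError):
        build_mortality_schedule(0.0, 0.0)


def test_zero_hazard_means_zero_deaths():
    lb = LivebirthsSeries("X", np.arange(1980, 2021), np.full(41, 100_000.0))
    sched = [cm.AgeSchedule(year=y, hazard_neonatal=0.0, hazard_postneonatal=0.0)
             for y in range(1980, 2021)]
    tab, ledger = compute_cohort_deaths(lb, sched, np.arange(1990, 2000),
                                        return_ledger=True)
    assert np.all(tab[["deaths_neonatal", "deaths_1_59m", "deaths_under5"]].to_numpy() == 0)
    assert np.allclose(ledger.survivors_age5, ledger.cohort_size)


def test_steady_state_matches_closed_form():
    """Constant schedule, constant births B: annual under-5 deaths equal
    B * U5MR/1000 and neonatal deaths B * NMR/1000 (within 0.2%)."""
    lb, sched = _const_world(50.0, 20.0)
    tab = compute_cohort_deaths(lb, sched, np.arange(1990, 2020))
    assert np.allclose(tab.deaths_under5, 5000.0, rtol=2e-3)
    assert np.allclose(tab.deaths_neonatal, 2000.0, rtol=2e-3)
    assert np.all(tab.deaths_under5 == tab.deaths_neonatal + tab.deaths_1_59m)


def test_cohort_conservation_to_machine_precision():
    lb, sched = _const_world(80.0, 30.0)
    _, ledger = compute_cohort_deaths(lb, sched, np.arange(1990, 2020),
                                      return_ledger=True)
    rel = (ledger.deaths + ledger.survivors_age5 - ledger.cohort_size).abs() / ledger.cohort_size
    assert rel.max() < 1e-9


def test_calendar_and_cohort_bookkeeping_agree():
    """Total deaths summed over calendar years equals total deaths summed
    over birth cohorts when the reporting window spans all exposure."""
    years = np.arange(1980, 2026)
    lb = LivebirthsSeries("X", years, np.full(len(years), 50_000.0))
    rng = np.random.default_rng(3)
    sched = [build_mortality_schedule(u, u * 0.4, year=y)
             for y, u in zip(years, rng.uniform(20, 90, len(years)))]
    # births only in 1995-1999 isolate five fully-observed cohorts
    lb2 = LivebirthsSeries("X", years,
                           np.where((years >= 1995) & (years <= 1999), 50_000.0, 1e-9))
    tab, ledger = compute_cohort_deaths(lb2, sched, np.arange(1995, 2006),
                                        return_ledger=True)
    cohorts = ledger[(ledger.birth_year >= 1995) & (ledger.birth_year <= 1999)]
    assert tab.deaths_under5.sum() == pytest.approx(cohorts.deaths.sum(), rel=1e-6)


def daily_microsim(lb, sched_by_year, report_years, steps_per_year=365):
    """Brute-force daily-resolution oracle: 52 weekly cohorts aged day by
    day against the same piecewise-constant hazards."""
    dt = 1.0 / steps_per_year
    deaths = {(y, g): 0.0 for y in report_years for g in (0, 1)}
    y_last = max(sched_by_year)
    for Y in range(min(report_years) - 5, max(report_years) + 1):
        n0 = lb.at(Y) / 52.0
        for w in range(1, 53):
            t0 = Y + (w - 0.5) / 52.0
            ages = dt * np.arange(int(AGE_END / dt))
            times = t0 + ages
            cal = np.minimum(np.floor(times).astype(int), y_last)
            grp = (ages + dt / 2 >= NEONATAL_YEARS).astype(int)
            h = np.array([
                sched_by_year[c].hazard_neonatal if g == 0
                else sched_by_year[c].hazard_postneonatal
                for c, g in zip(cal, grp)
            ])
            surv = n0 * np.exp(-np.cumsum(h * dt))
            prev = np.concatenate([[n0], surv[:-1]])
            d = prev - surv
            for yy, gg, dd in zip(np.floor(times).astype(int), grp, d):
                if (yy, gg) in deaths:
                    deaths[(yy, gg)] += dd
    return deaths


def test_agrees_with_daily_resolution_microsimulation():
    """3-year toy world with time-varying hazards: weekly-step allocation
    within 0.5% of a 1/365-step microsimulation."""
    years = np.arange(1993, 2004)
    lb = LivebirthsSeries("X", years, 80_000.0 * 1.01 ** (years - years[0]))
    rates = {y: (40.0 + 3.0 * (y - 1993), 16.0 + 1.0 * (y - 1993)) for y in years}
    sched = {y: build_mortality_schedule(*rates[y], year=y) for y in years}
    report = np.arange(2000, 2003)
    tab = compute_cohort_deaths(lb, list(sched.values()), report)
    oracle = daily_microsim(lb, sched, report)
    for i, y in enumerate(report):
        assert tab.deaths_neonatal.iloc[i] == pytest.approx(oracle[(y, 0)], rel=5e-3)
        assert tab.deaths_1_59m.iloc[i] == pytest.approx(oracle[(y, 1)], rel=5e-3)


def test_uncertainty_degenerate_and_linearity():
    years = np.arange(1985, 2020)
    u5 = np.full((30, len(years)), 50.0)
    nm = np.full((30, len(years)), 20.0)
    lb = LivebirthsSeries("X", years, np.full(len(years), 100_000.0))
    report = np.arange(1995, 2000)
    tab = deaths_uncertainty(u5, nm, years, lb, report)
    assert np.allclose(tab.lower90, tab.upper90)  # degenerate posterior: zero width
    lb2 = LivebirthsSeries("X", years, np.full(len(years), 200_000.0))
    tab2 = deaths_uncertainty(u5, nm, years, lb2, report)
    assert np.allclose(tab2["median"], 2.0 * tab["median"])  # homogeneous in births


def test_uncertainty_tracks_rate_quantiles_monotonically():
    rng = np.random.default_rng(1)
    years = np.arange(1985, 2020)
    base = rng.uniform(30, 70, size=(200, 1))
    u5 = np.broadcast_to(base, (200, len(years))).copy()
    nm = u5 * 0.4
    lb = LivebirthsSeries("X", years, np.full(len(years), 100_000.0))
    report = np.arange(2000, 2003)
    tab = deaths_uncertainty(u5, nm, years, lb, report, max_draws=None)
    u5_q = np.quantile(base, [0.05, 0.95])
    d = tab[tab.age_group == "under5"]
    # deaths are monotone in the (constant) rate draw, so death quantiles
    # match the deaths computed at the rate quantiles
    lo = compute_cohort_deaths(
        lb, [build_mortality_schedule(u5_q[0], 0.4 * u5_q[0], y) for y in years], report
    )
    hi = compute_cohort_deaths(
        lb, [build_mortality_schedule(u5_q[1], 0.4 * u5_q[1], y) for y in years], report
    )
    assert np.allclose(d.lower90.to_numpy(), lo.deaths_under5.to_numpy(), rtol=0.02)
    assert np.allclose(d.upper90.to_numpy(), hi.deaths_under5.to_numpy(), rtol=0.02)


def test_missing_schedule_year_fails():
    lb = LivebirthsSeries("X", np.arange(1980, 2021), np.full(41, 1000.0))
    sched = [build_mortality_schedule(50.0, 20.0, year=y) for y in range(1990, 2021)]
    with pytest.raises(ValueError, match="missing mortality schedule"):
        compute_cohort_deaths(lb, sched, np.arange(1990, 2000))
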