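import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import childmort as cm
from childmort.cohort import build_mortality_schedule, compute_cohort_deaths
from childmort.records import EstimateSeries, LivebirthsSeries
from childmort.scenarios import (
    ScenarioConfig,
    averted_deaths,
    compute_arr,
    project_country,
    project_nmr,
    project_u5mr,
    required_arr,
)


def test_arr_reproduces_published_global_paces():
    # 93.0 -> 37.7 over 1990-2019: 3.1%/yr; 36.6 -> 17.5: 2.5%/yr
    assert round(100 * compute_arr(93.0, 37.7, 1990, 2019), 1) == 3.1
    assert round(100 * compute_arr(36.6, 17.5, 1990, 2019), 1) == 2.5
    assert compute_arr(40.0, 40.0, 2000, 2010) == 0.0
    with pytest.raises(ValueError):
        compute_arr(-1.0, 5.0, 2000, 2010)
    with pytest.raises(ValueError):
        compute_arr(5.0, 5.0, 2010, 2000)


def test_required_arr_closed_forms():
    assert required_arr(25.0, 25.0) == 0.0
    assert required_arr(50.0, 25.0) == pytest.approx(np.log(2) / 11)
    assert required_arr(20.0, 25.0) == 0.0  # already achieved


@settings(deadline=None, max_examples=50)
@given(rate=st.floats(2.0, 300.0), arr=st.floats(0.0, 0.1), k=st.integers(1, 10))
def test_arr_round_trip_to_machine_precision(rate, arr, k):
    cfg = ScenarioConfig(name="current_trends", u5mr_floor=1e-6, nmr_floor=1e-7)
    path = project_u5mr(rate, arr, cfg)
    assert compute_arr(path[0], path[k], 2020, 2020 + k) == pytest.approx(arr, abs=1e-12)


def test_constant_scenario_is_flat():
    cfg = ScenarioConfig(name="constant_2019")
    np.testing.assert_array_equal(project_u5mr(40.0, 0.05, cfg), 40.0)


def test_current_trends_floor_activation():
    """A fast-declining low-mortality country hits the 1.7 floor and stays there."""
    cfg = ScenarioConfig(name="current_trends")
    path = project_u5mr(2.0, 0.10, cfg)
    unfloored = 2.0 * np.exp(-0.10 * (cfg.years - 2019))
    crossing = unfloored < 1.7
    assert crossing.any()
    np.testing.assert_allclose(path[crossing], 1.7)
    np.testing.assert_allclose(path[~crossing], unfloored[~crossing])
    # negative ARR: held constant at the 2019 level
    np.testing.assert_array_equal(project_u5mr(40.0, -0.02, cfg), 40.0)


def test_sdg_path_hits_target_exactly_in_2030():
    cfg = ScenarioConfig(name="achieve_sdg")
    path = project_u5mr(50.0, 0.01, cfg)  # not on track
    assert path[-1] == pytest.approx(25.0, abs=1e-12)
    nmr_path = project_nmr(30.0, 0.0, np.full(11, 60.0), cfg)
    assert nmr_path[-1] == pytest.approx(12.0, abs=1e-12)


def test_on_track_countries_keep_current_trends():
    cfg = ScenarioConfig(name="achieve_sdg")
    ct = ScenarioConfig(name="current_trends")
    # 30 * exp(-0.05*11) = 17.3 <= 25: on track
    np.testing.assert_array_equal(project_u5mr(30.0, 0.05, cfg),
                                  project_u5mr(30.0, 0.05, ct))
    # already achieved
    np.testing.assert_array_equal(project_u5mr(20.0, 0.02, cfg),
                                  project_u5mr(20.0, 0.02, ct))


def test_nmr_ratio_cap():
    cfg = ScenarioConfig(name="constant_2019")
    u5 = np.full(11, 40.0)
    # flat NMR 10 with U5MR 40: cap 31.6 inactive
    np.testing.assert_array_equal(project_nmr(10.0, 0.0, u5, cfg), 10.0)
    # NMR level that would exceed 0.79*U5MR is capped there
    capped = project_nmr(38.0, 0.0, u5, cfg)
    np.testing.assert_allclose(capped, 0.79 * 40.0)


def test_scenario_ordering_invariant():
    """achieve_hic <= achieve_sdg <= current_trends <= constant_2019 for a
    declining country above the HIC level."""
    paths = {
        name: project_u5mr(80.0, 0.02, ScenarioConfig(name=name))
        for name in cm.scenarios.SCENARIO_NAMES
    }
    assert np.all(paths["achieve_hic"] <= paths["achieve_sdg"] + 1e-12)
    assert np.all(paths["achieve_sdg"] <= paths["current_trends"] + 1e-12)
    assert np.all(paths["current_trends"] <= paths["constant_2019"] + 1e-12)


def _toy_estimates(u5mr=50.0, nmr=20.0):
    years = np.arange(1985.5, 2020.0)
    mk = lambda v, ind: EstimateSeries(
        country="X", years=years, median=np.full(len(years), v),
        lower90=np.full(len(years), v * 0.95), upper90=np.full(len(years), v * 1.05),
        indicator=ind,
    )
    return {"X": mk(u5mr, "U5MR")}, {"X": mk(nmr, "NMR")}


def test_projected_deaths_steady_state_closed_form():
    """Births 100k/yr at constant U5MR 50: cumulative 2020-30 under-5 deaths
    approximate 11 * 5000 = 55 000 within 1%."""
    u5, nm = _toy_estimates()
    lb = {"X": LivebirthsSeries("X", np.arange(1985, 2031), np.full(46, 100_000.0))}
    cfg = ScenarioConfig(name="constant_2019")
    proj = {"X": project_country(u5["X"], nm["X"], cfg)}
    deaths = cm.project_deaths(proj, lb, u5, nm)
    assert deaths.deaths_under5.sum() == pytest.approx(55_000, rel=0.01)


def test_identical_scenarios_avert_nothing_and_constant_dominates():
    u5, nm = _toy_estimates()
    # gentle decline so current-trends differs from constant
    years = u5["X"].years
    med = 50.0 * np.exp(-0.02 * (years - years[0]))
    u5d = {"X": EstimateSeries(country="X", years=years, median=med,
                               lower90=med * 0.95, upper90=med * 1.05)}
    nmd = {"X": EstimateSeries(country="X", years=years, median=med * 0.4,
                               lower90=med * 0.38, upper90=med * 0.42,
                               indicator="NMR")}
    lb = {"X": LivebirthsSeries("X", np.arange(1985, 2031), np.full(46, 100_000.0))}
    const = cm.project_deaths(
        {"X": project_country(u5d["X"], nmd["X"], ScenarioConfig(name="constant_2019"))},
        lb, u5d, nmd)
    current = cm.project_deaths(
        {"X": project_country(u5d["X"], nmd["X"], ScenarioConfig(name="current_trends"))},
        lb, u5d, nmd)
    assert averted_deaths(const, const) == 0.0
    assert averted_deaths(const, current) > 0.0  # positive ARR: constant has more deaths


def test_unknown_scenario_and_bad_inputs_rejected():
    with pytest.raises(ValueError, match="unknown scenario"):
        ScenarioConfig(name="optimistic")
    cfg = ScenarioConfig(name="current_trends")
    with pytest.raises(ValueError):
        project_u5mr(-5.0, 0.02, cfg)
    with pytest.raises(ValueError, match="misaligned"):
        project_nmr(10.0, 0.0, np.full(5, 40.0), cfg)
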