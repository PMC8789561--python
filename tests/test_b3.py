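import numpy as np
import pytest

import childmort as cm
from childmort.b3 import MCMCConfig, PosteriorU5MR
from childmort.synthetic import SourceSpec


def _vr_spec(years, sd=0.01):
    return SourceSpec(source_type="VR", bias_multiplier=1.0, sampling_sd_log=sd,
                      extra_sd_log=0.0, coverage_years=np.asarray(years, dtype=float))


def test_dense_unbiased_recovery(small_mcmc):
    """Dense low-noise VR observations pin the posterior to the truth."""
    sched = cm.generate_true_trajectory(seed=2, u5mr_start=80.0, arr=0.03)
    obs = cm.generate_observations(sched, [_vr_spec(sched.years)], seed=4)
    basis = cm.build_spline_basis(sched.years[0], sched.years[-1])
    fit = cm.fit_b3(obs, basis, mcmc=small_mcmc, seed=0)
    post = fit[sched.country]
    med = np.median(post.draws, axis=0)
    truth = np.log(sched.u5mr_at(post.years))
    assert np.max(np.abs(med - truth)) < 0.05


def test_bias_recovery_against_vr_anchor(small_mcmc):
    """A source observing at 0.8x the truth earns a negative mean bias near log 0.8."""
    sched = cm.generate_true_trajectory(seed=9, u5mr_start=100.0, arr=0.02)
    biased = SourceSpec(source_type="survey_FBH", bias_multiplier=0.8,
                        sampling_sd_log=0.05, extra_sd_log=0.0,
                        coverage_years=sched.years.copy())
    obs = cm.generate_observations(sched, [_vr_spec(sched.years), biased], seed=5)
    basis = cm.build_spline_basis(sched.years[0], sched.years[-1])
    fit = cm.fit_b3(obs, basis, mcmc=small_mcmc, seed=0)
    b = float(fit.bias_draws["survey_FBH"].mean())
    assert b < 0
    assert abs(b - np.log(0.8)) < 0.5 * abs(np.log(0.8))


def test_single_observation_interval_contains_it():
    rec = cm.ObservationRecord(country="X", reference_year=2005.5, value=40.0,
                               se_log=0.05, series_id="s", source_type="VR")
    basis = cm.build_spline_basis(1995.5, 2015.5)
    fit = cm.fit_b3([rec], basis, mcmc=MCMCConfig(chains=4, warmup=200, samples=300),
                    seed=0)
    est = cm.summarize_posterior(fit["X"])
    i = np.argmin(np.abs(est.years - 2005.5))
    assert est.lower90[i] <= 40.0 <= est.upper90[i]


def test_scale_equivariance(small_mcmc):
    """Multiplying all observations by k shifts the posterior median log rate by log k."""
    sched = cm.generate_true_trajectory(seed=2, u5mr_start=60.0, arr=0.02)
    obs = cm.generate_observations(sched, [_vr_spec(sched.years, sd=0.03)], seed=1)
    k = 2.0
    scaled = [
        cm.ObservationRecord(country=r.country, reference_year=r.reference_year,
                             value=k * r.value, se_log=r.se_log,
                             series_id=r.series_id, source_type=r.source_type)
        for r in obs
    ]
    basis = cm.build_spline_basis(sched.years[0], sched.years[-1])
    m1 = np.median(cm.fit_b3(obs, basis, mcmc=small_mcmc, seed=3)[sched.country].draws, axis=0)
    m2 = np.median(cm.fit_b3(scaled, basis, mcmc=small_mcmc, seed=3)[sched.country].draws, axis=0)
    np.testing.assert_allclose(m2 - m1, np.log(k), atol=0.02)


def _lognormal_posterior(mu=3.0, sigma=0.2, n=200_000, seed=0):
    rng = np.random.default_rng(seed)
    draws = rng.normal(mu, sigma, size=(n, 1))
    return PosteriorU5MR(country="X", years=np.array([2000.5]), draws=draws,
                         innovation_sd=np.zeros(n))


def test_summary_matches_lognormal_quantile_oracle():
    mu, sigma = 3.0, 0.2
    est = cm.summarize_posterior(_lognormal_posterior(mu, sigma))
    z = 1.6448536269514722
    assert abs(est.median[0] - np.exp(mu)) / np.exp(mu) < 0.01
    assert abs(est.lower90[0] - np.exp(mu - z * sigma)) / np.exp(mu - z * sigma) < 0.01
    assert abs(est.upper90[0] - np.exp(mu + z * sigma)) / np.exp(mu + z * sigma) < 0.01


def test_summary_degenerate_and_nesting():
    post = PosteriorU5MR(country="X", years=np.array([2000.5]),
                         draws=np.full((50, 1), np.log(40.0)),
                         innovation_sd=np.zeros(50))
    est = cm.summarize_posterior(post)
    assert est.median[0] == est.lower90[0] == est.upper90[0] == pytest.approx(40.0)
    ln = _lognormal_posterior()
    wide = cm.summarize_posterior(ln, level=0.9)
    narrow = cm.summarize_posterior(ln, level=0.5)
    assert narrow.upper90[0] - narrow.lower90[0] < wide.upper90[0] - wide.lower90[0]


def _flat_posterior(rate=50.0, n=500, years=None):
    years = years if years is not None else np.arange(2000.5, 2015.0)
    draws = np.full((n, len(years)), np.log(rate))
    return PosteriorU5MR(country="X", years=years, draws=draws,
                         innovation_sd=np.full(n, 0.02))


def test_extrapolation_degenerate_blends():
    rate = 50.0
    years = np.arange(2000.5, 2015.0)
    decline = np.log(rate) - 0.04 * (years - years[0])
    post = PosteriorU5MR(country="X", years=years,
                         draws=np.tile(decline, (100, 1)),
                         innovation_sd=np.zeros(100))
    # full weight on the country trend: exact continuation at 4%/yr
    ext = cm.extrapolate(post, global_arr=0.01, horizon_end=2019.5, rho=1.0,
                         innovation_sd=0.0)
    np.testing.assert_allclose(
        ext.draws[0, -5:], decline[-1] - 0.04 * np.arange(1, 6), atol=1e-12
    )
    # full weight on the global trend
    ext_g = cm.extrapolate(post, global_arr=0.01, horizon_end=2019.5, rho=0.0,
                           innovation_sd=0.0)
    np.testing.assert_allclose(
        ext_g.draws[0, -5:], decline[-1] - 0.01 * np.arange(1, 6), atol=1e-12
    )


def test_extrapolation_widens_interval():
    rng = np.random.default_rng(0)
    years = np.arange(2000.5, 2015.0)
    draws = np.log(50.0) + rng.normal(0, 0.03, size=(400, 1)) - 0.02 * (years - years[0])
    post = PosteriorU5MR(country="X", years=years, draws=draws,
                         innovation_sd=np.full(400, 0.02))
    ext = cm.extrapolate(post, global_arr=0.02, horizon_end=2024.5, seed=1)
    est = cm.summarize_posterior(ext)
    width = np.log(est.upper90) - np.log(est.lower90)
    last_obs = np.argmin(np.abs(ext.years - 2014.5))
    assert width[-1] >= width[last_obs]


def test_fit_requires_observations():
    basis = cm.build_spline_basis(1990.5, 2019.5)
    with pytest.raises(ValueError):
        cm.fit_b3([], basis)
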