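"""End-to-end pipeline stages: simulate, fit, project, report.

Each stage reads and writes plain CSV files under a run directory so that the
chain can be driven from the command line or from Python.  Stages log their
seed and settings to stderr and record them in a small metadata YAML.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .b3 import B3Fit, MCMCConfig, PosteriorU5MR, extrapolate, fit_b3, summarize_posterior
from .cohort import deaths_uncertainty
from .io import (
    RunConfig,
    read_estimates,
    read_livebirths,
    read_observations,
    write_estimates,
    write_livebirths,
    write_observations,
)
from .nmr import derive_nmr, fit_country_multiplier, fit_global_relation, ratio_draws
from .progress import RegionMap, classify_progress, progress_table
from .records import EstimateSeries
from .scenarios import SCENARIO_NAMES, ScenarioConfig, averted_deaths, project_country, project_deaths
from .splines import build_spline_basis
from .synthetic import generate_world

logger = logging.getLogger(__name__)


def _write_meta(out: Path, stage: str, config: RunConfig, t0: float) -> None:
    meta = {
        "stage": stage,
        "seed": config.seed,
        "version": __version__,
        "runtime_s": round(time.time() - t0, 2),
    }
    with open(out / f"meta_{stage}.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    logger.info("stage %s done in %.1fs (seed=%d)", stage, time.time() - t0, config.seed)


def stage_simulate(config: RunConfig) -> Path:
    """Generate the synthetic world and write its CSVs."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world = generate_world(seed=config.seed, n_countries=config.n_countries,
                           years=np.arange(config.estimate_years[0],
                                           config.estimate_years[1] + 0.5))
    write_observations(world.observations, out / "observations.csv")
    write_livebirths(world.livebirths, out / "livebirths.csv")
    world.truth_frame().to_csv(out / "truth.csv", index=False)
    _write_meta(out, "simulate", config, t0)
    return out


def _mcmc(config: RunConfig) -> MCMCConfig:
    return MCMCConfig(chains=config.chains, warmup=config.warmup, samples=config.samples)


def fit_u5mr_batch(
    observations,
    config: RunConfig,
    horizon_end: float | None = None,
) -> tuple[dict[str, PosteriorU5MR], B3Fit]:
    """Fit the bias-adjusted model and extrapolate every country to the
    common endpoint.

    Countries whose data end early are truncated at their last observation
    year and extended by blending their own recent trend with the global
    (cross-country median) annual reduction rate.
    """
    u5 = [r for r in observations if r.indicator == "U5MR"]
    lo = np.floor(min(r.reference_year for r in u5)) + 0.5
    hi_obs = max(r.reference_year for r in u5)
    horizon_end = horizon_end or config.estimate_years[1]
    basis = build_spline_basis(min(lo, config.estimate_years[0]), hi_obs)
    fit = fit_b3(u5, basis, mcmc=_mcmc(config), seed=config.seed)

    # global trend: median country ARR over the last decade of the fit grid
    arrs = []
    for c, post in fit.posteriors.items():
        med = np.median(post.draws, axis=0)
        k = min(10, len(post.years) - 1)
        arrs.append((med[-1 - k] - med[-1]) / k)
    global_arr = float(np.median(arrs))

    last_obs = {}
    for r in u5:
        last_obs[r.country] = max(last_obs.get(r.country, -np.inf), r.reference_year)
    posteriors: dict[str, PosteriorU5MR] = {}
    for c, post in fit.posteriors.items():
        keep = post.years <= last_obs[c] + 0.5
        trunc = PosteriorU5MR(
            country=c,
            years=post.years[keep],
            draws=post.draws[:, keep],
            innovation_sd=post.innovation_sd,
            diagnostics=post.diagnostics,
        )
        if trunc.years[-1] < horizon_end - 1e-9:
            trunc = extrapolate(trunc, global_arr, horizon_end,
                                seed=config.seed + 1)
        posteriors[c] = trunc
    return posteriors, fit


def stage_fit(config: RunConfig) -> Path:
    """Fit U5MR and NMR to the simulated observations and write estimates."""
    t0 = time.time()
    out = Path(config.out_dir)
    observations = read_observations(out / "observations.csv")
    livebirths = read_livebirths(out / "livebirths.csv")
    obs_countries = {r.country for r in observations}
    missing = sorted(set(livebirths) - obs_countries)
    if missing:
        raise ValueError(f"no observations for countries: {missing}")

    posteriors, fit = fit_u5mr_batch(observations, config)
    u5mr_est = {c: summarize_posterior(p, config.level) for c, p in posteriors.items()}
    write_estimates(u5mr_est, out / "u5mr_estimates.csv")

    # global ratio relation from pooled (estimated U5MR, observed ratio) pairs
    nmr_obs = [r for r in observations if r.indicator == "NMR"]
    pairs = []
    for r in nmr_obs:
        u = u5mr_est[r.country].at(r.reference_year)
        if r.value < u:
            pairs.append({"u5mr": u, "ratio": r.value / (u - r.value)})
    w = fit_global_relation(pd.DataFrame(pairs))
    basis = build_spline_basis(config.estimate_years[0], config.estimate_years[1])
    nfit = fit_country_multiplier(nmr_obs, u5mr_est, w, basis,
                                  seed=config.seed, mcmc=_mcmc(config))
    nmr_est: dict[str, EstimateSeries] = {}
    nmr_draw_store: dict[str, np.ndarray] = {}
    for c, post in posteriors.items():
        r_d = ratio_draws(nfit, post)
        u_d = np.exp(np.column_stack(
            [post.draws[:, np.argmin(np.abs(post.years - y))] for y in nfit.years]
        ))
        est, nd = derive_nmr(r_d, u_d, nfit.years, c, level=config.level)
        nmr_est[c] = est
        nmr_draw_store[c] = nd
    write_estimates(nmr_est, out / "nmr_estimates.csv")

    with open(out / "fit_diagnostics.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "u5mr": {k: float(v) if isinstance(v, (int, float)) else v
                          for k, v in fit.diagnostics.items()},
                "nmr": {k: float(v) if isinstance(v, (int, float)) else v
                         for k, v in nfit.diagnostics.items()},
                "w_function": {"b0": nfit.w.b0, "b1": nfit.w.b1, "b2": nfit.w.b2},
            },
            fh,
        )
    _write_meta(out, "fit", config, t0)
    return out


def stage_project(config: RunConfig) -> Path:
    """Project 2020-2030 rates and deaths under the requested scenarios."""
    t0 = time.time()
    out = Path(config.out_dir)
    u5mr_est = read_estimates(out / "u5mr_estimates.csv")
    nmr_est = read_estimates(out / "nmr_estimates.csv")
    livebirths = read_livebirths(out / "livebirths.csv")
    names = SCENARIO_NAMES if config.scenario == "all" else (config.scenario,)
    rate_frames, death_frames = [], []
    for name in names:
        cfg = ScenarioConfig(name=name)
        projections = {
            c: project_country(u5mr_est[c], nmr_est[c], cfg) for c in u5mr_est
        }
        for c, p in projections.items():
            rate_frames.append(
                pd.DataFrame(
                    {
                        "country": c,
                        "scenario": name,
                        "year": p.years,
                        "u5mr": p.u5mr,
                        "nmr": p.nmr,
                    }
                )
            )
        death_frames.append(project_deaths(projections, livebirths, u5mr_est, nmr_est))
    pd.concat(rate_frames, ignore_index=True).to_csv(out / "scenario_rates.csv", index=False)
    pd.concat(death_frames, ignore_index=True).to_csv(out / "scenario_deaths.csv", index=False)
    _write_meta(out, "project", config, t0)
    return out


def synthetic_region_map(countries: list[str], u5mr_est: dict[str, EstimateSeries]) -> RegionMap:
    """Stand-in groupings: regions by round-robin, income groups by 2019
    mortality quartile (the real memberships are an external table)."""
    region = {c: f"R{i % 5 + 1}" for i, c in enumerate(sorted(countries))}
    levels = {c: u5mr_est[c].at(2019.5) for c in countries}
    qs = np.quantile(list(levels.values()), [0.25, 0.5, 0.75])
    labels = ["high_income", "upper_middle", "lower_middle", "low_income"]
    income = {c: labels[int(np.searchsorted(qs, lvl))] for c, lvl in levels.items()}
    return RegionMap(region=region, income=income)


def stage_report(config: RunConfig) -> Path:
    """Progress classification and scenario summary tables."""
    t0 = time.time()
    out = Path(config.out_dir)
    u5mr_est = read_estimates(out / "u5mr_estimates.csv")
    nmr_est = read_estimates(out / "nmr_estimates.csv")
    statuses = []
    for c in sorted(u5mr_est):
        for est, target, ind in ((u5mr_est[c], 25.0, "U5MR"), (nmr_est[c], 12.0, "NMR")):
            arr = float(np.log(est.at(2010.5) / est.at(2019.5)) / 9.0)
            statuses.append(
                classify_progress(est.at(2019.5), arr, target, country=c, indicator=ind)
            )
    progress_table(statuses).to_csv(out / "progress.csv", index=False)

    deaths = pd.read_csv(out / "scenario_deaths.csv")
    summary = (
        deaths.groupby(["scenario", "year"])[
            ["deaths_neonatal", "deaths_1_59m", "deaths_under5"]
        ]
        .sum()
        .reset_index()
    )
    totals = (
        summary.groupby("scenario")[["deaths_neonatal", "deaths_under5"]]
        .sum()
        .rename(columns=lambda s: s + "_2020_30")
        .reset_index()
    )
    summary.to_csv(out / "scenario_summary.csv", index=False)
    totals.to_csv(out / "scenario_totals.csv", index=False)
    _write_meta(out, "report", config, t0)
    return out
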