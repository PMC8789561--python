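"""Neonatal mortality estimated through the ratio to under-5 mortality.

Rather than modelling NMR directly, the model works with the ratio

    R(c, t) = NMR / (U5MR - NMR) = W(c, t) * P(c, t)

where ``W`` is the expected ratio at a country-year's U5MR level (a global
relation, here a log-log quadratic fitted by least squares to pooled
country-year pairs) and ``P`` is a country multiplier capturing departures
from that relation, modelled as the exponential of a B-spline with a
random-walk prior centred at zero.  Back-transforming through

    NMR = U5MR * R / (1 + R)

keeps every NMR draw strictly below its paired U5MR draw, and countries with
sparse or no neonatal data fall back to the global relation (P -> 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .b3 import ConvergenceError, MCMCConfig, PosteriorU5MR, _chol_sample, summarize_posterior
from .records import EstimateSeries, ObservationRecord
from .splines import SplineBasis

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WFunction:
    """Global expected ratio as a function of U5MR: log W = b0 + b1 x + b2 x**2
    with x = log(U5MR)."""

    b0: float
    b1: float
    b2: float = 0.0

    def __call__(self, u5mr: np.ndarray | float) -> np.ndarray:
        x = np.log(np.asarray(u5mr, dtype=float))
        return np.exp(self.b0 + self.b1 * x + self.b2 * x * x)


@dataclass
class RatioComponents:
    """Posterior-median decomposition R = W * P for one country."""

    country: str
    years: np.ndarray
    R: np.ndarray
    W: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.R <= 0) or np.any(self.W <= 0) or np.any(self.P <= 0):
            raise ValueError("R, W, P must be positive")
        if not np.allclose(self.R, self.W * self.P, rtol=1e-9):
            raise ValueError("decomposition must satisfy R = W * P")


@dataclass
class NMRFit:
    """Country-multiplier posteriors plus the fitted global relation."""

    w: WFunction
    logp_draws: dict[str, np.ndarray]  # country -> (n_draws, n_years)
    years: np.ndarray
    diagnostics: dict


def ratio_from_rates(nmr: np.ndarray | float, u5mr: np.ndarray | float) -> np.ndarray:
    """R = NMR / (U5MR - NMR); requires NMR < U5MR."""
    nmr = np.asarray(nmr, dtype=float)
    u5mr = np.asarray(u5mr, dtype=float)
    if np.any(nmr >= u5mr):
        raise ValueError("NMR must be below U5MR")
    return nmr / (u5mr - nmr)


def fit_global_relation(pairs: pd.DataFrame) -> WFunction:
    """Least-squares fit of the log-log relation between ratio and U5MR.

    ``pairs`` needs columns ``u5mr`` and ``ratio`` (country-year pooled
    observations).  Requires at least 20 pairs spanning a non-degenerate
    U5MR range.
    """
    if len(pairs) < 20:
        raise ValueError("need at least 20 country-year pairs")
    x = np.log(pairs["u5mr"].to_numpy(dtype=float))
    y = np.log(pairs["ratio"].to_numpy(dtype=float))
    if np.ptp(x) < 1e-6:
        raise ValueError("degenerate input: U5MR range is constant")
    c2, c1, c0 = np.polyfit(x, y, 2)
    return WFunction(b0=float(c0), b1=float(c1), b2=float(c2))


def fit_country_multiplier(
    nmr_observations: list[ObservationRecord],
    u5mr_estimates: dict[str, EstimateSeries],
    w: WFunction,
    basis: SplineBasis,
    seed: int = 0,
    mcmc: MCMCConfig | None = None,
    countries: list[str] | None = None,
    level_prior_sd: float = 0.3,
) -> NMRFit:
    """Fit the country multiplier P(c, t) = exp(spline) for every country.

    Ratio observations are formed from each NMR observation and the posterior
    median U5MR at its reference year; their log-scale variance carries the
    delta-method factor (U5MR / (U5MR - NMR))**2 on the reported NMR sampling
    error.  The smoothing variance and the extra non-sampling variance are
    pooled across countries.  Countries listed in ``countries`` (default: all
    countries with U5MR estimates) but lacking usable NMR data get
    prior-dominated draws, i.e. P centred at 1.
    """
    mcmc = mcmc or MCMCConfig()
    if countries is None:
        countries = sorted(u5mr_estimates)
    lo, hi = basis.support
    start = np.floor(lo) + 0.5
    if start < lo:
        start += 1.0
    grid_years = np.arange(start, hi + 1e-9)
    B_grid = basis.design_matrix(grid_years)
    K = basis.n_coef
    Dm = basis.difference_matrix(1)
    DtD = Dm.T @ Dm

    blocks: dict[str, dict] = {}
    for c in countries:
        recs = [r for r in nmr_observations if r.country == c and r.indicator == "NMR"]
        est = u5mr_estimates.get(c)
        t, y, v = [], [], []
        for r in recs:
            if est is None:
                break
            u = est.at(r.reference_year)
            if r.value >= u:
                logger.warning("%s %.1f: NMR observation %.2f >= U5MR estimate %.2f; dropped",
                               c, r.reference_year, r.value, u)
                continue
            ratio = r.value / (u - r.value)
            t.append(r.reference_year)
            y.append(np.log(ratio) - np.log(float(w(u))))
            v.append((u / (u - r.value)) ** 2 * r.se_log**2)
        blocks[c] = dict(
            B=basis.design_matrix(np.array(t)) if t else np.zeros((0, K)),
            y=np.array(y),
            v=np.array(v),
        )

    e0 = np.zeros((K, K))
    e0[0, 0] = 1.0 / level_prior_sd**2
    root = np.random.SeedSequence([seed, 0x4E4D52])
    chain_seeds = root.spawn(mcmc.chains)
    total = mcmc.warmup + mcmc.samples
    store = np.empty((mcmc.chains, mcmc.samples, len(countries), len(grid_years)))

    for ch, ssq in enumerate(chain_seeds):
        rng = np.random.default_rng(ssq)
        tau2 = 0.005 * (1 + rng.random())
        sig = 0.05 * np.exp(rng.normal(0, 0.3))
        gammas = {c: np.zeros(K) for c in countries}
        for it in range(total):
            ss_inc, n_inc = 0.0, 0
            for ci, c in enumerate(countries):
                blk = blocks[c]
                A = DtD / tau2 + e0
                rhs = np.zeros(K)
                if len(blk["y"]):
                    wts = 1.0 / (blk["v"] + sig**2)
                    A = A + blk["B"].T @ (wts[:, None] * blk["B"])
                    rhs = blk["B"].T @ (wts * blk["y"])
                cf = cho_factor(A, lower=True)
                mean = cho_solve(cf, rhs)
                gammas[c] = mean + _chol_sample(A, rng.standard_normal(K))
                d = Dm @ gammas[c]
                ss_inc += float(d @ d)
                n_inc += len(d)
            tau2 = 1.0 / rng.gamma(mcmc.tau2_a + 0.5 * n_inc,
                                   1.0 / (mcmc.tau2_b + 0.5 * ss_inc))
            # Metropolis step on the shared extra non-sampling SD
            prop = sig * np.exp(mcmc.mh_step * rng.standard_normal())
            delta = 0.0
            for c in countries:
                blk = blocks[c]
                if not len(blk["y"]):
                    continue
                resid = blk["y"] - blk["B"] @ gammas[c]
                v_cur = blk["v"] + sig**2
                v_prop = blk["v"] + prop**2
                delta += np.sum(-0.5 * np.log(v_prop) - 0.5 * resid**2 / v_prop)
                delta -= np.sum(-0.5 * np.log(v_cur) - 0.5 * resid**2 / v_cur)
            delta += -0.5 * (prop / 0.1) ** 2 + np.log(prop)
            delta -= -0.5 * (sig / 0.1) ** 2 + np.log(sig)
            if np.log(rng.random()) < delta:
                sig = prop
            if it >= mcmc.warmup:
                for ci, c in enumerate(countries):
                    store[ch, it - mcmc.warmup, ci] = B_grid @ gammas[c]

    mids = [0, len(grid_years) // 2, len(grid_years) - 1]
    # monitor only data-bearing countries: prior-only draws are iid by design
    has_data = [ci for ci, c in enumerate(countries) if len(blocks[c]["y"])]
    diag: dict = {"chains": mcmc.chains, "samples_per_chain": mcmc.samples, "seed": seed}
    if has_data:
        rhat_ds = az.rhat(az.from_dict(posterior={"logp": store[:, :, has_data][:, :, :, mids]}))
        rhat_max = float(rhat_ds["logp"].values.max())
        diag["rhat_max"] = rhat_max
        if rhat_max > mcmc.rhat_max:
            raise ConvergenceError(f"split-R-hat {rhat_max:.3f} exceeds {mcmc.rhat_max}")
    flat = store.reshape(-1, len(countries), len(grid_years))
    return NMRFit(
        w=w,
        logp_draws={c: flat[:, ci, :].copy() for ci, c in enumerate(countries)},
        years=grid_years,
        diagnostics=diag,
    )


def ratio_components(fit: NMRFit, u5mr_est: EstimateSeries) -> RatioComponents:
    """Posterior-median decomposition R = W * P for one fitted country."""
    c = u5mr_est.country
    u_med = np.exp(np.interp(fit.years, u5mr_est.years, np.log(u5mr_est.median)))
    W = np.asarray(fit.w(u_med), dtype=float)
    P = np.exp(np.median(fit.logp_draws[c], axis=0))
    return RatioComponents(country=c, years=fit.years.copy(), R=W * P, W=W, P=P)


def ratio_draws(fit: NMRFit, u5mr_posterior: PosteriorU5MR) -> np.ndarray:
    """Per-draw ratio R = W(U5MR) * P on the joint year grid of the fit and
    the U5MR posterior (draws are paired one-to-one)."""
    c = u5mr_posterior.country
    logp = fit.logp_draws[c]
    years = fit.years
    # align U5MR draws onto the ratio-year grid (log-linear interpolation)
    u_draws = np.empty((u5mr_posterior.n_draws, len(years)))
    for i, yr in enumerate(years):
        u_draws[:, i] = _interp_draws(u5mr_posterior, yr)
    if logp.shape[0] != u_draws.shape[0]:
        raise ValueError(
            f"draw counts differ: {logp.shape[0]} ratio vs {u_draws.shape[0]} U5MR"
        )
    return fit.w(np.exp(u_draws)) * np.exp(logp)


def _interp_draws(post: PosteriorU5MR, year: float) -> np.ndarray:
    j = np.searchsorted(post.years, year)
    if j == 0:
        return post.draws[:, 0]
    if j >= len(post.years):
        return post.draws[:, -1]
    t0, t1 = post.years[j - 1], post.years[j]
    lam = (year - t0) / (t1 - t0)
    return (1 - lam) * post.draws[:, j - 1] + lam * post.draws[:, j]


def derive_nmr(
    r_draws: np.ndarray,
    u5mr_draws: np.ndarray,
    years: np.ndarray,
    country: str,
    level: float = 0.90,
) -> tuple[EstimateSeries, np.ndarray]:
    """Transform ratio draws and U5MR rate draws into NMR estimates.

    ``u5mr_draws`` are on the rate scale (per 1000).  The transform
    NMR = U5MR * R / (1 + R) guarantees NMR < U5MR draw by draw.  Returns the
    posterior summary and the NMR draw matrix.
    """
    r_draws = np.asarray(r_draws, dtype=float)
    u5mr_draws = np.asarray(u5mr_draws, dtype=float)
    if r_draws.shape != u5mr_draws.shape:
        raise ValueError("ratio and U5MR draws must be aligned in shape")
    nmr = u5mr_draws * r_draws / (1.0 + r_draws)
    post = PosteriorU5MR(
        country=country,
        years=np.asarray(years, dtype=float),
        draws=np.log(nmr),
        innovation_sd=np.zeros(nmr.shape[0]),
        indicator="NMR",
    )
    return summarize_posterior(post, level=level), nmr
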