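"""Bayesian B-spline bias-adjusted estimation of under-5 mortality.

The model treats each observed rate as the true rate times a multiplicative
error: on the log scale

    log(observed) = log(true) + mean_bias[source type] + u[series] + epsilon,
    Var(epsilon)  = se_log**2 + extra_var[source type],

where the true log-rate trajectory of each country is a cubic B-spline with a
first-order random-walk prior on its coefficients (shared smoothing variance
across the fit batch).  The bias model is hierarchical: vital-registration
series anchor the bias scale at zero; every other source type carries a mean
bias pooled across all countries in the batch, and each individual series
additionally carries a persistent effect ``u`` drawn around that mean (with a
per-source-type variance), so a survey programme that sits systematically
high or low is treated as correlated error rather than independent noise.

Conditional on the variance parameters the model is linear-Gaussian, so the
sampler is a blocked Gibbs scheme: exact multivariate-normal draws for each
country's spline coefficients and for the source biases, a conjugate
inverse-gamma draw for the smoothing variance, and Metropolis steps on the
log of each extra non-sampling SD.  Four chains are run and split-R-hat is
checked before any summary is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .records import EstimateSeries, ObservationRecord
from .splines import SplineBasis

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Raised when chains fail the R-hat acceptance threshold."""


@dataclass(frozen=True)
class BiasModel:
    """Priors for the source-type error model.

    ``anchor`` is the source type whose mean bias is fixed at zero for
    identifiability (vital registration by convention); ``mean_bias_sd`` is
    the prior SD of the other types' mean log-biases; ``extra_sd_scale`` the
    half-normal scale of the extra non-sampling SDs.
    """

    anchor: str = "VR"
    mean_bias_sd: float = 0.3
    extra_sd_scale: float = 0.1


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 4
    warmup: int = 500
    samples: int = 600
    rhat_max: float = 1.05
    # random-walk smoothing variance prior (inverse gamma)
    tau2_a: float = 1.0
    tau2_b: float = 0.005
    # inverse-gamma prior on the per-source series-effect variance
    series_sd_a: float = 1.5
    series_sd_b: float = 0.003
    level_prior_sd: float = 2.0
    mh_step: float = 0.25


@dataclass
class PosteriorU5MR:
    """Posterior draws of one country's log-rate trajectory."""

    country: str
    years: np.ndarray
    draws: np.ndarray  # (n_draws, n_years), log rate per 1000
    innovation_sd: np.ndarray  # (n_draws,) per-year trend innovation SD
    diagnostics: dict = field(default_factory=dict)
    indicator: str = "U5MR"

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]


@dataclass
class B3Fit:
    """Joint fit of one batch of countries (shared bias/variance posteriors)."""

    posteriors: dict[str, PosteriorU5MR]
    bias_draws: pd.DataFrame  # one column per non-anchor source type
    extra_sd_draws: pd.DataFrame  # one column per source type
    diagnostics: dict

    def __getitem__(self, country: str) -> PosteriorU5MR:
        return self.posteriors[country]

    @property
    def countries(self) -> list[str]:
        return sorted(self.posteriors)


def _weighted_mean(y: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * y) / np.sum(w))


def fit_b3(
    observations: list[ObservationRecord],
    basis: SplineBasis,
    bias_prior: BiasModel | None = None,
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
    output_years: np.ndarray | None = None,
) -> B3Fit:
    """Fit the bias-adjusted spline model to a batch of countries.

    Raises :class:`ConvergenceError` if any monitored quantity exceeds the
    R-hat threshold, rather than silently returning a bad posterior.
    """
    if not observations:
        raise ValueError("need at least one observation")
    bias_prior = bias_prior or BiasModel()
    mcmc = mcmc or MCMCConfig()

    lo, hi = basis.support
    if output_years is None:
        start = np.floor(lo) + 0.5
        if start < lo:
            start += 1.0
        output_years = np.arange(start, hi + 1e-9)
    output_years = np.asarray(output_years, dtype=float)

    countries = sorted({r.country for r in observations})
    source_types = sorted({r.source_type for r in observations})
    anchor = bias_prior.anchor
    if anchor not in source_types:
        counts = {s: sum(r.source_type == s for r in observations) for s in source_types}
        anchor = max(counts, key=counts.get)
        logger.warning("anchor source %r absent; anchoring %r instead",
                       bias_prior.anchor, anchor)
    free_sources = [s for s in source_types if s != anchor]
    s_index = {s: k for k, s in enumerate(source_types)}

    # per-country data blocks
    K = basis.n_coef
    D = basis.difference_matrix(1)
    DtD = D.T @ D
    knot_spacing = float(np.median(np.diff(basis.greville))) or 1.0
    B_grid = basis.design_matrix(output_years)
    blocks = {}
    free_index = {s: j for j, s in enumerate(free_sources)}
    for c in countries:
        recs = [r for r in observations if r.country == c]
        t = np.array([r.reference_year for r in recs])
        y = np.log([r.value for r in recs])
        se2 = np.array([r.se_log**2 for r in recs])
        src = np.array([s_index[r.source_type] for r in recs])
        # indicator columns mapping each observation to its free-source bias
        Z = np.zeros((len(recs), len(free_sources)))
        for i, r in enumerate(recs):
            if r.source_type in free_index:
                Z[i, free_index[r.source_type]] = 1.0
        # series-level bias effects: one column per non-anchor series, so
        # persistent within-series departures from the source-type mean are
        # modelled as correlated error, not averaged away as noise
        series_ids = sorted({r.series_id for r in recs if r.source_type != anchor})
        G = np.zeros((len(recs), len(series_ids)))
        series_src = np.zeros(len(series_ids), dtype=int)
        for j, sid in enumerate(series_ids):
            rows = [i for i, r in enumerate(recs) if r.series_id == sid]
            G[rows, j] = 1.0
            series_src[j] = free_index[recs[rows[0]].source_type]
        w0 = 1.0 / (se2 + 0.01)
        B = basis.design_matrix(t)
        blocks[c] = dict(B=B, X=np.concatenate([B, G], axis=1), y=y, se2=se2,
                         src=src, Z=Z, G=G, series_src=series_src,
                         m=len(series_ids), ybar=_weighted_mean(y, w0))

    n_free = len(free_sources)
    n_src = len(source_types)
    total_iters = mcmc.warmup + mcmc.samples
    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(mcmc.chains)

    curves = np.empty((mcmc.chains, mcmc.samples, len(countries), len(output_years)))
    tau_store = np.empty((mcmc.chains, mcmc.samples))
    bias_store = np.empty((mcmc.chains, mcmc.samples, n_free))
    sd_store = np.empty((mcmc.chains, mcmc.samples, n_src))

    e0 = np.zeros((K, K))
    e0[0, 0] = 1.0 / mcmc.level_prior_sd**2

    for ch, ss in enumerate(chain_seeds):
        rng = np.random.default_rng(ss)
        # initial state
        tau2 = 0.02 * (1.0 + 0.5 * rng.random())
        sigma = np.full(n_src, 0.05) * np.exp(rng.normal(0, 0.3, n_src))
        omega2 = np.full(max(n_free, 1), 0.002)  # series-effect variances
        bias = np.zeros(n_src)
        betas = {c: np.zeros(K) for c in countries}
        series_u = {c: np.zeros(blocks[c]["m"]) for c in countries}

        for it in range(total_iters):
            sig2 = sigma**2
            # --- joint exact draw of (biases, spline coefs, series effects) ---
            # Conditional on the variances the model is Gaussian with an
            # arrowhead precision (countries are independent given the shared
            # source biases), so the biases are drawn from their marginal via
            # a Schur complement and each country's local block conditionally.
            S = np.eye(n_free) / bias_prior.mean_bias_sd**2
            rhs_b = np.zeros(n_free)
            cache = {}
            for c in countries:
                blk = blocks[c]
                m = blk["m"]
                w = 1.0 / (blk["se2"] + sig2[blk["src"]])
                wX = w[:, None] * blk["X"]
                A = blk["X"].T @ wX
                A[:K, :K] += DtD / tau2 + e0
                if m:
                    A[K:, K:] += np.diag(1.0 / omega2[blk["series_src"]])
                rhs = blk["X"].T @ (w * blk["y"])
                rhs[0] += blk["ybar"] / mcmc.level_prior_sd**2
                cf = cho_factor(A, lower=True)
                if n_free:
                    U = wX.T @ blk["Z"]  # (K+m, n_free)
                    S += blk["Z"].T @ (w[:, None] * blk["Z"]) - U.T @ cho_solve(cf, U)
                    rhs_b += blk["Z"].T @ (w * blk["y"]) - U.T @ cho_solve(cf, rhs)
                cache[c] = (cf, A, rhs, wX)
            if n_free:
                bias_free = np.linalg.solve(S, rhs_b) + _chol_sample(
                    S, rng.standard_normal(n_free)
                )
                for s, j in free_index.items():
                    bias[s_index[s]] = bias_free[j]
            for c in countries:
                cf, A, rhs, wX = cache[c]
                blk = blocks[c]
                if n_free:
                    rhs = rhs - wX.T @ (blk["Z"] @ bias_free)
                x = cho_solve(cf, rhs) + _chol_sample(A, rng.standard_normal(A.shape[0]))
                betas[c] = x[:K]
                series_u[c] = x[K:]

            # --- smoothing variance (conjugate inverse gamma) ---
            ss_inc, n_inc = 0.0, 0
            for c in countries:
                d = D @ betas[c]
                ss_inc += float(d @ d)
                n_inc += len(d)
            tau2 = 1.0 / rng.gamma(mcmc.tau2_a + 0.5 * n_inc,
                                   1.0 / (mcmc.tau2_b + 0.5 * ss_inc))

            # --- series-effect variances per source type (conjugate IG) ---
            for j in range(n_free):
                u_all = np.concatenate(
                    [series_u[c][blocks[c]["series_src"] == j] for c in countries]
                )
                omega2[j] = 1.0 / rng.gamma(
                    mcmc.series_sd_a + 0.5 * len(u_all),
                    1.0 / (mcmc.series_sd_b + 0.5 * float(u_all @ u_all)),
                )

            # --- extra non-sampling SDs (Metropolis on log sigma) ---
            for k in range(n_src):
                cur = sigma[k]
                prop = cur * np.exp(mcmc.mh_step * rng.standard_normal())
                delta = 0.0
                for c in countries:
                    blk = blocks[c]
                    msk = blk["src"] == k
                    if not msk.any():
                        continue
                    fitv = blk["B"] @ betas[c] + blk["G"] @ series_u[c] + bias[k]
                    resid = blk["y"][msk] - fitv[msk]
                    v_cur = blk["se2"][msk] + cur**2
                    v_prop = blk["se2"][msk] + prop**2
                    delta += np.sum(-0.5 * np.log(v_prop) - 0.5 * resid**2 / v_prop)
                    delta -= np.sum(-0.5 * np.log(v_cur) - 0.5 * resid**2 / v_cur)
                # half-normal prior + log-scale Jacobian
                delta += (-0.5 * (prop / bias_prior.extra_sd_scale) ** 2 + np.log(prop))
                delta -= (-0.5 * (cur / bias_prior.extra_sd_scale) ** 2 + np.log(cur))
                if np.log(rng.random()) < delta:
                    sigma[k] = prop

            if it >= mcmc.warmup:
                j = it - mcmc.warmup
                for ci, c in enumerate(countries):
                    curves[ch, j, ci] = B_grid @ betas[c]
                tau_store[ch, j] = np.sqrt(tau2)
                bias_store[ch, j] = bias[[s_index[s] for s in free_sources]]
                sd_store[ch, j] = sigma

    # --- convergence check on trajectory endpoints/midpoints and biases ---
    mids = [0, len(output_years) // 2, len(output_years) - 1]
    monitored = {"log_rate": curves[:, :, :, mids]}
    if n_free:
        monitored["bias"] = bias_store
    rhat_ds = az.rhat(az.from_dict(posterior=monitored))
    rhat_max = float(max(rhat_ds[v].values.max() for v in rhat_ds.data_vars))
    ess_note = {"rhat_max": rhat_max, "chains": mcmc.chains,
                "samples_per_chain": mcmc.samples, "seed": seed, "anchor": anchor}
    if rhat_max > mcmc.rhat_max:
        raise ConvergenceError(
            f"split-R-hat {rhat_max:.3f} exceeds {mcmc.rhat_max}; "
            "increase warmup/samples"
        )

    flat_curves = curves.reshape(-1, len(countries), len(output_years))
    flat_tau = tau_store.reshape(-1)
    per_year_sd = flat_tau / np.sqrt(knot_spacing)
    posteriors = {
        c: PosteriorU5MR(
            country=c,
            years=output_years.copy(),
            draws=flat_curves[:, ci, :].copy(),
            innovation_sd=per_year_sd.copy(),
            diagnostics=dict(ess_note),
        )
        for ci, c in enumerate(countries)
    }
    n_flat = mcmc.chains * mcmc.samples
    bias_df = pd.DataFrame(bias_store.reshape(n_flat, n_free), columns=free_sources)
    sd_df = pd.DataFrame(sd_store.reshape(n_flat, n_src), columns=source_types)
    return B3Fit(posteriors=posteriors, bias_draws=bias_df,
                 extra_sd_draws=sd_df, diagnostics=ess_note)


def _chol_sample(A: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Draw with covariance A^{-1} from standard normals z via L^{-T} z."""
    L = cholesky(A, lower=True)
    return solve_triangular(L.T, z, lower=False)


def summarize_posterior(posterior: PosteriorU5MR, level: float = 0.90) -> EstimateSeries:
    """Median and equal-tailed interval on the rate scale (per 1000)."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    a = (1.0 - level) / 2.0
    rates = np.exp(posterior.draws)
    return EstimateSeries(
        country=posterior.country,
        years=posterior.years,
        median=np.quantile(rates, 0.5, axis=0),
        lower90=np.quantile(rates, a, axis=0),
        upper90=np.quantile(rates, 1.0 - a, axis=0),
        indicator=posterior.indicator,
    )


def extrapolate(
    posterior: PosteriorU5MR,
    global_arr: float,
    horizon_end: float,
    rho: float = 0.9,
    trend_window: float = 10.0,
    innovation_sd: np.ndarray | float | None = None,
    seed: int = 0,
) -> PosteriorU5MR:
    """Extend each posterior draw past the last fitted year.

    The per-year log decrement in extrapolated year ``k`` blends the draw's
    own recent trend (annual reduction rate over the last ``trend_window``
    years) with ``global_arr``:

        decrement_k = rho**k * country_arr + (1 - rho**k) * global_arr

    so the country's momentum dominates at first and the global trend takes
    over with horizon.  Gaussian innovations (SD per year taken from the
    posterior smoothing scale unless overridden) make the interval widen with
    extrapolation length.
    """
    years = posterior.years
    last = years[-1]
    if horizon_end <= last:
        raise ValueError("horizon_end must lie beyond the last fitted year")
    n_ext = int(np.round(horizon_end - last))
    w = min(trend_window, years[-1] - years[0])
    i0 = int(np.argmin(np.abs(years - (last - w))))
    span = last - years[i0]
    country_arr = (posterior.draws[:, i0] - posterior.draws[:, -1]) / span

    if innovation_sd is None:
        sd = posterior.innovation_sd
    else:
        sd = np.broadcast_to(np.asarray(innovation_sd, dtype=float),
                             (posterior.n_draws,))
    rng = np.random.default_rng(seed)
    ext = np.empty((posterior.n_draws, n_ext))
    level = posterior.draws[:, -1].copy()
    for k in range(1, n_ext + 1):
        wk = rho**k
        level = level - (wk * country_arr + (1 - wk) * global_arr)
        level = level + rng.standard_normal(posterior.n_draws) * sd
        ext[:, k - 1] = level
    return PosteriorU5MR(
        country=posterior.country,
        years=np.concatenate([years, last + np.arange(1, n_ext + 1)]),
        draws=np.concatenate([posterior.draws, ext], axis=1),
        innovation_sd=np.asarray(sd, dtype=float).copy(),
        diagnostics=dict(posterior.diagnostics),
        indicator=posterior.indicator,
    )
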