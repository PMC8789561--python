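"""Estimate neonatal mortality through the ratio model.

NMR is derived from the ratio R = NMR/(U5MR - NMR) = W(U5MR) x P(country),
where W is a global relation fitted to pooled country-years and P a smooth
country multiplier.  The back-transform NMR = U5MR * R/(1+R) keeps every NMR
draw below its paired U5MR draw.
"""

import numpy as np
import pandas as pd

import childmort as cm
from childmort.b3 import MCMCConfig
from childmort.nmr import derive_nmr, ratio_draws

world = cm.generate_world(seed=7, n_countries=6)
mcmc = MCMCConfig(chains=4, warmup=300, samples=400)
basis = cm.build_spline_basis(1985.5, 2019.5)

fit = cm.fit_b3([r for r in world.observations if r.indicator == "U5MR"],
                basis, mcmc=mcmc, seed=1)
u5mr_est = {c: cm.summarize_posterior(fit[c]) for c in fit.countries}

nmr_obs = [r for r in world.observations if r.indicator == "NMR"]
pairs = pd.DataFrame(
    {"u5mr": [u5mr_est[r.country].at(r.reference_year) for r in nmr_obs],
     "ratio": [r.value / (u5mr_est[r.country].at(r.reference_year) - r.value)
               for r in nmr_obs]}
)
w = cm.fit_global_relation(pairs)
print(f"global relation log W = {w.b0:.2f} {w.b1:+.2f} log(U5MR) "
      f"{w.b2:+.3f} log(U5MR)^2")
print("W(100) =", round(float(w(100.0)), 3), " W(20) =", round(float(w(20.0)), 3),
      " (ratio rises as mortality falls: larger neonatal share)")

nfit = cm.fit_country_multiplier(nmr_obs, u5mr_est, w, basis, seed=2, mcmc=mcmc)
print("\n2019 NMR estimates (per 1000), always below U5MR:")
for c in fit.countries:
    post = fit[c]
    r_d = ratio_draws(nfit, post)
    est, nmr_draws = derive_nmr(r_d, np.exp(post.draws), nfit.years, c)
    truth = float(world.schedules[c].nmr_at(2019.5))
    print(f"  {c}: NMR {est.median[-1]:5.1f} [{est.lower90[-1]:5.1f}, "
          f"{est.upper90[-1]:5.1f}]  truth {truth:5.1f}  "
          f"U5MR {u5mr_est[c].median[-1]:5.1f}")
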