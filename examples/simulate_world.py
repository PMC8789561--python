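"""Generate a synthetic multi-country observation database and inspect it.

Each country gets a smooth true U5MR/NMR trajectory, annual livebirths, and
several overlapping observation series (vital registration, sample
registration, full-birth-history surveys, summary-birth-history censuses)
with source-specific biases and sampling noise.
"""

import numpy as np

import childmort as cm

world = cm.generate_world(seed=7, n_countries=6)

print(f"{len(world.countries)} countries, {len(world.observations)} observations\n")
for c in world.countries:
    sched = world.schedules[c]
    series = {s.series_id: s.source_type for s in world.specs[c]}
    print(
        f"{c}: true U5MR {sched.u5mr_true[0]:6.1f} -> {sched.u5mr_true[-1]:6.1f} "
        f"per 1000 over {sched.years[0]:.1f}-{sched.years[-1]:.1f}, "
        f"{len(series)} series ({', '.join(sorted(set(series.values())))})"
    )

# the observations a fit would see for one country: truth x bias x noise
c = world.countries[0]
obs = [r for r in world.observations if r.country == c and r.indicator == "U5MR"]
print(f"\nfirst observations for {c} (value is per 1000 livebirths):")
for r in obs[:5]:
    truth = float(world.schedules[c].u5mr_at(r.reference_year))
    print(f"  {r.reference_year:.1f}  {r.source_type:<12} value={r.value:7.2f} "
          f"truth={truth:7.2f}  se_log={r.se_log}")
print("\nEvery NMR lies below its U5MR:",
      all(np.all(s.nmr_true < s.u5mr_true) for s in world.schedules.values()))
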