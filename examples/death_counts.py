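"""Convert rates and livebirths into death counts with the birth-week
cohort method.

Each annual cohort is split into 52 weekly cohorts exposed step by step to
calendar- and age-specific hazards; deaths are allocated to the calendar
year and age group (neonatal vs 1-59 months) in which they occur.  Under a
constant schedule the annual deaths equal births x rate/1000, which the
example verifies.
"""

import numpy as np

import childmort as cm
from childmort.cohort import build_mortality_schedule, compute_cohort_deaths

years = np.arange(1980, 2021)
births = cm.LivebirthsSeries("X", years, np.full(len(years), 100_000.0))
schedules = [build_mortality_schedule(u5mr=50.0, nmr=20.0, year=y) for y in years]

table, ledger = compute_cohort_deaths(births, schedules, np.arange(2000, 2005),
                                      return_ledger=True)
print(table.round(1).to_string(index=False))
print("\nsteady state: 100000 births x 50/1000 = 5000 under-5 deaths/yr;"
      " 20/1000 -> 2000 neonatal")
cons = (ledger.deaths + ledger.survivors_age5 - ledger.cohort_size).abs().max()
print(f"cohort conservation error (deaths + survivors - births): {cons:.2e}")
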