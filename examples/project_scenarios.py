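"""Project 2020-2030 mortality under the four scenarios for one country.

A country at U5MR 80 per 1000 declining at 2%/yr is projected under:
constant 2019 levels; current trends; achieving the SDG target (25 by 2030);
and achieving the 2019 high-income-country average (5.0 by 2030).
"""

import numpy as np

import childmort as cm
from childmort.scenarios import SCENARIO_NAMES, ScenarioConfig, project_nmr, project_u5mr

est_2019_u5mr, arr_u5mr = 80.0, 0.02
est_2019_nmr, arr_nmr = 30.0, 0.015

print("projected U5MR per 1000 (2020, 2025, 2030):")
paths = {}
for name in SCENARIO_NAMES:
    cfg = ScenarioConfig(name=name)
    u = project_u5mr(est_2019_u5mr, arr_u5mr, cfg)
    n = project_nmr(est_2019_nmr, arr_nmr, u, cfg)
    paths[name] = (u, n)
    print(f"  {name:<15} {u[0]:6.1f} {u[5]:6.1f} {u[-1]:6.1f}   "
          f"(NMR 2030: {n[-1]:5.1f})")

print("\nSDG path ends exactly on target; the scenarios are ordered "
      "hic <= sdg <= current <= constant at every year:",
      bool(np.all(paths["achieve_hic"][0] <= paths["achieve_sdg"][0])
           and np.all(paths["achieve_sdg"][0] <= paths["current_trends"][0])
           and np.all(paths["current_trends"][0] <= paths["constant_2019"][0])))

# a fast-declining low-mortality country hits the 1.7 floor and stays there
floor_path = project_u5mr(2.0, 0.10, ScenarioConfig(name="current_trends"))
print("\nfloor rule: U5MR 2.0 declining 10%/yr ->", np.round(floor_path, 2))
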