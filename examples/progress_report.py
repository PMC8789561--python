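"""Classify SDG progress and recompute published derived indicators.

The classifier compares a country's 2019 estimate and 2010-19 annual rate of
reduction (ARR) against the 2030 target; the derived indicators reproduce
the published global summary figures from the printed rates.
"""

from childmort.progress import (
    classify_progress,
    fold_ratio,
    one_in_n,
    percent_decline,
    share_percent,
)
from childmort.published import summary_table
from childmort.scenarios import compute_arr

for est, arr in [(20.0, 0.03), (30.0, 0.05), (50.0, 0.02), (90.0, -0.01)]:
    s = classify_progress(est, arr, target=25.0)
    print(f"U5MR 2019 = {est:5.1f}, ARR = {100*arr:+.0f}%/yr -> {s.status:<20} "
          f"(needs {s.acceleration_factor:.1f}x pace, band {s.band}, "
          f"reaches target {s.achievement_year})")

t = summary_table()
w = t.loc["World"]
print("\nderived indicators from published rates:")
print("  global U5MR decline 1990-2019:",
      percent_decline(w.u5mr_1990, w.u5mr_2019), "%")
print("  global U5MR ARR 1990-2019:",
      round(100 * compute_arr(w.u5mr_1990, w.u5mr_2019, 1990, 2019), 1), "%/yr")
print("  neonatal share of under-5 deaths 2019:",
      share_percent(w.neo_deaths_2019, w.u5_deaths_2019), "%")
print("  sub-Saharan Africa 2019: one child in",
      one_in_n(t.loc['Sub-Saharan Africa', 'u5mr_2019']), "dies before age 5")
print("  west/central Africa vs high-income U5MR:",
      fold_ratio(t.loc['West and central Africa', 'u5mr_2019'],
                 t.loc['High income', 'u5mr_2019']), "times higher")
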