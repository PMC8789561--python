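"""Published global and regional 2019-round mortality summaries (input data).

Point estimates transcribed from the publicly released UN IGME 2020-round
global/regional summary tables: mortality rates per 1000 livebirths and death
counts in thousands, for 1990 and 2019.  These serve as *inputs* to the
derived-indicator functions (percent declines, annual rates of reduction,
shares, one-in-N and fold ratios); nothing in the estimation pipeline reads
them.
"""

from __future__ import annotations

import pandas as pd

# columns: group, kind, u5mr_1990, u5mr_2019, u5_deaths_1990, u5_deaths_2019,
#          nmr_1990, nmr_2019, neo_deaths_1990, neo_deaths_2019
_ROWS = [
    ("World", "global", 93.0, 37.7, 12494, 5189, 36.6, 17.5, 5014, 2440),
    ("Sub-Saharan Africa", "region", 178.5, 75.8, 3826, 2844, 45.3, 27.5, 1016, 1059),
    ("West and central Africa", "region", 196.2, 94.7, 2020, 1836, 48.0, 30.9, 519, 616),
    ("Eastern and southern Africa", "region", 161.9, 55.4, 1806, 1009, 42.7, 23.8, 497, 443),
    ("Middle East and north Africa", "region", 64.9, 21.8, 545, 219, 27.8, 12.3, 235, 123),
    ("South Asia", "region", 129.7, 40.2, 4748, 1406, 58.7, 25.1, 2193, 882),
    ("East Asia and Pacific", "region", 56.7, 14.3, 2301, 435, 27.5, 7.2, 1106, 218),
    ("Latin America and the Caribbean", "region", 54.6, 16.3, 641, 169, 22.5, 9.1, 266, 94),
    ("Europe and central Asia", "region", 30.7, 8.1, 386, 88, 14.0, 4.4, 174, 47),
    ("Eastern Europe and central Asia", "region", 46.3, 11.5, 328, 70, 20.5, 6.0, 144, 36),
    ("Western Europe", "region", 10.5, 3.8, 58, 19, 5.6, 2.3, 30, 11),
    ("North America", "region", 11.0, 6.3, 47, 27, 5.6, 3.7, 24, 16),
    ("Low income", "income", 182.5, 67.6, 2359, 1509, 48.2, 26.6, 656, 609),
    ("Lower-middle income", "income", 124.3, 48.9, 7151, 3074, 49.8, 23.8, 2929, 1516),
    ("Upper-middle income", "income", 54.7, 13.3, 2804, 542, 26.4, 6.9, 1338, 280),
    ("High income", "income", 13.0, 5.0, 179, 63, 6.6, 2.9, 91, 36),
]

COLUMNS = [
    "group", "kind",
    "u5mr_1990", "u5mr_2019", "u5_deaths_1990", "u5_deaths_2019",
    "nmr_1990", "nmr_2019", "neo_deaths_1990", "neo_deaths_2019",
]


def summary_table() -> pd.DataFrame:
    """The published summary table as a DataFrame indexed by group name."""
    return pd.DataFrame(_ROWS, columns=COLUMNS).set_index("group")
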