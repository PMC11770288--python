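"""Published cohort benchmark table (December 2023 US DHI case study).

Per-cohort mean KPI for 712 farms (>=30 milking cows each) grouped into
8 equal cohorts of 89 farms by balanced K-means on their KPI.  Units
are the ones farmers use: lb/cow/day, $/cwt, $/cow/day; SCC in x1,000
cells/mL.  Used as a worked example: the FE column should be
reproducible as ECM(milk, fat, protein) / DMI, and the IOFC column as
milk/100 x price - feed cost (small residuals reflect that the printed
numbers are means of per-farm ratios).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["DECEMBER_2023_COHORTS"]

_COLUMNS = [
    "cohort", "n_farms", "cows_per_farm", "mean_lactation", "mean_age_days",
    "milk_lb", "fat_pct", "protein_pct", "scc_kcells", "dmi_lb", "fe",
    "milk_price_cwt", "feed_cost_day", "iofc_day",
]

_ROWS = [
    (1, 89, 78, 2.35, 1519, 71.7, 4.32, 3.37, 305, 54.7, 1.47, 19.26, 6.02, 7.71),
    (2, 89, 76, 2.59, 1661, 75.8, 4.13, 3.28, 135, 56.0, 1.48, 18.89, 6.17, 8.10),
    (3, 89, 77, 3.47, 2034, 76.2, 4.29, 3.33, 202, 56.4, 1.49, 19.31, 6.23, 8.42),
    (4, 89, 76, 2.36, 1498, 80.1, 4.22, 3.29, 112, 57.8, 1.53, 19.21, 6.38, 8.94),
    (5, 89, 108, 2.04, 1320, 82.2, 4.27, 3.31, 111, 58.7, 1.56, 19.38, 6.49, 9.41),
    (6, 89, 271, 2.49, 1509, 86.5, 4.32, 3.34, 145, 60.0, 1.61, 19.52, 6.63, 10.20),
    (7, 89, 1781, 2.37, 1404, 88.9, 4.36, 3.37, 155, 61.4, 1.63, 19.66, 6.93, 10.50),
    (8, 89, 536, 2.39, 1427, 91.6, 4.31, 3.30, 120, 61.9, 1.66, 19.47, 6.87, 10.88),
]

DECEMBER_2023_COHORTS: pd.DataFrame = pd.DataFrame(_ROWS, columns=_COLUMNS)
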