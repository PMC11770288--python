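"""Quadrant analysis and progressive goals for one farm.

Picks a mid-pack farm from a synthetic cohort, classifies its peers on
the milk-vs-IOFC plane (yellow = better on both = candidate farms), and
derives the four goal levels per KPI from the candidates: basic (first
quartile of improvement), moderate (mean), medium (third quartile),
strong (cohort extreme), each with the IOFC impact of attaining it.
"""

from herdbench import (
    GeneratorSpec, PriceConfig, add_economics, cluster_farms, generate,
    quadrant_classify, recommend, snapshot_herds,
)
from herdbench.goals import goals_frame

records, _ = generate(GeneratorSpec(n_farms=120), seed=7)
snaps = add_economics(snapshot_herds(records, "2023-12"), PriceConfig())
assignment = cluster_farms(snaps, k=4, seed=0)

focal = snaps.sort_values("milk_lb")["farm_id"].iloc[len(snaps) // 2]
cohort = snaps[snaps["farm_id"].map(assignment.assignment) == assignment.cohort_of(focal)]

quad = quadrant_classify(cohort, "milk_lb", "iofc_day", focal)
print(f"farm {focal} vs {len(cohort) - 1} peers:", quad.counts())
print(f"candidate farms (better milk AND better IOFC): {len(quad.candidates)}\n")

focal_row = cohort[cohort["farm_id"] == focal].iloc[0]
goals = goals_frame(recommend(focal_row, cohort, PriceConfig()))
cols = ["kpi", "current", "basic", "moderate", "medium", "strong", "impact_strong_pct"]
print(goals[cols].round(2).to_string(index=False))
print("\nEvery goal is a value some cohort peer already achieves; the impact")
print("column is the % IOFC change if the farm reaches the strong target.")
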