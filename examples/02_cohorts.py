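"""Equal-size peer cohorts on a synthetic DHI month.

Generates 240 farms of December test-day records, aggregates them to
farm snapshots with full economics, and clusters them into 8 cohorts of
exactly 30 farms each by balanced K-means on the z-scored KPI.  The
summary table (one row per cohort, ordered by mean milk) is the shape a
farmer's benchmark report takes.
"""

from herdbench import (
    GeneratorSpec, PriceConfig, add_economics, cluster_farms,
    cohort_summary, generate, snapshot_herds,
)

records, _ = generate(GeneratorSpec(n_farms=240), seed=42)
snaps = add_economics(snapshot_herds(records, "2023-12"), PriceConfig())
assignment = cluster_farms(snaps, k=8, seed=0)

print("cohort sizes:", assignment.sizes())
summary = cohort_summary(snaps, assignment)
cols = ["cohort", "n_farms", "milk_lb", "fat_pct", "scc_kcells", "fe", "iofc_day"]
print(summary[cols].round(2).to_string(index=False))
print("\nEach row is one peer group; milk rises down the table while IOFC")
print("tracks it, so a farm is compared against herds that look like it.")
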