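# Methods

This note records the models behind `herdbench`, the defaults and why
they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## The KPI chain

One farm-month snapshot is built from each cow's latest test in the
month; milk, fat %, protein %, age, lactation and days in milk are
arithmetic means over cows. SCC aggregation is the arithmetic mean of
cow SCC by default; a milk-weighted mean is available via
`scc_policy="milk_weighted"` (bulk-tank SCC is milk-weighted by nature,
but test-day reports are cow-level, and the plain mean keeps the
snapshot a simple average of its rows — the policy is a one-flag
choice).

**Energy-corrected milk.** `ECM = 0.323·M + 12.82·fat_lb + 7.13·protein_lb`
with the 3.5% fat / 3.2% protein normalization: the coefficients satisfy
`0.323 + 12.82(0.035) + 7.13(0.032) = 0.99986`, so ECM equals raw milk
at the reference composition to 0.02%. Reconstructing FE for all eight
rows of the December 2023 benchmark cohort table with this coefficient
set matches the printed FE column within ±0.02 (the residual is
consistent with those rows being means of per-farm ratios rather than
ratios of means).

**Dry matter intake.** Test-day files carry no intake, so DMI is
predicted from performance with the NRC-2001-style equation
`DMI_kg = (0.372·ECM_kg + 0.0968·BW^0.75)·(1 − e^{−0.192(WOL+3.67)})`,
BW defaulting to 680 kg (a mature Holstein) and WOL = DIM/7. When DIM
is unavailable the lag factor is taken at its asymptote of 1. Predicted
DMI feeds both feed cost (`DMI × ration price`) and FE; it is a
modeling estimate, not a measurement, and all economic KPI inherit that
approximation.

**Pricing.** A single standardized schedule replaces the zoo of
cooperative premium schedules: Class III base plus linear
differentials on fat, protein and SCC and a flat volume premium.
Defaults (late-2023 US conditions): base 16.04 $/cwt, fat +2.50 $/cwt
per point, protein +2.00, SCC +0.0005 $/cwt per 1,000 cells below 350,
volume premium 0.50 $/cwt, ration 0.11 $/lb DM. These produce farm
prices near 19.3 $/cwt and IOFC near 9–10 $/cow/day at typical
composition — the range the published cohort table reports. Every
constant lives in `PriceConfig`; none is hard-coded downstream.

**IOFC** is `milk/100 × price − feed cost` (cwt = 100 lb). Reconstructed
IOFC for the published cohort rows agrees with the printed column
within $0.10/cow/day, again a mean-of-ratios residual.

## Balanced K-means cohorts

Farms are clustered on z-scored KPI (population SD; the default feature
set is the full snapshot KPI column list). Plain K-means produces
wildly unequal clusters on herd data (herd size is heavy-tailed), so
the assignment step is replaced by an exact transportation problem:
minimize total squared distance subject to every farm in exactly one
cluster and every cluster size within [⌊n/k⌋, ⌈n/k⌉]. When k divides n
this is solved as a linear assignment on a slot-expanded square matrix
(`scipy.optimize.linear_sum_assignment`); otherwise as an LP
(`scipy.optimize.linprog`/HiGHS) whose constraint matrix is totally
unimodular, so the optimal vertex is integral — which clusters take the
extra farm is part of the optimization, not a fixed choice. Both
alternating steps are exact minimizations, so the within-cluster sum of
squares is non-increasing and the size invariant holds at every
iteration.

Alternating minimization under a balance constraint has noticeably more
local minima than free K-means, so convergence is followed by a
best-improvement exchange polish: repeatedly apply the pairwise swap
(or, when sizes are unequal, the single-point move from a ceil-size to
a floor-size cluster) that most reduces the true WCSS, using the
`WCSS_j = Σ‖x‖² − ‖s_j‖²/n_j` identity for O(d) deltas, until no
exchange improves. On all tested instances with n ≤ 8 the best of 20
k-means++ restarts then attains the exhaustive-search balanced optimum;
without the polish it misses on a few percent of instances.

Initialization is k-means++ from the caller's seed; after convergence
cohorts are relabeled 1..k by ascending mean milk, which both matches
how benchmark tables are presented and removes label-permutation
nondeterminism. Assignment ties are resolved by the deterministic
solver; fixed seed and input order give identical assignments.

## Quadrants and goals

Each KPI carries an improvement direction (SCC and feed cost improve
downward; everything else upward). Quadrant classification orients both
axes so "better" is positive and uses strict inequality — a peer tied
with the focal farm is not better, hence not a candidate. This makes
the four categories an exact partition of the cohort minus the focal
farm and keeps candidacy conservative; the strictness choice is
centralized in one comparison.

Goal levels come from the candidate distribution *in the improvement
direction*: basic = first quartile of improvement (the 75th raw
percentile for a lower-better KPI), moderate = mean, medium = third
quartile, strong = the extreme. Percentiles use linear interpolation on
sorted values (`numpy.percentile` default). With one candidate all
levels coincide; with none the farm "leads its cohort" and the
recommender returns a marker rather than goals. For the per-KPI goal
table, candidacy is one-dimensional (peers better on that KPI alone);
the two-KPI candidate set from the quadrant view serves the scatter
analysis — per-KPI goal rows cannot all derive from one 2-D candidate
set.

Economic impact of a goal rebuilds the chain with only that KPI moved:
a milk goal propagates through ECM into predicted intake and feed cost;
fat, protein and SCC goals act on revenue only (intake held at
baseline — a composition goal should not silently change the feed
bill); a feed-cost goal overrides the predicted feed cost directly.
Impact is the relative IOFC change in percent; a zero baseline IOFC
makes relative impact undefined and raises.

## Scenario simulation

Deltas (absolute or percent) apply at the cow level within scope (whole
herd or a set of lactation numbers), then aggregation and economics are
recomputed from scratch — lactation scoping is impossible on herd
means. The ration-price delta acts on $/lb DM rather than total feed
spend so that simulated feed cost still responds to intake driven by
simulated yield. Deltas that push any cow outside physiological bounds
(milk < 0, fat outside (0, 12), protein outside (0, 8), SCC < 0) abort
naming the cow. Zero-delta scenarios are exact identities; sequential
absolute scenarios compose additively.

## The synthetic generator

The generator emulates one December of monthly DHI testing at the scale
of a large upper-midwest processing center: 712 farms by default, herd
sizes lognormal(μ=5.2, σ=1.1) floored at 30 cows (mean ≈ 330 cows/farm,
herd total ≈ 2×10⁵ cows), whole herds tested on a single farm-specific
day. Farm-level milk means spread 60–105 lb/day, fat means 4.1–4.4%,
protein 3.2–3.4%, SCC medians 60–400; milk is negatively correlated
with fat (−0.3) and SCC (−0.25) across farms through a Gaussian copula,
reflecting dilution and udder-health gradients. Cow-level values are
normal around farm means (SCC lognormal), lactation 1 + Poisson(1.4)
(mean ≈ 2.4), age tied to lactation, DIM uniform 5–305. These ranges
bracket the published cohort-mean table so the clustered synthetic
population exercises the same KPI space.

What it does not emulate: lactation-curve structure (milk is not a
function of DIM), seasonal effects, herd-level management correlations
beyond the three-way copula, missing data and typographical noise, or
multi-month cow tracking. Tests passing on this data therefore
demonstrate correctness of the computations and the structural
guarantees (balance, determinism, partitions), not calibration against
real herd heterogeneity.

A ground-truth sidecar (true farm means and medians) is written next to
every generated CSV so aggregation can be validated by parameter
recovery: at 100 cows/farm, ≥99% of farm milk means land within 3
standard errors of truth (the 5 lb floor clips the left tail slightly).

## Numerical and interface choices

- All arithmetic is in farmer units (lb, cwt, $) with 1 lb = 0.454 kg
  as the single conversion constant.
- Validation rejects rows rather than dropping them: every reject
  carries its 1-based file line and a reason; duplicate
  (farm, cow, date) keys keep the first occurrence.
- Pseudonymization is a keyed BLAKE2b hash (12 hex chars) of the salted
  id — deterministic per salt, non-reversible without it; an empty salt
  is refused.
- Problem sizes in the test and acceptance suites: full-scale
  clustering uses the 712-farm default over 5 seeds; exhaustive
  clustering oracles use n ≤ 8, k ∈ {2, 3} where brute force over all
  balanced partitions is exact; goal and quadrant oracles use 1,000
  random instances each.
- The CLI is a thin typer layer over the library; every subcommand is a
  few lines calling one public function, and all randomness flows from
  explicit `--seed` arguments.

## Known limitations

- Predicted DMI makes FE and IOFC model-based; farms feeding far from
  the assumed ration price or body weight need config overrides.
- The balanced K-means polish is a local search: global optimality is
  verified only at oracle scale. At 712 farms the result is a
  high-quality local optimum — never worse than the unpolished
  alternating fixed point, and bounded below by the unconstrained
  K-means objective (the constraint can only cost WCSS).
- Goal impacts are single-KPI, holding the rest fixed; attaining several
  goals at once is not additive in general.
- One month at a time: no longitudinal joins or trend analytics.
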