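"""Progressive-goal recommendation from candidate-farm performance.

For each KPI, candidate farms are the cohort peers strictly better than
the evaluated farm on that KPI.  Four goal levels are read off the
candidates' distribution in the improvement direction:

    basic    = first quartile of improvement
    moderate = arithmetic mean
    medium   = third quartile of improvement
    strong   = the extreme (max for higher-better, min for lower-better)

so every goal is a value some cohort peer already achieves.  For a
lower-better KPI such as SCC the "first quartile of improvement" is the
75th percentile of the raw values.  The economic impact of attaining a
goal is the relative IOFC change when only that KPI is moved to the goal
value and the rest of the KPI chain is rebuilt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import (
    PriceConfig,
    ecm_lb,
    estimate_dmi,
    feed_cost_day,
    iofc_day,
    milk_price_cwt,
)
from .quadrants import Direction, kpi_direction

__all__ = [
    "GoalLevels",
    "GoalSet",
    "NoCandidateFarms",
    "goal_levels",
    "economic_impact",
    "recommend",
]

LEVELS = ("basic", "moderate", "medium", "strong")

#: KPI the recommender can move through the economic chain.
IMPACT_KPIS = ("milk_lb", "fat_pct", "protein_pct", "scc_kcells", "feed_cost_day")


class NoCandidateFarms(Exception):
    """No cohort peer outperforms the farm on this KPI (farm leads cohort)."""


@dataclass(frozen=True)
class GoalLevels:
    basic: float
    moderate: float
    medium: float
    strong: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.basic, self.moderate, self.medium, self.strong)


@dataclass
class GoalSet:
    """Recommended targets and IOFC impact for one KPI.

    ``leads_cohort`` marks a KPI on which no peer outperforms the farm;
    goals and impacts are then None.
    """

    kpi: str
    current: float
    levels: GoalLevels | None
    impact_pct: dict[str, float] | None = field(default=None)
    leads_cohort: bool = False


def goal_levels(candidate_values, direction: Direction | str) -> GoalLevels:
    """Quartile/mean/extreme goal levels from candidate-farm values.

    Percentiles use linear interpolation on the sorted values.  With a
    single candidate all four levels equal that value.  Raises
    :class:`NoCandidateFarms` on an empty candidate set.
    """
    v = np.asarray(candidate_values, dtype=float)
    if v.size == 0:
        raise NoCandidateFarms("no goals available: empty candidate set")
    direction = Direction(direction)
    if direction is Direction.HIGHER_BETTER:
        q1, q3, extreme = (
            np.percentile(v, 25), np.percentile(v, 75), np.max(v),
        )
    else:
        q1, q3, extreme = (
            np.percentile(v, 75), np.percentile(v, 25), np.min(v),
        )
    return GoalLevels(
        basic=float(q1), moderate=float(v.mean()), medium=float(q3),
        strong=float(extreme),
    )


def _iofc_chain(
    milk: float, fat: float, protein: float, scc: float,
    cfg: PriceConfig, dim: float | None, feed_cost_override: float | None = None,
) -> float:
    price = milk_price_cwt(fat, protein, scc, cfg)
    if feed_cost_override is None:
        dmi = estimate_dmi(ecm_lb(milk, fat, protein), cfg.bw_kg, dim)
        feed = feed_cost_day(dmi, cfg.ration_price_lb_dm)
    else:
        feed = feed_cost_override
    return iofc_day(milk, price, feed)


def _snapshot_fields(snapshot) -> dict[str, float]:
    get = snapshot.get if hasattr(snapshot, "get") else lambda k, d=None: getattr(snapshot, k, d)
    dim = get("mean_dim", None)
    if dim is not None and not np.isfinite(dim):
        dim = None
    return {
        "milk_lb": float(get("milk_lb")),
        "fat_pct": float(get("fat_pct")),
        "protein_pct": float(get("protein_pct")),
        "scc_kcells": float(get("scc_kcells")),
        "mean_dim": dim,
    }


def economic_impact(snapshot, kpi: str, goal_value: float, cfg: PriceConfig) -> float:
    """Percent IOFC change when one KPI is moved to ``goal_value``.

    The chain is rebuilt with only that KPI changed, everything else
    held fixed: a milk goal propagates through ECM into predicted intake
    and hence feed cost; composition and SCC goals act on revenue only
    (feed cost stays at the baseline prediction); a ``feed_cost_day``
    goal overrides the predicted feed cost directly.  Returns
    100 * (IOFC_new - IOFC_old) / IOFC_old.
    """
    if kpi not in IMPACT_KPIS:
        raise ValueError(f"impact undefined for KPI {kpi!r}; supported: {IMPACT_KPIS}")
    f = _snapshot_fields(snapshot)
    dim = f.pop("mean_dim")
    base_dmi = estimate_dmi(
        ecm_lb(f["milk_lb"], f["fat_pct"], f["protein_pct"]), cfg.bw_kg, dim
    )
    base_feed = feed_cost_day(base_dmi, cfg.ration_price_lb_dm)
    old = _iofc_chain(
        f["milk_lb"], f["fat_pct"], f["protein_pct"], f["scc_kcells"],
        cfg, dim, feed_cost_override=base_feed,
    )
    if old == 0:
        raise ZeroDivisionError("undefined relative impact: baseline IOFC is 0")
    if kpi == "feed_cost_day":
        feed = float(goal_value)
    elif kpi == "milk_lb":
        feed = None  # recompute from the new milk via ECM-driven intake
    else:
        feed = base_feed
    if kpi != "feed_cost_day":
        f[kpi] = float(goal_value)
    new = _iofc_chain(
        f["milk_lb"], f["fat_pct"], f["protein_pct"], f["scc_kcells"],
        cfg, dim, feed_cost_override=feed,
    )
    return 100.0 * (new - old) / old


def recommend(
    snapshot,
    cohort_snapshots: pd.DataFrame,
    cfg: PriceConfig,
    kpi_list: tuple[str, ...] = IMPACT_KPIS,
) -> list[GoalSet]:
    """Progressive goals for every KPI in ``kpi_list``.

    Candidacy is one-dimensional: for each KPI the candidates are the
    cohort peers strictly better on that KPI alone.  A KPI on which the
    farm already leads its cohort yields a ``leads_cohort`` marker
    instead of goals.
    """
    f = _snapshot_fields(snapshot)
    get = snapshot.get if hasattr(snapshot, "get") else lambda k, d=None: getattr(snapshot, k, d)
    focal_id = str(get("farm_id"))
    peers = cohort_snapshots[cohort_snapshots["farm_id"].astype(str) != focal_id]
    out: list[GoalSet] = []
    for kpi in kpi_list:
        if kpi not in peers.columns:
            raise ValueError(f"KPI {kpi!r} missing from cohort snapshots")
        direction = kpi_direction(kpi)
        current = float(get(kpi))
        values = peers[kpi].to_numpy(dtype=float)
        if direction is Direction.HIGHER_BETTER:
            cand = values[values > current]
        else:
            cand = values[values < current]
        try:
            levels = goal_levels(cand, direction)
        except NoCandidateFarms:
            out.append(GoalSet(kpi=kpi, current=current, levels=None, leads_cohort=True))
            continue
        impact = {
            name: economic_impact(snapshot, kpi, value, cfg)
            for name, value in zip(LEVELS, levels.as_tuple())
        }
        out.append(GoalSet(kpi=kpi, current=current, levels=levels, impact_pct=impact))
    return out


def goals_frame(goal_sets: list[GoalSet]) -> pd.DataFrame:
    """Tabulate goal sets: one row per KPI, goal and impact columns."""
    rows = []
    for g in goal_sets:
        row: dict[str, object] = {"kpi": g.kpi, "current": g.current, "leads_cohort": g.leads_cohort}
        for name in LEVELS:
            row[name] = getattr(g.levels, name) if g.levels else np.nan
            row[f"impact_{name}_pct"] = g.impact_pct[name] if g.impact_pct else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
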