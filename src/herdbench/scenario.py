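"""What-if simulation: apply management deltas and recompute the KPI chain.

A scenario perturbs variables under farm control — milk yield, fat and
protein content, SCC, and ration (diet) price — either herd-wide or for
specific lactation groups.  Deltas are applied at the cow level, the
farm snapshot is re-aggregated from scratch, and the economic chain is
recomputed, so a lactation-scoped change only moves the herd means
through the affected cows.  The ration-price delta acts on the $/lb DM
price (not total feed spend), so simulated feed cost still responds to
intake changes driven by milk yield.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .economics import PriceConfig, add_economics
from .ingest import snapshot_herds

__all__ = ["Scenario", "ScenarioReport", "apply_scenario"]

#: Variables a scenario may change, with their per-cow validity bounds.
_COW_BOUNDS = {
    "milk_lb": (0.0, float("inf"), "[0, inf)"),
    "fat_pct": (0.0, 12.0, "(0, 12)"),
    "protein_pct": (0.0, 8.0, "(0, 8)"),
    "scc_kcells": (0.0, float("inf"), "[0, inf)"),
}
ALLOWED_KEYS = tuple(_COW_BOUNDS) + ("ration_price_lb_dm",)
_MODES = ("absolute", "percent")

_KPI_REPORT = [
    "n_cows", "milk_lb", "fat_pct", "protein_pct", "scc_kcells",
    "dmi_lb", "fe", "milk_price_cwt", "feed_cost_day", "iofc_day",
]


@dataclass(frozen=True)
class Scenario:
    """A set of deltas with a scope.

    ``deltas`` maps a variable to ``(amount, mode)`` where mode is
    "absolute" (added) or "percent" (value scaled by 1 + amount/100).
    ``lactation_groups`` of None means the whole herd; otherwise only
    cows in the listed lactation numbers are changed.
    """

    deltas: dict[str, tuple[float, str]] = field(default_factory=dict)
    lactation_groups: frozenset[int] | None = None

    def __post_init__(self) -> None:
        for key, (_, mode) in self.deltas.items():
            if key not in ALLOWED_KEYS:
                raise ValueError(f"unknown scenario variable {key!r}; allowed: {ALLOWED_KEYS}")
            if mode not in _MODES:
                raise ValueError(f"unknown delta mode {mode!r}; allowed: {_MODES}")
        if self.lactation_groups is not None and len(self.lactation_groups) == 0:
            raise ValueError("lactation_groups must be nonempty when given")


@dataclass
class ScenarioReport:
    """Before/after snapshot rows plus a per-KPI delta table."""

    before: pd.Series
    after: pd.Series
    deltas: pd.DataFrame  # index: KPI; columns: old, new, change

    def change(self, kpi: str) -> float:
        return float(self.deltas.loc[kpi, "change"])


def _apply(values: pd.Series, amount: float, mode: str) -> pd.Series:
    if mode == "absolute":
        return values + amount
    return values * (1.0 + amount / 100.0)


def apply_scenario(
    records: pd.DataFrame,
    scenario: Scenario,
    cfg: PriceConfig,
    month: str,
    scc_policy: str = "mean",
) -> ScenarioReport:
    """Simulate a scenario on one farm's test-day records.

    Cow-level deltas are applied inside the scenario's scope, then the
    snapshot and economics are recomputed from scratch; cows outside the
    scope are untouched.  A delta that pushes any cow outside the
    physiological bounds aborts with the cow and the violated bound
    named.  An all-zero scenario is an exact identity on every KPI.
    """
    farms = records["farm_id"].unique()
    if len(farms) != 1:
        raise ValueError(f"apply_scenario expects one farm, got {len(farms)}")

    before = add_economics(snapshot_herds(records, month, scc_policy), cfg).iloc[0]

    modified = records.copy()
    if scenario.lactation_groups is None:
        scope = pd.Series(True, index=modified.index)
    else:
        scope = modified["lactation_no"].isin(scenario.lactation_groups)

    new_cfg = cfg
    for key, (amount, mode) in scenario.deltas.items():
        if key == "ration_price_lb_dm":
            base = new_cfg.ration_price_lb_dm
            new_price = base + amount if mode == "absolute" else base * (1 + amount / 100.0)
            if new_price <= 0:
                raise ValueError("scenario drives ration price nonpositive")
            new_cfg = new_cfg.with_updates(ration_price_lb_dm=float(new_price))
            continue
        new_vals = _apply(modified.loc[scope, key], amount, mode)
        lo, hi, bound = _COW_BOUNDS[key]
        bad = (new_vals < lo) | (new_vals > hi)
        if key in ("fat_pct", "protein_pct"):
            bad |= new_vals <= lo
        if bad.any():
            cow = modified.loc[bad[bad].index[0], "cow_id"]
            raise ValueError(f"scenario drives cow {cow!r} {key} outside {bound}")
        modified.loc[scope, key] = new_vals

    after = add_economics(snapshot_herds(modified, month, scc_policy), new_cfg).iloc[0]

    deltas = pd.DataFrame(
        {
            "old": [float(before[k]) for k in _KPI_REPORT],
            "new": [float(after[k]) for k in _KPI_REPORT],
        },
        index=_KPI_REPORT,
    )
    deltas["change"] = deltas["new"] - deltas["old"]
    return ScenarioReport(before=before, after=after, deltas=deltas)
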