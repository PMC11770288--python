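"""Economic KPI chain for dairy benchmarking.

The chain turns test-day physiology (milk yield, fat %, protein %, SCC)
into farm economics:

    ECM -> DMI estimate -> feed cost      (cost side)
    components + SCC -> milk price        (revenue side)
    IOFC = milk income - feed cost        (margin)

All quantities are kept in the units US dairy farmers use: lb/cow/day for
milk and intake, $/cwt for milk price (cwt = 100 lb), $/cow/day for costs
and IOFC.  1 lb = 0.454 kg.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "KG_PER_LB",
    "PriceConfig",
    "ecm_lb",
    "feed_efficiency",
    "estimate_dmi",
    "feed_cost_day",
    "milk_price_cwt",
    "iofc_day",
    "add_economics",
]

KG_PER_LB = 0.454

# Energy-corrected milk, normalized to 3.5% fat / 3.2% protein.  The
# coefficient set is chosen so that ECM equals raw milk at the reference
# composition: 0.323 + 12.82*0.035 + 7.13*0.032 = 0.99986.
_ECM_MILK = 0.323
_ECM_FAT = 12.82
_ECM_PROTEIN = 7.13


@dataclass(frozen=True)
class PriceConfig:
    """Standardized pricing: a Class III base plus linear component adjustments.

    Component differentials are expressed per percentage point deviation
    from the reference composition; the SCC adjustment is per 1,000
    cells/mL below the reference count (so a herd under the reference
    earns a premium).  Defaults reflect late-2023 US market conditions.

    Attributes
    ----------
    class3_base_cwt : Class III base milk price, $/cwt.
    fat_ref_pct, protein_ref_pct : reference composition, %.
    fat_diff, protein_diff : $/cwt per percentage point above reference.
    scc_ref_kcells : reference SCC, x1,000 cells/mL.
    scc_diff : $/cwt per 1,000 cells below reference (signed).
    volume_premium_cwt : flat premium, $/cwt.
    ration_price_lb_dm : ration price, $/lb dry matter.
    bw_kg : assumed mature body weight for intake prediction, kg.
    """

    class3_base_cwt: float = 16.04
    fat_ref_pct: float = 3.5
    protein_ref_pct: float = 3.0
    fat_diff: float = 2.50
    protein_diff: float = 2.00
    scc_ref_kcells: float = 350.0
    scc_diff: float = 0.0005
    volume_premium_cwt: float = 0.50
    ration_price_lb_dm: float = 0.11
    bw_kg: float = 680.0

    def __post_init__(self) -> None:
        if self.class3_base_cwt <= 0:
            raise ValueError("class3_base_cwt must be positive")
        if self.ration_price_lb_dm <= 0:
            raise ValueError("ration_price_lb_dm must be positive")
        if not (0 < self.fat_ref_pct < 12):
            raise ValueError("fat_ref_pct outside plausible bounds (0, 12)")
        if not (0 < self.protein_ref_pct < 8):
            raise ValueError("protein_ref_pct outside plausible bounds (0, 8)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PriceConfig":
        data: dict[str, Any] = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def with_updates(self, **kwargs: float) -> "PriceConfig":
        return replace(self, **kwargs)


def ecm_lb(milk_lb, fat_pct, protein_pct):
    """Energy-corrected milk, lb/day, at 3.5% fat / 3.2% protein reference.

    Accepts scalars or array-likes (broadcast).  At the reference
    composition ECM equals raw milk to within 0.02%.
    """
    milk = np.asarray(milk_lb, dtype=float)
    if np.any(milk < 0):
        raise ValueError("milk_lb must be nonnegative")
    fat = np.asarray(fat_pct, dtype=float)
    protein = np.asarray(protein_pct, dtype=float)
    out = _ECM_MILK * milk + _ECM_FAT * (milk * fat / 100.0) + _ECM_PROTEIN * (
        milk * protein / 100.0
    )
    return out if out.ndim else float(out)


def feed_efficiency(ecm, dmi_lb):
    """Feed efficiency: ECM divided by dry matter intake (unitless)."""
    dmi = np.asarray(dmi_lb, dtype=float)
    if np.any(dmi <= 0):
        raise ValueError("dmi_lb must be positive")
    out = np.asarray(ecm, dtype=float) / dmi
    return out if out.ndim else float(out)


def estimate_dmi(ecm, bw_kg=680.0, dim=None):
    """Predicted dry matter intake, lb/cow/day.

    NRC-2001-style prediction from energy-corrected milk and body weight,

        DMI_kg = (0.372 * ECM_kg + 0.0968 * BW^0.75)
                 * (1 - exp(-0.192 * (WOL + 3.67)))

    with WOL = days in milk / 7.  The exponential term is an early-
    lactation intake lag; when ``dim`` is None the lag factor is taken as
    1 (mature-lactation asymptote).  Monotone increasing in ECM and BW.
    """
    ecm_arr = np.asarray(ecm, dtype=float)
    if np.any(ecm_arr < 0):
        raise ValueError("ecm must be nonnegative")
    bw = np.asarray(bw_kg, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("bw_kg must be positive")
    ecm_kg = ecm_arr * KG_PER_LB
    base_kg = 0.372 * ecm_kg + 0.0968 * bw**0.75
    if dim is None:
        lag = 1.0
    else:
        wol = np.asarray(dim, dtype=float) / 7.0
        lag = 1.0 - np.exp(-0.192 * (wol + 3.67))
    out = base_kg * lag / KG_PER_LB
    return out if np.ndim(out) else float(out)


def feed_cost_day(dmi_lb, ration_price_lb_dm):
    """Daily feed cost, $/cow/day = intake (lb DM) x ration price ($/lb DM)."""
    dmi = np.asarray(dmi_lb, dtype=float)
    price = np.asarray(ration_price_lb_dm, dtype=float)
    if np.any(dmi < 0) or np.any(price < 0):
        raise ValueError("dmi_lb and ration_price_lb_dm must be nonnegative")
    out = dmi * price
    return out if out.ndim else float(out)


def milk_price_cwt(fat_pct, protein_pct, scc_kcells, cfg: PriceConfig):
    """Standardized milk price, $/cwt: base + linear component adjustments.

    price = base + (fat - fat_ref) * fat_diff
                 + (protein - protein_ref) * protein_diff
                 + (scc_ref - scc) * scc_diff
                 + volume premium
    """
    fat = np.asarray(fat_pct, dtype=float)
    protein = np.asarray(protein_pct, dtype=float)
    scc = np.asarray(scc_kcells, dtype=float)
    price = (
        cfg.class3_base_cwt
        + (fat - cfg.fat_ref_pct) * cfg.fat_diff
        + (protein - cfg.protein_ref_pct) * cfg.protein_diff
        + (cfg.scc_ref_kcells - scc) * cfg.scc_diff
        + cfg.volume_premium_cwt
    )
    if np.any(price <= 0):
        raise ValueError("pricing config implausible: nonpositive milk price")
    return price if price.ndim else float(price)


def iofc_day(milk_lb, milk_price, feed_cost):
    """Income over feed cost, $/cow/day = milk income - feed cost.

    Milk income is milk_lb / 100 x price ($/cwt); negative IOFC is legal.
    """
    milk = np.asarray(milk_lb, dtype=float)
    if np.any(milk < 0):
        raise ValueError("milk_lb must be nonnegative")
    out = milk / 100.0 * np.asarray(milk_price, dtype=float) - np.asarray(
        feed_cost, dtype=float
    )
    return out if out.ndim else float(out)


def add_economics(snapshots: pd.DataFrame, cfg: PriceConfig) -> pd.DataFrame:
    """Fill the economic columns of a farm-snapshot table.

    Adds ``dmi_lb``, ``fe``, ``milk_price_cwt``, ``feed_cost_day`` and
    ``iofc_day`` computed from the snapshot's physiological means, so that
    every economic field is recomputable from the row itself.  Uses
    ``mean_dim`` for the intake lag when present.
    """
    out = snapshots.copy()
    ecm = ecm_lb(out["milk_lb"], out["fat_pct"], out["protein_pct"])
    dim = out["mean_dim"] if "mean_dim" in out.columns else None
    dmi = estimate_dmi(ecm, cfg.bw_kg, dim)
    out["dmi_lb"] = dmi
    out["fe"] = feed_efficiency(ecm, dmi)
    out["milk_price_cwt"] = milk_price_cwt(
        out["fat_pct"], out["protein_pct"], out["scc_kcells"], cfg
    )
    out["feed_cost_day"] = feed_cost_day(dmi, cfg.ration_price_lb_dm)
    out["iofc_day"] = iofc_day(
        out["milk_lb"], out["milk_price_cwt"], out["feed_cost_day"]
    )
    return out
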