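"""Two-KPI quadrant peer analysis.

A focal farm is compared against its cohort on any pair of KPI; each
peer lands in one of four quadrants after orienting both axes so that
"better" is positive.  The better-on-both peers are the *candidate
farms* that feed the progressive-goal recommendation.  Quadrant tags map
to the conventional colors: worse on both = red, better on y only =
blue, better on x only = green, better on both = yellow.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

__all__ = [
    "Direction",
    "KPI_DIRECTIONS",
    "kpi_direction",
    "QuadrantResult",
    "quadrant_classify",
]


class Direction(str, Enum):
    HIGHER_BETTER = "higher_better"
    LOWER_BETTER = "lower_better"


#: Improvement direction per KPI: SCC and feed cost improve downward.
KPI_DIRECTIONS: dict[str, Direction] = {
    "milk_lb": Direction.HIGHER_BETTER,
    "fat_pct": Direction.HIGHER_BETTER,
    "protein_pct": Direction.HIGHER_BETTER,
    "scc_kcells": Direction.LOWER_BETTER,
    "fe": Direction.HIGHER_BETTER,
    "milk_price_cwt": Direction.HIGHER_BETTER,
    "feed_cost_day": Direction.LOWER_BETTER,
    "feed_cost_cwt": Direction.LOWER_BETTER,
    "iofc_day": Direction.HIGHER_BETTER,
}

#: Quadrant tag -> display color (focal farm itself is black).
QUADRANT_COLORS = {
    "worse_both": "red",
    "better_y_only": "blue",
    "better_x_only": "green",
    "better_both": "yellow",
}


def kpi_direction(kpi_name: str) -> Direction:
    """Improvement direction of a registered KPI; unknown names error."""
    try:
        return KPI_DIRECTIONS[kpi_name]
    except KeyError:
        raise ValueError(
            f"unknown KPI {kpi_name!r}; known: {sorted(KPI_DIRECTIONS)}"
        ) from None


def oriented(values, kpi_name: str):
    """Values signed so that larger is always better for this KPI."""
    if kpi_direction(kpi_name) is Direction.LOWER_BETTER:
        return -values
    return values


@dataclass
class QuadrantResult:
    """Quadrant partition of a cohort around a focal farm."""

    focal_farm: str
    kpi_x: str
    kpi_y: str
    categories: dict[str, str]  # peer farm_id -> quadrant tag
    candidates: list[str]  # the better_both subset

    def counts(self) -> dict[str, int]:
        out = {tag: 0 for tag in QUADRANT_COLORS}
        for tag in self.categories.values():
            out[tag] += 1
        return out


def quadrant_classify(
    snapshots: pd.DataFrame, kpi_x: str, kpi_y: str, focal: str
) -> QuadrantResult:
    """Classify cohort peers into the four quadrants around ``focal``.

    "Better" is strict on the oriented axis; a tie counts as not-better,
    so a peer tied with the focal farm on both axes is tagged
    ``worse_both``.  The four categories partition the cohort minus the
    focal farm.
    """
    ids = snapshots["farm_id"].astype(str)
    if focal not in set(ids):
        raise ValueError(f"focal farm {focal!r} not in snapshots")
    x = oriented(snapshots[kpi_x].to_numpy(dtype=float), kpi_x)
    y = oriented(snapshots[kpi_y].to_numpy(dtype=float), kpi_y)
    pos = int((ids.to_numpy() == focal).argmax())
    fx, fy = x[pos], y[pos]

    categories: dict[str, str] = {}
    for i, farm in enumerate(ids):
        if farm == focal:
            continue
        bx, by = x[i] > fx, y[i] > fy
        if bx and by:
            tag = "better_both"
        elif bx:
            tag = "better_x_only"
        elif by:
            tag = "better_y_only"
        else:
            tag = "worse_both"
        categories[farm] = tag
    candidates = [f for f, t in categories.items() if t == "better_both"]
    return QuadrantResult(
        focal_farm=focal, kpi_x=kpi_x, kpi_y=kpi_y,
        categories=categories, candidates=candidates,
    )


def plot_quadrants(snapshots, result: QuadrantResult, path=None):  # pragma: no cover
    """Scatter the cohort with the conventional quadrant color code.

    Requires matplotlib (optional extra); the focal farm is the large
    black point.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ids = snapshots["farm_id"].astype(str)
    fig, ax = plt.subplots(figsize=(6, 5))
    for i, farm in enumerate(ids):
        xv = snapshots[result.kpi_x].iloc[i]
        yv = snapshots[result.kpi_y].iloc[i]
        if farm == result.focal_farm:
            ax.scatter(xv, yv, c="black", s=120, zorder=3)
        else:
            ax.scatter(xv, yv, c=QUADRANT_COLORS[result.categories[farm]], s=35)
    ax.set_xlabel(result.kpi_x)
    ax.set_ylabel(result.kpi_y)
    ax.set_title(f"Peer quadrants around {result.focal_farm}")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
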