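"""End-to-end benchmarking run: ingest -> KPI -> cohorts -> analysis outputs.

``run_benchmark`` chains the full pipeline on a test-day CSV and writes
a deterministic output bundle (snapshots, cohort assignment, cohort
summary, quadrant classification, goal recommendations, worst/average/
best benchmark table) plus a manifest recording the seed, a config
hash, and a checksum per artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohorts import DEFAULT_FEATURES, cluster_farms, cohort_summary
from .economics import PriceConfig, add_economics
from .goals import goals_frame, recommend
from .ingest import filter_min_herd, read_testday_csv, snapshot_herds
from .quadrants import KPI_DIRECTIONS, Direction, quadrant_classify

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_benchmark", "benchmark_table"]

_FLOAT_FMT = "%.6f"


@dataclass
class RunConfig:
    """Configuration of one benchmarking run."""

    testday_csv: str
    out_dir: str
    seed: int = 0
    k: int = 8
    min_cows: int = 30
    month: str = "2023-12"
    features: list[str] = field(default_factory=lambda: list(DEFAULT_FEATURES))
    focal_farm: str | None = None  # default: median-milk farm
    kpi_x: str = "milk_lb"
    kpi_y: str = "iofc_day"
    price: PriceConfig = field(default_factory=PriceConfig)
    anonymize_salt: str | None = None


def benchmark_table(cohort_snaps: pd.DataFrame, focal_row: pd.Series) -> pd.DataFrame:
    """Worst / average / best per KPI over a cohort, next to the focal farm.

    Direction-aware: the worst SCC is the highest, the worst IOFC the
    lowest.  Only KPI with a registered improvement direction appear.
    """
    rows = []
    for kpi, direction in KPI_DIRECTIONS.items():
        if kpi not in cohort_snaps.columns:
            continue
        v = cohort_snaps[kpi].to_numpy(dtype=float)
        hi_better = direction is Direction.HIGHER_BETTER
        rows.append({
            "kpi": kpi,
            "farm": float(focal_row[kpi]),
            "worst": float(v.min() if hi_better else v.max()),
            "average": float(v.mean()),
            "best": float(v.max() if hi_better else v.min()),
        })
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_benchmark(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline and write the output bundle.

    Stages: read + validate the test-day CSV, optional anonymization,
    herd-size filter, farm aggregation, economic KPI, balanced K-means
    cohorts, quadrant analysis and goal recommendation for the focal
    farm, and the cohort worst/average/best table.  Any stage failure
    aborts with the stage named.  Returns the artifact paths; reruns of
    the same config produce byte-identical files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    records, rejects = stage("ingest", lambda: read_testday_csv(config.testday_csv))
    if config.anonymize_salt:
        from .ingest import anonymize
        records = stage("anonymize", lambda: anonymize(records, config.anonymize_salt))
    records = stage("filter", lambda: filter_min_herd(records, config.min_cows))
    snaps = stage("aggregate", lambda: snapshot_herds(records, config.month))
    snaps = stage("economics", lambda: add_economics(snaps, config.price))
    assignment = stage(
        "cohort",
        lambda: cluster_farms(snaps, config.k, config.seed, config.features),
    )
    summary = stage("summary", lambda: cohort_summary(snaps, assignment))

    focal = config.focal_farm
    if focal is None:
        order = snaps.sort_values(["milk_lb", "farm_id"]).reset_index(drop=True)
        focal = str(order["farm_id"].iloc[len(order) // 2])
    cohort_id = assignment.cohort_of(focal)
    cohort_snaps = snaps[
        snaps["farm_id"].astype(str).map(assignment.assignment) == cohort_id
    ].reset_index(drop=True)
    focal_row = cohort_snaps[cohort_snaps["farm_id"].astype(str) == focal].iloc[0]

    quad = stage(
        "analyze",
        lambda: quadrant_classify(cohort_snaps, config.kpi_x, config.kpi_y, focal),
    )
    goal_sets = stage(
        "recommend", lambda: recommend(focal_row, cohort_snaps, config.price)
    )
    bench = stage("benchmark", lambda: benchmark_table(cohort_snaps, focal_row))

    def write_csv(name: str, df: pd.DataFrame) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format=_FLOAT_FMT)
        paths[name] = p

    write_csv("snapshots.csv", snaps)
    write_csv("rejects.csv", rejects)
    write_csv("assignment.csv", assignment.to_frame())
    write_csv("cohort_summary.csv", summary)
    write_csv("goals.csv", goals_frame(goal_sets))
    write_csv("benchmark.csv", bench)
    quad_path = out / "quadrants.json"
    quad_path.write_text(json.dumps({
        "focal_farm": quad.focal_farm,
        "kpi_x": quad.kpi_x,
        "kpi_y": quad.kpi_y,
        "categories": dict(sorted(quad.categories.items())),
        "candidates": sorted(quad.candidates),
        "counts": quad.counts(),
    }, indent=1))
    paths["quadrants.json"] = quad_path

    cfg_dict = asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "seed": config.seed,
        "k": config.k,
        "focal_farm": focal,
        "focal_cohort": int(cohort_id),
        "config_sha256": cfg_hash,
        "outputs": {name: _sha256(p) for name, p in sorted(paths.items())},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    paths["manifest.json"] = manifest_path
    logger.info("benchmark run complete: %d artifacts in %s", len(paths), out)
    return paths
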