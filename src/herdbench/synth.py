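"""Seeded synthetic herd generator.

Emulates a monthly DHI test-day extract at the scale of a large December
2023 US upper-midwest recording dataset: ~700 farms, herd sizes
lognormal with a 30-cow floor, farm mean milk spanning roughly 60-105
lb/cow/day, fat means 4.1-4.4%, protein means 3.2-3.4%, and lognormal
SCC with farm medians from 60 to 400 (x1,000 cells/mL).  Farm-level
milk is negatively correlated with fat % and SCC via a Gaussian copula,
mimicking the dilution and udder-health gradients seen across herds.

Every run is fully determined by the spec and the seed, and a ground-
truth sidecar records each farm's true parameters so aggregation can be
checked by parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GeneratorSpec", "generate", "write_dataset"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic test-day generator.

    Herd sizes are lognormal(mu, sigma) truncated below at
    ``min_herd_size`` (or pinned to ``fixed_herd_size`` when given).
    Farm-level milk means are spread uniformly (via the copula) over
    ``milk_mean_range``; ``corr_milk_fat`` and ``corr_milk_scc`` set the
    between-farm correlation of milk with fat % and SCC.
    """

    n_farms: int = 712
    herd_size_mu: float = 5.2
    herd_size_sigma: float = 1.1
    min_herd_size: int = 30
    fixed_herd_size: int | None = None
    milk_mean_range: tuple[float, float] = (60.0, 105.0)
    milk_cow_sd: float = 16.0
    fat_mean_range: tuple[float, float] = (4.1, 4.4)
    fat_cow_sd: float = 0.45
    protein_mean_range: tuple[float, float] = (3.2, 3.4)
    protein_cow_sd: float = 0.22
    scc_median_range: tuple[float, float] = (60.0, 400.0)
    scc_cow_sigma: float = 1.0
    corr_milk_fat: float = -0.3
    corr_milk_scc: float = -0.25
    month: str = "2023-12"

    def __post_init__(self) -> None:
        if self.n_farms < 1:
            raise ValueError("n_farms must be >= 1")
        if self.herd_size_sigma <= 0 or self.scc_cow_sigma <= 0:
            raise ValueError("distribution sigmas must be positive")
        for lo, hi in (
            self.milk_mean_range, self.fat_mean_range,
            self.protein_mean_range, self.scc_median_range,
        ):
            if not lo < hi:
                raise ValueError(f"degenerate range ({lo}, {hi})")
        if not (-1 < self.corr_milk_fat < 1 and -1 < self.corr_milk_scc < 1):
            raise ValueError("correlations must lie in (-1, 1)")


def _copula(rng: np.random.Generator, n: int, corr_fat: float, corr_scc: float) -> np.ndarray:
    """Uniform(0,1) triples (milk, fat, scc) with the requested correlations."""
    from scipy.stats import norm

    cov = np.array([
        [1.0, corr_fat, corr_scc],
        [corr_fat, 1.0, 0.0],
        [corr_scc, 0.0, 1.0],
    ])
    # nudge to positive definite if the off-diagonals are extreme
    w, v = np.linalg.eigh(cov)
    cov = (v * np.maximum(w, 1e-6)) @ v.T
    z = rng.multivariate_normal(np.zeros(3), cov, size=n, method="cholesky")
    return norm.cdf(z)


def generate(spec: GeneratorSpec, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic test-day dataset.

    Returns ``(records, truth)``: the canonical test-day frame (one
    December test per cow, the whole herd tested on the farm's test
    date) and a ground-truth frame of each farm's true parameters
    (herd size and true milk/fat/protein means, SCC median).
    Identical spec + seed give identical output.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_farms

    if spec.fixed_herd_size is not None:
        sizes = np.full(n, spec.fixed_herd_size)
    else:
        sizes = np.maximum(
            np.round(rng.lognormal(spec.herd_size_mu, spec.herd_size_sigma, n)),
            spec.min_herd_size,
        ).astype(int)

    u = _copula(rng, n, spec.corr_milk_fat, spec.corr_milk_scc)
    milk_mu = spec.milk_mean_range[0] + u[:, 0] * np.ptp(spec.milk_mean_range)
    fat_mu = spec.fat_mean_range[0] + u[:, 1] * np.ptp(spec.fat_mean_range)
    protein_mu = spec.protein_mean_range[0] + rng.uniform(0, 1, n) * np.ptp(spec.protein_mean_range)
    log_lo, log_hi = np.log(spec.scc_median_range)
    scc_med = np.exp(log_lo + u[:, 2] * (log_hi - log_lo))
    test_day = rng.integers(1, 29, n)

    frames = []
    for i in range(n):
        m = sizes[i]
        lact = 1 + rng.poisson(1.4, m)
        age = np.round(640 + lact * 365 + rng.normal(0, 90, m)).astype(int)
        dim = rng.integers(5, 306, m)
        milk = np.clip(rng.normal(milk_mu[i], spec.milk_cow_sd, m), 5.0, None)
        fat = np.clip(rng.normal(fat_mu[i], spec.fat_cow_sd, m), 1.5, 9.0)
        protein = np.clip(rng.normal(protein_mu[i], spec.protein_cow_sd, m), 1.8, 6.0)
        scc = np.clip(rng.lognormal(np.log(scc_med[i]), spec.scc_cow_sigma, m), 1.0, 30000.0)
        frames.append(pd.DataFrame({
            "farm_id": f"F{i + 1:04d}",
            "cow_id": [f"C{j + 1:06d}" for j in range(m)],
            "test_date": f"{spec.month}-{test_day[i]:02d}",
            "lactation_no": lact,
            "age_days": age,
            "dim": dim,
            "milk_lb": np.round(milk, 2),
            "fat_pct": np.round(fat, 3),
            "protein_pct": np.round(protein, 3),
            "scc_kcells": np.round(scc, 1),
        }))
    records = pd.concat(frames, ignore_index=True)
    records["test_date"] = pd.to_datetime(records["test_date"])

    truth = pd.DataFrame({
        "farm_id": [f"F{i + 1:04d}" for i in range(n)],
        "n_cows": sizes,
        "milk_mean": milk_mu,
        "fat_mean": fat_mu,
        "protein_mean": protein_mu,
        "scc_median": scc_med,
        "milk_cow_sd": spec.milk_cow_sd,
    })
    return records, truth


def write_dataset(spec: GeneratorSpec, seed: int, out_dir: str | Path) -> tuple[Path, Path]:
    """Generate and write the test-day CSV plus the ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, truth = generate(spec, seed)
    csv_path = out / "testday.csv"
    rec = records.copy()
    rec["test_date"] = rec["test_date"].dt.strftime("%Y-%m-%d")
    rec.to_csv(csv_path, index=False)
    truth_path = out / "truth.json"
    payload = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(spec).items()},
        "seed": seed,
        "farms": truth.to_dict(orient="records"),
    }
    truth_path.write_text(json.dumps(payload, indent=1))
    return csv_path, truth_path
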