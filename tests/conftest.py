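import numpy as np
import pandas as pd
import pytest

from herdbench import GeneratorSpec, PriceConfig, add_economics, generate, snapshot_herds

MONTH = "2023-12"


@pytest.fixture(scope="session")
def price() -> PriceConfig:
    return PriceConfig()


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Hand-build a canonical test-day frame from sparse row dicts."""
    defaults = {
        "farm_id": "F1", "cow_id": "C1", "test_date": "2023-12-15",
        "lactation_no": 2, "age_days": 1400, "dim": 150,
        "milk_lb": 80.0, "fat_pct": 4.2, "protein_pct": 3.3, "scc_kcells": 150.0,
    }
    df = pd.DataFrame([{**defaults, **r} for r in rows])
    df["test_date"] = pd.to_datetime(df["test_date"])
    return df


@pytest.fixture(scope="session")
def small_herd() -> pd.DataFrame:
    """40 farms x ~40 cows of synthetic December test-day records."""
    records, _ = generate(
        GeneratorSpec(n_farms=40, herd_size_mu=3.7, herd_size_sigma=0.3), seed=7
    )
    return records


@pytest.fixture(scope="session")
def small_snaps(small_herd, price) -> pd.DataFrame:
    return add_economics(snapshot_herds(small_herd, MONTH), price)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2023)
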