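"""Read, validate, filter, anonymize and aggregate test-day records.

The in-memory container for test-day data is a pandas DataFrame with the
canonical column set (one row = one cow on one herd-test date):

    farm_id, cow_id, test_date, lactation_no, age_days, dim,
    milk_lb, fat_pct, protein_pct, scc_kcells

``dim`` (days in milk) is optional.  Monthly DHI test-day cadence is
assumed: aggregation produces one snapshot per farm-month from each cow's
latest test in that month.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TESTDAY_COLUMNS",
    "FarmSnapshot",
    "read_testday_csv",
    "validate_records",
    "filter_min_herd",
    "anonymize",
    "aggregate_farm",
    "snapshot_herds",
]

#: Canonical test-day schema; ``dim`` is the only optional column.
TESTDAY_COLUMNS = [
    "farm_id",
    "cow_id",
    "test_date",
    "lactation_no",
    "age_days",
    "dim",
    "milk_lb",
    "fat_pct",
    "protein_pct",
    "scc_kcells",
]
_MANDATORY = [c for c in TESTDAY_COLUMNS if c != "dim"]
_NUMERIC = ["lactation_no", "age_days", "dim", "milk_lb", "fat_pct", "protein_pct", "scc_kcells"]


@dataclass(frozen=True)
class FarmSnapshot:
    """One farm x one month of aggregated KPI (one benchmark-table row).

    Physiological fields are arithmetic means over the farm's cows;
    economic fields are filled by :func:`herdbench.economics.add_economics`
    and satisfy ``fe = ECM(milk_lb, fat_pct, protein_pct) / dmi_lb`` and
    ``iofc_day = milk_lb/100 * milk_price_cwt - feed_cost_day``.
    """

    farm_id: str
    month: str
    n_cows: int
    mean_lactation: float
    mean_age_days: float
    milk_lb: float
    fat_pct: float
    protein_pct: float
    scc_kcells: float
    mean_dim: float | None = None
    dmi_lb: float | None = None
    fe: float | None = None
    milk_price_cwt: float | None = None
    feed_cost_day: float | None = None
    iofc_day: float | None = None


def _row_violations(df: pd.DataFrame) -> pd.Series:
    """Return a reason string per row, '' where the row is valid."""
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        sel = mask & (reasons == "")
        reasons[sel] = reason

    for col in _MANDATORY:
        flag(df[col].isna(), f"missing {col}")
    flag(df["test_date"].isna(), "unparseable test_date")
    flag(df["lactation_no"] < 1, "lactation_no < 1")
    flag(df["lactation_no"] % 1 != 0, "lactation_no not an integer")
    flag(df["age_days"] <= 0, "age_days <= 0")
    flag(df["dim"].notna() & (df["dim"] < 0), "dim < 0")
    flag(df["milk_lb"] < 0, "milk_lb < 0")
    flag((df["fat_pct"] <= 0) | (df["fat_pct"] >= 12), "fat_pct outside (0, 12)")
    flag((df["protein_pct"] <= 0) | (df["protein_pct"] >= 8), "protein_pct outside (0, 8)")
    flag(df["scc_kcells"] < 0, "scc_kcells < 0")
    dup = df.duplicated(subset=["farm_id", "cow_id", "test_date"], keep="first")
    flag(dup, "duplicate (farm_id, cow_id, test_date)")
    return reasons


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw test-day frame into (valid records, rejects report).

    The rejects report carries the original line number (``line``, 1-based
    counting the header as line 1) and a ``reason`` string; bad rows are
    never silently dropped.
    """
    reasons = _row_violations(df)
    bad = reasons != ""
    rejects = df.loc[bad].copy()
    rejects.insert(0, "line", rejects.index + 2)
    rejects["reason"] = reasons[bad]
    records = df.loc[~bad].reset_index(drop=True)
    return records, rejects.reset_index(drop=True)


def read_testday_csv(
    path: str | Path,
    schema: dict[str, str] | None = None,
    rejects_path: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a test-day CSV, validate every row, and report rejects.

    Parameters
    ----------
    path : CSV file with a header row.
    schema : optional map from canonical column name to the column name
        used in the file, for ingesting foreign layouts.
    rejects_path : when given, the rejects report is also written there.

    Returns
    -------
    (records, rejects) : validated records in canonical columns, and the
    rejects report with line numbers and reasons.

    Raises
    ------
    ValueError : if a mandatory column is absent (named in the message).
    """
    raw = pd.read_csv(Path(path), dtype={0: str})
    if schema:
        raw = raw.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in _MANDATORY if c not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    if "dim" not in raw.columns:
        raw["dim"] = np.nan
    raw = raw[TESTDAY_COLUMNS]
    raw["farm_id"] = raw["farm_id"].astype(str)
    raw["cow_id"] = raw["cow_id"].astype(str)
    raw["test_date"] = pd.to_datetime(raw["test_date"], format="%Y-%m-%d", errors="coerce")
    for col in _NUMERIC:
        raw[col] = pd.to_numeric(raw[col], errors="coerce")

    records, rejects = validate_records(raw)
    logger.info(
        "read %d test-day rows from %s: %d valid, %d rejected",
        len(raw), path, len(records), len(rejects),
    )
    if rejects_path is not None:
        rejects.to_csv(rejects_path, index=False)
    return records, rejects


def filter_min_herd(records: pd.DataFrame, min_cows: int = 30) -> pd.DataFrame:
    """Keep only farms with at least ``min_cows`` distinct milking cows.

    The boundary is inclusive: a farm with exactly ``min_cows`` cows is
    kept.  An empty result is permitted.
    """
    counts = records.groupby("farm_id")["cow_id"].nunique()
    keep = counts.index[counts >= min_cows]
    return records[records["farm_id"].isin(keep)].reset_index(drop=True)


def _pseudonym(identifier: str, salt: str, length: int = 12) -> str:
    h = hashlib.blake2b(identifier.encode(), key=salt.encode(), digest_size=16)
    return h.hexdigest()[:length]


def anonymize(records: pd.DataFrame, salt: str) -> pd.DataFrame:
    """Replace farm and cow ids with stable keyed-hash pseudonyms.

    The mapping is deterministic for a fixed salt, injective on the
    observed ids, and non-reversible without the salt.  The original ids
    do not appear in the output.
    """
    if not salt:
        raise ValueError("salt must be nonempty")
    out = records.copy()
    for col in ("farm_id", "cow_id"):
        ids = out[col].astype(str)
        mapping = {i: _pseudonym(f"{col}:{i}", salt) for i in ids.unique()}
        if len(set(mapping.values())) != len(mapping):  # pragma: no cover
            raise RuntimeError(f"pseudonym collision on {col}; use a longer digest")
        out[col] = ids.map(mapping)
    return out


def _latest_in_month(records: pd.DataFrame, month: str) -> pd.DataFrame:
    dates = pd.to_datetime(records["test_date"])
    in_month = dates.dt.strftime("%Y-%m") == month
    sub = records[in_month]
    # each cow's latest test in the month
    idx = (
        sub.assign(_d=pd.to_datetime(sub["test_date"]))
        .sort_values("_d")
        .groupby(["farm_id", "cow_id"], sort=False)
        .tail(1)
        .index
    )
    return sub.loc[idx]


def _aggregate(group: pd.DataFrame, scc_policy: str) -> dict:
    if scc_policy == "mean":
        scc = group["scc_kcells"].mean()
    elif scc_policy == "milk_weighted":
        w = group["milk_lb"].to_numpy()
        scc = float(np.average(group["scc_kcells"], weights=w)) if w.sum() > 0 else group["scc_kcells"].mean()
    else:
        raise ValueError(f"unknown scc_policy: {scc_policy!r}")
    dim = group["dim"].mean()
    return {
        "n_cows": int(group["cow_id"].nunique()),
        "mean_lactation": float(group["lactation_no"].mean()),
        "mean_age_days": float(group["age_days"].mean()),
        "mean_dim": float(dim) if pd.notna(dim) else np.nan,
        "milk_lb": float(group["milk_lb"].mean()),
        "fat_pct": float(group["fat_pct"].mean()),
        "protein_pct": float(group["protein_pct"].mean()),
        "scc_kcells": float(scc),
    }


def aggregate_farm(records: pd.DataFrame, month: str, scc_policy: str = "mean") -> FarmSnapshot:
    """Aggregate one farm's test-day records into a monthly snapshot.

    Uses each cow's latest test in the month.  Milk, fat, protein, age
    and lactation are arithmetic means over cows; SCC follows
    ``scc_policy`` ("mean", the default, or "milk_weighted").  Economic
    fields are left for :func:`herdbench.economics.add_economics`.
    """
    farms = records["farm_id"].unique()
    if len(farms) != 1:
        raise ValueError(f"aggregate_farm expects one farm, got {len(farms)}")
    latest = _latest_in_month(records, month)
    if latest.empty:
        raise ValueError(f"empty farm-month: {farms[0] if len(farms) else '?'} {month}")
    agg = _aggregate(latest, scc_policy)
    return FarmSnapshot(farm_id=str(farms[0]), month=month, **agg)


def snapshot_herds(records: pd.DataFrame, month: str, scc_policy: str = "mean") -> pd.DataFrame:
    """Aggregate every farm present in ``records`` into one snapshot row.

    Vectorized equivalent of calling :func:`aggregate_farm` per farm;
    returns a DataFrame with one row per farm, sorted by farm_id.
    """
    latest = _latest_in_month(records, month)
    if latest.empty:
        raise ValueError(f"empty farm-month: no records in {month}")
    rows = []
    for farm_id, group in latest.groupby("farm_id", sort=True):
        rows.append({"farm_id": str(farm_id), "month": month, **_aggregate(group, scc_policy)})
    return pd.DataFrame(rows)
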