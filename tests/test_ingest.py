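"""Reading, validation, filtering, anonymization and farm aggregation."""

import numpy as np
import pandas as pd
import pytest

from herdbench import (
    GeneratorSpec,
    aggregate_farm,
    anonymize,
    filter_min_herd,
    read_testday_csv,
    snapshot_herds,
    write_dataset,
)
from herdbench.ingest import validate_records

from conftest import MONTH, make_records

CSV_HEADER = "farm_id,cow_id,test_date,lactation_no,age_days,dim,milk_lb,fat_pct,protein_pct,scc_kcells\n"


def write_csv(tmp_path, body: str):
    p = tmp_path / "testday.csv"
    p.write_text(CSV_HEADER + body)
    return p


class TestReadTestdayCsv:
    def test_well_formed_rows_all_read(self, tmp_path):
        p = write_csv(
            tmp_path,
            "F1,C1,2023-12-01,1,800,100,70,4.1,3.2,120\n"
            "F1,C2,2023-12-01,2,1200,150,85,4.3,3.3,90\n"
            "F2,C1,2023-12-02,3,1700,200,95,4.0,3.1,300\n",
        )
        records, rejects = read_testday_csv(p)
        assert len(records) == 3
        assert rejects.empty

    def test_invalid_row_rejected_with_line_and_reason(self, tmp_path):
        p = write_csv(
            tmp_path,
            "F1,C1,2023-12-01,1,800,100,70,4.1,3.2,120\n"
            "F1,C2,2023-12-01,2,1200,150,85,-1,3.3,90\n"
            "F2,C1,2023-12-02,3,1700,200,95,4.0,3.1,300\n",
        )
        records, rejects = read_testday_csv(p)
        assert len(records) == 2
        assert len(rejects) == 1
        assert rejects.loc[0, "line"] == 3
        assert "fat_pct" in rejects.loc[0, "reason"]

    def test_missing_mandatory_column_aborts_naming_it(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("farm_id,cow_id,test_date\nF1,C1,2023-12-01\n")
        with pytest.raises(ValueError, match="milk_lb"):
            read_testday_csv(p)

    def test_duplicate_cow_test_date_rejected(self, tmp_path):
        p = write_csv(
            tmp_path,
            "F1,C1,2023-12-01,1,800,100,70,4.1,3.2,120\n"
            "F1,C1,2023-12-01,1,800,100,71,4.1,3.2,120\n",
        )
        records, rejects = read_testday_csv(p)
        assert len(records) == 1
        assert "duplicate" in rejects.loc[0, "reason"]

    def test_fixture_round_trip(self, tmp_path):
        """Written synthetic data re-reads to the exact written values."""
        csv_path, _ = write_dataset(GeneratorSpec(n_farms=5), seed=42, out_dir=tmp_path)
        records, rejects = read_testday_csv(csv_path)
        assert rejects.empty
        written = pd.read_csv(csv_path)
        assert len(records) == len(written)
        for col in ("milk_lb", "fat_pct", "protein_pct", "scc_kcells"):
            np.testing.assert_array_equal(records[col].to_numpy(), written[col].to_numpy())

    def test_rewrite_is_byte_identical(self, tmp_path):
        """write -> read -> write round-trips the canonical dialect."""
        csv_path, _ = write_dataset(GeneratorSpec(n_farms=3), seed=1, out_dir=tmp_path)
        records, _ = read_testday_csv(csv_path)
        out = records.copy()
        out["test_date"] = out["test_date"].dt.strftime("%Y-%m-%d")
        second = tmp_path / "again.csv"
        out.to_csv(second, index=False)
        assert second.read_bytes() == csv_path.read_bytes()


class TestFilterMinHerd:
    def test_boundary_at_min_is_inclusive(self):
        sizes = {"A": 10, "B": 29, "C": 30, "D": 45, "E": 100}
        rows = [
            {"farm_id": f, "cow_id": f"C{i}"}
            for f, n in sizes.items()
            for i in range(n)
        ]
        kept = filter_min_herd(make_records(rows), min_cows=30)
        assert set(kept["farm_id"]) == {"C", "D", "E"}

    def test_min_one_is_identity(self, small_herd):
        kept = filter_min_herd(small_herd, min_cows=1)
        assert set(kept["farm_id"]) == set(small_herd["farm_id"])

    def test_monotone_in_threshold(self, small_herd):
        prev = None
        for m in (1, 20, 40, 60, 1000):
            farms = set(filter_min_herd(small_herd, m)["farm_id"])
            if prev is not None:
                assert farms <= prev
            prev = farms

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(7)
        sizes = np.maximum(np.round(rng.lognormal(3.3, 0.8, 25)), 1).astype(int)
        rows = [
            {"farm_id": f"F{i}", "cow_id": f"C{j}"}
            for i, n in enumerate(sizes)
            for j in range(n)
        ]
        records = make_records(rows)
        kept = set(filter_min_herd(records, 30)["farm_id"])
        brute = {
            f for f in records["farm_id"].unique()
            if records[records["farm_id"] == f]["cow_id"].nunique() >= 30
        }
        assert kept == brute


class TestAnonymize:
    def test_deterministic_for_fixed_salt(self, small_herd):
        a = anonymize(small_herd, "pepper")
        b = anonymize(small_herd, "pepper")
        pd.testing.assert_frame_equal(a, b)

    def test_salt_changes_pseudonyms(self, small_herd):
        a = anonymize(small_herd, "pepper")
        b = anonymize(small_herd, "sugar")
        assert (a["farm_id"] != b["farm_id"]).all()

    def test_original_ids_absent(self, small_herd):
        anon = anonymize(small_herd, "pepper")
        assert not set(anon["farm_id"]) & set(small_herd["farm_id"])
        assert not set(anon["cow_id"]) & set(small_herd["cow_id"])

    def test_injective_on_thousand_ids(self):
        rows = [{"farm_id": f"F{i}", "cow_id": f"C{i}"} for i in range(1000)]
        anon = anonymize(make_records(rows), "s")
        assert anon["farm_id"].nunique() == 1000
        assert anon["cow_id"].nunique() == 1000

    def test_empty_salt_rejected(self, small_herd):
        with pytest.raises(ValueError, match="salt"):
            anonymize(small_herd, "")


class TestAggregateFarm:
    def test_mean_of_two_cows(self):
        records = make_records(
            [{"cow_id": "C1", "milk_lb": 80.0}, {"cow_id": "C2", "milk_lb": 90.0}]
        )
        snap = aggregate_farm(records, MONTH)
        assert snap.milk_lb == pytest.approx(85.0)
        assert snap.n_cows == 2

    def test_single_cow_equals_its_values(self):
        records = make_records([{"milk_lb": 77.0, "fat_pct": 4.5, "scc_kcells": 99.0}])
        snap = aggregate_farm(records, MONTH)
        assert (snap.milk_lb, snap.fat_pct, snap.scc_kcells) == (77.0, 4.5, 99.0)

    def test_uses_latest_test_in_month(self):
        records = make_records([
            {"test_date": "2023-12-05", "milk_lb": 60.0},
            {"test_date": "2023-12-20", "milk_lb": 90.0},
        ])
        assert aggregate_farm(records, MONTH).milk_lb == 90.0

    def test_empty_farm_month_errors(self):
        records = make_records([{"test_date": "2023-11-15"}])
        with pytest.raises(ValueError, match="empty farm-month"):
            aggregate_farm(records, MONTH)

    def test_means_match_brute_force(self, rng):
        rows = [
            {
                "cow_id": f"C{i}",
                "milk_lb": float(rng.uniform(40, 120)),
                "fat_pct": float(rng.uniform(3, 6)),
                "protein_pct": float(rng.uniform(2.8, 4)),
                "scc_kcells": float(rng.uniform(20, 800)),
            }
            for i in range(50)
        ]
        records = make_records(rows)
        snap = aggregate_farm(records, MONTH)
        for field, col in [
            ("milk_lb", "milk_lb"), ("fat_pct", "fat_pct"),
            ("protein_pct", "protein_pct"), ("scc_kcells", "scc_kcells"),
        ]:
            brute = sum(r[col] for r in rows) / len(rows)
            assert getattr(snap, field) == pytest.approx(brute, abs=1e-9)

    def test_permutation_invariant(self, rng):
        rows = [
            {"cow_id": f"C{i}", "milk_lb": float(rng.uniform(40, 120))}
            for i in range(20)
        ]
        records = make_records(rows)
        shuffled = records.sample(frac=1, random_state=3).reset_index(drop=True)
        a, b = aggregate_farm(records, MONTH), aggregate_farm(shuffled, MONTH)
        assert a.milk_lb == pytest.approx(b.milk_lb, abs=1e-12)
        assert a.n_cows == b.n_cows

    def test_milk_weighted_scc_policy(self):
        records = make_records([
            {"cow_id": "C1", "milk_lb": 100.0, "scc_kcells": 100.0},
            {"cow_id": "C2", "milk_lb": 50.0, "scc_kcells": 400.0},
        ])
        plain = aggregate_farm(records, MONTH)
        weighted = aggregate_farm(records, MONTH, scc_policy="milk_weighted")
        assert plain.scc_kcells == pytest.approx(250.0)
        assert weighted.scc_kcells == pytest.approx((100 * 100 + 50 * 400) / 150)

    def test_snapshot_herds_matches_per_farm(self, small_herd):
        snaps = snapshot_herds(small_herd, MONTH)
        farm = snaps["farm_id"].iloc[3]
        single = aggregate_farm(small_herd[small_herd["farm_id"] == farm], MONTH)
        row = snaps[snaps["farm_id"] == farm].iloc[0]
        assert row["milk_lb"] == pytest.approx(single.milk_lb)
        assert row["n_cows"] == single.n_cows


def test_validate_records_accepts_generated_data(small_herd):
    records, rejects = validate_records(small_herd)
    assert rejects.empty
    assert len(records) == len(small_herd)
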