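"""Progressive goal levels, economic impact, and the recommender."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from herdbench import (
    NoCandidateFarms,
    PriceConfig,
    ecm_lb,
    economic_impact,
    estimate_dmi,
    feed_cost_day,
    goal_levels,
    iofc_day,
    milk_price_cwt,
    recommend,
)
from herdbench.goals import LEVELS


def oracle_levels(values, lower_better=False):
    """Independent sort-and-interpolate quartiles + mean + extreme."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)

    def pct(q):
        pos = q / 100 * (n - 1)
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        return v[lo] + (pos - lo) * (v[hi] - v[lo])

    if lower_better:
        return (pct(75), v.mean(), pct(25), v[0])
    return (pct(25), v.mean(), pct(75), v[-1])


SNAPSHOT = pd.Series({
    "farm_id": "FX",
    "milk_lb": 85.6, "fat_pct": 3.89, "protein_pct": 3.18,
    "scc_kcells": 233.0, "mean_dim": 180.0,
})


class TestGoalLevels:
    def test_five_point_grid_higher_better(self):
        g = goal_levels([1, 2, 3, 4, 5], "higher_better")
        assert g.as_tuple() == (2.0, 3.0, 4.0, 5.0)

    def test_five_point_grid_lower_better_is_mirrored(self):
        g = goal_levels([1, 2, 3, 4, 5], "lower_better")
        assert g.as_tuple() == (4.0, 3.0, 2.0, 1.0)

    def test_single_candidate_collapses(self):
        g = goal_levels([7.5], "higher_better")
        assert g.as_tuple() == (7.5, 7.5, 7.5, 7.5)

    def test_empty_candidates_signal_no_goals(self):
        with pytest.raises(NoCandidateFarms):
            goal_levels([], "higher_better")

    @pytest.mark.parametrize("lower_better", [False, True])
    def test_matches_independent_oracle(self, lower_better, rng):
        for _ in range(200):
            values = rng.uniform(0, 100, rng.integers(1, 40))
            direction = "lower_better" if lower_better else "higher_better"
            got = goal_levels(values, direction).as_tuple()
            np.testing.assert_allclose(got, oracle_levels(values, lower_better), atol=1e-9)

    @settings(derandomize=True, max_examples=200)
    @given(
        values=st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=1, max_size=50,
        ),
        lower=st.booleans(),
    )
    def test_monotone_ambition_and_achievability(self, values, lower):
        direction = "lower_better" if lower else "higher_better"
        g = goal_levels(values, direction)
        basic, moderate, medium, strong = g.as_tuple()
        if lower:
            assert basic >= medium >= strong
        else:
            assert basic <= medium <= strong
        lo, hi = min(values), max(values)
        for v in g.as_tuple():
            assert lo - 1e-9 <= v <= hi + 1e-9


class TestEconomicImpact:
    def test_goal_at_current_is_zero(self, price):
        for kpi in ("milk_lb", "fat_pct", "scc_kcells"):
            assert economic_impact(SNAPSHOT, kpi, SNAPSHOT[kpi], price) == pytest.approx(0.0)

    def test_fat_goal_with_zero_fat_differential_is_free(self):
        cfg = PriceConfig(fat_diff=0.0)
        assert economic_impact(SNAPSHOT, "fat_pct", SNAPSHOT["fat_pct"] + 0.5, cfg) == (
            pytest.approx(0.0)
        )

    def test_milk_goal_matches_closed_form(self, price):
        """Impact of milk 80 -> 88 equals the chain rebuilt by hand."""
        snap = SNAPSHOT.copy()
        snap["milk_lb"] = 80.0

        def chain(milk):
            p = milk_price_cwt(snap.fat_pct, snap.protein_pct, snap.scc_kcells, price)
            dmi = estimate_dmi(ecm_lb(milk, snap.fat_pct, snap.protein_pct),
                               price.bw_kg, snap.mean_dim)
            return iofc_day(milk, p, feed_cost_day(dmi, price.ration_price_lb_dm))

        expected = 100 * (chain(88.0) - chain(80.0)) / chain(80.0)
        assert economic_impact(snap, "milk_lb", 88.0, price) == pytest.approx(
            expected, abs=1e-9
        )

    def test_milk_goal_revenue_only_when_feed_negligible(self):
        """With near-free feed, impact reduces to the revenue closed form
        100 * (dmilk * P / 100) / (milk * P / 100) = 10% for 80 -> 88."""
        cfg = PriceConfig(ration_price_lb_dm=1e-12)
        snap = SNAPSHOT.copy()
        snap["milk_lb"] = 80.0
        assert economic_impact(snap, "milk_lb", 88.0, cfg) == pytest.approx(10.0, abs=1e-6)

    def test_feed_cost_goal_overrides_prediction(self, price):
        lower = economic_impact(SNAPSHOT, "feed_cost_day", 5.0, price)
        higher = economic_impact(SNAPSHOT, "feed_cost_day", 8.0, price)
        assert lower > higher

    def test_unsupported_kpi_rejected(self, price):
        with pytest.raises(ValueError, match="impact undefined"):
            economic_impact(SNAPSHOT, "fe", 1.7, price)

    def test_impact_increases_with_ambition_for_revenue_kpi(self, price):
        goals = [88.0, 92.0, 96.0, 100.0]
        impacts = [economic_impact(SNAPSHOT, "milk_lb", g, price) for g in goals]
        assert impacts == sorted(impacts)


class TestRecommend:
    def cohort(self):
        rng = np.random.default_rng(3)
        n = 25
        return pd.DataFrame({
            "farm_id": [f"F{i}" for i in range(n)],
            "milk_lb": rng.uniform(65, 105, n),
            "fat_pct": rng.uniform(3.8, 4.6, n),
            "protein_pct": rng.uniform(3.0, 3.5, n),
            "scc_kcells": rng.uniform(60, 500, n),
            "feed_cost_day": rng.uniform(5.5, 7.5, n),
            "mean_dim": rng.uniform(120, 220, n),
        })

    def test_leader_gets_markers_everywhere(self, price):
        df = self.cohort()
        best = df.iloc[0].copy()
        best["milk_lb"], best["fat_pct"], best["protein_pct"] = 200.0, 7.0, 5.0
        best["scc_kcells"], best["feed_cost_day"] = 1.0, 0.1
        df.iloc[0] = best
        out = recommend(df.iloc[0], df, price)
        assert all(g.leads_cohort for g in out)
        assert all(g.levels is None for g in out)

    def test_two_farm_cohort_goals_collapse_to_peer(self, price):
        df = self.cohort().iloc[:2].copy()
        worse = df["milk_lb"].idxmin()
        focal, peer = df.loc[worse], df.loc[df["milk_lb"].idxmax()]
        out = recommend(focal, df, price)
        milk = next(g for g in out if g.kpi == "milk_lb")
        assert milk.levels.as_tuple() == (peer["milk_lb"],) * 4

    def test_pipeline_equals_composed_steps(self, price):
        """recommend == candidate filter + goal_levels + economic_impact."""
        df = self.cohort()
        focal = df.iloc[7]
        out = recommend(focal, df, price)
        for g in out:
            peers = df[df["farm_id"] != focal["farm_id"]][g.kpi].to_numpy()
            if g.kpi in ("scc_kcells", "feed_cost_day"):
                cand = peers[peers < focal[g.kpi]]
                direction = "lower_better"
            else:
                cand = peers[peers > focal[g.kpi]]
                direction = "higher_better"
            if cand.size == 0:
                assert g.leads_cohort
                continue
            expected = goal_levels(cand, direction)
            np.testing.assert_allclose(g.levels.as_tuple(), expected.as_tuple(), atol=1e-12)
            for name, value in zip(LEVELS, expected.as_tuple()):
                assert g.impact_pct[name] == pytest.approx(
                    economic_impact(focal, g.kpi, value, price), abs=1e-12
                )
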