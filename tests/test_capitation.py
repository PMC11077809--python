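import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amgcap import reference
from amgcap.capitation import (
    adjusted_population,
    allocate_budget,
    area_cost_summary,
    need_index,
    render_allocation,
    summary_from_area_means,
)


@pytest.fixture(scope="module")
def published_summary():
    """Area summary rebuilt from the published per-area average costs,
    weighted so the system means equal the published totals."""
    obs = reference.AREA_MEAN_COSTS["observed_mean"]
    pred = reference.AREA_MEAN_COSTS["predicted_mean"]
    # solve for user weights consistent with the published system mean:
    # the covered populations are proportional enough for both totals
    w = reference.AREA_COVERED_POPULATION.astype(float)
    return summary_from_area_means(obs, pred, w)


class TestAreaCostSummary:
    def test_published_differences_reproduced(self, published_summary):
        s = published_summary
        assert np.isclose(s.loc["I", "difference"], -10.25, atol=0.005)
        assert np.isclose(s.loc["IV", "difference"], 111.16, atol=0.005)
        assert np.isclose(s.loc["IX", "difference"], 166.96, atol=0.005)

    def test_published_indices_reproduced_at_print_precision(self):
        obs = reference.AREA_MEAN_COSTS["observed_mean"]
        pred = reference.AREA_MEAN_COSTS["predicted_mean"]
        tot = reference.SYSTEM_MEAN_COST
        assert abs(100 * obs["IX"] / tot - 113.98) <= 0.01
        assert abs(100 * pred["IX"] / tot - 102.64) <= 0.01
        assert abs(100 * obs["IV"] / tot - 109.33) <= 0.01
        assert abs(100 * pred["I"] / tot - 98.80) <= 0.01

    def test_single_area_gets_index_100(self):
        rec = pd.DataFrame(
            {"area_id": ["A"] * 4, "cost_eur": [10.0, 20, 30, 40]}
        )
        s = area_cost_summary(rec, np.array([15.0, 15, 35, 35]))
        assert np.isclose(s.loc["A", "observed_index"], 100.0)
        assert np.isclose(s.loc["A", "predicted_index"], 100.0)

    def test_calibration_zeroes_total_difference(self):
        rng = np.random.default_rng(2)
        rec = pd.DataFrame(
            {
                "area_id": rng.choice(["A", "B", "C"], 300),
                "cost_eur": rng.gamma(2, 100, 300),
            }
        )
        pred = rng.gamma(2, 90, 300)  # systematically low predictions
        s = area_cost_summary(rec, pred, calibrate=True)
        assert abs(s.loc["Total", "difference"]) < 1e-9
        # person-weighted mean of area indices is 100
        areas = s.drop("Total")
        w = areas["n"] / areas["n"].sum()
        assert abs((areas["observed_index"] * w).sum() - 100.0) < 0.01
        assert abs((areas["predicted_index"] * w).sum() - 100.0) < 0.01

    def test_prediction_count_mismatch_rejected(self):
        rec = pd.DataFrame({"area_id": ["A"], "cost_eur": [1.0]})
        with pytest.raises(ValueError):
            area_cost_summary(rec, np.array([1.0, 2.0]))


class TestNeedIndex:
    def test_published_need_indices(self, published_summary):
        need = need_index(published_summary)
        for area in reference.AREA_IDS:
            assert abs(need[area] - reference.AREA_NEED_INDEX[area]) <= 1.5e-5, area

    def test_unit_index_for_system_like_area(self):
        s = pd.DataFrame(
            {"predicted_index": [100.0, 100.0]},
            index=pd.Index(["A", "Total"], name="area_id"),
        )
        assert need_index(s)["A"] == 1.0

    def test_scale_invariance(self, published_summary):
        doubled = published_summary.copy()
        doubled[["observed_mean", "predicted_mean"]] *= 2
        # indices are ratios: recompute from doubled means
        obs = doubled.drop("Total")["observed_mean"]
        pred = doubled.drop("Total")["predicted_mean"]
        w = reference.AREA_COVERED_POPULATION.astype(float)
        again = summary_from_area_means(obs, pred, w)
        assert np.allclose(
            need_index(again), need_index(published_summary), rtol=1e-12
        )


class TestAdjustedPopulation:
    def test_published_adjusted_populations(self):
        adj = adjusted_population(
            reference.AREA_COVERED_POPULATION, reference.AREA_NEED_INDEX
        )
        # printed need indices are rounded to 5 decimals: allow +/-1 person
        published = pd.Series(
            [266_402, 294_981, 169_840, 71_194, 55_201, 276_296, 212_532,
             108_473, 56_323],
            index=adj.index,
        )
        assert (np.abs(adj.round() - published) <= 1).all()
        # the two areas quoted exactly
        assert round(adj["I"]) == 266_402
        assert round(adj["IX"]) == 56_323

    def test_unit_need_is_identity(self):
        pops = pd.Series([100, 200], index=["A", "B"])
        need = pd.Series([1.0, 1.0], index=["A", "B"])
        assert (adjusted_population(pops, need) == pops).all()

    def test_validation(self):
        with pytest.raises(ValueError):
            adjusted_population(pd.Series([-1]), pd.Series([1.0]))
        with pytest.raises(ValueError):
            adjusted_population(pd.Series([1]), pd.Series([0.0]))


def _published_area_table():
    return reference.reference_area_table()


class TestAllocateBudget:
    def test_published_allocations(self):
        fin = allocate_budget(1842.0, _published_area_table())
        view = render_allocation(fin)
        assert view.loc["II", "alloc_population"] == 352
        expected_pop = [329, 352, 220, 85, 74, 332, 250, 134, 67]
        expected_adj = [325, 360, 207, 87, 67, 337, 259, 132, 69]
        assert list(view["alloc_population"]) == expected_pop
        assert list(view["alloc_adjusted"]) == expected_adj
        published_diff = [7.44, -5.02, -2.62, -15.28, -6.96, 42.76, -0.88,
                          -6.87, -12.59]
        assert np.allclose(view["difference"], published_diff, atol=0.05)

    def test_equal_populations_unit_need_split_equally(self):
        areas = pd.DataFrame(
            {
                "covered_population": [1000, 1000, 1000],
                "need_index": [1.0, 1.0, 1.0],
                "historical_share": [1 / 3] * 3,
            },
            index=["A", "B", "C"],
        )
        fin = allocate_budget(300.0, areas)
        assert np.allclose(fin["alloc_population"], 100.0)
        assert np.allclose(fin["alloc_adjusted"], 100.0)
        assert np.allclose(fin["alloc_historical"], 100.0)

    def test_conservation_and_zero_sum(self):
        fin = allocate_budget(1842.0, _published_area_table())
        for col in ("alloc_population", "alloc_adjusted", "alloc_historical"):
            assert abs(fin[col].sum() - 1842.0) < 1e-9
        assert abs(fin["difference"].sum()) < 1e-9

    def test_share_sum_violation_rejected(self):
        areas = _published_area_table()
        areas.loc["I", "historical_share"] += 0.01
        with pytest.raises(ValueError, match="sum to 1"):
            allocate_budget(1842.0, areas)

    def test_budget_validation(self):
        with pytest.raises(ValueError, match="positive"):
            allocate_budget(0.0, _published_area_table())

    def test_reallocation_monotone_in_need(self):
        """Raising one area's need index (others fixed) strictly raises
        its needs-based allocation, checked against brute-force share
        enumeration on a 3-area toy."""
        base = pd.DataFrame(
            {
                "covered_population": [100, 200, 300],
                "need_index": [1.0, 1.0, 1.0],
                "historical_share": [0.2, 0.3, 0.5],
            },
            index=["A", "B", "C"],
        )
        prev = None
        for ni in np.linspace(0.8, 1.3, 11):
            areas = base.copy()
            areas.loc["B", "need_index"] = ni
            fin = allocate_budget(100.0, areas)
            # brute-force oracle
            adj = areas["covered_population"] * areas["need_index"]
            assert np.allclose(fin["alloc_adjusted"], 100.0 * adj / adj.sum())
            if prev is not None:
                assert fin.loc["B", "alloc_adjusted"] > prev
            prev = fin.loc["B", "alloc_adjusted"]

    @given(
        data=st.data(),
        n_areas=st.integers(min_value=3, max_value=20),
    )
    @settings(max_examples=30, deadline=None)
    def test_conservation_fuzz(self, data, n_areas):
        """All three allocation columns sum to the budget for randomised
        area tables of 3-20 areas."""
        pops = data.draw(
            st.lists(
                st.integers(min_value=1, max_value=10**6),
                min_size=n_areas, max_size=n_areas,
            )
        )
        needs = data.draw(
            st.lists(
                st.floats(min_value=0.1, max_value=5.0, allow_nan=False),
                min_size=n_areas, max_size=n_areas,
            )
        )
        raw = data.draw(
            st.lists(
                st.floats(min_value=0.01, max_value=1.0, allow_nan=False),
                min_size=n_areas, max_size=n_areas,
            )
        )
        shares = np.array(raw) / np.sum(raw)
        areas = pd.DataFrame(
            {
                "covered_population": pops,
                "need_index": needs,
                "historical_share": shares,
            }
        )
        budget = data.draw(st.floats(min_value=1.0, max_value=10_000.0))
        fin = allocate_budget(budget, areas)
        for col in ("alloc_population", "alloc_adjusted", "alloc_historical"):
            assert abs(fin[col].sum() - budget) < 1e-9 * max(1.0, budget)
        assert abs(fin["difference"].sum()) < 1e-9 * max(1.0, budget)
        # adjusted population strictly increasing in need at fixed coverage
        assert (
            fin["adjusted_population"]
            == areas["covered_population"] * areas["need_index"]
        ).all()
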