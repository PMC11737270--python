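"""Allocative-efficiency optimizer: LP, frontiers, change points, draws."""

import itertools

import numpy as np
import pytest

from nutriopt.allocate import (
    cost_changepoint,
    optimize_allocation,
    priority_order,
    reallocate_baseline,
    summarize_draws,
    sweep_budgets,
)
from nutriopt.burden import BurdenLedger
from nutriopt.interventions import InterventionSet
from nutriopt.params.model import CostModel
from nutriopt.scenarios import ScenarioOutcome

COST_MODEL = CostModel(
    product_cost={"alpha": 10.0, "beta": 20.0},
    nonproduct_components={"program": 0.15, "logistics_waste": 0.05,
                           "inefficiency": 0.17},
)


def synthetic_outcome(cost, dalys, interventions=None, counts=None,
                      not_stunted=0.0, unit_costs=None, saturation=None):
    led = BurdenLedger()
    led.add_yll("child", "all", dalys)
    led.person_time[2, 0] = not_stunted
    oc = ScenarioOutcome(
        label=interventions.label if interventions else "toy",
        draw_index=0, ledger=led, counts=counts or {}, cost=cost,
        n_pregnancies=1, n_children=1, interventions=interventions,
        unit_costs=unit_costs or {}, saturation=saturation or {},
    )
    return oc


def vertex_enumeration_optimum(costs, dalys, budget):
    """Independent oracle: optimal LP value over simplex-and-budget vertices
    (single scenarios plus budget-tight two-scenario mixtures)."""
    best = np.inf
    n = len(costs)
    for i in range(n):
        if costs[i] <= budget + 1e-12:
            best = min(best, dalys[i])
    for i, j in itertools.combinations(range(n), 2):
        ci, cj = costs[i], costs[j]
        if (ci - budget) * (cj - budget) < 0:
            t = (budget - cj) / (ci - cj)
            best = min(best, t * dalys[i] + (1 - t) * dalys[j])
    return best


class TestOptimizer:
    toy = [synthetic_outcome(0.0, 100.0), synthetic_outcome(10.0, 80.0),
           synthetic_outcome(20.0, 50.0)]

    def test_toy_instance_matches_oracle(self):
        """Costs (0, 10, 20), DALYs (100, 80, 50), budget 10: the optimum
        mixes scenarios 1 and 3 at 0.5/0.5 with objective 75."""
        r = optimize_allocation(self.toy, 10.0)
        assert r.objective_value == pytest.approx(75.0, abs=1e-9)
        assert r.weights[0] == pytest.approx(0.5, abs=1e-9)
        assert r.weights[2] == pytest.approx(0.5, abs=1e-9)

    def test_zero_budget_all_weight_on_free_scenario(self):
        r = optimize_allocation(self.toy, 0.0)
        assert r.weights[0] == pytest.approx(1.0)
        assert r.total_cost == 0.0

    def test_large_budget_selects_best_scenario(self):
        r = optimize_allocation(self.toy, 1e6)
        assert r.objective_value == pytest.approx(50.0, abs=1e-9)
        assert r.weights[2] == pytest.approx(1.0)

    def test_matches_vertex_enumeration_on_random_instances(self):
        """LP optimum equals exhaustive vertex enumeration to 1e-9 on every
        random instance with <= 6 scenarios."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 7))
            costs = np.round(rng.random(n) * 100, 2)
            costs[0] = 0.0
            dalys = np.round(rng.random(n) * 1000, 3)
            budget = float(rng.random() * 100)
            ocs = [synthetic_outcome(c, d) for c, d in zip(costs, dalys)]
            lp = optimize_allocation(ocs, budget).objective_value
            oracle = vertex_enumeration_optimum(costs, dalys, budget)
            assert lp == pytest.approx(oracle, abs=1e-9)

    def test_support_size_at_most_two_plus_anchor(self):
        """In general position the optimal mixture uses at most 2 scenarios."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(3, 7))
            costs = rng.random(n) * 100
            costs[0] = 0.0
            dalys = rng.random(n) * 1000
            ocs = [synthetic_outcome(c, d) for c, d in zip(costs, dalys)]
            r = optimize_allocation(ocs, float(rng.random() * 100))
            assert (r.weights > 1e-9).sum() <= 2

    def test_max_not_stunted_objective(self):
        ocs = [
            synthetic_outcome(0.0, 0.0, not_stunted=50.0),
            synthetic_outcome(10.0, 0.0, not_stunted=90.0),
        ]
        r = optimize_allocation(ocs, 10.0, objective="max_not_stunted_time")
        assert r.objective_value == pytest.approx(90.0)

    def test_unknown_objective_rejected(self):
        with pytest.raises(ValueError):
            optimize_allocation(self.toy, 10.0, objective="min_cost")


def _product_fixture():
    """Three scenarios (zero, product alpha, product beta) with counts so
    repricing works: alpha treats 1 unit, beta 1 unit, with different
    health returns."""
    sat = {"sam_tx": 0.7, "mam_targeted": 0.7, "mam_universal": 0.7,
           "sqlns": 0.7, "ifa": 0.757, "mmn": 0.757, "bep": 0.757}
    unit = {p: COST_MODEL.final_unit_cost(p) for p in COST_MODEL.product_cost}
    zero = synthetic_outcome(0.0, 1000.0, InterventionSet(), {},
                             unit_costs=unit, saturation=sat)
    a = synthetic_outcome(
        COST_MODEL.final_unit_cost("alpha"), 900.0,
        InterventionSet(sam_tx=True), {"alpha": 1.0},
        unit_costs=unit, saturation=sat,
    )
    b = synthetic_outcome(
        COST_MODEL.final_unit_cost("beta"), 820.0,
        InterventionSet(sqlns=True), {"beta": 1.0},
        unit_costs=unit, saturation=sat,
    )
    return [zero, a, b]


class TestFrontier:
    def test_monotone_and_concave(self):
        ocs = _product_fixture()
        fr = sweep_budgets(ocs, n_points=25)
        obj = np.array([r.objective_value for r in fr.results])
        assert (np.diff(obj) <= 1e-9).all()
        # DALYs-averted curve is concave: increments non-increasing.
        inc = np.diff(fr.dalys_averted)
        assert (np.diff(inc) <= 1e-6).all()

    def test_first_point_is_zero_budget(self):
        ocs = _product_fixture()
        fr = sweep_budgets(ocs, n_points=10)
        assert fr.budgets[0] == 0.0
        assert fr.results[0].objective_value == pytest.approx(1000.0)
        assert fr.dalys_averted[0] == 0.0

    def test_icer_positive_and_relative_to_zero_spending(self):
        ocs = _product_fixture()
        fr = sweep_budgets(ocs, n_points=10)
        later = fr.icers[1:]
        assert np.all(later[~np.isnan(later)] > 0)
        k = 5
        assert fr.icers[k] == pytest.approx(
            fr.results[k].total_cost / fr.dalys_averted[k]
        )

    def test_grid_refinement_stable_priority(self):
        ocs = _product_fixture()
        p25 = priority_order(sweep_budgets(ocs, 25))
        p100 = priority_order(sweep_budgets(ocs, 100))
        assert p25 == p100


class TestPriorityAndReallocation:
    def test_cheap_high_impact_product_first(self):
        ocs = _product_fixture()
        order = priority_order(sweep_budgets(ocs, 25))
        # alpha: 100 averted / $11.70 = 8.5 per $; beta: 180 / $23.40 = 7.7.
        assert order[0] == "sam_tx"
        assert "sqlns" in order

    def test_never_funded_product_absent(self):
        ocs = _product_fixture()
        ocs[2].ledger.ylls[("child", "all")] = 1000.0  # beta now useless
        order = priority_order(sweep_budgets(ocs, 25))
        assert "sqlns" not in order

    def test_baseline_already_optimal_zero_improvement(self):
        ocs = _product_fixture()
        # Baseline = optimum at its own cost.
        opt = optimize_allocation(ocs, ocs[1].cost)
        rec = reallocate_baseline(ocs, opt.weights)
        assert rec["dalys_averted"] == pytest.approx(0.0, abs=1e-6)

    def test_dominant_scenario_fully_funded(self):
        ocs = _product_fixture()
        baseline = np.array([0.5, 0.0, 0.5])
        rec = reallocate_baseline(ocs, baseline)
        assert rec["dalys_averted"] >= 0
        assert rec["optimized_dalys"] <= rec["baseline_dalys"]

    def test_improvement_nonnegative_for_any_baseline(self):
        ocs = _product_fixture()
        rng = np.random.default_rng(3)
        for _ in range(10):
            w = rng.dirichlet(np.ones(3))
            rec = reallocate_baseline(ocs, w)
            assert rec["dalys_averted"] >= -1e-9


class TestChangepoint:
    def test_closed_form_tie_price(self):
        """Products tie in DALYs-averted per dollar where
        100 / (1.37 p) = 180 / (1.37 x 20), i.e. p* = 100 x 20 / 180 = 11.11;
        raising alpha's price past p* flips the funding order, and bisection
        finds the tie within $0.01 (plus cent rounding)."""
        ocs = _product_fixture()
        result = cost_changepoint("alpha", ocs, COST_MODEL, direction="increase")
        assert result["changed"]
        p_star = 100.0 * 20.0 / 180.0
        assert result["price"] == pytest.approx(p_star, abs=0.03)

    def test_order_differs_across_the_change_point(self):
        ocs = _product_fixture()
        result = cost_changepoint("beta", ocs, COST_MODEL, direction="decrease")
        assert result["changed"]
        assert result["order_before"] != result["order_after"]

    def test_never_funded_product_reports_bound(self):
        ocs = _product_fixture()
        ocs[2].ledger.ylls[("child", "all")] = 1000.0
        result = cost_changepoint("beta", ocs, COST_MODEL, direction="increase")
        assert not result["changed"]

    def test_unknown_product_rejected(self):
        with pytest.raises(ValueError):
            cost_changepoint("gamma", _product_fixture(), COST_MODEL)


class TestDrawSummary:
    def test_identical_draws_full_agreement(self):
        orders = [["mmn", "sam_tx", "sqlns"]] * 5
        s = summarize_draws(orders, objective_values=[10.0] * 5)
        frac = s["pairwise_priority_fraction"]
        assert frac[("mmn", "sam_tx")] == 1.0
        assert frac[("sam_tx", "mmn")] == 0.0
        assert s["objective_interval"] == (10.0, 10.0)

    def test_constructed_seventy_thirty_split(self):
        """Draws built with a known 70/30 ordering split recover 0.70."""
        orders = [["mmn", "sqlns"]] * 7 + [["sqlns", "mmn"]] * 3
        s = summarize_draws(orders)
        assert s["pairwise_priority_fraction"][("mmn", "sqlns")] == pytest.approx(0.7)

    def test_interval_contains_mean(self):
        vals = list(np.random.default_rng(4).random(20) * 100)
        s = summarize_draws([["mmn"]] * 20, objective_values=vals)
        assert s["interval_contains_mean"]

    def test_requires_two_draws(self):
        with pytest.raises(ValueError):
            summarize_draws([["mmn"]])
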