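"""Linear-programming allocative efficiency analysis.

Given the recorded outcomes and costs of every intervention scenario, the
optimizer chooses the fractional combination (convex weights over scenarios)
that optimizes a health objective subject to a budget:

    minimize / maximize   sum_s w_s * objective_s
    subject to            sum_s w_s = 1,  sum_s w_s * cost_s <= budget,  w >= 0

Because scenario mixing equals partial coverage for independent simulants,
the weights translate directly into per-intervention coverage (weight times
the scenario's saturation coverage) and spending.  Structural rules (BEP
only with MMN, mutually exclusive MAM modes) are encoded in the scenario set
itself rather than as LP rows; this also yields the property that targeted
MAM treatment is never less cost-effective than universal MAM, since it
treats a subset of cases at the same unit cost.

Degenerate ties are broken deterministically by a second LP stage that
selects the cheapest mixture among objective-optimal ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .params.model import CostModel
from .scenarios import ScenarioOutcome, mix_outcomes

REPORT_PRODUCTS = [
    "ifa", "mmn", "bep", "sam_tx", "mam_targeted", "mam_universal", "sqlns",
]

OBJECTIVES = ("min_dalys", "max_not_stunted_time")


def _product_active(scenario, product: str) -> bool:
    if product == "mam_targeted":
        return scenario.mam_tx == "targeted"
    if product == "mam_universal":
        return scenario.mam_tx == "universal"
    return product in scenario.active_products()


def _count_key(product: str) -> str:
    return "mam_tx" if product.startswith("mam_") else product


@dataclass
class AllocationResult:
    weights: np.ndarray
    objective: str
    objective_value: float
    total_cost: float
    budget: float
    spending: dict = field(default_factory=dict)  # product -> USD
    coverage: dict = field(default_factory=dict)  # product -> proportion
    draw_index: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "intervention": list(self.spending),
            "spending": list(self.spending.values()),
            "coverage": [self.coverage[p] for p in self.spending],
        })


def optimize_allocation(
    outcomes: list[ScenarioOutcome],
    budget: float,
    objective: str = "min_dalys",
    costs: np.ndarray | None = None,
) -> AllocationResult:
    """Optimal scenario mixture under a budget.

    ``costs`` overrides the scenario costs recorded in the outcomes (used by
    the change-point analysis to reprice scenarios).  Requires at least one
    zero-cost scenario for feasibility at budget 0.
    """
    if objective not in OBJECTIVES:
        raise ValueError(f"unknown objective {objective!r}")
    cost = np.asarray(
        [oc.cost for oc in outcomes] if costs is None else costs, dtype=float
    )
    vals = np.array([oc.objective(objective) for oc in outcomes])
    sense = 1.0 if objective == "min_dalys" else -1.0
    c = sense * vals

    n = len(outcomes)
    a_ub = cost[None, :]
    res = linprog(
        c, A_ub=a_ub, b_ub=[budget], A_eq=np.ones((1, n)), b_eq=[1.0],
        bounds=(0.0, 1.0), method="highs",
    )
    if not res.success:
        raise RuntimeError(f"allocation LP failed: {res.message}")
    opt = res.fun

    # Tie-break: cheapest mixture among objective-optimal ones.  The slack
    # on the optimality row is far below the LP's own tolerance so the
    # tie-break cannot degrade the objective measurably.
    span = max(1.0, float(np.ptp(vals)))
    res2 = linprog(
        cost,
        A_ub=np.vstack([a_ub, c[None, :]]),
        b_ub=[budget, opt + 1e-12 * span],
        A_eq=np.ones((1, n)), b_eq=[1.0],
        bounds=(0.0, 1.0), method="highs",
    )
    if res2.success and (c @ res2.x) <= opt + 1e-9 * span:
        w = res2.x
    else:  # pragma: no cover - fall back to the first-stage solution
        w = res.x
    w = np.where(w < 1e-12, 0.0, w)
    w = w / w.sum()

    value = float(vals @ w)
    total_cost = float(cost @ w)
    spending: dict[str, float] = {}
    coverage: dict[str, float] = {}
    for product in REPORT_PRODUCTS:
        cov = 0.0
        spend = 0.0
        for wi, oc in zip(w, outcomes):
            if wi == 0.0 or oc.interventions is None:
                continue
            if _product_active(oc.interventions, product):
                sat = oc.interventions and _saturation(oc, product)
                cov += wi * sat
                key = _count_key(product)
                spend += wi * oc.counts.get(key, 0.0) * oc.unit_costs.get(key, 0.0)
        spending[product] = spend
        coverage[product] = cov

    return AllocationResult(
        weights=w,
        objective=objective,
        objective_value=value,
        total_cost=total_cost,
        budget=float(budget),
        spending=spending,
        coverage=coverage,
        draw_index=outcomes[0].draw_index,
    )


def _saturation(outcome: ScenarioOutcome, product: str) -> float:
    # Scenario runs at saturation coverage; derive it from the unit-cost
    # bookkeeping or default caps stored at run time.
    sat = getattr(outcome, "saturation", None)
    if sat and product in sat:
        return sat[product]
    return 0.757 if product in ("ifa", "mmn", "bep") else 0.70


@dataclass
class BudgetFrontier:
    budgets: np.ndarray
    results: list[AllocationResult]
    dalys_averted: np.ndarray  # vs zero spending
    icers: np.ndarray  # USD per DALY averted vs zero spending
    objective: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "budget": self.budgets,
            "objective_value": [r.objective_value for r in self.results],
            "total_cost": [r.total_cost for r in self.results],
            "dalys_averted": self.dalys_averted,
            "icer": self.icers,
        })


def sweep_budgets(
    outcomes: list[ScenarioOutcome],
    n_points: int = 25,
    objective: str = "min_dalys",
    costs: np.ndarray | None = None,
) -> BudgetFrontier:
    """Optimize across evenly spaced budgets from 0 to full saturation cost.

    The top budget is the spending required for saturation coverage of all
    interventions (the most expensive scenario).  DALYs averted and the ICER
    are computed relative to the zero-spending optimum.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    cost = np.asarray(
        [oc.cost for oc in outcomes] if costs is None else costs, dtype=float
    )
    budgets = np.linspace(0.0, float(cost.max()), n_points)
    results = [
        optimize_allocation(outcomes, b, objective, costs) for b in budgets
    ]
    zero_dalys = _dalys_of(results[0], outcomes)
    dalys = np.array([_dalys_of(r, outcomes) for r in results])
    averted = zero_dalys - dalys
    with np.errstate(divide="ignore", invalid="ignore"):
        icers = np.where(
            averted > 0, np.array([r.total_cost for r in results]) / averted, np.nan
        )
    return BudgetFrontier(
        budgets=budgets, results=results, dalys_averted=averted,
        icers=icers, objective=objective,
    )


def _dalys_of(result: AllocationResult, outcomes: list[ScenarioOutcome]) -> float:
    return float(np.array([oc.dalys for oc in outcomes]) @ result.weights)


def reallocate_baseline(
    outcomes: list[ScenarioOutcome],
    baseline_weights: np.ndarray,
    objective: str = "min_dalys",
) -> dict:
    """Re-optimize the baseline budget and report the improvement.

    Returns the baseline and optimized outcomes at the baseline cost, the
    DALY difference, percent reduction, and per-intervention coverage before
    and after.
    """
    baseline = mix_outcomes(baseline_weights, outcomes)
    result = optimize_allocation(outcomes, baseline.cost, objective)
    base_dalys = float(np.array([oc.dalys for oc in outcomes]) @ baseline_weights)
    opt_dalys = _dalys_of(result, outcomes)
    base_cov = {}
    for product in REPORT_PRODUCTS:
        cov = 0.0
        for wi, oc in zip(baseline_weights, outcomes):
            if wi > 0 and oc.interventions is not None and _product_active(
                oc.interventions, product
            ):
                cov += wi * _saturation(oc, product)
        base_cov[product] = cov
    return {
        "baseline_cost": baseline.cost,
        "baseline_dalys": base_dalys,
        "optimized_dalys": opt_dalys,
        "dalys_averted": base_dalys - opt_dalys,
        "percent_reduction": 100.0 * (base_dalys - opt_dalys) / base_dalys,
        "coverage_before": base_cov,
        "coverage_after": result.coverage,
        "allocation": result,
    }


def priority_order(
    frontier: BudgetFrontier, threshold: float = 0.01
) -> list[str]:
    """Products ordered by the budget at which optimal coverage first
    exceeds ``threshold``; products never funded are absent."""
    first_budget = {}
    for product in REPORT_PRODUCTS:
        for b, r in zip(frontier.budgets, frontier.results):
            if r.coverage.get(product, 0.0) > threshold:
                first_budget[product] = b
                break
    return sorted(first_budget, key=lambda p: (first_budget[p],
                                               REPORT_PRODUCTS.index(p)))


def _repriced_costs(
    outcomes: list[ScenarioOutcome], cost_model: CostModel, product: str,
    new_product_cost: float,
) -> np.ndarray:
    """Scenario costs recomputed from administration counts at a trial price."""
    unit = {}
    for p in cost_model.product_cost:
        base = cost_model.product_cost[p]
        pc = new_product_cost if p == product else base
        unit[p] = round(pc * cost_model.multiplier, 2)
    costs = []
    for oc in outcomes:
        total = 0.0
        for p, u in unit.items():
            total += oc.counts.get(p, 0.0) * u
        costs.append(total)
    return np.asarray(costs)


def cost_changepoint(
    product: str,
    outcomes: list[ScenarioOutcome],
    cost_model: CostModel,
    direction: str = "increase",
    n_points: int = 25,
    objective: str = "min_dalys",
    max_factor: float = 20.0,
    tol: float = 0.01,
) -> dict:
    """Smallest product-price change that alters the funding priority order.

    Bisection on the product's unit cost; at each trial price every scenario
    is repriced from its administration counts and the budget sweep is
    re-run.  Returns the change-point price within ``tol`` dollars, or the
    search bound if no change occurs.
    """
    if product not in cost_model.product_cost:
        raise ValueError(f"unknown product {product!r}")
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    base_price = cost_model.product_cost[product]

    def order_at(price: float) -> tuple:
        costs = _repriced_costs(outcomes, cost_model, product, price)
        return tuple(priority_order(sweep_budgets(
            outcomes, n_points, objective, costs
        )))

    base_order = order_at(base_price)
    lo, hi = (base_price, base_price * max_factor) if direction == "increase" \
        else (max(0.01, base_price / max_factor), base_price)
    probe = hi if direction == "increase" else lo
    if order_at(probe) == base_order:
        return {
            "product": product, "changed": False, "price": probe,
            "order_before": list(base_order), "order_after": list(base_order),
        }

    # Invariant: order differs at `far`, matches at `near`.
    near, far = (lo, hi) if direction == "increase" else (hi, lo)
    while abs(far - near) > tol:
        mid = 0.5 * (near + far)
        if order_at(mid) == base_order:
            near = mid
        else:
            far = mid
    return {
        "product": product, "changed": True, "price": round(far, 2),
        "order_before": list(base_order), "order_after": list(order_at(far)),
    }


def summarize_draws(
    orders: list[list[str]],
    objective_values: list[float] | None = None,
) -> dict:
    """Uncertainty summary over per-draw allocation results.

    Reports, for each product pair, the fraction of draws in which the first
    is prioritized ahead of the second (absent products rank last), and a
    95% interval of the objective values.
    """
    if len(orders) < 2:
        raise ValueError("need at least two draws")
    pair_frac = {}
    for a in REPORT_PRODUCTS:
        for b in REPORT_PRODUCTS:
            if a == b:
                continue
            hits = 0
            for order in orders:
                ra = order.index(a) if a in order else len(order)
                rb = order.index(b) if b in order else len(order) + 1
                hits += ra < rb
            pair_frac[(a, b)] = hits / len(orders)
    out = {"pairwise_priority_fraction": pair_frac, "n_draws": len(orders)}
    if objective_values is not None:
        vals = np.asarray(objective_values, dtype=float)
        lo, hi = np.percentile(vals, [2.5, 97.5])
        out["objective_interval"] = (float(lo), float(hi))
        out["objective_mean"] = float(vals.mean())
        out["interval_contains_mean"] = bool(lo <= vals.mean() <= hi)
    return out
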