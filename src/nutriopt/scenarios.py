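"""Scenario enumeration, paired simulation runs, costing, and outcome algebra.

A scenario is one combination of the modeled interventions, simulated at
saturation coverage (the optimizer's convex weights then span coverage from
0 to saturation directly).  The engine runs the pregnancy and child
simulations for each scenario x draw with common random numbers (one random
stream per simulant, shared across scenarios), records the burden ledger and
intervention administration counts, and prices the scenario by multiplying
counts with final unit costs.

Because simulants are independent, population outcomes under partial
coverage are convex mixtures of the all-on and all-off scenario outcomes;
:func:`mix_outcomes` implements that mixing exactly, and the empirical
validation of the assumption is part of the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .burden import BurdenLedger
from .children import ChildResult, ChildSimulation
from .constants import OUTCOME_LIVE_BIRTH
from .interventions import InterventionSet, calibrate_sqlns_hazard_scale
from .params.model import CostModel, ParameterDraw
from .pregnancy import run_pregnancy_sim
from .wasting import WastingRates, calibrate_from_draw

PREGNANCY_PRODUCTS = ("ifa", "mmn", "bep")
CHILD_PRODUCTS = ("sam_tx", "mam_tx", "sqlns", "screening")

DEFAULT_N_PREGNANCIES = 20_000
DEFAULT_CHILD_SAMPLE_FRACTION = 0.25


def final_unit_cost(product_cost: float, cost_model: CostModel) -> float:
    """Unit cost with the additive non-product components, rounded to cents."""
    return round(product_cost * cost_model.multiplier, 2)


@dataclass
class ScenarioDefinition:
    interventions: InterventionSet
    coverage: dict = field(default_factory=dict)  # product -> proportion

    @property
    def label(self) -> str:
        return self.interventions.label


@dataclass
class ScenarioOutcome:
    """Recorded outcomes of one scenario under one parameter draw.

    Child-population fields are scaled to the full pregnancy-cohort basis
    (divided by the child sample fraction), so pregnancy- and child-side
    counts and burden are directly addable and the cost identity
    ``cost = sum(counts x final unit cost)`` holds on one population basis.
    """

    label: str
    draw_index: int
    ledger: BurdenLedger
    counts: dict
    cost: float
    n_pregnancies: int
    n_children: int
    interventions: InterventionSet | None = None
    unit_costs: dict = field(default_factory=dict)  # product -> final USD
    saturation: dict = field(default_factory=dict)  # product -> coverage cap

    @property
    def dalys(self) -> float:
        return self.ledger.dalys

    @property
    def not_stunted_person_time(self) -> float:
        return self.ledger.not_stunted_person_time()

    def objective(self, name: str) -> float:
        if name == "min_dalys":
            return self.dalys
        if name == "max_not_stunted_time":
            return self.not_stunted_person_time
        raise ValueError(f"unknown objective {name!r}")


def enumerate_scenarios(
    antenatal=("none", "ifa", "mmn", "mmn_bep"),
    sam=(False, True),
    mam=("none", "targeted", "universal"),
    sqlns=(False, True),
) -> list[InterventionSet]:
    """Cartesian product of intervention options (48 in the full config).

    BEP-without-MMN combinations cannot be expressed: the antenatal axis
    only offers ``mmn_bep`` as a package.
    """
    return [
        InterventionSet(antenatal=a, sam_tx=s, mam_tx=m, sqlns=q)
        for a, s, m, q in itertools.product(antenatal, sam, mam, sqlns)
    ]


def compute_cost(counts: dict, cost_model: CostModel) -> float:
    """Scenario cost: administration counts times final unit costs."""
    total = 0.0
    for product, count in counts.items():
        if product in cost_model.product_cost:
            total += count * cost_model.final_unit_cost(product)
    return total


def run_scenario(
    draw: ParameterDraw,
    scenario: InterventionSet,
    n_pregnancies: int = DEFAULT_N_PREGNANCIES,
    child_sample_fraction: float = DEFAULT_CHILD_SAMPLE_FRACTION,
    seed: int = 0,
    draw_index: int = 0,
    coverage_overrides: dict | None = None,
    rates: WastingRates | None = None,
    sqlns_eta: float | None = None,
) -> ScenarioOutcome:
    """Run the paired pregnancy + child simulation for one scenario.

    The child cohort is seeded from a seed-determined subsample of
    pregnancies (the candidate set is scenario-independent, so scenarios
    share children where both produce a live birth).  Identical seed and
    scenario give bit-identical outcomes.
    """
    preg = run_pregnancy_sim(
        draw, n_pregnancies, seed, scenario,
        coverage=(coverage_overrides or {}).get("antenatal"),
    )
    cohort = preg.cohort

    sample_rng = np.random.default_rng([seed, 983])
    candidates = sample_rng.random(n_pregnancies) < child_sample_fraction
    idx = np.flatnonzero(candidates)
    live = cohort.outcome[idx] == OUTCOME_LIVE_BIRTH

    child_sim = ChildSimulation(
        draw, scenario,
        sex=cohort.infant_sex[idx],
        ga=cohort.ga_weeks[idx],
        bw=cohort.birthweight[idx],
        live=live,
        seed=seed + 15_485_863,
        coverage_overrides=coverage_overrides,
        rates=rates,
        sqlns_eta=sqlns_eta,
    )
    child = child_sim.run()

    child_scale = 1.0 / child_sample_fraction
    ledger = preg.ledger().merged(child.ledger.scale_populations(0.0, child_scale))

    counts = {p: 0.0 for p in PREGNANCY_PRODUCTS + CHILD_PRODUCTS}
    counts.update(preg.supplemented_counts)
    for product in CHILD_PRODUCTS:
        counts[product] = child.counts.get(product, 0.0) * child_scale
    counts["screening_contacts"] = child.counts.get("screening_contacts", 0.0) * child_scale

    cost = compute_cost(counts, draw.costs)
    unit_costs = {
        p: draw.costs.final_unit_cost(p) for p in draw.costs.product_cost
    }
    return ScenarioOutcome(
        label=scenario.label,
        draw_index=draw_index,
        ledger=ledger,
        counts=counts,
        cost=cost,
        n_pregnancies=n_pregnancies,
        n_children=int(live.sum()),
        interventions=scenario,
        unit_costs=unit_costs,
        saturation={
            "mam_targeted": draw.coverage.saturation["mam_tx"],
            "mam_universal": draw.coverage.saturation["mam_tx"],
            **draw.coverage.saturation,
        },
    )


def run_all_scenarios(
    draw: ParameterDraw,
    scenarios: list[InterventionSet] | None = None,
    n_pregnancies: int = DEFAULT_N_PREGNANCIES,
    child_sample_fraction: float = DEFAULT_CHILD_SAMPLE_FRACTION,
    seed: int = 0,
    draw_index: int = 0,
    progress: bool = False,
) -> list[ScenarioOutcome]:
    """Run every scenario under one draw, sharing calibration and randoms."""
    scenarios = scenarios if scenarios is not None else enumerate_scenarios()
    rates = calibrate_from_draw(draw)
    eta = calibrate_sqlns_hazard_scale(
        rates, draw.effects.sqlns_severe_wasting_pr.value
    )
    out = []
    for sc in scenarios:
        out.append(
            run_scenario(
                draw, sc, n_pregnancies, child_sample_fraction, seed,
                draw_index=draw_index, rates=rates, sqlns_eta=eta,
            )
        )
        if progress:  # pragma: no cover - console nicety
            print(f"  scenario {sc.label}: dalys={out[-1].dalys:.0f} cost={out[-1].cost:.0f}")
    return out


# ---------------------------------------------------------------------------
# Outcome algebra
# ---------------------------------------------------------------------------


def mix_outcomes(weights, outcomes: list[ScenarioOutcome]) -> ScenarioOutcome:
    """Convex mixture of scenario outcomes (field-wise weighted sum).

    Represents partial-coverage populations: e.g. 50% coverage equals the
    50/50 mixture of the all-on and all-off scenario outcomes.
    """
    w = np.asarray(weights, dtype=float)
    if len(w) != len(outcomes):
        raise ValueError("weights and outcomes length mismatch")
    if np.any(w < -1e-12):
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")

    ledger = BurdenLedger()
    counts: dict[str, float] = {}
    cost = 0.0
    for wi, oc in zip(w, outcomes):
        if wi == 0.0:
            continue
        ledger = ledger.merged(oc.ledger.scale_populations(wi, wi))
        for k, v in oc.counts.items():
            counts[k] = counts.get(k, 0.0) + wi * v
        cost += wi * oc.cost
    return ScenarioOutcome(
        label="mixture",
        draw_index=outcomes[0].draw_index,
        ledger=ledger,
        counts=counts,
        cost=cost,
        n_pregnancies=outcomes[0].n_pregnancies,
        n_children=outcomes[0].n_children,
        unit_costs=dict(outcomes[0].unit_costs),
    )


def scale_to_national(
    outcome: ScenarioOutcome, pregnancy_factor: float, child_factor: float
) -> ScenarioOutcome:
    """Scale simulated outcomes to national totals.

    Pregnancy-population fields scale by ``pregnancy_factor`` and
    child-population fields by ``child_factor`` (the two factors differ when
    the child cohort was seeded from a subsample of pregnancies).
    """
    if pregnancy_factor <= 0 or child_factor <= 0:
        raise ValueError("scale factors must be positive")
    ledger = outcome.ledger.scale_populations(pregnancy_factor, child_factor)
    counts = {}
    for k, v in outcome.counts.items():
        counts[k] = v * (pregnancy_factor if k in PREGNANCY_PRODUCTS else child_factor)
    cost = sum(
        counts[p] * uc for p, uc in outcome.unit_costs.items() if p in counts
    )
    return ScenarioOutcome(
        label=outcome.label,
        draw_index=outcome.draw_index,
        ledger=ledger,
        counts=counts,
        cost=cost,
        n_pregnancies=outcome.n_pregnancies,
        n_children=outcome.n_children,
        interventions=outcome.interventions,
        unit_costs=dict(outcome.unit_costs),
    )


def baseline_scenario_weights(
    draw: ParameterDraw, scenarios: list[InterventionSet]
) -> np.ndarray:
    """Product-form weight vector representing baseline coverage.

    Each intervention axis splits its weight between off and on(-at-
    saturation) scenarios in the ratio baseline/saturation, independently
    across interventions; baseline MAM treatment is assumed to be the
    universal implementation.
    """
    base = {k: u.value for k, u in draw.coverage.baseline.items()}
    sat = draw.coverage.saturation

    w_ant = {
        "ifa": base["ifa"] / sat["ifa"],
        "mmn": base["mmn"] / sat["mmn"],
        "mmn_bep": base["bep"] / sat["bep"],
    }
    w_ant["none"] = 1.0 - sum(w_ant.values())
    w_sam = {True: base["sam_tx"] / sat["sam_tx"]}
    w_sam[False] = 1.0 - w_sam[True]
    w_mam = {"universal": base["mam_tx"] / sat["mam_tx"], "targeted": 0.0}
    w_mam["none"] = 1.0 - w_mam["universal"]
    w_sq = {True: base["sqlns"] / sat["sqlns"]}
    w_sq[False] = 1.0 - w_sq[True]

    w = np.array([
        w_ant[s.antenatal] * w_sam[s.sam_tx] * w_mam[s.mam_tx] * w_sq[s.sqlns]
        for s in scenarios
    ])
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("baseline weights do not form a distribution; "
                         "scenario list must be the full factorial set")
    return w


def parse_scenario_label(label: str) -> InterventionSet:
    """Inverse of :attr:`InterventionSet.label`."""
    antenatal, sam, mam, sqlns = label.split("+")
    return InterventionSet(
        antenatal=antenatal,
        sam_tx=sam == "sam",
        mam_tx=mam.removeprefix("mam-"),
        sqlns=sqlns == "sqlns",
    )


def outcomes_from_frame(
    df: pd.DataFrame, draw: ParameterDraw
) -> list[ScenarioOutcome]:
    """Rebuild allocator-ready outcomes from a stored outcome table.

    The ledger is reduced to the aggregate measures the optimizer consumes
    (DALY components and not-stunted person-time); per-stratum detail is not
    round-tripped.
    """
    out = []
    unit_costs = {p: draw.costs.final_unit_cost(p) for p in draw.costs.product_cost}
    sat = {
        "mam_targeted": draw.coverage.saturation["mam_tx"],
        "mam_universal": draw.coverage.saturation["mam_tx"],
        **draw.coverage.saturation,
    }
    for _, row in df.iterrows():
        led = BurdenLedger()
        led.add_yll("all", "all", float(row["ylls"]))
        led.add_yld("all", "all", float(row["ylds"]))
        led.stillbirths = float(row["stillbirths"])
        led.person_time[2, 0] = float(row["not_stunted_person_time"])
        counts = {
            k.removeprefix("count_"): float(row[k])
            for k in df.columns if k.startswith("count_")
        }
        out.append(ScenarioOutcome(
            label=row["scenario"],
            draw_index=int(row["draw"]),
            ledger=led,
            counts=counts,
            cost=float(row["cost"]),
            n_pregnancies=int(row["n_pregnancies"]),
            n_children=int(row["n_children"]),
            interventions=parse_scenario_label(row["scenario"]),
            unit_costs=unit_costs,
            saturation=sat,
        ))
    return out


def outcomes_to_frame(outcomes: list[ScenarioOutcome]) -> pd.DataFrame:
    """One row per scenario x draw with ledger fields, counts, and cost."""
    rows = []
    for oc in outcomes:
        row = {
            "scenario": oc.label,
            "draw": oc.draw_index,
            "dalys": oc.dalys,
            "ylls": oc.ledger.total_ylls,
            "ylds": oc.ledger.total_ylds,
            "deaths_pregnancy": oc.ledger.deaths.get("pregnancy", 0.0),
            "deaths_child": oc.ledger.deaths.get("child", 0.0),
            "stillbirths": oc.ledger.stillbirths,
            "not_stunted_person_time": oc.not_stunted_person_time,
            "cost": oc.cost,
            "n_pregnancies": oc.n_pregnancies,
            "n_children": oc.n_children,
        }
        for k, v in sorted(oc.counts.items()):
            row[f"count_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
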