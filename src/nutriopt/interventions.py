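"""Intervention eligibility, delivery, and effect application.

Antenatal products (IFA, MMN, BEP) form a cumulative effect chain: each
row of the effect table is defined relative to the previous product, so the
MMN effect set is IFA's plus MMN's marginal effects, and BEP (given only to
low-BMI pregnancies, and only when MMN is also provided) adds its marginal
effects on top of MMN.  Preterm-birth relative risks are converted into
population mean differences on the continuous gestational-age distribution
by root-finding, including the two-segment shift that reproduces both the
preterm (<37 wk) and very-preterm (<32 wk) targets simultaneously.

Child interventions are SAM treatment, MAM treatment (universal or
targeted), and SQ-LNS supplementation, all reached through monthly CMAM
screening contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .constants import ANTENATAL_PRODUCTS, MAM_MODES
from .wasting import (
    WastingRates,
    discrete_step_matrix,
    stationary_distribution_discrete,
)

PRETERM_CUT_WEEKS = 37.0
VERY_PRETERM_CUT_WEEKS = 32.0
SQLNS_START_DAYS = 182.625  # 6 months
SQLNS_END_DAYS = 547.875  # 18 months (12-month course)
TX_AGE_MIN_DAYS = 182.625  # treatment window 6-59 months
TX_AGE_MAX_DAYS = 1826.25


@dataclass
class InterventionSet:
    """One combination of interventions defining a scenario."""

    antenatal: str = "none"  # none | ifa | mmn | mmn_bep
    sam_tx: bool = False
    mam_tx: str = "none"  # none | targeted | universal
    sqlns: bool = False

    def __post_init__(self):
        if self.antenatal not in ANTENATAL_PRODUCTS:
            raise ValueError(f"unknown antenatal product {self.antenatal!r}")
        if self.mam_tx not in MAM_MODES:
            raise ValueError(f"unknown MAM mode {self.mam_tx!r}")

    @property
    def label(self) -> str:
        parts = [self.antenatal]
        parts.append("sam" if self.sam_tx else "nosam")
        parts.append(f"mam-{self.mam_tx}")
        parts.append("sqlns" if self.sqlns else "nosqlns")
        return "+".join(parts)

    def active_products(self) -> list[str]:
        out = []
        if self.antenatal == "ifa":
            out.append("ifa")
        elif self.antenatal == "mmn":
            out.append("mmn")
        elif self.antenatal == "mmn_bep":
            out.extend(["mmn", "bep"])
        if self.sam_tx:
            out.append("sam_tx")
        if self.mam_tx != "none":
            out.append("mam_tx")
        if self.sqlns:
            out.append("sqlns")
        return out


@dataclass
class AntenatalEffects:
    """Cumulative antenatal effect set relative to no supplementation."""

    hb_md: float = 0.0  # g/L, applied at gestational week 8
    stillbirth_rr: float = 1.0
    bw_md: float = 0.0  # grams
    # Gestational-age shift stages applied in order: a uniform shift (IFA),
    # then a conditional two-segment shift (MMN) keyed on the post-IFA GA.
    ga_uniform_shift: float = 0.0  # weeks
    ga_two_segment: tuple | None = None  # (delta_below_32, delta_above_32)

    def apply_ga_shift(self, ga_weeks: np.ndarray) -> np.ndarray:
        ga = np.asarray(ga_weeks, dtype=float) + self.ga_uniform_shift
        if self.ga_two_segment is not None:
            d_lo, d_hi = self.ga_two_segment
            ga = ga + np.where(ga < VERY_PRETERM_CUT_WEEKS, d_lo, d_hi)
        return ga


def solve_ga_shift(ga_mean: float, ga_sd: float, rr: float, cut: float) -> float:
    """Uniform gestational-age shift reproducing a preterm relative risk.

    Finds delta >= 0 with ``P(GA + delta < cut) = rr * P(GA < cut)`` for a
    normal GA distribution, by root-finding to 1e-9.
    """
    if not 0 < rr <= 1:
        raise ValueError("rr must be in (0, 1]; risk-increasing shifts unsupported")
    base = norm.cdf(cut, ga_mean, ga_sd)
    if base <= 0:
        raise ValueError("P(GA < cut) must be positive")
    if rr == 1.0:
        return 0.0
    target = rr * base

    def f(delta):
        return norm.cdf(cut - delta, ga_mean, ga_sd) - target

    return brentq(f, 0.0, 20.0, xtol=1e-12)


def solve_two_segment_ga_shift(
    ga_mean: float, ga_sd: float, rr37: float, rr32: float
) -> tuple[float, float]:
    """Conditional shifts reproducing preterm and very-preterm RRs jointly.

    ``delta_below32`` applies to births with (untreated) GA < 32 weeks and
    ``delta_above32`` to the rest, such that both ``P(<32)`` and ``P(<37)``
    scale by their target relative risks; at the point estimates the
    below-32 group receives the larger *relative* effect (rr32 <= rr37),
    though resampled draws may invert the order.  Note the week-shifts themselves
    need not be ordered — for a normal GA distribution the far tail thins
    faster per week of shift, so a stronger relative reduction there can
    require a slightly smaller shift.  Raises if no non-negative pair
    achieves both targets.
    """
    if not (0 < rr32 <= 1 and 0 < rr37 <= 1):
        raise ValueError("need relative risks in (0, 1]")
    if rr37 == 1.0 and rr32 == 1.0:
        return 0.0, 0.0
    p32 = norm.cdf(VERY_PRETERM_CUT_WEEKS, ga_mean, ga_sd)
    p37 = norm.cdf(PRETERM_CUT_WEEKS, ga_mean, ga_sd)

    # Below-32 group: only delta_below32 moves mass across the 32-week cut.
    t32 = rr32 * p32

    def f_lo(d):
        return norm.cdf(VERY_PRETERM_CUT_WEEKS - d, ga_mean, ga_sd) - t32

    d_lo = brentq(f_lo, 0.0, 25.0, xtol=1e-12)

    # <37 mass after shifting: below-32 births land at GA + d_lo; above-32
    # births at GA + d_hi (d_hi >= 0 cannot push anyone below 32).
    t37 = rr37 * p37
    a_part = norm.cdf(
        min(VERY_PRETERM_CUT_WEEKS, PRETERM_CUT_WEEKS - d_lo), ga_mean, ga_sd
    )

    def f_hi(d):
        b_part = max(
            0.0, norm.cdf(PRETERM_CUT_WEEKS - d, ga_mean, ga_sd) - p32
        )
        return a_part + b_part - t37

    if f_hi(0.0) < 0 or f_hi(25.0) > 0:
        raise ValueError(
            f"infeasible preterm RR pair (rr37={rr37}, rr32={rr32}): no "
            "non-negative shift pair reproduces both targets"
        )
    d_hi = brentq(f_hi, 0.0, 25.0, xtol=1e-12)
    return float(d_lo), float(d_hi)


def antenatal_effect_chain(product: str, low_bmi: bool, draw) -> AntenatalEffects:
    """Compose cumulative antenatal effects for one product assignment.

    ``product`` is the scenario-level product; a low-BMI pregnancy in an
    ``mmn_bep`` scenario receives MMN+BEP while adequate-BMI pregnancies
    receive MMN only.  Requesting BEP for an adequate-BMI pregnancy raises.
    """
    if product not in ANTENATAL_PRODUCTS:
        raise ValueError(f"unknown antenatal product {product!r}")
    e = draw.effects
    j = draw.ga_bw_joint
    out = AntenatalEffects()
    if product == "none":
        return out
    if product == "mmn_bep" and not low_bmi:
        raise ValueError("BEP is restricted to low-BMI pregnancies")

    # IFA tier (every supplemented pregnancy).  Preterm RR draws above 1 are
    # clamped to the null: the mean-difference machinery models protective
    # shifts only.
    out.hb_md += e.ifa_hb_md.value
    out.bw_md += e.ifa_bw_md.value
    out.ga_uniform_shift = solve_ga_shift(
        j.ga_mean, j.ga_sd, min(1.0, e.ifa_preterm_rr.value), PRETERM_CUT_WEEKS
    )
    if product == "ifa":
        return out

    # MMN tier (relative to IFA).
    out.stillbirth_rr *= e.mmn_stillbirth_rr.value
    out.bw_md += e.mmn_bw_md.value
    shifted_mean = j.ga_mean + out.ga_uniform_shift
    out.ga_two_segment = solve_two_segment_ga_shift(
        shifted_mean, j.ga_sd,
        min(1.0, e.mmn_preterm_rr.value), min(1.0, e.mmn_vpreterm_rr.value),
    )
    if product == "mmn":
        return out

    # BEP tier (relative to MMN; low-BMI subpopulation only).
    out.stillbirth_rr *= e.bep_stillbirth_rr.value
    out.bw_md += e.bep_bw_md.value
    return out


# ---------------------------------------------------------------------------
# Child intervention eligibility
# ---------------------------------------------------------------------------


def mam_targeting_eligible(age_months, whz_substate_low, waz_severe):
    """Targeted-MAM criteria: (a) age < 24 m, (b) WHZ in [-3, -2.5), or
    (c) WAZ < -3.  Vectorized over arrays; inputs describe children already
    in the moderate wasting (MAM) state aged 6-59 months.
    """
    age_months = np.asarray(age_months, dtype=float)
    a = age_months < 24.0
    b = np.asarray(whz_substate_low, dtype=bool)
    c = np.asarray(waz_severe, dtype=bool)
    out = a | b | c
    return bool(out) if out.ndim == 0 else out


def treatment_eligibility(
    age_days: float,
    wasting_state: int,
    whz_substate_low: bool,
    waz_severe: bool,
    scenario: InterventionSet,
) -> str:
    """Treatment arm for one incident wasting case: ``none``/``MAM_tx``/``SAM_tx``.

    SAM treatment covers incident severe wasting (WHZ < -3) at 6-59 months;
    MAM treatment covers incident moderate wasting, either universally or per
    the targeted criteria.  Coverage gating is applied separately.
    """
    if not (TX_AGE_MIN_DAYS <= age_days < TX_AGE_MAX_DAYS):
        return "none"
    if wasting_state == 3 and scenario.sam_tx:
        return "SAM_tx"
    if wasting_state == 2 and scenario.mam_tx != "none":
        if scenario.mam_tx == "universal":
            return "MAM_tx"
        if mam_targeting_eligible(age_days / 30.4375, whz_substate_low, waz_severe):
            return "MAM_tx"
    return "none"


# ---------------------------------------------------------------------------
# SQ-LNS
# ---------------------------------------------------------------------------


def sqlns_stunting_shift(prevalence_severe_first: np.ndarray, pr_severe: float,
                         pr_moderate: float) -> np.ndarray:
    """Shift a stunting prevalence vector by SQ-LNS prevalence ratios.

    Moderate and severe mass scales by the respective prevalence ratios and
    the freed mass moves to the unaffected category.
    """
    p = np.asarray(prevalence_severe_first, dtype=float).copy()
    freed = p[..., 0] * (1 - pr_severe) + p[..., 1] * (1 - pr_moderate)
    p[..., 0] *= pr_severe
    p[..., 1] *= pr_moderate
    p[..., 3] += freed
    return p


def calibrate_sqlns_hazard_scale(
    rates: WastingRates,
    target_severe_pr: float,
    step_days: float = 4.0,
    tol: float = 1e-10,
) -> float:
    """Shared multiplier on the three forward wasting hazards for SQ-LNS.

    Solves a 1-D root-find for the scale ``eta`` such that the stationary
    severe-wasting prevalence of the stepping chain under scaled forward
    rates (remission unchanged) equals ``target_severe_pr`` times the
    unscaled stationary severe prevalence.
    """
    if not 0 < target_severe_pr <= 1:
        raise ValueError("severe-wasting prevalence ratio must be in (0, 1]")
    if target_severe_pr == 1.0:
        return 1.0
    fwd = rates.forward()
    rem = rates.effective_remission()
    m = rates.excess_mortality

    def severe_prev(eta):
        pm = discrete_step_matrix(fwd * eta, rem, m, step_days)
        return stationary_distribution_discrete(pm)[3]

    target = target_severe_pr * severe_prev(1.0)
    return brentq(lambda eta: severe_prev(eta) - target, 1e-3, 1.0, xtol=tol)


def screening_coverage(scenario: InterventionSet, coverages: dict) -> float:
    """CMAM screening coverage: the max of active child-intervention coverages."""
    levels = [0.0]
    if scenario.sam_tx:
        levels.append(coverages["sam_tx"])
    if scenario.mam_tx != "none":
        levels.append(coverages["mam_tx"])
    if scenario.sqlns:
        levels.append(coverages["sqlns"])
    return max(levels)


def count_administrations(receipts: dict, scenario: InterventionSet) -> dict:
    """Aggregate per-product administration counts from simulation receipts.

    ``receipts`` carries raw counters from the pregnancy and child
    simulations (supplemented pregnancies by product, treated episode counts,
    SQ-LNS courses, screened children).  Returns a complete product -> count
    map with zeros for inactive products.
    """
    counts = {p: 0.0 for p in
              ("ifa", "mmn", "bep", "sam_tx", "mam_tx", "sqlns", "screening")}
    active = set(scenario.active_products()) | {"screening"}
    for product, value in receipts.items():
        if product in active:
            counts[product] = float(value)
    return counts
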