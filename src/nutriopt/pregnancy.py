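"""Closed-cohort pregnancy simulation in 7-day steps.

Each simulant starts on day 0 of pregnancy with a maternal age band, a
hemoglobin concentration and a dichotomous low-BMI exposure (correlated via
a Gaussian copula), and a pregnancy outcome (live birth, stillbirth, or
abortion/miscarriage).  Gestational age for birth outcomes comes from the
joint gestational-age/birthweight distribution; abortion/miscarriage
durations are uniform on 6-24 weeks.  The clock advances in 7-day steps:
anemia severity is re-assessed from current hemoglobin each step and accrues
YLDs, antenatal supplementation shifts hemoglobin once at gestational week
8, and when a simulant's duration elapses the birth resolves (maternal
disorders and postpartum hemorrhage modified by hemoglobin, birthweight
drawn conditional on gestational age).  Mothers with birth outcomes are
followed for anemia morbidity for 6 further weeks postpartum; no background
mortality applies.

The cohort is stored as a struct of numpy arrays and every random quantity
is pre-drawn from the seed alone, so two scenarios simulated with the same
seed share common random numbers and scenario contrasts are paired at the
individual level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .burden import BurdenLedger, yll_at_death
from .constants import (
    DAYS_PER_YEAR,
    MATERNAL_AGE_MIDPOINTS,
    OUTCOME_ABORTION,
    OUTCOME_LIVE_BIRTH,
    OUTCOME_STILLBIRTH,
)
from .interventions import AntenatalEffects, InterventionSet, antenatal_effect_chain

DT_DAYS = 7.0
HB_SHIFT_GESTATIONAL_DAY = 56.0  # week 8
POSTPARTUM_WEEKS = 6
HB_FLOOR = 25.0  # g/L; numerical floor after PPH decrement
BW_FLOOR = 300.0  # grams


@dataclass
class PregnancyRandoms:
    """All random inputs for a cohort, drawn from the seed alone."""

    u_age: np.ndarray
    z_hb: np.ndarray
    z_bmi: np.ndarray
    u_outcome: np.ndarray
    u_duration_ab: np.ndarray
    z_ga: np.ndarray
    z_bw: np.ndarray
    u_sex: np.ndarray
    u_disorder: np.ndarray
    u_fatal: np.ndarray
    u_pph: np.ndarray
    u_cov: np.ndarray

    @classmethod
    def generate(cls, n: int, seed: int) -> "PregnancyRandoms":
        rng = np.random.default_rng(seed)
        return cls(
            u_age=rng.random(n),
            z_hb=rng.standard_normal(n),
            z_bmi=rng.standard_normal(n),
            u_outcome=rng.random(n),
            u_duration_ab=rng.random(n),
            z_ga=rng.standard_normal(n),
            z_bw=rng.standard_normal(n),
            u_sex=rng.random(n),
            u_disorder=rng.random(n),
            u_fatal=rng.random(n),
            u_pph=rng.random(n),
            u_cov=rng.random(n),
        )


@dataclass
class PregnancyCohort:
    """Vectorized simulant state; one entry per pregnancy."""

    n: int
    maternal_age: np.ndarray  # years (band midpoint; band fixed at entry)
    low_bmi: np.ndarray  # bool
    hb: np.ndarray  # g/L, time-varying
    covered: np.ndarray  # bool, antenatal coverage propensity realized
    bep_recipient: np.ndarray  # bool (covered low-BMI in an MMN+BEP scenario)
    outcome: np.ndarray  # int codes
    ga_weeks: np.ndarray  # gestational age at birth (nan for abortion)
    duration_days: np.ndarray
    infant_sex: np.ndarray  # 0 male, 1 female (meaningful for live births)
    hb_shift: np.ndarray  # g/L to add at week 8
    bw_md: np.ndarray  # grams to add at birth
    alive: np.ndarray
    exited: np.ndarray
    hb_shift_applied: np.ndarray
    resolved: np.ndarray
    postpartum_steps_left: np.ndarray
    yld_anemia: np.ndarray
    yld_disorder: np.ndarray
    ylls: np.ndarray
    birthweight: np.ndarray  # grams, nan until resolved
    person_time_days: np.ndarray
    supplemented: np.ndarray  # bool: reached the week-8 distribution point

    @property
    def ylds(self) -> np.ndarray:
        return self.yld_anemia + self.yld_disorder


def _anemia_dw(hb: np.ndarray, thresholds: np.ndarray, dws: np.ndarray) -> np.ndarray:
    """Disability weight by anemia severity; 0 above the mild cut point."""
    severity = np.searchsorted(thresholds, hb, side="right")  # 0 severe .. 3 none
    dw_table = np.append(dws, 0.0)
    return dw_table[severity]


def _hb_risk_multiplier(hb, reference_hb, rr_per_10g):
    return rr_per_10g ** (np.maximum(0.0, reference_hb - hb) / 10.0)


def initialize_pregnancy_cohort(
    draw,
    n: int,
    rng: PregnancyRandoms | int,
    scenario: InterventionSet | None = None,
    coverage: float | None = None,
) -> PregnancyCohort:
    """Build the cohort at day 0 of pregnancy under one scenario.

    ``rng`` is either a :class:`PregnancyRandoms` bundle (for common random
    numbers across scenarios) or an integer seed.  ``coverage`` overrides the
    scenario's saturation coverage for the antenatal product.
    """
    if isinstance(rng, (int, np.integer)):
        rng = PregnancyRandoms.generate(n, int(rng))
    scenario = scenario or InterventionSet()
    d, h, j = draw.demography, draw.hemoglobin, draw.ga_bw_joint

    band = np.searchsorted(np.cumsum(d.maternal_age_shares), rng.u_age, side="right")
    band = np.minimum(band, len(MATERNAL_AGE_MIDPOINTS) - 1)
    maternal_age = MATERNAL_AGE_MIDPOINTS[band]

    # Gaussian copula between hemoglobin and the latent BMI percentile; the
    # latent correlation reproduces the configured Spearman correlation.
    rho = 2.0 * np.sin(np.pi * h.hb_bmi_rank_corr / 6.0)
    z_bmi_corr = rho * rng.z_hb + np.sqrt(1.0 - rho**2) * rng.z_bmi
    from scipy.stats import norm as _norm

    bmi_pct = _norm.cdf(z_bmi_corr)
    low_bmi = bmi_pct < h.low_bmi_prevalence
    hb = h.hb_mean + h.hb_sd * rng.z_hb

    product = scenario.antenatal
    if coverage is None:
        coverage = (
            0.0 if product == "none"
            else draw.coverage.saturation[product.split("_")[0]]
        )
    covered = rng.u_cov < coverage

    # Per-simulant effect assignment.  In an MMN+BEP scenario adequate-BMI
    # pregnancies receive MMN only.
    hb_shift = np.zeros(n)
    bw_md = np.zeros(n)
    sb_rr = np.ones(n)
    eff_main: AntenatalEffects | None = None
    eff_bep: AntenatalEffects | None = None
    bep_recipient = np.zeros(n, dtype=bool)
    if product != "none":
        main_product = "mmn" if product == "mmn_bep" else product
        eff_main = antenatal_effect_chain(main_product, False, draw)
        hb_shift[covered] = eff_main.hb_md
        bw_md[covered] = eff_main.bw_md
        sb_rr[covered] = eff_main.stillbirth_rr
        if product == "mmn_bep":
            eff_bep = antenatal_effect_chain("mmn_bep", True, draw)
            bep_recipient = covered & low_bmi
            hb_shift[bep_recipient] = eff_bep.hb_md
            bw_md[bep_recipient] = eff_bep.bw_md
            sb_rr[bep_recipient] = eff_bep.stillbirth_rr

    # Outcome with the stillbirth RR reallocating mass to live birth only.
    p_live, p_still, _ = d.birth_outcome_probs
    thr_live = p_live + p_still * (1.0 - sb_rr)
    thr_still = thr_live + p_still * sb_rr
    outcome = np.where(
        rng.u_outcome < thr_live,
        OUTCOME_LIVE_BIRTH,
        np.where(rng.u_outcome < thr_still, OUTCOME_STILLBIRTH, OUTCOME_ABORTION),
    )

    is_birth = outcome != OUTCOME_ABORTION
    ga = np.where(is_birth, j.ga_mean + j.ga_sd * rng.z_ga, np.nan)
    if eff_main is not None:
        shifted = eff_main.apply_ga_shift(ga[covered & ~bep_recipient])
        ga[covered & ~bep_recipient] = shifted
        if eff_bep is not None:
            ga[bep_recipient] = eff_bep.apply_ga_shift(ga[bep_recipient])
    ga = np.where(is_birth, np.maximum(ga, 22.0), np.nan)

    duration = np.where(
        is_birth, ga * 7.0, (6.0 + 18.0 * rng.u_duration_ab) * 7.0
    )
    infant_sex = (rng.u_sex >= d.infant_sex_ratio).astype(np.int8)

    return PregnancyCohort(
        n=n,
        maternal_age=maternal_age,
        low_bmi=low_bmi,
        hb=hb,
        covered=covered,
        bep_recipient=bep_recipient,
        outcome=outcome.astype(np.int8),
        ga_weeks=ga,
        duration_days=duration,
        infant_sex=infant_sex,
        hb_shift=hb_shift,
        bw_md=bw_md,
        alive=np.ones(n, dtype=bool),
        exited=np.zeros(n, dtype=bool),
        hb_shift_applied=np.zeros(n, dtype=bool),
        resolved=np.zeros(n, dtype=bool),
        postpartum_steps_left=np.full(n, -1, dtype=np.int16),
        yld_anemia=np.zeros(n),
        yld_disorder=np.zeros(n),
        ylls=np.zeros(n),
        birthweight=np.full(n, np.nan),
        person_time_days=np.zeros(n),
        supplemented=np.zeros(n, dtype=bool),
    )


def resolve_birth(cohort: PregnancyCohort, draw, mask: np.ndarray,
                  randoms: PregnancyRandoms) -> None:
    """Resolve births for the masked simulants (duration just elapsed).

    Applies hemoglobin-modified maternal-disorder and postpartum-hemorrhage
    risks, draws birthweight conditional on gestational age (plus anemia,
    low-BMI, and intervention shifts), and starts the 6-week postpartum
    follow-up (abortion/miscarriage outcomes exit immediately).
    """
    m, h, j = draw.maternal_risks, draw.hemoglobin, draw.ga_bw_joint
    all_idx = np.flatnonzero(mask)
    if all_idx.size == 0:
        return
    # Maternal disorder and PPH risks are per *birth* event; abortion/
    # miscarriage resolutions exit without them.
    idx = all_idx[cohort.outcome[all_idx] != OUTCOME_ABORTION]
    hb = cohort.hb[idx]
    rr = _hb_risk_multiplier(hb, h.reference_hb, m.hb_rr_per_10g)

    p_dis = np.minimum(1.0, m.disorder_risk * rr)
    incident = randoms.u_disorder[idx] < p_dis
    fatal = incident & (randoms.u_fatal[idx] < m.disorder_cfr)
    cohort.yld_disorder[idx[incident & ~fatal]] += m.disorder_yld
    fatal_idx = idx[fatal]
    cohort.ylls[fatal_idx] += yll_at_death(
        cohort.maternal_age[fatal_idx], draw.tmrle_ages, draw.tmrle_values
    )
    cohort.alive[fatal_idx] = False
    cohort.exited[fatal_idx] = True

    p_pph = np.minimum(1.0, m.pph_risk * rr)
    pph = randoms.u_pph[idx] < p_pph
    cohort.hb[idx[pph]] = np.maximum(HB_FLOOR, cohort.hb[idx[pph]] - m.pph_hb_decrement)

    birth_idx = idx
    if birth_idx.size:
        ga = cohort.ga_weeks[birth_idx]
        cond_mean = j.bw_mean + j.corr * j.bw_sd * (ga - j.ga_mean) / j.ga_sd
        cond_sd = j.bw_sd * np.sqrt(1.0 - j.corr**2)
        bw = cond_mean + cond_sd * randoms.z_bw[birth_idx]
        anemic = cohort.hb[birth_idx] < h.anemia_thresholds[-1]
        bw = bw - anemic * m.bw_anemia_decrement
        bw = bw - cohort.low_bmi[birth_idx] * m.bw_low_bmi_decrement
        bw = bw + cohort.bw_md[birth_idx]
        cohort.birthweight[birth_idx] = np.maximum(BW_FLOOR, bw)

    cohort.resolved[all_idx] = True
    # Postpartum anemia follow-up for (surviving) birth outcomes only.
    follow = birth_idx[cohort.alive[birth_idx]]
    cohort.postpartum_steps_left[follow] = POSTPARTUM_WEEKS
    abort_idx = all_idx[cohort.outcome[all_idx] == OUTCOME_ABORTION]
    cohort.exited[abort_idx] = True


def step_pregnancy(cohort: PregnancyCohort, draw, t_days: float,
                   randoms: PregnancyRandoms, dt_days: float = DT_DAYS) -> dict:
    """Advance the cohort one 7-day step starting at ``t_days``.

    Sub-step order: age advance, week-8 intervention hemoglobin shift,
    anemia YLD accrual, birth resolution for elapsed durations, postpartum
    countdown.  Returns an event log dict.
    """
    if t_days % dt_days != 0:
        raise ValueError("step must start on the 7-day grid")
    h = draw.hemoglobin
    active = ~cohort.exited
    if not active.any():
        return {"births": 0, "exits": 0}

    pregnant = active & ~cohort.resolved
    cohort.person_time_days[active] += dt_days

    # Week-8 hemoglobin shift for covered simulants still pregnant.
    crossing = (
        pregnant
        & ~cohort.hb_shift_applied
        & (t_days + dt_days > HB_SHIFT_GESTATIONAL_DAY - 1e-9)
        & (cohort.duration_days >= HB_SHIFT_GESTATIONAL_DAY)
    )
    cohort.hb[crossing] += cohort.hb_shift[crossing]
    cohort.hb_shift_applied[crossing] = True
    cohort.supplemented[crossing & cohort.covered] = True

    # Anemia morbidity for everyone still in the simulation.
    dw = _anemia_dw(cohort.hb[active], h.anemia_thresholds, h.anemia_dws)
    cohort.yld_anemia[active] += dw * dt_days / DAYS_PER_YEAR

    # Birth resolution for durations elapsing within this step.
    due = pregnant & (cohort.duration_days <= t_days + dt_days)
    resolve_birth(cohort, draw, due, randoms)

    # Postpartum countdown.
    post = active & cohort.resolved & (cohort.postpartum_steps_left >= 0)
    cohort.postpartum_steps_left[post] -= 1
    done = post & (cohort.postpartum_steps_left < 0)
    cohort.exited[done] = True
    return {"births": int(due.sum()), "exits": int(done.sum())}


def finalize_postpartum(cohort: PregnancyCohort) -> dict:
    """Maternal outcome tallies once all simulants have exited."""
    if not cohort.exited.all():
        raise RuntimeError("cohort still has active simulants")
    live = cohort.outcome == OUTCOME_LIVE_BIRTH
    return {
        "ylds_anemia": float(cohort.yld_anemia.sum()),
        "ylds_disorder": float(cohort.yld_disorder.sum()),
        "ylls": float(cohort.ylls.sum()),
        "deaths": int((~cohort.alive).sum()),
        "stillbirths": int((cohort.outcome == OUTCOME_STILLBIRTH).sum()),
        "live_births": int(live.sum()),
        "person_time_years": float(cohort.person_time_days.sum() / DAYS_PER_YEAR),
    }


@dataclass
class PregnancyResult:
    cohort: PregnancyCohort
    summary: dict
    supplemented_counts: dict = field(default_factory=dict)

    def births_table(self) -> pd.DataFrame:
        """Live and stillbirths with sex, gestational age, and birthweight."""
        mask = self.cohort.outcome != OUTCOME_ABORTION
        idx = np.flatnonzero(mask)
        return pd.DataFrame({
            "id": idx,
            "sex": np.where(self.cohort.infant_sex[idx] == 0, "male", "female"),
            "gestational_age_weeks": self.cohort.ga_weeks[idx],
            "birthweight_g": self.cohort.birthweight[idx],
            "outcome": np.where(
                self.cohort.outcome[idx] == OUTCOME_LIVE_BIRTH,
                "live_birth", "stillbirth",
            ),
        })

    def live_birth_index(self) -> np.ndarray:
        return np.flatnonzero(self.cohort.outcome == OUTCOME_LIVE_BIRTH)

    def ledger(self) -> BurdenLedger:
        led = BurdenLedger()
        led.add_yld("pregnancy", "anemia", self.summary["ylds_anemia"])
        led.add_yld("pregnancy", "maternal_disorders", self.summary["ylds_disorder"])
        led.add_yll("pregnancy", "maternal_disorders", self.summary["ylls"])
        led.add_deaths("pregnancy", self.summary["deaths"])
        led.stillbirths = self.summary["stillbirths"]
        led.person_time_total["pregnancy"] = self.summary["person_time_years"]
        return led


def run_pregnancy_sim(
    draw,
    n: int,
    seed: int,
    scenario: InterventionSet | None = None,
    coverage: float | None = None,
) -> PregnancyResult:
    """Simulate the full pregnancy cohort from day 0 through 6 weeks postpartum."""
    randoms = PregnancyRandoms.generate(n, seed)
    scenario = scenario or InterventionSet()
    cohort = initialize_pregnancy_cohort(draw, n, randoms, scenario, coverage)
    t = 0.0
    while not cohort.exited.all():
        step_pregnancy(cohort, draw, t, randoms)
        t += DT_DAYS
        if t > 400 * 7:  # pragma: no cover - defensive
            raise RuntimeError("pregnancy simulation failed to terminate")
    summary = finalize_postpartum(cohort)

    counts: dict[str, float] = {}
    product = scenario.antenatal
    if product != "none":
        supp = cohort.supplemented
        if product == "ifa":
            counts["ifa"] = float(supp.sum())
        else:
            counts["mmn"] = float(supp.sum())
            if product == "mmn_bep":
                counts["bep"] = float((supp & cohort.bep_recipient).sum())
    return PregnancyResult(cohort=cohort, summary=summary, supplemented_counts=counts)
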