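"""Child simulation: each live birth from day 0 to age 5 in 4-day steps.

Modeled components, in fixed sub-step order: aging (with exposure refresh at
age-band boundaries), the dynamic wasting transition model (with treatment
and SQ-LNS hazard modifiers), incidence/resolution of four infectious causes
(diarrheal diseases, lower respiratory infections, malaria, measles) with
growth-failure relative risks, protein-energy malnutrition morbidity and
mortality driven entirely by wasting state, and background mortality (scaled
in the first 28 days by the low birthweight/short gestation risk surface).
Deaths accrue YLLs from the reference life-expectancy table; condition time
accrues YLDs by disability weight.

Because the cohort is closed and initialized at birth, age is a single
scalar shared by all simulants, and every step draws the same fixed set of
random arrays over a scenario-independent candidate set, so identical seeds
give common random numbers across scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .burden import BurdenLedger
from .constants import (
    CAUSES,
    CGF_AGE_BANDS,
    DAYS_PER_YEAR,
    N_CGF_BANDS,
    child_age_band,
)
from .interventions import (
    InterventionSet,
    SQLNS_END_DAYS,
    SQLNS_START_DAYS,
    TX_AGE_MAX_DAYS,
    TX_AGE_MIN_DAYS,
    calibrate_sqlns_hazard_scale,
    screening_coverage,
    sqlns_stunting_shift,
)
from .wasting import WastingRates, calibrate_from_draw

DT_DAYS = 4.0
DT_YEARS = DT_DAYS / DAYS_PER_YEAR
CGF_START_DAYS = 28.0
END_AGE_DAYS = 1826.25  # exit at the 5th birthday


# ---------------------------------------------------------------------------
# Low birthweight / short gestation risk surface
# ---------------------------------------------------------------------------


def _bilinear_log_rr(lbwsg, ga, bw):
    ga = np.clip(ga, lbwsg.ga_grid[0], lbwsg.ga_grid[-1])
    bw = np.clip(bw, lbwsg.bw_grid[0], lbwsg.bw_grid[-1])
    gi = np.clip(np.searchsorted(lbwsg.ga_grid, ga) - 1, 0, len(lbwsg.ga_grid) - 2)
    bi = np.clip(np.searchsorted(lbwsg.bw_grid, bw) - 1, 0, len(lbwsg.bw_grid) - 2)
    g0, g1 = lbwsg.ga_grid[gi], lbwsg.ga_grid[gi + 1]
    b0, b1 = lbwsg.bw_grid[bi], lbwsg.bw_grid[bi + 1]
    tg = (ga - g0) / (g1 - g0)
    tb = (bw - b0) / (b1 - b0)
    z = lbwsg.log_rr
    return (
        z[gi, bi] * (1 - tg) * (1 - tb)
        + z[gi + 1, bi] * tg * (1 - tb)
        + z[gi, bi + 1] * (1 - tg) * tb
        + z[gi + 1, bi + 1] * tg * tb
    )


def lbwsg_population_mean_rr(draw, n_nodes: int = 40) -> float:
    """Population-average raw RR under the GA x birthweight joint normal.

    Gauss-Hermite quadrature on the bivariate normal; used to renormalize
    the surface so the population-average multiplier is 1 (burden conserved).
    """
    j = draw.ga_bw_joint
    x, wx = np.polynomial.hermite_e.hermegauss(n_nodes)
    wx = wx / wx.sum()
    ga = j.ga_mean + j.ga_sd * x
    bw_cond_sd = j.bw_sd * np.sqrt(1 - j.corr**2)
    total = 0.0
    for gi, wgi in zip(ga, wx):
        bw = j.bw_mean + j.corr * j.bw_sd * (gi - j.ga_mean) / j.ga_sd + bw_cond_sd * x
        total += wgi * float(
            np.sum(wx * np.exp(_bilinear_log_rr(draw.lbwsg, np.full_like(bw, gi), bw)))
        )
    return total


def lbwsg_mortality_multiplier(ga, bw, age_days, draw, mean_rr: float | None = None):
    """Neonatal mortality multiplier from the LBWSG surface.

    Bilinear interpolation on the log-RR grid (out-of-grid values clamp to
    the boundary), renormalized by the population-average RR so the mean
    multiplier is 1; returns 1 for ages >= 28 days.
    """
    if mean_rr is None:
        mean_rr = lbwsg_population_mean_rr(draw)
    mult = np.exp(_bilinear_log_rr(draw.lbwsg, np.asarray(ga, float),
                                   np.asarray(bw, float))) / mean_rr
    out = np.where(np.asarray(age_days, float) < CGF_START_DAYS, mult, 1.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Growth-failure helpers
# ---------------------------------------------------------------------------


def _shifted_percentile(z, bw_std, beta):
    """Uniform percentile tilted by standardized birthweight.

    ``Phi((z + beta * w) / sqrt(1 + beta^2))`` is marginally uniform, so the
    population category distribution matches the prevalence exactly while
    low-birthweight children land at worse (lower) percentiles when
    ``beta > 0``.
    """
    from scipy.stats import norm

    return norm.cdf((z + beta * bw_std) / np.sqrt(1.0 + beta * beta))


def categorize(percentile, prevalence_severe_first):
    """Severe-first category index from a percentile (low = worse)."""
    cum = np.cumsum(prevalence_severe_first, axis=-1)
    if cum.ndim == 1:
        return np.searchsorted(cum[:3], percentile, side="right")
    # per-individual prevalence rows
    return (percentile[:, None] >= cum[:, :3]).sum(axis=1)


def wasting_rr_index(state, substate_low):
    """Map engine wasting state (+ moderate substate) to severe-first index 0-4."""
    return np.where(
        state == 3, 0,
        np.where(state == 2, np.where(substate_low, 1, 2), 4 - state),
    )


def update_underweight(u, w4, s4, band, sex, cum_conditional):
    """Draw underweight categories from the conditional table.

    ``cum_conditional`` is the cumulative (over the last axis) table
    P(underweight | wasting, stunting, band, sex); ``u`` one uniform per
    child.  Re-invoked whenever wasting, stunting, or age band changes.
    """
    c = cum_conditional[w4, s4, band, sex]
    return (u[:, None] >= c[:, :3]).sum(axis=1)


def _rr_normalizers(draw):
    """Population-average combined RR per (band, sex) for incidence/mortality.

    Expectation over the joint exposure distribution (wasting x stunting
    independent, underweight conditional), used to convert population-average
    cause rates into unexposed-reference rates, GBD-style.  The mortality
    normalizer is ``E[rr_inc * rr_mort] / E[rr_inc]`` rather than
    ``E[rr_mort]`` because deaths occur at the product of the two (cases
    arise at rr_inc and die at rr_mort), so this choice keeps the
    population-average cause death rate equal to incidence x case fatality.
    """
    split = draw.cgf_prevalence.mam_substate_split
    rr = draw.cgf_rrs
    norm_inc = np.zeros((N_CGF_BANDS, 2))
    norm_mort = np.zeros((N_CGF_BANDS, 2))
    for b in range(N_CGF_BANDS):
        for s in range(2):
            pw4 = draw.cgf_prevalence.wasting[b, s]
            pw5 = np.array([
                pw4[0], pw4[1] * split, pw4[1] * (1 - split), pw4[2], pw4[3],
            ])
            ps = draw.cgf_prevalence.stunting[b, s]
            cond = draw.cgf_prevalence.underweight_conditional[:, :, b, s, :]
            w4_of_w5 = np.array([0, 1, 1, 2, 3])
            e_inc = 0.0
            e_prod = 0.0
            for w5 in range(5):
                for st in range(4):
                    pu = cond[w4_of_w5[w5], st]
                    ri = rr.wasting_incidence[w5] * rr.stunting_incidence[st] * (
                        pu @ rr.underweight_incidence
                    )
                    # E[rr_inc * rr_mort] needs the underweight expectation of
                    # the product, computed within the (w, s) stratum.
                    rip = (
                        rr.wasting_incidence[w5] * rr.wasting_mortality[w5]
                        * rr.stunting_incidence[st] * rr.stunting_mortality[st]
                        * (pu @ (rr.underweight_incidence * rr.underweight_mortality))
                    )
                    e_inc += pw5[w5] * ps[st] * ri
                    e_prod += pw5[w5] * ps[st] * rip
            norm_inc[b, s] = e_inc
            norm_mort[b, s] = e_prod / e_inc
    return norm_inc, norm_mort


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


@dataclass
class ChildResult:
    """Per-scenario child-cohort outcome bundle."""

    n_live: int
    ledger: BurdenLedger
    counts: dict
    dalys_per_child: np.ndarray  # ylls + ylds per candidate row (0 if not live)
    live_mask: np.ndarray


class ChildSimulation:
    """Vectorized cohort simulation over a fixed candidate set.

    The candidate set (rows) is scenario-independent; rows whose pregnancy
    did not end in a live birth under the current scenario are simply never
    alive.  All per-step random draws cover the full candidate set in a fixed
    order, which guarantees common random numbers across scenarios.
    """

    def __init__(
        self,
        draw,
        scenario: InterventionSet,
        sex: np.ndarray,  # 0/1 per candidate
        ga: np.ndarray,
        bw: np.ndarray,
        live: np.ndarray,  # bool per candidate
        seed: int,
        coverage_overrides: dict | None = None,
        rates: WastingRates | None = None,
        sqlns_eta: float | None = None,
    ):
        self.draw = draw
        self.scenario = scenario
        self.n = len(sex)
        self.sex = np.asarray(sex, dtype=np.int64)
        self.ga = np.where(np.isnan(ga), draw.ga_bw_joint.ga_mean, ga)
        self.bw = np.where(np.isnan(bw), draw.ga_bw_joint.bw_mean, bw)
        self.live = np.asarray(live, dtype=bool)
        self.rng = np.random.default_rng(seed)

        cov = dict(draw.coverage.saturation)
        if coverage_overrides:
            cov.update(coverage_overrides)
        self.cov = cov
        self.c_sam = cov["sam_tx"] if scenario.sam_tx else 0.0
        self.c_mam = cov["mam_tx"] if scenario.mam_tx != "none" else 0.0
        self.c_sqlns = cov["sqlns"] if scenario.sqlns else 0.0
        self.c_screen = screening_coverage(
            scenario, {k: cov[k] for k in ("sam_tx", "mam_tx", "sqlns")}
        )

        self.rates = rates if rates is not None else calibrate_from_draw(draw)
        if scenario.sqlns and sqlns_eta is None:
            sqlns_eta = calibrate_sqlns_hazard_scale(
                self.rates, draw.effects.sqlns_severe_wasting_pr.value
            )
        self.sqlns_eta = sqlns_eta if sqlns_eta is not None else 1.0
        self.norm_inc, self.norm_mort = _rr_normalizers(draw)
        self.lbwsg_mean_rr = lbwsg_population_mean_rr(draw)
        self.cum_cond = np.cumsum(draw.cgf_prevalence.underweight_conditional, axis=-1)

        self._initialize()

    # -- initialization -----------------------------------------------------

    def _initialize(self):
        d = self.draw
        n = self.n
        rng = self.rng

        self.z_stunt = rng.standard_normal(n)
        self.z_wast = rng.standard_normal(n)
        self.u_cov = rng.random(n)
        self.u_uw_init = rng.random(n)
        self.u_sub_init = rng.random(n)
        self.stunting_pct = np.full(n, 0.5)
        self.wasting_init_pct = np.full(n, 0.5)

        self.alive = self.live.copy()
        self.wasting_state = np.zeros(n, dtype=np.int64)  # engine order
        self.substate_low = np.zeros(n, dtype=bool)
        self.stunting_cat = np.full(n, 3, dtype=np.int64)  # severe-first idx
        self.uw_cat = np.full(n, 3, dtype=np.int64)
        self.stunting_shifted = np.zeros(n, dtype=bool)

        self.treated_mam = np.zeros(n, dtype=bool)
        self.treated_sam = np.zeros(n, dtype=bool)
        self.responder = np.zeros(n, dtype=bool)

        self.remaining = np.zeros((n, len(CAUSES)))
        self.measles_immune = np.zeros(n, dtype=bool)

        self.ylds = np.zeros(n)
        self.ylls = np.zeros(n)
        self.yld_by_cause: dict[str, float] = {}
        self.yll_by_cause: dict[str, float] = {}
        self.deaths_by_cause: dict[str, float] = {}

        self.person_time = np.zeros((4, N_CGF_BANDS))
        self.person_time_total = 0.0
        self.wasting_person_time = np.zeros(4)  # engine state order
        self.wasting_incident: dict[str, float] = {
            "mild": 0.0, "moderate": 0.0, "severe": 0.0,
        }
        self.counts = {
            "sam_tx": 0.0, "mam_tx": 0.0, "sqlns": 0.0, "screening": 0.0,
        }
        self.screening_contacts = 0.0
        self.screened = np.zeros(n, dtype=bool)
        self.sqlns_covered = np.zeros(n, dtype=bool)
        self._window_entered = False

        self.lbwsg_mult = lbwsg_mortality_multiplier(
            self.ga, self.bw, 0.0, d, self.lbwsg_mean_rr
        )

    def _stunting_prevalence_rows(self, band):
        """Per-child stunting prevalence rows for the current band, with the
        SQ-LNS shift applied to supplemented children."""
        p = self.draw.cgf_prevalence.stunting[band, self.sex]
        if self.stunting_shifted.any():
            e = self.draw.effects
            shifted = sqlns_stunting_shift(
                p, e.sqlns_severe_stunting_pr.value, e.sqlns_moderate_stunting_pr.value
            )
            p = np.where(self.stunting_shifted[:, None], shifted, p)
        return p

    def _refresh_stunting(self, band, mask):
        rows = self._stunting_prevalence_rows(band)
        cat = categorize(self.stunting_pct, rows)
        self.stunting_cat[mask] = cat[mask]

    def _refresh_underweight(self, band, mask, u):
        w4 = 3 - self.wasting_state
        new = update_underweight(
            u, w4, self.stunting_cat, np.full(self.n, band), self.sex, self.cum_cond
        )
        self.uw_cat[mask] = new[mask]

    def _assign_cgf_at_28d(self):
        band = 0
        alive = self.alive
        # Standardize birthweight by rank *among survivors at 28 days*:
        # neonatal mortality selects against low birthweight, so raw
        # standardization would break the marginal uniformity of the tilted
        # percentiles and skew category populations off the prevalence
        # targets.  Rank scores keep the association and the calibration.
        from scipy.stats import norm

        p = self.draw.cgf_prevalence
        bw_score = np.zeros(self.n)
        idx = np.flatnonzero(alive)
        ranks = np.empty(idx.size)
        ranks[np.argsort(self.bw[idx], kind="stable")] = np.arange(idx.size)
        bw_score[idx] = norm.ppf((ranks + 0.5) / idx.size)
        self.stunting_pct = _shifted_percentile(
            self.z_stunt, bw_score, p.stunting_bw_beta
        )
        self.wasting_init_pct = _shifted_percentile(
            self.z_wast, bw_score, p.wasting_bw_beta
        )
        self._refresh_stunting(band, alive)
        wast_rows = self.draw.cgf_prevalence.wasting[band, self.sex]
        cat_sf = categorize(self.wasting_init_pct, wast_rows)
        self.wasting_state[alive] = (3 - cat_sf)[alive]
        mod = alive & (self.wasting_state == 2)
        split = self.draw.cgf_prevalence.mam_substate_split
        self.substate_low[mod] = self.u_sub_init[mod] < split
        self._refresh_underweight(band, alive, self.u_uw_init)

    # -- stepping -----------------------------------------------------------

    def _record_death(self, idx, cause, age_years):
        if idx.size == 0:
            return
        from .burden import yll_at_death

        yll = yll_at_death(age_years, self.draw.tmrle_ages, self.draw.tmrle_values)
        self.ylls[idx] += yll
        self.alive[idx] = False
        self.yll_by_cause[cause] = self.yll_by_cause.get(cause, 0.0) + yll * idx.size
        self.deaths_by_cause[cause] = self.deaths_by_cause.get(cause, 0.0) + idx.size

    def _add_yld(self, mask_or_idx, cause, amount_per_child):
        inc = np.zeros(self.n)
        inc[mask_or_idx] = amount_per_child
        self.ylds += inc
        self.yld_by_cause[cause] = self.yld_by_cause.get(cause, 0.0) + float(inc.sum())

    def step(self, age_days: float, prev_band: int, band: int):
        """One 4-day step from ``age_days``; returns the new band index."""
        d = self.draw
        n = self.n
        rng = self.rng
        alive = self.alive
        age_years = age_days / DAYS_PER_YEAR
        cgf_active = age_days >= CGF_START_DAYS
        cgf_band = max(band - 2, 0)

        # Fixed random-draw schedule (scenario-independent).
        u_wast = rng.random(n)
        u_sub = rng.random(n)
        u_tx = rng.random(n)
        u_uw = rng.random(n)
        u_inc = rng.random((n, len(CAUSES)))
        u_die = rng.random((n, len(CAUSES)))
        u_pem = rng.random(n)
        u_bg = rng.random(n)

        # Person-time accrual.
        self.person_time_total += float(alive.sum()) * DT_YEARS
        if cgf_active:
            occ = np.bincount(self.stunting_cat[alive], minlength=4)
            self.person_time[:, cgf_band] += occ * DT_YEARS
            self.wasting_person_time += (
                np.bincount(self.wasting_state[alive], minlength=4) * DT_YEARS
            )

        # 28-day exposure assignment.
        if age_days == CGF_START_DAYS:
            self._assign_cgf_at_28d()

        # Band crossing: stunting re-threshold and underweight refresh.
        if band != prev_band and cgf_active and age_days > CGF_START_DAYS:
            self._refresh_stunting(cgf_band, alive)
            self._refresh_underweight(cgf_band, alive, u_uw)

        # SQ-LNS window bookkeeping.
        sqlns_window = SQLNS_START_DAYS <= age_days < SQLNS_END_DAYS
        if self.scenario.sqlns and age_days >= SQLNS_START_DAYS and not self.sqlns_covered.any():
            start = alive & (self.u_cov < self.c_sqlns)
            self.sqlns_covered = start
            self.counts["sqlns"] += float(start.sum())
            if start.any():
                self.stunting_shifted |= start
                self._refresh_stunting(cgf_band, start)
                self._refresh_underweight(cgf_band, start, u_uw)
        if age_days >= TX_AGE_MIN_DAYS and not self.screened.any() and self.c_screen > 0:
            self.screened = alive & (self.u_cov < self.c_screen)
            self.counts["screening"] += float(self.screened.sum())
        if self.c_screen > 0 and age_days >= TX_AGE_MIN_DAYS:
            # Monthly CMAM screening contacts among covered, alive children.
            self.screening_contacts += float(
                (self.screened & alive).sum()
            ) * DT_DAYS / 30.4375

        # Prevalent-case detection at entry to the 6-59 m treatment window:
        # the first CMAM screening contact refers covered children already in
        # an eligible wasting state, so baseline treatment coverage acts on
        # the same case pool the steady-state calibration assumes.
        if age_days >= TX_AGE_MIN_DAYS and not self._window_entered:
            self._window_entered = True
            if self.scenario.sam_tx:
                start = (
                    alive & (self.wasting_state == 3)
                    & ~self.treated_sam & (self.u_cov < self.c_sam)
                )
                self.treated_sam[start] = True
                self.responder[start] = u_tx[start] >= d.wasting.nonresponse_fraction
                self.counts["sam_tx"] += float(start.sum())
            if self.scenario.mam_tx != "none":
                eligible = alive & (self.wasting_state == 2) & ~self.treated_mam
                if self.scenario.mam_tx == "targeted":
                    age_months = age_days / 30.4375
                    eligible &= (
                        (age_months < 24.0) | self.substate_low | (self.uw_cat == 0)
                    )
                start = eligible & (self.u_cov < self.c_mam)
                self.treated_mam[start] = True
                self.responder[start] = u_tx[start] >= d.wasting.nonresponse_fraction
                self.counts["mam_tx"] += float(start.sum())

        # -- wasting transitions -------------------------------------------
        if cgf_active:
            rem = np.empty((n, 3))
            rem[:, 0] = self.rates.r2
            rem[:, 1] = np.where(
                self.treated_mam & self.responder, self.rates.t3, self.rates.r3
            )
            rem[:, 2] = np.where(
                self.treated_sam & self.responder, self.rates.t4, self.rates.r4
            )
            fwd_mult = np.where(
                self.sqlns_covered & sqlns_window, self.sqlns_eta, 1.0
            )
            from .wasting import step_wasting_states

            old_state = self.wasting_state
            new_state, progressed, remitted = step_wasting_states(
                old_state, u_wast, DT_DAYS, self.rates.forward(), rem, fwd_mult
            )
            progressed &= alive
            remitted &= alive
            changed = progressed | remitted
            self.wasting_state = np.where(alive, new_state, old_state)

            # Substate assignment on entry to moderate (either direction).
            entered_mod = changed & (self.wasting_state == 2)
            split = d.cgf_prevalence.mam_substate_split
            self.substate_low[entered_mod] = u_sub[entered_mod] < split

            # Incident-case tallies.
            new_mild = progressed & (self.wasting_state == 1)
            new_mod = progressed & (self.wasting_state == 2)
            new_sev = progressed & (self.wasting_state == 3)
            self.wasting_incident["mild"] += float(new_mild.sum())
            self.wasting_incident["moderate"] += float(new_mod.sum())
            self.wasting_incident["severe"] += float(new_sev.sum())

            # Treatment episodes end when the state is left.
            self.treated_mam &= self.wasting_state == 2
            self.treated_sam &= self.wasting_state == 3

            # Incident-case treatment initiation (6-59 months).
            in_window = TX_AGE_MIN_DAYS <= age_days < TX_AGE_MAX_DAYS
            if in_window:
                if self.scenario.sam_tx:
                    start = new_sev & (self.u_cov < self.c_sam)
                    self.treated_sam[start] = True
                    self.responder[start] = (
                        u_tx[start] >= d.wasting.nonresponse_fraction
                    )
                    self.counts["sam_tx"] += float(start.sum())
                if self.scenario.mam_tx != "none":
                    eligible = new_mod
                    if self.scenario.mam_tx == "targeted":
                        age_months = age_days / 30.4375
                        crit = (
                            (age_months < 24.0)
                            | self.substate_low
                            | (self.uw_cat == 0)
                        )
                        eligible = eligible & crit
                    start = eligible & (self.u_cov < self.c_mam)
                    self.treated_mam[start] = True
                    self.responder[start] = (
                        u_tx[start] >= d.wasting.nonresponse_fraction
                    )
                    self.counts["mam_tx"] += float(start.sum())

            # Underweight refresh on wasting change.
            if changed.any():
                self._refresh_underweight(cgf_band, changed, u_uw)

        # -- infectious causes ---------------------------------------------
        if cgf_active:
            rr = d.cgf_rrs
            w5 = wasting_rr_index(self.wasting_state, self.substate_low)
            rr_inc = (
                rr.wasting_incidence[w5]
                * rr.stunting_incidence[self.stunting_cat]
                * rr.underweight_incidence[self.uw_cat]
            ) / self.norm_inc[cgf_band, self.sex]
            rr_mort = (
                rr.wasting_mortality[w5]
                * rr.stunting_mortality[self.stunting_cat]
                * rr.underweight_mortality[self.uw_cat]
            ) / self.norm_mort[cgf_band, self.sex]

            for ci, cause in enumerate(CAUSES):
                cp = d.causes[cause]
                infected = self.remaining[:, ci] > 0
                susceptible = alive & ~infected
                if cause == "measles":
                    susceptible &= ~self.measles_immune
                lam = cp.incidence * rr_inc
                p_inc = -np.expm1(-lam * DT_YEARS)
                new_cases = susceptible & (u_inc[:, ci] < p_inc)
                self.remaining[new_cases, ci] = cp.duration_days
                if cause == "measles":
                    self.measles_immune |= new_cases
                infected = alive & (self.remaining[:, ci] > 0)
                if infected.any():
                    self._add_yld(infected, cause, cp.dw * DT_YEARS)
                    # Case fatality as an excess hazard over the episode.
                    dur_y = cp.duration_days / DAYS_PER_YEAR
                    h = -np.log(max(1e-300, 1.0 - cp.cfr)) / dur_y * rr_mort
                    p_die = -np.expm1(-h * DT_YEARS)
                    died = infected & (u_die[:, ci] < p_die)
                    self._record_death(np.flatnonzero(died), cause, age_years)
                    alive = self.alive
                    self.remaining[infected, ci] -= DT_DAYS
                    self.remaining[self.remaining[:, ci] < 0, ci] = 0.0

            # -- protein-energy malnutrition -------------------------------
            wasted = alive & (self.wasting_state >= 2)
            if wasted.any():
                self._add_yld(wasted, "pem", d.pem.dw * DT_YEARS)
            m_pem = d.pem.mortality_by_wasting[w5]
            p_die = -np.expm1(-m_pem * DT_YEARS)
            died = alive & (u_pem < p_die)
            self._record_death(np.flatnonzero(died), "pem", age_years)
            alive = self.alive

        # -- background mortality (LBWSG-modified in the first 28 days) -----
        bg = d.background_mortality[band]
        if bg > 0:
            rate = bg * (self.lbwsg_mult if age_days < CGF_START_DAYS else 1.0)
            p_die = -np.expm1(-rate * DT_YEARS)
            died = alive & (u_bg < p_die)
            self._record_death(np.flatnonzero(died), "lbwsg_background", age_years)

        return band

    def run(self) -> ChildResult:
        age = 0.0
        prev_band = 0
        while age < END_AGE_DAYS:
            band = int(child_age_band(np.array([age]))[0])
            self.step(age, prev_band, band)
            prev_band = band
            age += DT_DAYS
        return self._result()

    def _result(self) -> ChildResult:
        led = BurdenLedger()
        for cause, v in self.yld_by_cause.items():
            led.add_yld("child", cause, v)
        for cause, v in self.yll_by_cause.items():
            led.add_yll("child", cause, v)
        led.add_deaths("child", float(sum(self.deaths_by_cause.values())))
        led.person_time = self.person_time.copy()
        led.person_time_total["child"] = self.person_time_total
        led.wasting_incident_cases = dict(self.wasting_incident)
        from .wasting import STATE_NAMES

        led.wasting_person_time = {
            name: float(self.wasting_person_time[s])
            for s, name in enumerate(STATE_NAMES)
        }
        counts = dict(self.counts)
        counts["screening_contacts"] = self.screening_contacts
        return ChildResult(
            n_live=int(self.live.sum()),
            ledger=led,
            counts=counts,
            dalys_per_child=self.ylds + self.ylls,
            live_mask=self.live.copy(),
        )


def initialize_child_cohort(draw, scenario, sex, ga, bw, live, seed, **kw):
    """Construct (but do not run) a child simulation; see :class:`ChildSimulation`."""
    return ChildSimulation(draw, scenario, sex, ga, bw, live, seed, **kw)


def run_child_sim(draw, scenario, sex, ga, bw, live, seed, **kw) -> ChildResult:
    return ChildSimulation(draw, scenario, sex, ga, bw, live, seed, **kw).run()
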