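"""Child simulation: LBWSG surface, growth-failure exposures, stepping."""

import copy

import numpy as np
import pytest
from scipy import stats

from nutriopt.children import (
    ChildSimulation,
    categorize,
    lbwsg_mortality_multiplier,
    lbwsg_population_mean_rr,
    run_child_sim,
    update_underweight,
    wasting_rr_index,
    _shifted_percentile,
)
from nutriopt.constants import DAYS_PER_YEAR, child_age_band
from nutriopt.interventions import InterventionSet
from nutriopt.wasting import (
    WastingStateDistribution,
    solve_untreated_remission,
    state_excess_mortality,
    treated_remission_rate,
)
import nutriopt.children as C


def _run_partial(sim, end_days):
    age, prev_band = 0.0, 0
    while age < end_days:
        band = int(child_age_band(np.array([age]))[0])
        sim.step(age, prev_band, band)
        prev_band = band
        age += 4.0


class TestLBWSG:
    def test_reference_corner_has_unit_raw_rr(self, draw_hb):
        from nutriopt.children import _bilinear_log_rr

        raw = np.exp(_bilinear_log_rr(
            draw_hb.lbwsg, np.array([40.0]), np.array([3500.0])
        ))
        assert raw[0] == pytest.approx(1.0)

    def test_population_mean_multiplier_is_one(self, draw_hb):
        """Monte Carlo mean of the renormalized multiplier over the GA x BW
        joint distribution is 1 within 0.5% at n = 100,000."""
        j = draw_hb.ga_bw_joint
        rng = np.random.default_rng(17)
        n = 100_000
        ga = j.ga_mean + j.ga_sd * rng.standard_normal(n)
        bw = (
            j.bw_mean + j.corr * j.bw_sd * (ga - j.ga_mean) / j.ga_sd
            + j.bw_sd * np.sqrt(1 - j.corr**2) * rng.standard_normal(n)
        )
        mult = lbwsg_mortality_multiplier(ga, bw, 0.0, draw_hb)
        assert abs(mult.mean() - 1.0) < 0.005

    def test_effect_window_ends_at_28_days(self, draw_hb):
        assert lbwsg_mortality_multiplier(28.0, 600.0, 29.0, draw_hb) == 1.0
        assert lbwsg_mortality_multiplier(28.0, 600.0, 27.0, draw_hb) > 1.0

    def test_out_of_grid_clamps_to_boundary(self, draw_hb):
        mean_rr = lbwsg_population_mean_rr(draw_hb)
        inside = lbwsg_mortality_multiplier(24.0, 500.0, 0.0, draw_hb, mean_rr)
        outside = lbwsg_mortality_multiplier(18.0, 200.0, 0.0, draw_hb, mean_rr)
        assert outside == pytest.approx(inside)


class TestGrowthFailureAssignment:
    def test_null_association_gives_uniform_percentiles(self):
        rng = np.random.default_rng(3)
        pct = _shifted_percentile(rng.standard_normal(10_000), rng.standard_normal(10_000), 0.0)
        assert stats.kstest(pct, stats.uniform.cdf).pvalue > 0.01

    def test_shifted_percentile_remains_marginally_uniform(self):
        rng = np.random.default_rng(4)
        pct = _shifted_percentile(
            rng.standard_normal(20_000), rng.standard_normal(20_000), 0.6
        )
        assert stats.kstest(pct, stats.uniform.cdf).pvalue > 0.01

    def test_low_birthweight_stratum_more_severely_stunted(self, draw_hb, birth_arrays):
        """Under the positive birthweight association, the low-birthweight
        half of the cohort shows a higher severe-stunting share."""
        sex, ga, bw = birth_arrays
        sim = ChildSimulation(
            draw_hb, InterventionSet(), sex, ga, bw, np.ones(len(sex), bool), seed=41
        )
        _run_partial(sim, 32.0)
        low = bw < np.median(bw)
        sev_low = (sim.stunting_cat[low] == 0).mean()
        sev_high = (sim.stunting_cat[~low] == 0).mean()
        assert sev_low > sev_high
        sev_low_w = (sim.wasting_state[low] == 3).mean()
        sev_high_w = (sim.wasting_state[~low] == 3).mean()
        assert sev_low_w > sev_high_w

    def test_category_population_matches_prevalence(self, draw_hb, birth_arrays):
        """Assigned categories at 28 days match the prevalence vectors
        within 3 SE per category (multinomial check)."""
        sex, ga, bw = birth_arrays
        n = len(sex)
        sim = ChildSimulation(
            draw_hb, InterventionSet(), sex, ga, bw, np.ones(n, bool), seed=42
        )
        _run_partial(sim, 32.0)
        for cat in range(4):
            for arrays, prev_col in (
                (sim.stunting_cat, draw_hb.cgf_prevalence.stunting),
                (3 - sim.wasting_state, draw_hb.cgf_prevalence.wasting),
            ):
                for s in (0, 1):
                    mask = sim.sex == s
                    p = prev_col[0, s, cat]
                    frac = (arrays[mask] == cat).mean()
                    se = np.sqrt(p * (1 - p) / mask.sum())
                    assert abs(frac - p) < 3.5 * se

    def test_wasting_stunting_independent(self, draw_hb, birth_arrays):
        sex, ga, bw = birth_arrays
        d = copy.deepcopy(draw_hb)
        d.cgf_prevalence.stunting_bw_beta = 0.0
        d.cgf_prevalence.wasting_bw_beta = 0.0
        n = len(sex)
        sim = ChildSimulation(d, InterventionSet(), sex, ga, bw, np.ones(n, bool), seed=43)
        _run_partial(sim, 32.0)
        r = np.corrcoef(sim.stunting_cat, sim.wasting_state)[0, 1]
        assert abs(r) < 3 / np.sqrt(n)

    def test_determinism(self, draw_hb, birth_arrays):
        sex, ga, bw = birth_arrays
        live = np.ones(len(sex), bool)
        a = run_child_sim(draw_hb, InterventionSet(), sex, ga, bw, live, seed=44)
        b = run_child_sim(draw_hb, InterventionSet(), sex, ga, bw, live, seed=44)
        assert a.ledger.dalys == b.ledger.dalys
        assert np.array_equal(a.dalys_per_child, b.dalys_per_child)


class TestUnderweight:
    def test_degenerate_table_returns_certain_category(self):
        cum = np.zeros((4, 4, 4, 2, 4))
        cum[..., 1:] = 1.0  # all mass on severe-first category 1 (moderate)
        u = np.random.default_rng(5).random(100)
        out = update_underweight(
            u, np.zeros(100, int), np.zeros(100, int),
            np.zeros(100, int), np.zeros(100, int), cum,
        )
        assert (out == 1).all()

    def test_marginal_matches_law_of_total_probability(self, draw_hb):
        """Sampling the conditional table at the population wasting/stunting
        mix reproduces the implied marginal within 3 SE at n = 50,000."""
        p = draw_hb.cgf_prevalence
        rng = np.random.default_rng(6)
        n = 50_000
        w4 = rng.choice(4, size=n, p=p.wasting[0, 0])
        s4 = rng.choice(4, size=n, p=p.stunting[0, 0])
        cum = np.cumsum(p.underweight_conditional, axis=-1)
        out = update_underweight(
            rng.random(n), w4, s4, np.zeros(n, int), np.zeros(n, int), cum
        )
        implied = p.underweight[0, 0]
        for cat in range(4):
            frac = (out == cat).mean()
            se = np.sqrt(implied[cat] * (1 - implied[cat]) / n)
            assert abs(frac - implied[cat]) < 3.5 * se

    def test_positive_dependence_encoded_in_fixture_table(self, draw_hb):
        cond = draw_hb.cgf_prevalence.underweight_conditional
        worst = cond[0, 0, 0, 0, 0]  # severe wasting+stunting -> severe underweight
        best = cond[3, 3, 0, 0, 0]
        assert worst > best


class TestStepping:
    def test_toy_draw_only_ages(self, draw_toy, birth_arrays):
        """With all rates zero only aging occurs: person-time accrues
        4/365.25 years per child per step and nobody dies."""
        sex, ga, bw = birth_arrays
        n = 500
        res = run_child_sim(
            draw_toy, InterventionSet(), sex[:n], ga[:n], bw[:n],
            np.ones(n, bool), seed=51,
        )
        assert res.ledger.deaths["child"] == 0
        steps = int(np.ceil(C.END_AGE_DAYS / 4.0))
        assert res.ledger.person_time_total["child"] == pytest.approx(
            n * steps * 4.0 / DAYS_PER_YEAR
        )

    def test_incidence_probability_formula(self):
        """Diarrheal incidence 2/yr under a combined RR of 3 gives a 4-day
        incidence probability 1 - exp(-6 x 4/365.25) ~ 0.0636."""
        p = -np.expm1(-2.0 * 3.0 * 4.0 / DAYS_PER_YEAR)
        assert p == pytest.approx(0.0636, abs=2e-4)

    def test_death_yll_equals_tmrle_at_age(self, draw_hb, birth_arrays):
        """Any child death accrues YLLs equal to the reference remaining
        life expectancy at the age of death."""
        sex, ga, bw = birth_arrays
        n = 2_000
        sim = ChildSimulation(
            draw_hb, InterventionSet(), sex[:n], ga[:n], bw[:n],
            np.ones(n, bool), seed=52,
        )
        res = sim.run()
        dead = ~sim.alive & sim.live
        ylls = sim.ylls[dead]
        lo = np.interp(5.0, draw_hb.tmrle_ages, draw_hb.tmrle_values)
        hi = np.interp(0.0, draw_hb.tmrle_ages, draw_hb.tmrle_values)
        assert ((ylls >= lo) & (ylls <= hi)).all()
        assert res.ledger.total_ylls == pytest.approx(ylls.sum())

    def test_death_count_identity(self, draw_hb, birth_arrays):
        """All-cause child deaths equal the sum over modeled causes plus
        background (exact count identity)."""
        sex, ga, bw = birth_arrays
        n = 5_000
        sim = ChildSimulation(
            draw_hb, InterventionSet(), sex[:n], ga[:n], bw[:n],
            np.ones(n, bool), seed=53,
        )
        res = sim.run()
        assert res.ledger.deaths["child"] == sum(sim.deaths_by_cause.values())
        assert res.ledger.deaths["child"] == (~sim.alive & sim.live).sum()

    def test_daly_identity_every_stratum(self, draw_hb, birth_arrays):
        sex, ga, bw = birth_arrays
        n = 3_000
        res = run_child_sim(
            draw_hb, InterventionSet(), sex[:n], ga[:n], bw[:n],
            np.ones(n, bool), seed=54,
        )
        led = res.ledger
        assert led.dalys == pytest.approx(led.total_ylls + led.total_ylds)
        assert led.total_ylds == pytest.approx(sum(led.ylds.values()))

    def test_person_time_stratification_sums_to_alive_time(self, draw_hb, birth_arrays):
        """Person-time by stunting state x age band equals total alive
        person-time in the growth-failure bands exactly."""
        sex, ga, bw = birth_arrays
        n = 3_000
        sim = ChildSimulation(
            draw_hb, InterventionSet(), sex[:n], ga[:n], bw[:n],
            np.ones(n, bool), seed=55,
        )
        # Independent accumulator of alive time at ages >= 28 d.
        age, prev_band, alive_time = 0.0, 0, 0.0
        while age < C.END_AGE_DAYS:
            band = int(child_age_band(np.array([age]))[0])
            if age >= 28.0:
                alive_time += sim.alive.sum() * 4.0 / DAYS_PER_YEAR
            sim.step(age, prev_band, band)
            prev_band = band
            age += 4.0
        assert sim.person_time.sum() == pytest.approx(alive_time, rel=1e-12)

    def test_wasting_prevalence_stationary_when_selfconsistent(self, draw_hb, birth_arrays):
        """With no interventions and rates calibrated at zero treatment
        coverage, 6-59 m wasting prevalence holds the calibration target
        within 1% absolute over the run."""
        sex, ga, bw = birth_arrays
        d = draw_hb
        dist = WastingStateDistribution.from_severe_first(
            d.cgf_prevalence.wasting[2, 0], d.cgf_prevalence.mam_substate_split
        )
        rates0 = solve_untreated_remission(
            dist, (d.wasting.i1, d.wasting.i2, d.wasting.i3),
            state_excess_mortality(d),
            (treated_remission_rate(d.wasting.treated_recovery_days_mam),
             treated_remission_rate(d.wasting.treated_recovery_days_sam)),
            (0.0, 0.0), d.wasting.nonresponse_fraction, step_days=4.0,
        )
        sim = ChildSimulation(
            d, InterventionSet(), sex, ga, bw, np.ones(len(sex), bool),
            seed=56, rates=rates0,
        )
        age, prev_band = 0.0, 0
        occ = np.zeros(4)
        while age < C.END_AGE_DAYS:
            band = int(child_age_band(np.array([age]))[0])
            sim.step(age, prev_band, band)
            prev_band = band
            age += 4.0
            if age >= 182.625:
                occ += np.bincount(sim.wasting_state[sim.alive], minlength=4)
        prev = occ / occ.sum()
        assert np.abs(prev - dist.proportions).max() < 0.01

    def test_substate_occupancy_matches_split_in_steady_state(self, draw_hb, birth_arrays):
        """Within moderate wasting the lower-WHZ substate share equals the
        configured split, since rates are substate-invariant."""
        sex, ga, bw = birth_arrays
        sim = ChildSimulation(
            draw_hb, InterventionSet(), sex, ga, bw, np.ones(len(sex), bool), seed=57
        )
        age, prev_band = 0.0, 0
        low, tot = 0.0, 0.0
        while age < 730.0:
            band = int(child_age_band(np.array([age]))[0])
            sim.step(age, prev_band, band)
            prev_band = band
            age += 4.0
            mod = sim.alive & (sim.wasting_state == 2)
            low += (mod & sim.substate_low).sum()
            tot += mod.sum()
        split = draw_hb.cgf_prevalence.mam_substate_split
        assert low / tot == pytest.approx(split, abs=0.03)

    def test_wasting_rr_index_mapping(self):
        states = np.array([0, 1, 2, 2, 3])
        sub = np.array([False, False, True, False, False])
        assert np.array_equal(wasting_rr_index(states, sub), [4, 3, 1, 2, 0])
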