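"""Synthetic parameter fixtures emulating GBD-2021-like structure.

The generator produces a fully populated, internally consistent
:class:`~nutriopt.params.model.ParameterDraw` for a hypothetical country-year
without consuming any external data: age/sex-stratified rates, categorical
exposure prevalences summing to one, a gestational-age x birthweight joint
distribution, and an underweight category table conditional on wasting and
stunting whose implied marginal *is* the stored underweight prevalence (the
two are consistent by construction).

Profiles
--------
``high-burden``
    Default desk-scale setting: prevalences, rates and costs in the range a
    high-burden sub-Saharan setting would show.  Continuous parameters are
    jittered per seed so distinct seeds give distinct but valid fixtures.
``low-burden``
    Same structure with roughly halved burden.
``toy``
    Closed-form-checkable values: uniform exposure vectors (0.25 each),
    round transition rates, zero jitter.  Used by the oracle tests.
"""

from __future__ import annotations

import numpy as np

from ..constants import CAUSES, CGF_AGE_BANDS, CHILD_AGE_BANDS, SEXES
from .model import (
    CauseParams,
    CGFPrevalence,
    CGFRelativeRisks,
    CostModel,
    CoverageSpec,
    Demography,
    EffectsTable,
    GABWJoint,
    HemoglobinModel,
    LBWSGGrid,
    MaternalRisks,
    ParameterDraw,
    PEMParams,
    Uncertain,
    WastingModelParams,
    validate_parameters,
)

PROFILES = ("high-burden", "low-burden", "toy")

# Severity scores used to build the underweight-given-(wasting, stunting)
# ordinal table: probit shift per wasting / stunting category (severe-first).
_WASTING_SCORE = np.array([1.6, 0.9, 0.35, -0.15])
_STUNTING_SCORE = np.array([1.1, 0.6, 0.2, -0.25])


def _underweight_conditional(
    base_marginal: np.ndarray, a_w: float, a_s: float
) -> np.ndarray:
    """Ordinal-probit conditional table P(underweight | wasting, stunting).

    ``base_marginal`` is a severe-first 4-vector giving the underweight
    distribution of an unexposed reference child; positive loadings shift
    mass toward severe underweight for worse wasting/stunting.
    """
    from scipy.stats import norm

    cum = np.cumsum(base_marginal)[:-1]
    cuts = norm.ppf(cum)  # thresholds on a latent N(0,1), severe side low? no:
    # severe-first cumulative: P(severe) = Phi(cuts[0] - shift) with positive
    # shift for worse exposure moving mass into severe.
    table = np.zeros((4, 4, 4))
    for w in range(4):
        for s in range(4):
            shift = a_w * _WASTING_SCORE[w] + a_s * _STUNTING_SCORE[s]
            cdf = norm.cdf(cuts + shift)
            probs = np.diff(np.concatenate(([0.0], cdf, [1.0])))
            table[w, s] = probs
    return table


def _band_sex_grid(values_by_band: np.ndarray) -> np.ndarray:
    """Tile severe-first 4-vectors per band into a (band, sex, 4) array."""
    return np.repeat(values_by_band[:, None, :], len(SEXES), axis=1)


def _tmrle_table() -> tuple[np.ndarray, np.ndarray]:
    # Reference remaining life expectancy (years) at selected ages, patterned
    # after a theoretical-minimum-risk life table.
    ages = np.array([0, 1, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60], float)
    values = np.array(
        [88.9, 88.0, 84.0, 79.1, 74.1, 69.1, 64.2, 59.3, 54.4, 49.5, 44.7, 39.9, 35.2, 30.6]
    )
    return ages, values


def _effects_table() -> EffectsTable:
    # Antenatal effect rows are each relative to the previous product.
    return EffectsTable(
        ifa_hb_md=Uncertain(7.8, 4.08, 11.52, "normal"),
        ifa_bw_md=Uncertain(57.73, 7.66, 107.79, "normal"),
        ifa_preterm_rr=Uncertain(0.90, 0.86, 0.95, "lognormal"),
        mmn_stillbirth_rr=Uncertain(0.91, 0.71, 0.93, "lognormal"),
        mmn_bw_md=Uncertain(45.16, 32.31, 58.02, "normal"),
        mmn_preterm_rr=Uncertain(0.91, 0.84, 0.99, "lognormal"),
        mmn_vpreterm_rr=Uncertain(0.81, 0.71, 0.93, "lognormal"),
        bep_stillbirth_rr=Uncertain(0.39, 0.19, 0.80, "lognormal"),
        bep_bw_md=Uncertain(66.96, 13.13, 120.78, "normal"),
        sqlns_severe_stunting_pr=Uncertain(0.83, 0.74, 0.93, "lognormal"),
        sqlns_moderate_stunting_pr=Uncertain(0.89, 0.83, 0.95, "lognormal"),
        sqlns_severe_wasting_pr=Uncertain(0.69, 0.53, 0.89, "lognormal"),
    )


def _coverage_and_costs() -> tuple[CoverageSpec, CostModel]:
    coverage = CoverageSpec(
        baseline={
            "ifa": Uncertain(0.602, 0.487, 0.726, "normal"),
            "mmn": Uncertain(0.0),
            "bep": Uncertain(0.0),
            "sam_tx": Uncertain(0.488, 0.374, 0.604, "normal"),
            "mam_tx": Uncertain(0.15, 0.10, 0.20, "normal"),
            "sqlns": Uncertain(0.0),
        },
        saturation={
            "ifa": 0.757, "mmn": 0.757, "bep": 0.757,
            "sam_tx": 0.70, "mam_tx": 0.70, "sqlns": 0.70,
            "screening": 0.70,
        },
    )
    costs = CostModel(
        product_cost={
            "ifa": 2.27, "mmn": 3.47, "bep": 40.28,
            "sam_tx": 41.84, "mam_tx": 29.70, "sqlns": 35.75,
            "screening": 0.0,
        },
        nonproduct_components={
            "program": 0.15, "logistics_waste": 0.05, "inefficiency": 0.17,
        },
    )
    return coverage, costs


def generate_synthetic_fixture(seed: int, profile: str = "high-burden") -> ParameterDraw:
    """Deterministically generate a valid :class:`ParameterDraw`.

    Parameters
    ----------
    seed
        Controls the per-fixture jitter of continuous parameters for the
        ``high-burden``/``low-burden`` profiles (the ``toy`` profile is
        seed-invariant by design).
    profile
        One of ``{"high-burden", "low-burden", "toy"}``.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {PROFILES}")
    rng = np.random.default_rng(seed)
    toy = profile == "toy"
    low = profile == "low-burden"
    scale = 0.5 if low else 1.0

    def jitter(x, rel=0.03):
        return x if toy else float(x * (1.0 + rel * rng.standard_normal()))

    age_shares = np.array([0.01, 0.16, 0.27, 0.24, 0.17, 0.10, 0.04, 0.008, 0.002])
    if not toy:
        age_shares = age_shares * np.exp(0.05 * rng.standard_normal(9))
    age_shares /= age_shares.sum()

    p_still = jitter(0.02 * scale, 0.05)
    p_abort = jitter(0.10, 0.05)
    demography = Demography(
        maternal_age_shares=age_shares,
        birth_outcome_probs=np.array([1.0 - p_still - p_abort, p_still, p_abort]),
        infant_sex_ratio=0.512,
    )

    ga_bw = GABWJoint(
        ga_mean=jitter(38.7, 0.005), ga_sd=jitter(2.0, 0.03),
        bw_mean=jitter(3100.0, 0.01), bw_sd=jitter(460.0, 0.03),
        corr=0.45,
    )

    hemoglobin = HemoglobinModel(
        hb_mean=jitter(121.0 + 6.0 * scale * 0, 0.02) if toy else float(
            rng.normal(121.0 + (6.0 if low else 0.0), 2.0)
        ),
        hb_sd=jitter(14.0),
        low_bmi_prevalence=jitter(0.22 * scale, 0.05),
        hb_bmi_rank_corr=0.2,
        anemia_thresholds=np.array([70.0, 100.0, 110.0]),
        anemia_dws=np.array([0.149, 0.052, 0.004]),
        reference_hb=120.0,
    )

    maternal = MaternalRisks(
        disorder_risk=jitter(0.15 * scale, 0.05),
        disorder_cfr=jitter(0.025 * scale, 0.05),
        disorder_yld=jitter(0.05, 0.05),
        pph_risk=jitter(0.05 * scale, 0.05),
        hb_rr_per_10g=1.25,
        pph_hb_decrement=15.0,
        bw_anemia_decrement=50.0,
        bw_low_bmi_decrement=120.0,
    )

    if toy:
        wast_prev = np.tile(np.array([0.25, 0.25, 0.25, 0.25]), (4, 1))
        stunt_prev = np.tile(np.array([0.25, 0.25, 0.25, 0.25]), (4, 1))
    else:
        # Severe-first (severe, moderate, mild, unaffected).  Wasting
        # prevalence is age-invariant because the transition rates are
        # age-invariant within 6-59 months and the steady-state calibration
        # needs a single stationary target; stunting rises with age as
        # deficits accumulate.
        base_w = np.array([0.015, 0.040, 0.120, 0.825]) * np.array([scale, scale, 1, 1])
        base_w[3] = 1 - base_w[:3].sum()
        base_s = np.array([0.14, 0.22, 0.28, 0.36]) * np.array([scale, scale, 1, 1])
        band_mult = np.array([0.7, 0.9, 1.1, 1.0])
        wast_prev = np.tile(base_w, (4, 1))
        stunt_prev = np.stack([
            np.concatenate((base_s[:3] * m, [1 - (base_s[:3] * m).sum()]))
            for m in band_mult
        ])

    base_uw_ref = np.array([0.02, 0.08, 0.22, 0.68])
    cond = _underweight_conditional(base_uw_ref, a_w=0.0 if toy else 0.6,
                                    a_s=0.0 if toy else 0.4)
    # (wasting, stunting, cat) -> tile over bands/sexes, then derive the
    # marginal underweight prevalence by the law of total probability.
    cond_full = np.zeros((4, 4, len(CGF_AGE_BANDS), len(SEXES), 4))
    uw_prev = np.zeros((len(CGF_AGE_BANDS), len(SEXES), 4))
    for b in range(len(CGF_AGE_BANDS)):
        for s in range(len(SEXES)):
            cond_full[:, :, b, s, :] = cond
            joint = np.einsum("w,s,wsk->k", wast_prev[b], stunt_prev[b], cond)
            uw_prev[b, s] = joint / joint.sum()

    cgf = CGFPrevalence(
        wasting=_band_sex_grid(wast_prev),
        stunting=_band_sex_grid(stunt_prev),
        underweight=uw_prev,
        mam_substate_split=0.4,
        underweight_conditional=cond_full,
        stunting_bw_beta=0.0 if toy else 0.35,
        wasting_bw_beta=0.0 if toy else 0.30,
    )

    if toy:
        wasting = WastingModelParams(
            i1=2.0, i2=1.0, i3=0.5,
            treated_recovery_days_mam=40.0, treated_recovery_days_sam=50.0,
            nonresponse_fraction=0.0,
        )
    else:
        # Forward rates chosen for realistic episode dynamics: children cycle
        # into mild wasting roughly yearly and mild/moderate episodes last
        # weeks; i3 is high enough that observed severe prevalence remains
        # consistent with baseline SAM treatment coverage in calibration.
        wasting = WastingModelParams(
            i1=jitter(1.2), i2=jitter(0.95), i3=jitter(1.5),
            treated_recovery_days_mam=jitter(40.0),
            treated_recovery_days_sam=jitter(50.0),
            nonresponse_fraction=0.15,
        )

    # Episode rates and case fatality chosen so all-cause under-5 mortality
    # lands near 75-80 per 1000 live births (high-burden archetype), with
    # roughly a third of deaths from the four modeled infectious causes.
    causes = {
        "diarrheal_diseases": CauseParams(jitter(2.0 * scale), 7.0, 0.188, jitter(0.0008 * scale)),
        "lri": CauseParams(jitter(0.5 * scale), 10.0, 0.133, jitter(0.004 * scale)),
        "malaria": CauseParams(jitter(0.3 * scale), 14.0, 0.21, jitter(0.004 * scale)),
        "measles": CauseParams(jitter(0.05 * scale), 10.0, 0.23, jitter(0.012 * scale)),
    }
    if toy:
        causes = {c: CauseParams(0.0, 7.0, 0.1, 0.0) for c in CAUSES}

    ones5, ones4 = np.ones(5), np.ones(4)
    cgf_rrs = CGFRelativeRisks(
        wasting_incidence=ones5 if toy else np.array([3.0, 2.1, 1.8, 1.3, 1.0]),
        wasting_mortality=ones5 if toy else np.array([4.0, 2.5, 2.0, 1.4, 1.0]),
        stunting_incidence=ones4 if toy else np.array([1.5, 1.3, 1.1, 1.0]),
        stunting_mortality=ones4 if toy else np.array([2.0, 1.5, 1.2, 1.0]),
        underweight_incidence=ones4 if toy else np.array([1.6, 1.3, 1.1, 1.0]),
        underweight_mortality=ones4 if toy else np.array([2.2, 1.6, 1.2, 1.0]),
    )

    pem = PEMParams(
        dw=0.051,
        mortality_by_wasting=np.zeros(5) if toy else np.array(
            [0.08, 0.030, 0.015, 0.0, 0.0]
        ),
    )

    ga_grid = np.array([24.0, 28.0, 32.0, 34.0, 36.0, 38.0, 40.0, 42.0])
    bw_grid = np.array([500.0, 1000.0, 1500.0, 2000.0, 2500.0, 3000.0, 3500.0, 4500.0])
    # Log-RR surface decreasing in both axes, 0 at the (40 wk, 3500 g) corner.
    log_rr = (
        0.30 * np.maximum(0.0, 40.0 - ga_grid)[:, None]
        + 1.1e-3 * np.maximum(0.0, 3500.0 - bw_grid)[None, :]
    )
    if toy:
        log_rr = np.zeros_like(log_rr)
    lbwsg = LBWSGGrid(ga_grid=ga_grid, bw_grid=bw_grid, log_rr=log_rr)

    # All-other-cause mortality per person-year by band; neonatal bands carry
    # most of it (prematurity complications via the LBWSG multiplier).
    background = np.zeros(len(CHILD_AGE_BANDS)) if toy else scale * np.array(
        [0.80, 0.25, 0.012, 0.008, 0.004, 0.0015]
    )

    tmrle_ages, tmrle_values = _tmrle_table()
    coverage, costs = _coverage_and_costs()

    draw = ParameterDraw(
        demography=demography,
        ga_bw_joint=ga_bw,
        hemoglobin=hemoglobin,
        maternal_risks=maternal,
        cgf_prevalence=cgf,
        wasting=wasting,
        causes=causes,
        cgf_rrs=cgf_rrs,
        pem=pem,
        lbwsg=lbwsg,
        background_mortality=background,
        tmrle_ages=tmrle_ages,
        tmrle_values=tmrle_values,
        effects=_effects_table(),
        coverage=coverage,
        costs=costs,
        label=f"{profile}-seed{seed}",
    )
    problems = validate_parameters(draw)
    if problems:  # pragma: no cover - generator contract
        raise AssertionError(f"fixture generator produced invalid draw: {problems}")
    return draw
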