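"""Parameter data model for one country-year.

A :class:`ParameterDraw` carries everything one Monte Carlo draw of the
simulation needs: demographic shares, exposure distributions, cause rates,
risk effects, intervention effect sizes, coverage bounds, and unit costs.
Uncertain quantities are held as :class:`Uncertain` values (a point estimate
plus an optional 95% interval) so that draw generation can resample them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, is_dataclass
from typing import Optional

import numpy as np

from ..constants import (
    CAUSES,
    CGF_AGE_BANDS,
    CHILD_AGE_BANDS,
    MATERNAL_AGE_BANDS,
    PRODUCTS,
    SEXES,
)

SCHEMA_VERSION = 1

_PROB_TOL = 1e-9


@dataclass
class Uncertain:
    """A scalar parameter with an optional 95% uncertainty interval.

    ``dist`` selects the resampling family: ``"normal"`` for mean
    differences, ``"lognormal"`` for relative risks (normal on the log
    scale).  Asymmetric intervals are handled by a split-normal quantile
    rule with separate spreads below and above the point estimate, so the
    2.5th/97.5th percentiles of the sampling distribution reproduce the
    printed bounds exactly and the median equals the point estimate.
    """

    value: float
    lo: Optional[float] = None
    hi: Optional[float] = None
    dist: str = "normal"

    def has_interval(self) -> bool:
        return self.lo is not None and self.hi is not None

    def _spreads(self) -> tuple[float, float, float]:
        if self.dist == "lognormal":
            v, lo, hi = np.log(self.value), np.log(self.lo), np.log(self.hi)
        else:
            v, lo, hi = self.value, self.lo, self.hi
        return v, (v - lo) / 1.959963984540054, (hi - v) / 1.959963984540054

    def sample(self, rng: np.random.Generator) -> float:
        """One split-normal sample; returns the point value if no interval."""
        if not self.has_interval():
            return self.value
        if self.lo > self.hi:
            raise ValueError(
                f"inverted interval ({self.lo}, {self.hi}) for value {self.value}"
            )
        v, sd_lo, sd_hi = self._spreads()
        u = rng.standard_normal()
        x = v + u * (sd_lo if u < 0 else sd_hi)
        return float(np.exp(x)) if self.dist == "lognormal" else float(x)

    def analytic_mean(self) -> float:
        """Mean of the sampling distribution on its sampling scale.

        For the split-normal quantile rule the mean on the (possibly log)
        sampling scale is ``m + (sd_hi - sd_lo) / sqrt(2*pi)``.
        """
        if not self.has_interval():
            return self.value
        v, sd_lo, sd_hi = self._spreads()
        return v + (sd_hi - sd_lo) / np.sqrt(2.0 * np.pi)

    def ppf(self, q: float) -> float:
        """Quantile of the sampling distribution (natural scale)."""
        from scipy.stats import norm

        v, sd_lo, sd_hi = self._spreads()
        z = norm.ppf(q)
        x = v + z * (sd_lo if z < 0 else sd_hi)
        return float(np.exp(x)) if self.dist == "lognormal" else float(x)


@dataclass
class Demography:
    maternal_age_shares: np.ndarray  # (9,) over 5-year bands, 10-54 y
    birth_outcome_probs: np.ndarray  # (3,) live, stillbirth, abortion/miscarriage
    infant_sex_ratio: float  # P(male | live birth)


@dataclass
class GABWJoint:
    """Bivariate-normal joint distribution of gestational age and birthweight."""

    ga_mean: float  # weeks
    ga_sd: float
    bw_mean: float  # grams
    bw_sd: float
    corr: float


@dataclass
class HemoglobinModel:
    hb_mean: float  # g/L, antenatal
    hb_sd: float
    low_bmi_prevalence: float  # P(pre-pregnancy BMI < 18.5)
    hb_bmi_rank_corr: float  # Spearman corr between hemoglobin and latent BMI
    anemia_thresholds: np.ndarray  # (3,) severe/moderate/mild cut points, increasing
    anemia_dws: np.ndarray  # (3,) disability weights: severe, moderate, mild
    reference_hb: float = 120.0  # g/L; anchor of the hemoglobin risk gradient


@dataclass
class MaternalRisks:
    disorder_risk: float  # per-birth probability of pregnancy-related disorder
    disorder_cfr: float  # case fatality proportion
    disorder_yld: float  # YLDs per nonfatal case
    pph_risk: float  # per-birth probability of postpartum hemorrhage
    hb_rr_per_10g: float  # RR multiplier per 10 g/L hemoglobin below reference
    pph_hb_decrement: float  # g/L drop after PPH
    bw_anemia_decrement: float  # grams, birthweight shift if anemic at birth
    bw_low_bmi_decrement: float  # grams, birthweight shift for low-BMI pregnancies


@dataclass
class CGFPrevalence:
    """Four-category prevalence (severe-first) by growth-failure band x sex."""

    wasting: np.ndarray  # (4 bands, 2 sexes, 4 cats)
    stunting: np.ndarray
    underweight: np.ndarray
    mam_substate_split: float  # share of moderate wasting with WHZ in [-3, -2.5)
    # P(underweight cat | wasting cat, stunting cat, band, sex):
    underweight_conditional: np.ndarray  # (4, 4, 4 bands, 2 sexes, 4 cats)
    stunting_bw_beta: float  # birthweight -> stunting percentile association (probit)
    wasting_bw_beta: float  # birthweight -> wasting state at 28 d association


@dataclass
class WastingModelParams:
    i1: float  # unaffected -> mild, per person-year
    i2: float  # mild -> moderate
    i3: float  # moderate -> severe
    treated_recovery_days_mam: float
    treated_recovery_days_sam: float
    nonresponse_fraction: float


@dataclass
class CauseParams:
    incidence: float  # per person-year, ages 28 d - 5 y, population average
    duration_days: float  # mean episode duration
    dw: float  # disability weight during an episode
    cfr: float  # case fatality proportion per episode


@dataclass
class CGFRelativeRisks:
    """Incidence/mortality relative risks per exposure category (severe-first).

    Wasting vectors have 5 entries (severe, the two moderate WHZ substates,
    mild, unaffected); stunting and underweight have 4.  The fixture supplies
    RRs already de-overlapped across the three indices; effects combine
    multiplicatively and are renormalized so the population-average combined
    RR is 1 within each age band.
    """

    wasting_incidence: np.ndarray  # (5,)
    wasting_mortality: np.ndarray  # (5,)
    stunting_incidence: np.ndarray  # (4,)
    stunting_mortality: np.ndarray  # (4,)
    underweight_incidence: np.ndarray  # (4,)
    underweight_mortality: np.ndarray  # (4,)


@dataclass
class PEMParams:
    dw: float  # disability weight while moderately/severely wasted
    # excess mortality per person-year by wasting substate (severe-first, 5):
    mortality_by_wasting: np.ndarray


@dataclass
class LBWSGGrid:
    """Relative-risk surface over (gestational age, birthweight) cells.

    Applied to neonatal (age < 28 d) mortality after renormalization so the
    population-average multiplier under the gestational-age/birthweight joint
    distribution equals 1.
    """

    ga_grid: np.ndarray  # (g,) weeks, increasing
    bw_grid: np.ndarray  # (b,) grams, increasing
    log_rr: np.ndarray  # (g, b)


@dataclass
class EffectsTable:
    """Antenatal effect set plus SQ-LNS calibration targets.

    Antenatal rows are each *relative to the previous product* (IFA vs no
    supplementation, MMN vs IFA, BEP vs MMN) and compose cumulatively.
    """

    ifa_hb_md: Uncertain  # g/L
    ifa_bw_md: Uncertain  # grams
    ifa_preterm_rr: Uncertain  # <37 wk
    mmn_stillbirth_rr: Uncertain
    mmn_bw_md: Uncertain
    mmn_preterm_rr: Uncertain
    mmn_vpreterm_rr: Uncertain  # <32 wk
    bep_stillbirth_rr: Uncertain
    bep_bw_md: Uncertain
    sqlns_severe_stunting_pr: Uncertain  # prevalence ratio
    sqlns_moderate_stunting_pr: Uncertain
    sqlns_severe_wasting_pr: Uncertain  # calibration target for hazard ratios


@dataclass
class CoverageSpec:
    baseline: dict  # product -> Uncertain (proportion)
    saturation: dict  # product -> float


@dataclass
class CostModel:
    """Product costs plus an additive non-product multiplier.

    ``final = product_cost * (1 + sum(nonproduct_components.values()))``.
    """

    product_cost: dict  # product -> USD per unit (pregnancy / treated child / course)
    nonproduct_components: dict  # e.g. program, logistics_waste, inefficiency

    @property
    def multiplier(self) -> float:
        return 1.0 + sum(self.nonproduct_components.values())

    def final_unit_cost(self, product: str, *, rounded: bool = True) -> float:
        cost = self.product_cost[product] * self.multiplier
        return round(cost, 2) if rounded else cost


@dataclass
class ParameterDraw:
    """One full parameter set for a single Monte Carlo draw."""

    demography: Demography
    ga_bw_joint: GABWJoint
    hemoglobin: HemoglobinModel
    maternal_risks: MaternalRisks
    cgf_prevalence: CGFPrevalence
    wasting: WastingModelParams
    causes: dict  # cause name -> CauseParams
    cgf_rrs: CGFRelativeRisks
    pem: PEMParams
    lbwsg: LBWSGGrid
    background_mortality: np.ndarray  # (6,) per person-year by child age band
    tmrle_ages: np.ndarray  # (k,) years, increasing
    tmrle_values: np.ndarray  # (k,) remaining life expectancy, non-increasing
    effects: EffectsTable
    coverage: CoverageSpec
    costs: CostModel
    schema_version: int = SCHEMA_VERSION
    label: str = ""


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _check_prob(report, name, x):
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(arr < -_PROB_TOL) or np.any(arr > 1 + _PROB_TOL):
        report.append(f"{name}: probability outside [0, 1]")


def _check_simplex(report, name, x):
    arr = np.asarray(x, dtype=float)
    sums = arr.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-9):
        report.append(f"{name}: categorical prevalence does not sum to 1")
    if np.any(arr < -_PROB_TOL):
        report.append(f"{name}: negative prevalence entry")


def _check_nonneg(report, name, x):
    if np.any(np.asarray(x, dtype=float) < 0):
        report.append(f"{name}: negative value")


def validate_parameters(draw: ParameterDraw) -> list[str]:
    """Return the list of violated invariants; empty iff the draw is valid.

    Raises ``ValueError`` naming the field if a required field is missing
    (``None``).
    """
    for f in fields(draw):
        if getattr(draw, f.name) is None:
            raise ValueError(f"missing parameter field: {f.name}")

    report: list[str] = []
    d = draw.demography
    _check_simplex(report, "demography.maternal_age_shares", d.maternal_age_shares)
    _check_simplex(report, "demography.birth_outcome_probs", d.birth_outcome_probs)
    _check_prob(report, "demography.infant_sex_ratio", d.infant_sex_ratio)
    if len(d.maternal_age_shares) != len(MATERNAL_AGE_BANDS):
        report.append("demography.maternal_age_shares: wrong length")

    j = draw.ga_bw_joint
    if j.ga_sd <= 0 or j.bw_sd <= 0:
        report.append("ga_bw_joint: SDs must be positive")
    if not abs(j.corr) < 1:
        report.append("ga_bw_joint: |correlation| must be < 1")

    h = draw.hemoglobin
    if h.hb_mean <= 0 or h.hb_sd <= 0:
        report.append("hemoglobin: mean and SD must be positive")
    _check_prob(report, "hemoglobin.low_bmi_prevalence", h.low_bmi_prevalence)
    thr = np.asarray(h.anemia_thresholds, dtype=float)
    if not np.all(np.diff(thr) > 0):
        report.append("hemoglobin.anemia_thresholds: not strictly increasing")
    _check_prob(report, "hemoglobin.anemia_dws", h.anemia_dws)
    if not (-1 < h.hb_bmi_rank_corr < 1):
        report.append("hemoglobin.hb_bmi_rank_corr: outside (-1, 1)")

    m = draw.maternal_risks
    for name in ("disorder_risk", "disorder_cfr", "pph_risk"):
        _check_prob(report, f"maternal_risks.{name}", getattr(m, name))
    _check_nonneg(report, "maternal_risks.disorder_yld", m.disorder_yld)
    _check_nonneg(report, "maternal_risks.pph_hb_decrement", m.pph_hb_decrement)
    if m.hb_rr_per_10g <= 0:
        report.append("maternal_risks.hb_rr_per_10g: must be positive")

    p = draw.cgf_prevalence
    for name in ("wasting", "stunting", "underweight"):
        arr = getattr(p, name)
        if arr.shape != (len(CGF_AGE_BANDS), len(SEXES), 4):
            report.append(f"cgf_prevalence.{name}: wrong shape {arr.shape}")
        else:
            _check_simplex(report, f"cgf_prevalence.{name}", arr)
    _check_prob(report, "cgf_prevalence.mam_substate_split", p.mam_substate_split)
    if p.underweight_conditional.shape != (4, 4, len(CGF_AGE_BANDS), len(SEXES), 4):
        report.append("cgf_prevalence.underweight_conditional: wrong shape")
    else:
        _check_simplex(
            report, "cgf_prevalence.underweight_conditional", p.underweight_conditional
        )

    w = draw.wasting
    _check_nonneg(report, "wasting.rates", [w.i1, w.i2, w.i3])
    if w.treated_recovery_days_mam <= 0 or w.treated_recovery_days_sam <= 0:
        report.append("wasting.treated_recovery_days: must be positive")
    _check_prob(report, "wasting.nonresponse_fraction", w.nonresponse_fraction)

    for cause in CAUSES:
        if cause not in draw.causes:
            report.append(f"causes: missing {cause}")
            continue
        c = draw.causes[cause]
        _check_nonneg(report, f"causes.{cause}.incidence", c.incidence)
        if c.duration_days <= 0:
            report.append(f"causes.{cause}.duration_days: must be positive")
        _check_prob(report, f"causes.{cause}.dw", c.dw)
        _check_prob(report, f"causes.{cause}.cfr", c.cfr)

    r = draw.cgf_rrs
    for name in (
        "wasting_incidence", "wasting_mortality", "stunting_incidence",
        "stunting_mortality", "underweight_incidence", "underweight_mortality",
    ):
        if np.any(np.asarray(getattr(r, name)) <= 0):
            report.append(f"cgf_rrs.{name}: relative risks must be positive")

    _check_prob(report, "pem.dw", draw.pem.dw)
    _check_nonneg(report, "pem.mortality_by_wasting", draw.pem.mortality_by_wasting)

    g = draw.lbwsg
    if not (np.all(np.diff(g.ga_grid) > 0) and np.all(np.diff(g.bw_grid) > 0)):
        report.append("lbwsg: grid axes must be increasing")
    if g.log_rr.shape != (len(g.ga_grid), len(g.bw_grid)):
        report.append("lbwsg: log_rr shape does not match grid")

    _check_nonneg(report, "background_mortality", draw.background_mortality)
    if len(draw.background_mortality) != len(CHILD_AGE_BANDS):
        report.append("background_mortality: wrong length")

    if not np.all(np.diff(draw.tmrle_ages) > 0):
        report.append("tmrle_ages: not increasing")
    if np.any(np.diff(draw.tmrle_values) > 0):
        report.append("tmrle_values: not non-increasing in age")
    _check_nonneg(report, "tmrle_values", draw.tmrle_values)

    for f in fields(draw.effects):
        eff: Uncertain = getattr(draw.effects, f.name)
        if eff.dist == "lognormal" and eff.value <= 0:
            report.append(f"effects.{f.name}: relative risk must be positive")
        if eff.has_interval() and eff.lo > eff.hi:
            report.append(f"effects.{f.name}: inverted interval")

    cov = draw.coverage
    for product, u in cov.baseline.items():
        _check_prob(report, f"coverage.baseline.{product}", u.value)
    for product, v in cov.saturation.items():
        _check_prob(report, f"coverage.saturation.{product}", v)
        base = cov.baseline.get(product)
        if base is not None and base.value > v + _PROB_TOL:
            report.append(f"coverage.{product}: baseline exceeds saturation")

    for product, c in draw.costs.product_cost.items():
        if c < 0:
            report.append(f"costs.product_cost.{product}: negative cost")
    for name, c in draw.costs.nonproduct_components.items():
        if c < 0:
            report.append(f"costs.nonproduct_components.{name}: negative component")
    for product in PRODUCTS:
        if product not in draw.costs.product_cost:
            report.append(f"costs.product_cost: missing {product}")

    return report


def iter_uncertain(obj, prefix: str = ""):
    """Yield ``(path, Uncertain)`` pairs over a parameter structure."""
    if isinstance(obj, Uncertain):
        yield prefix, obj
    elif is_dataclass(obj):
        for f in fields(obj):
            yield from iter_uncertain(getattr(obj, f.name), f"{prefix}.{f.name}".lstrip("."))
    elif isinstance(obj, dict):
        for k, v in obj.items():
            yield from iter_uncertain(v, f"{prefix}.{k}".lstrip("."))
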