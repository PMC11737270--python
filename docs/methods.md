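# Methods

This note documents the model structure, the parameter defaults of the
synthetic-data generator, the numerical choices, and the design decisions
made where the design was genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Populations and time

Two closed cohorts are simulated per scenario. The pregnancy cohort starts
on day 0 of pregnancy and advances in 7-day steps until 6 weeks after the
birth event (abortion/miscarriage outcomes exit at resolution; durations
for those are uniform on 6–24 weeks). The child cohort is seeded from a
fixed random subsample of pregnancies; each live birth enters on day 0 of
life and advances in 4-day steps to the 5th birthday, tracked through the
age bands 0–6 d, 7–28 d, 1–5 m, 6–11 m, 12–23 m, 2–4 y. All per-simulant
state lives in numpy arrays; every random draw is taken for the full
(scenario-independent) candidate set in a fixed per-step order, so two
scenarios run with the same seed share common random numbers and scenario
contrasts are paired at the individual level. This is what lets small
numbers of Monte Carlo draws resolve scenario differences.

## Pregnancy model

- **Exposures.** Hemoglobin is normal (mean 121 g/L jittered per fixture
  seed, SD 14). The low-BMI indicator (pre-pregnancy BMI < 18.5,
  prevalence 0.22) is linked to hemoglobin through a Gaussian copula whose
  latent correlation is set from the configured Spearman correlation
  (default +0.2, i.e. lower BMI with lower hemoglobin) via
  ρ = 2·sin(π·ρ_s/6).
- **Anemia.** Pregnancy-specific cut points 70/100/110 g/L
  (severe/moderate/mild) with disability weights 0.149/0.052/0.004; each
  7-day step accrues dw × 7/365.25 YLDs.
- **Birth events.** Maternal disorders (per-birth risk 0.15, case fatality
  0.025, YLD 0.05 per nonfatal case) and postpartum hemorrhage (risk 0.05,
  postpartum hemoglobin drop 15 g/L) apply at live/stillbirth events only,
  each scaled by RR^((120 − Hb)/10) with RR = 1.25 per 10 g/L below the
  reference. Deaths accrue YLLs from the reference remaining-life-
  expectancy table at the (band-midpoint) maternal age. No other maternal
  mortality is modeled.
- **Birthweight.** Drawn conditional on gestational age from a bivariate
  normal (GA mean 38.7 wk SD 2.0; BW mean 3100 g SD 460; correlation
  0.45), then shifted: −50 g if anemic at birth, −120 g for low-BMI
  pregnancies, plus any antenatal-product mean difference.

## Antenatal intervention effects

Effects compose cumulatively along none → IFA → MMN → (+BEP, low-BMI
pregnancies only): hemoglobin +7.8 g/L at gestational week 8 (all
products); birthweight +57.73 / +45.16 / +66.96 g; stillbirth RR 0.91
(MMN) × 0.39 (BEP), with averted stillbirths reallocated to live births
only; preterm effects as gestational-age mean differences solved so the
continuous GA distribution reproduces the target relative risks — a single
uniform shift for IFA (RR 0.90 at <37 wk), then a two-segment shift for
MMN conditional on the post-IFA GA being below/above 32 weeks so that both
the <37 wk (RR 0.91) and <32 wk (RR 0.81) targets hold simultaneously.
Both solvers are brentq root-finds against the normal CDF (xtol 1e-12).
Two notes: (i) the week-shift for the <32 group can be slightly *smaller*
than for the ≥32 group even though its relative effect is larger, because
a normal far tail thins faster per week of shift; the solver therefore
constrains both shifts to be non-negative but not ordered. (ii) resampled
preterm RR draws above 1 are clamped to the null — the shift machinery
models protective effects only.

Supplemented-pregnancy counts (for costing) are covered pregnancies that
reach the week-8 distribution point; in an MMN+BEP scenario low-BMI covered
pregnancies count under both MMN and BEP.

## Wasting model and steady-state calibration

States unaffected → mild → moderate → severe with forward rates
i1 = 1.2, i2 = 0.95, i3 = 1.5 per person-year (fixture defaults chosen for
realistic episode dynamics: children cycle into mild wasting roughly
yearly, mild/moderate episodes last weeks; i3 is high enough that observed
severe prevalence is consistent with baseline SAM-treatment coverage).
Moderate wasting splits into WHZ [−3,−2.5) and [−2.5,−2) substates
(split 0.4) that share transition rates. Treated remission rates are
365.25/recovery-days (MAM 40 d, SAM 50 d); a 15% nonresponse fraction
recovers at untreated rates.

Untreated remission rates are unobservable and are recovered from the
steady-state assumption. The flow-balance equations of the 4-state chain
with mortality exits replaced into the unaffected state are triangular and
solve in closed form from the severe end down. Two refinements:

1. **Effective remission is a harmonic mix.** With per-individual
   treatment, state person-time is inflow × mean episode duration, and the
   mean duration of a treated/untreated mixture is c′/t + (1−c′)/r (with
   c′ = coverage × responder fraction), so the single-rate chain consistent
   with the microsimulation uses R = 1/(c′/t + (1−c′)/r), not the
   arithmetic rate mix. With an arithmetic mix, simulated severe-wasting
   prevalence under baseline coverage sits ~2.6× above the calibration
   target; with the harmonic mix, simulation and calibration agree.
2. **Discrete-step refinement.** The stepping engine allows at most one
   transition per 4-day step, which at realistic mild-wasting turnover
   shifts stationary occupancy visibly off the continuous-time solution.
   The closed-form solve therefore seeds a root-find (scipy hybr, log-rate
   space) against the stationary distribution of the exact 4-day transition
   matrix; residuals are verified below 1e-8. A pure continuous-time mode
   (`step_days=None`) is retained and verified against an independent
   generator null-space oracle.

State excess mortality entering the calibration sums protein-energy-
malnutrition mortality (0.08/0.03/0.015 per person-year for
severe/moderate-low/moderate-high) and the wasting-attributable share of
modeled-cause deaths. Covered children already in an eligible state when
they age into the 6–59 m treatment window start treatment at that first
screening contact (prevalent-case detection); without this, the
incident-only rule leaves a slow-remitting untreated pool the calibration
assumes treated.

## Growth failure, causes, and mortality in childhood

- **Stunting** is a fixed lifetime percentile re-thresholded against the
  band-specific prevalence. The percentile is tilted by birthweight,
  Φ((z + β·w)/√(1+β²)) with β = 0.35 (stunting) and 0.30 (28-day wasting
  state), where w is the child's birthweight standardized *by rank among
  survivors at 28 days* — neonatal mortality selects against low
  birthweight, and raw standardization would push category populations off
  the prevalence targets.
- **Underweight** is drawn from P(WAZ | WHZ, HAZ, band, sex), an
  ordinal-probit table with positive loadings on wasting (0.6) and stunting
  (0.4) severity; the stored underweight marginal is derived from this
  table, so the two are consistent by construction. It refreshes on any
  wasting, stunting, or band change.
- **Causes.** Diarrheal diseases (2.0/yr, 7 d, DW 0.188, CFR 0.0008), LRI
  (0.5/yr, 10 d, 0.133, 0.004), malaria (0.3/yr, 14 d, 0.21, 0.004),
  measles (0.05/yr, 10 d, 0.23, 0.012; one episode grants immunity), all
  ages 28 d–5 y, at most one concurrent episode per cause. Case fatality
  acts as an excess hazard over the episode. Growth-failure relative risks
  multiply across wasting (substate-resolved), stunting and underweight and
  are renormalized per band so the population-average incidence RR is 1;
  the mortality normalizer is E[rr_inc·rr_mort]/E[rr_inc] so the
  population-average cause *death* rate equals incidence × CFR.
- **Background mortality** (all other causes) is 0.80/0.25/0.012/0.008/
  0.004/0.0015 per person-year across the six bands, multiplied in the
  first 28 days by the low-birthweight/short-gestation surface: bilinear
  interpolation of a log-RR grid over (GA, BW), clamped at the grid edges
  and renormalized by Gauss–Hermite quadrature so the population-average
  multiplier is 1. These levels give an all-cause under-5 death toll near
  90–100 per 1000 live births in the zero-treatment counterfactual — a
  high-burden archetype with roughly a third of deaths from the four
  modeled causes.

## Child interventions

SAM treatment covers incident severe wasting at 6–59 m; MAM treatment
covers incident moderate wasting either universally or targeted (age <24 m,
or WHZ in [−3,−2.5), or WAZ < −3). SQ-LNS runs 6–18 m: forward wasting
hazards are multiplied by a single calibrated scale (1-D root-find matching
the stationary severe-wasting prevalence ratio, default target 0.69) that
expires at 18 m, and the stunting prevalence used for thresholding shifts
(severe PR 0.83, moderate PR 0.89, freed mass to unaffected) — the
stunting shift persists after the window, as stunting is a chronic state.
A single per-child propensity uniform gates all child interventions
(nested coverage), mirroring their shared CMAM screening platform; all
covered 6–59 m children count as screened regardless of state, and monthly
screening contacts are tallied separately. Coverage caps: 75.7% antenatal,
70% child interventions; baseline coverages IFA 60.2%, SAM 48.8%, MAM
(universal) 15%, others 0.

## Costing

Final unit cost = product cost × (1 + 0.15 program + 0.05 logistics/waste
+ 0.17 inefficiency) = product cost × 1.37, rounded to cents: IFA
2.27→3.11, MMN 3.47→4.75, BEP 40.28→55.18, SAM 41.84→57.32, MAM
29.70→40.69, SQ-LNS 35.75→48.98 USD; screening is free. Scenario cost is
administration counts × final unit costs, with child-side counts scaled to
the full pregnancy-cohort basis (divided by the child sample fraction) so
the pregnancy and child populations share one accounting basis.

## Optimization

Scenarios are the full factorial {none, IFA, MMN, MMN+BEP} × {SAM off/on}
× {MAM none/targeted/universal} × {SQ-LNS off/on} = 48, each at saturation
coverage, so convex weights span coverage 0…saturation directly.
Structural rules (BEP only with MMN; MAM modes exclusive) are encoded in
the scenario set, not as LP rows — this also yields the structural
property that targeted MAM is never less cost-effective than universal
MAM (a subset of cases at the same unit cost). The LP (scipy linprog,
HiGHS) minimizes DALYs or maximizes not-stunted person-time (person-time
in the unaffected + mild stunting categories — maximizing time not
stunted rather than minimizing time stunted avoids rewarding allocations
with fewer children alive); ties are broken by a second stage minimizing
cost among objective-optimal mixtures, with slack far below the solver
tolerance. Budget sweeps run 25 evenly spaced budgets from 0 to the cost
of the most expensive scenario; DALYs averted and ICERs are relative to
the zero-spending optimum. The change-point analysis bisects one product's
unit cost (repricing every scenario from its stored administration counts)
until the funding priority order — products ordered by the budget at which
optimal coverage first exceeds 1% — changes, to $0.01.

## Monte Carlo uncertainty

Every parameter carrying a 95% interval (the antenatal effect table, the
SQ-LNS prevalence ratios, baseline coverages) resamples per draw: mean
differences on the natural scale, relative risks on the log scale, both
via a split-normal quantile rule (u ~ N(0,1); x = m + u·sd_lo for u < 0,
else m + u·sd_hi with sd_± = interval half-widths / 1.96). This makes the
median equal the point estimate and the 2.5th/97.5th percentiles equal the
printed bounds exactly, including asymmetric intervals. Draw 0 is the
point-estimate set; the same draw index uses identical parameters in every
scenario, so allocation uncertainty summaries (pairwise priority-order
fractions, percentile intervals) are computed within draws.

## Problem sizes

Defaults are desk-scale: 20,000 pregnancies with a 25% child sample; the
tests and the acceptance script use 3,000 pregnancies × 3 draws for the
48-scenario frontier, 20,000 children for the mixing validation, 100,000
pregnancies for the paired stillbirth contrast, and 20,000 children × 5
years (1e5 person-years) for the calibration round trip. Larger
populations are configuration options.

## What the synthetic generator does and does not emulate

The fixture reproduces the *structure* of burden-study inputs —
age/sex-stratified rates, categorical prevalences summing to one,
uncertainty intervals, a continuous GA × birthweight joint distribution —
with plausible high-burden values, but not any real country: hemoglobin is
a single normal rather than an ensemble distribution, cause rates are
age-invariant within 28 d–5 y, wasting prevalence is age-invariant
(consistent with age-invariant transition rates), and growth-failure RRs
are invented de-overlapped values. Passing tests therefore demonstrate
internal consistency, calibration fidelity, and the correctness of the
simulation and optimization machinery — not agreement with any published
country estimate. Headline magnitudes (e.g. percent DALY reductions from
reallocation) scale with the synthetic burden levels and should not be
read as empirical findings.

## Known limitations

No wasting–stunting feedback, no infection→growth-failure feedback, no
wasting seasonality, WHZ-only acute-malnutrition classification (no MUAC/
edema), single aggregate pregnancy-related disorder cause, no maternal
background mortality, no service costs, linear cost–coverage relationship,
and treatment initiation only at incident cases plus first window entry
(no continuous re-screening of missed prevalent cases).
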