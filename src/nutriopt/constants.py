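"""Shared label sets, orderings, and age-band definitions.

Category vectors for the growth-failure exposures are stored severe-first
(severe, moderate, mild, unaffected), mirroring the cat1..cat4 convention of
risk-exposure tables.  The wasting transition engine uses the opposite
ordering internally (0 = unaffected .. 3 = severe); converters live in
:mod:`nutriopt.wasting`.
"""

from __future__ import annotations

import numpy as np

DAYS_PER_YEAR = 365.25

MATERNAL_AGE_BANDS = [
    "10-14", "15-19", "20-24", "25-29", "30-34",
    "35-39", "40-44", "45-49", "50-54",
]
MATERNAL_AGE_MIDPOINTS = np.arange(12.5, 55.0, 5.0)

# Pregnancy outcome order used everywhere: live birth, stillbirth,
# abortion/miscarriage.
OUTCOME_LIVE_BIRTH = 0
OUTCOME_STILLBIRTH = 1
OUTCOME_ABORTION = 2
PREGNANCY_OUTCOMES = ["live_birth", "stillbirth", "abortion_miscarriage"]

CHILD_AGE_BANDS = ["0-6d", "7-28d", "1-5m", "6-11m", "12-23m", "2-4y"]
# Band edges in days of age (right-open intervals).
CHILD_BAND_EDGES_DAYS = np.array([0.0, 7.0, 28.0, 182.625, 365.25, 730.5, 1826.25])
# Bands in which growth-failure exposures are tracked (age >= 28 days).
CGF_AGE_BANDS = CHILD_AGE_BANDS[2:]
N_CGF_BANDS = len(CGF_AGE_BANDS)

SEXES = ["male", "female"]

# Four-category growth-failure exposures, severe first.
CGF_CATEGORIES = ["severe", "moderate", "mild", "unaffected"]
CGF_SEVERE, CGF_MODERATE, CGF_MILD, CGF_UNAFFECTED = range(4)

# Wasting states with the moderate category split into two WHZ substates
# (severe-first ordering used for prevalence-style vectors with substates).
WASTING_SUBSTATES = ["severe", "mod_whz_m3_m2p5", "mod_whz_m2p5_m2", "mild", "unaffected"]

CAUSES = ["diarrheal_diseases", "lri", "malaria", "measles"]

PRODUCTS = ["ifa", "mmn", "bep", "sam_tx", "mam_tx", "sqlns", "screening"]
ANTENATAL_PRODUCTS = ["none", "ifa", "mmn", "mmn_bep"]
MAM_MODES = ["none", "targeted", "universal"]


def child_age_band(age_days: np.ndarray) -> np.ndarray:
    """Map ages in days to band indices (0..5); ages >= 5 y clamp to the last band."""
    idx = np.searchsorted(CHILD_BAND_EDGES_DAYS[1:], age_days, side="right")
    return np.minimum(idx, len(CHILD_AGE_BANDS) - 1)


def cgf_band(age_days: np.ndarray) -> np.ndarray:
    """Band index within the four growth-failure bands; -1 below 28 days."""
    return child_age_band(age_days) - 2
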