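"""Shared DALY accounting: YLD accrual, YLLs at death, ledger aggregation.

DALYs follow the standard convention without age-weighting or discounting:
YLDs are disability weight x affected time, YLLs are the reference remaining
life expectancy at the age of death, and DALYs = YLLs + YLDs.  Stillbirths
are tallied separately and excluded from DALYs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import CGF_AGE_BANDS, CGF_CATEGORIES

MATERNAL_CAUSES = ["anemia", "maternal_disorders"]
CHILD_CAUSES = [
    "diarrheal_diseases", "lri", "malaria", "measles", "pem", "lbwsg_background",
]


def accrue_yld(dw: float, duration_years) -> float:
    """YLD increment for time spent affected: ``dw * duration``."""
    if not 0.0 <= dw <= 1.0:
        raise ValueError(f"disability weight {dw} outside [0, 1]")
    duration = np.asarray(duration_years, dtype=float)
    if np.any(duration < 0):
        raise ValueError("negative duration")
    out = dw * duration
    return float(out) if out.ndim == 0 else out


def yll_at_death(age_years, tmrle_ages: np.ndarray, tmrle_values: np.ndarray):
    """Remaining reference life expectancy at age, linearly interpolated.

    Ages beyond the table range clamp to the boundary values.
    """
    age = np.asarray(age_years, dtype=float)
    out = np.interp(age, tmrle_ages, tmrle_values)
    return float(out) if out.ndim == 0 else out


@dataclass
class BurdenLedger:
    """Counts of deaths, stillbirths, YLLs, YLDs, and stratified person-time.

    ``ylds``/``ylls`` are keyed ``(population, cause)`` with population in
    ``{"pregnancy", "child"}``.  ``person_time`` is a child-population array
    stratified by stunting category x growth-failure age band (years);
    ``person_time_total`` additionally includes time below 28 days and the
    pregnancy population, so the stratified table sums to child alive-time in
    the growth-failure bands exactly.
    """

    ylds: dict = field(default_factory=dict)
    ylls: dict = field(default_factory=dict)
    deaths: dict = field(default_factory=dict)  # population -> count
    stillbirths: float = 0.0
    person_time: np.ndarray = field(
        default_factory=lambda: np.zeros((len(CGF_CATEGORIES), len(CGF_AGE_BANDS)))
    )
    person_time_total: dict = field(default_factory=dict)  # population -> years
    wasting_incident_cases: dict = field(default_factory=dict)  # state -> count
    wasting_person_time: dict = field(default_factory=dict)  # state -> years

    def add_yld(self, population: str, cause: str, amount: float) -> None:
        key = (population, cause)
        self.ylds[key] = self.ylds.get(key, 0.0) + amount

    def add_yll(self, population: str, cause: str, amount: float) -> None:
        key = (population, cause)
        self.ylls[key] = self.ylls.get(key, 0.0) + amount

    def add_deaths(self, population: str, n: float) -> None:
        self.deaths[population] = self.deaths.get(population, 0.0) + n

    @property
    def total_ylds(self) -> float:
        return float(sum(self.ylds.values()))

    @property
    def total_ylls(self) -> float:
        return float(sum(self.ylls.values()))

    @property
    def dalys(self) -> float:
        return self.total_ylls + self.total_ylds

    def dalys_by_population(self, population: str) -> float:
        return float(
            sum(v for (p, _), v in self.ylls.items() if p == population)
            + sum(v for (p, _), v in self.ylds.items() if p == population)
        )

    def not_stunted_person_time(self) -> float:
        """Person-time in the unaffected + mild stunting categories (HAZ >= -2)."""
        return float(self.person_time[2:, :].sum())

    # -- algebra ------------------------------------------------------------

    def scaled(self, k: float) -> "BurdenLedger":
        out = BurdenLedger()
        out.ylds = {key: v * k for key, v in self.ylds.items()}
        out.ylls = {key: v * k for key, v in self.ylls.items()}
        out.deaths = {key: v * k for key, v in self.deaths.items()}
        out.stillbirths = self.stillbirths * k
        out.person_time = self.person_time * k
        out.person_time_total = {key: v * k for key, v in self.person_time_total.items()}
        out.wasting_incident_cases = {
            key: v * k for key, v in self.wasting_incident_cases.items()
        }
        out.wasting_person_time = {
            key: v * k for key, v in self.wasting_person_time.items()
        }
        return out

    def merged(self, other: "BurdenLedger") -> "BurdenLedger":
        out = self.scaled(1.0)
        for key, v in other.ylds.items():
            out.ylds[key] = out.ylds.get(key, 0.0) + v
        for key, v in other.ylls.items():
            out.ylls[key] = out.ylls.get(key, 0.0) + v
        for key, v in other.deaths.items():
            out.deaths[key] = out.deaths.get(key, 0.0) + v
        out.stillbirths += other.stillbirths
        out.person_time = out.person_time + other.person_time
        for key, v in other.person_time_total.items():
            out.person_time_total[key] = out.person_time_total.get(key, 0.0) + v
        for key, v in other.wasting_incident_cases.items():
            out.wasting_incident_cases[key] = (
                out.wasting_incident_cases.get(key, 0.0) + v
            )
        for key, v in other.wasting_person_time.items():
            out.wasting_person_time[key] = (
                out.wasting_person_time.get(key, 0.0) + v
            )
        return out

    def scale_populations(self, pregnancy_factor: float, child_factor: float) -> "BurdenLedger":
        """Scale pregnancy-population and child-population fields separately."""
        out = BurdenLedger()
        for src, dst in ((self.ylds, out.ylds), (self.ylls, out.ylls)):
            for (pop, cause), v in src.items():
                dst[(pop, cause)] = v * (
                    pregnancy_factor if pop == "pregnancy" else child_factor
                )
        for pop, v in self.deaths.items():
            out.deaths[pop] = v * (pregnancy_factor if pop == "pregnancy" else child_factor)
        out.stillbirths = self.stillbirths * pregnancy_factor
        out.person_time = self.person_time * child_factor
        for pop, v in self.person_time_total.items():
            out.person_time_total[pop] = v * (
                pregnancy_factor if pop == "pregnancy" else child_factor
            )
        out.wasting_incident_cases = {
            k: v * child_factor for k, v in self.wasting_incident_cases.items()
        }
        out.wasting_person_time = {
            k: v * child_factor for k, v in self.wasting_person_time.items()
        }
        return out

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Tidy (stratum, measure, value) table."""
        rows = []
        for (pop, cause), v in sorted(self.ylds.items()):
            rows.append((f"{pop}/{cause}", "ylds", v))
        for (pop, cause), v in sorted(self.ylls.items()):
            rows.append((f"{pop}/{cause}", "ylls", v))
        for pop, v in sorted(self.deaths.items()):
            rows.append((pop, "deaths", v))
        rows.append(("pregnancy", "stillbirths", self.stillbirths))
        for i, cat in enumerate(CGF_CATEGORIES):
            for b, band in enumerate(CGF_AGE_BANDS):
                rows.append((f"stunting_{cat}/{band}", "person_time", self.person_time[i, b]))
        for pop, v in sorted(self.person_time_total.items()):
            rows.append((pop, "person_time_total", v))
        for state, v in sorted(self.wasting_incident_cases.items()):
            rows.append((state, "wasting_incident_cases", v))
        for state, v in sorted(self.wasting_person_time.items()):
            rows.append((state, "wasting_person_time", v))
        return pd.DataFrame(rows, columns=["stratum", "measure", "value"])
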