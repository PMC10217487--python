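"""Baseline epidemiological parameters, unit costs and the cycle/year grid.

Defaults are the published model inputs: 85% of incident patients start
in watchful waiting, the calibrated WW-to-treatment probability is 1.65%
per 28-day cycle, del(17p) prevalence 7%, IGHV-mutated 40% of the
remainder, the age split at diagnosis is (33.75, 14.34, 51.91)% for
<65 / 65-70 / >70, fitness by age (90, 50, 15)%, oral-therapy
discontinuation 0.70%/cycle in first line and 1.40%/cycle at relapse,
and pooled background mortality 0.695% per cycle.  All costs are 2020
Canadian dollars.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml

from .states import AGE_GROUPS, STRATA, HealthState, Stratum

log = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0  # 30.4375


class ParameterError(ValueError):
    """A parameter failed range validation; the message names the field."""


def default_unit_costs() -> dict[str, float]:
    """Unit costs (2020 CAD): laboratory panels, administration,
    professional fees and wages, and grade 3/4 adverse-event management."""
    return {
        "electrolyte_panel": 18.08,
        "renal_panel": 13.32,
        "liver_panel": 21.15,
        "cbc_panel": 14.74,
        "coagulation_panel": 13.42,
        "serology_panel": 21.01,
        "infusion_administration": 105.15,
        "consult_hematology": 157.00,
        "partial_assessment": 38.05,
        "nurse_wage_per_min": 0.63,
        "pharmacist_wage_per_min": 0.87,
        "anemia": 759.71,
        "neutropenia": 523.23,
        "febrile_neutropenia": 10918.0,
        "thrombocytopenia": 441.86,
        "infection": 1831.0,
        "atrial_fibrillation": 1413.0,
    }


#: panels drawn together as one routine monitoring visit
FULL_LAB_PANEL = ("electrolyte_panel", "renal_panel", "liver_panel", "cbc_panel")


@dataclass
class BaselineParameters:
    p_ww_at_diagnosis: float = 0.85
    median_time_to_first_tx: float = 4.8  # years, informational
    p_ww_to_tx_per_cycle: float = 0.0165  # calibrated, used as-is
    prevalence_del17p: float = 0.07
    p_ighv_mutated: float = 0.40  # among non-del(17p)
    age_distribution: tuple[float, float, float] = (0.3375, 0.1434, 0.5191)
    fitness_by_age: tuple[float, float, float] = (0.90, 0.50, 0.15)
    p_discontinue_1L_per_cycle: float = 0.0070
    p_discontinue_2L_per_cycle: float = 0.0140
    p_background_death_per_cycle: float = 0.00695
    cycle_days: int = 28
    palliative_care_cost: float = 9326.0
    unit_costs: dict[str, float] = field(default_factory=default_unit_costs)

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        probs = {
            "p_ww_at_diagnosis": self.p_ww_at_diagnosis,
            "p_ww_to_tx_per_cycle": self.p_ww_to_tx_per_cycle,
            "prevalence_del17p": self.prevalence_del17p,
            "p_ighv_mutated": self.p_ighv_mutated,
            "p_discontinue_1L_per_cycle": self.p_discontinue_1L_per_cycle,
            "p_discontinue_2L_per_cycle": self.p_discontinue_2L_per_cycle,
            "p_background_death_per_cycle": self.p_background_death_per_cycle,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0) or not math.isfinite(p):
                raise ParameterError(f"{name} must be in [0, 1], got {p!r}")
        for i, p in enumerate(self.age_distribution):
            if not (0.0 <= p <= 1.0):
                raise ParameterError(
                    f"age_distribution[{i}] must be in [0, 1], got {p!r}"
                )
        if abs(sum(self.age_distribution) - 1.0) > 1e-9:
            raise ParameterError("age_distribution must sum to 1")
        for i, p in enumerate(self.fitness_by_age):
            if not (0.0 <= p <= 1.0):
                raise ParameterError(
                    f"fitness_by_age[{i}] must be in [0, 1], got {p!r}"
                )
        if self.median_time_to_first_tx <= 0:
            raise ParameterError("median_time_to_first_tx must be positive")
        if self.cycle_days != 28:
            raise ParameterError("cycle_days must equal 28")
        if self.palliative_care_cost < 0:
            raise ParameterError("palliative_care_cost must be non-negative")
        for name, c in self.unit_costs.items():
            if c < 0:
                raise ParameterError(f"unit_costs[{name!r}] must be non-negative")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "p_ww_at_diagnosis": float(self.p_ww_at_diagnosis),
            "median_time_to_first_tx": float(self.median_time_to_first_tx),
            "p_ww_to_tx_per_cycle": float(self.p_ww_to_tx_per_cycle),
            "prevalence_del17p": float(self.prevalence_del17p),
            "p_ighv_mutated": float(self.p_ighv_mutated),
            "age_distribution": [float(p) for p in self.age_distribution],
            "fitness_by_age": [float(p) for p in self.fitness_by_age],
            "p_discontinue_1L_per_cycle": float(self.p_discontinue_1L_per_cycle),
            "p_discontinue_2L_per_cycle": float(self.p_discontinue_2L_per_cycle),
            "p_background_death_per_cycle": float(self.p_background_death_per_cycle),
            "cycle_days": int(self.cycle_days),
            "palliative_care_cost": float(self.palliative_care_cost),
            "unit_costs": {k: float(v) for k, v in self.unit_costs.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BaselineParameters":
        defaults = cls()
        kwargs = {}
        for name in (
            "p_ww_at_diagnosis",
            "median_time_to_first_tx",
            "p_ww_to_tx_per_cycle",
            "prevalence_del17p",
            "p_ighv_mutated",
            "p_discontinue_1L_per_cycle",
            "p_discontinue_2L_per_cycle",
            "p_background_death_per_cycle",
            "cycle_days",
            "palliative_care_cost",
        ):
            if name in d:
                kwargs[name] = d[name]
            else:
                log.info("parameter %s omitted; using default %r",
                         name, getattr(defaults, name))
        if "age_distribution" in d:
            kwargs["age_distribution"] = tuple(d["age_distribution"])
        if "fitness_by_age" in d:
            kwargs["fitness_by_age"] = tuple(d["fitness_by_age"])
        uc = default_unit_costs()
        uc.update(d.get("unit_costs", {}))
        kwargs["unit_costs"] = uc
        out = cls(**kwargs)
        out.validate()
        return out

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "BaselineParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def copy(self, **changes) -> "BaselineParameters":
        out = replace(self, **changes)
        if "unit_costs" not in changes:
            out.unit_costs = dict(self.unit_costs)
        return out


def stratum_probability(params: BaselineParameters, s: Stratum) -> float:
    """Joint baseline probability of a stratum.

    Factorizes as age x (fitness | age) x del(17p) x (IGHV | not del17p).
    """
    i = AGE_GROUPS.index(s.age_group)
    p = params.age_distribution[i]
    p_fit = params.fitness_by_age[i]
    p *= p_fit if s.fit else (1.0 - p_fit)
    if s.del17p:
        p *= params.prevalence_del17p
    else:
        p *= 1.0 - params.prevalence_del17p
        p *= params.p_ighv_mutated if s.ighv_mutated else 1.0 - params.p_ighv_mutated
    return p


def stratum_probabilities(params: BaselineParameters) -> np.ndarray:
    """Probabilities over :data:`cllburden.states.STRATA` (sums to 1)."""
    return np.array([stratum_probability(params, s) for s in STRATA])


def build_entry_distribution(
    params: BaselineParameters,
) -> dict[tuple[Stratum, HealthState], float]:
    """Distribution of an incident patient over (stratum, entry state).

    Entry states are watchful waiting (with mass ``p_ww_at_diagnosis``)
    and direct first-line treatment (the remainder).
    """
    params.validate()
    out: dict[tuple[Stratum, HealthState], float] = {}
    p_ww = params.p_ww_at_diagnosis
    for s, ps in zip(STRATA, stratum_probabilities(params)):
        out[(s, HealthState.WATCHFUL_WAITING)] = ps * p_ww
        out[(s, HealthState.FIRST_LINE)] = ps * (1.0 - p_ww)
    return out


@dataclass(frozen=True)
class TimeGrid:
    """28-day cycle grid over whole calendar years.

    Cycle ``k`` (0-based from 1 January of ``start_year``) belongs to
    calendar year ``start_year + floor(k * 28 / 365.25)``; the grid
    contains every cycle whose year is at most ``end_year``.
    """

    start_year: int
    end_year: int
    cycle_days: int = 28

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")

    @property
    def cycles_per_year(self) -> float:
        return DAYS_PER_YEAR / self.cycle_days

    @property
    def n_cycles(self) -> int:
        span_days = (self.end_year - self.start_year + 1) * DAYS_PER_YEAR
        return int(math.ceil(span_days / self.cycle_days))

    def year_of_cycle(self, k: int) -> int:
        return self.start_year + int(math.floor(k * self.cycle_days / DAYS_PER_YEAR))

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.end_year + 1))

    def cycles_in_year(self, year: int) -> list[int]:
        if not (self.start_year <= year <= self.end_year):
            raise ValueError(f"year {year} outside grid "
                             f"[{self.start_year}, {self.end_year}]")
        y0 = year - self.start_year
        lo = int(math.ceil(y0 * DAYS_PER_YEAR / self.cycle_days))
        hi = int(math.ceil((y0 + 1) * DAYS_PER_YEAR / self.cycle_days))
        return list(range(lo, min(hi, self.n_cycles)))
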