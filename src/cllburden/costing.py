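"""Direct-medical-cost accrual and annual ledgers (2020 CAD).

Per cycle the accountant charges, from the post-transition state vector
and the cycle's flows:

* drug acquisition by the regimen's cycle-indexed schedule (cost of
  on-treatment cycle ``t + 1`` for a cell with ``t`` completed cycles);
* administration: infusion fee plus nursing time per infusion, and
  pharmacist dispensing time per on-drug cycle;
* follow-up/monitoring: routine laboratory panels (full panel per
  on-treatment cycle, half that frequency in watchful waiting and after
  course completion), quarterly partial assessments, and a hematology
  consultation at every treatment initiation;
* adverse events: the expected grade 3/4 management cost, charged once
  per treatment-course initiation (per-cycle basis available as a
  configuration switch);
* palliative care: a one-time per-stay charge on palliative entry.

No discounting or inflation adjustment is applied within the horizon.
Ledger cells are keyed by (calendar year, line, category); watchful
waiting and palliative costs fall under the "other" line.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .engine import Flows, ModelOptions, StateVector
from .params import BaselineParameters, FULL_LAB_PANEL, TimeGrid
from .registry import (
    FIRST,
    SECOND,
    Registry,
    drug_cost_for_cycle,
    expected_ae_cost,
    infusions_for_cycle,
)

LEDGER_LINES = ("first", "second", "other")
CATEGORIES = ("drug", "monitoring", "administration", "ae", "palliative")


@dataclass
class MonitoringSchedule:
    """Follow-up frequencies (configuration; the published sources give
    unit costs but not frequencies)."""

    panels_per_cycle_on_treatment: float = 1.0
    panels_per_cycle_ww: float = 0.5
    consults_per_initiation: float = 1.0
    partial_assessments_per_year: float = 4.0
    nurse_minutes_per_infusion: float = 30.0
    pharmacist_minutes_per_cycle: float = 15.0

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v!r}")

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "MonitoringSchedule":
        out = cls(**dict(d))
        out.validate()
        return out

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "MonitoringSchedule":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class CostLedger:
    """Accrued CAD by (calendar year, line, category)."""

    def __init__(self):
        self.cells: dict[tuple[int, str, str], float] = {}

    def add(self, year: int, line: str, category: str, amount: float) -> None:
        if amount == 0.0:
            return
        if line not in LEDGER_LINES or category not in CATEGORIES:
            raise ValueError(f"unknown ledger cell ({line!r}, {category!r})")
        key = (year, line, category)
        self.cells[key] = self.cells.get(key, 0.0) + amount

    @property
    def years(self) -> list[int]:
        return sorted({y for (y, _, _) in self.cells})

    def grand_total(self) -> float:
        return sum(self.cells.values())

    def annual_total(self, year: int) -> float:
        return sum(v for (y, _, _), v in self.cells.items() if y == year)

    def line_total(self, line: str) -> float:
        return sum(v for (_, ln, _), v in self.cells.items() if ln == line)

    def cell(self, year: int, line: str, category: str) -> float:
        return self.cells.get((year, line, category), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"year": y, "line": ln, "category": cat, "cost_cad": v}
            for (y, ln, cat), v in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows, columns=["year", "line", "category", "cost_cad"])

    def scaled(self, factor: float) -> "CostLedger":
        out = CostLedger()
        for key, v in self.cells.items():
            out.cells[key] = v * factor
        return out


class CostModel:
    """Cost arrays compiled against a registry, parameter set and
    monitoring schedule; ``multipliers`` scale whole drug-cost schedules
    by regimen name (used by the sensitivity analysis)."""

    def __init__(
        self,
        registry: Registry,
        params: BaselineParameters,
        schedule: Optional[MonitoringSchedule] = None,
        options: Optional[ModelOptions] = None,
        multipliers: Optional[Mapping[str, float]] = None,
    ):
        schedule = schedule or MonitoringSchedule()
        schedule.validate()
        options = options or ModelOptions()
        self.params = params
        self.schedule = schedule
        self.options = options
        mult = dict(multipliers or {})

        self.r1_names = registry.names(FIRST)
        self.r2_names = registry.names(SECOND)
        T = options.tunnel_cap
        uc = params.unit_costs

        def _compile(names, line):
            R = len(names)
            drug = np.zeros((R, T))
            infus = np.zeros((R, T))
            ae = np.zeros(R)
            for j, name in enumerate(names):
                reg = registry.get(line, name)
                m = mult.get(name, 1.0)
                for t in range(T):
                    drug[j, t] = m * drug_cost_for_cycle(reg, t + 1)
                    infus[j, t] = infusions_for_cycle(reg, t + 1)
                drug[j, 0] += m * reg.ramp_up_cost
                ae[j] = expected_ae_cost(reg, uc)
            return drug, infus, ae

        self.drug1, self.infus1, self.ae1 = _compile(self.r1_names, FIRST)
        self.drug2, self.infus2, self.ae2 = _compile(self.r2_names, SECOND)

        self.panel_cost = sum(uc[name] for name in FULL_LAB_PANEL)
        self.admin_per_infusion = (
            uc["infusion_administration"]
            + schedule.nurse_minutes_per_infusion * uc["nurse_wage_per_min"]
        )
        self.pharm_per_cycle = (
            schedule.pharmacist_minutes_per_cycle * uc["pharmacist_wage_per_min"]
        )
        cycles_per_year = 365.25 / params.cycle_days
        self.partial_per_cycle = (
            schedule.partial_assessments_per_year / cycles_per_year
        ) * uc["partial_assessment"]
        self.consult = schedule.consults_per_initiation * uc["consult_hematology"]

    def new_ledger(self) -> CostLedger:
        return CostLedger()

    def accrue_cycle(self, sv: StateVector, flows: Flows) -> dict[tuple[str, str], float]:
        """One cycle's cost increment by (line, category)."""
        inc: dict[tuple[str, str], float] = {}
        sch = self.schedule

        def put(line, cat, amount):
            if amount:
                inc[(line, cat)] = inc.get((line, cat), 0.0) + float(amount)

        for line, l, l_off, drug, infus, ae, init in (
            ("first", sv.l1, sv.l1_off, self.drug1, self.infus1, self.ae1,
             flows.init1),
            ("second", sv.l2, sv.l2_off, self.drug2, self.infus2, self.ae2,
             flows.init2),
        ):
            on_mass = float(l.sum())
            off_mass = float(l_off.sum())
            put(line, "drug", (l * drug[None]).sum())
            put(line, "administration",
                (l * infus[None]).sum() * self.admin_per_infusion
                + on_mass * self.pharm_per_cycle)
            put(line, "monitoring",
                self.panel_cost * (
                    on_mass * sch.panels_per_cycle_on_treatment
                    + off_mass * sch.panels_per_cycle_ww)
                + self.partial_per_cycle * (on_mass + off_mass)
                + self.consult * float(init.sum()))
            if self.options.ae_cost_basis == "per_course":
                put(line, "ae", float((init * ae[None]).sum()))
            else:  # per on-drug cycle
                put(line, "ae", float((l.sum(axis=(0, 2)) * ae).sum()))

        ww_mass = float(sv.ww.sum())
        put("other", "monitoring",
            ww_mass * (self.panel_cost * sch.panels_per_cycle_ww
                       + self.partial_per_cycle))
        put("other", "palliative",
            flows.pall_entries * self.params.palliative_care_cost)
        return inc

    def accrue(self, sv: StateVector, flows: Flows, ledger: CostLedger,
               year: int) -> None:
        for (line, cat), amount in self.accrue_cycle(sv, flows).items():
            ledger.add(year, line, cat, amount)


def aggregate_annual(
    increments: Iterable[tuple[int, Mapping[tuple[str, str], float]]],
    grid: TimeGrid,
) -> CostLedger:
    """Assign cycle-tagged increments to calendar years (cycle ``k``
    belongs to ``start_year + floor(k * 28 / 365.25)``)."""
    ledger = CostLedger()
    for cycle, inc in increments:
        year = grid.year_of_cycle(cycle)
        for (line, cat), amount in inc.items():
            ledger.add(year, line, cat, amount)
    return ledger


def compare_scenarios(ledger_fixed: CostLedger,
                      ledger_continuous: CostLedger) -> dict:
    """Fixed-vs-continuous difference report.

    Savings percent is 100 x (continuous - fixed) / continuous, on
    cumulative totals, overall and by line.
    """
    years_f, years_c = ledger_fixed.years, ledger_continuous.years
    if years_f != years_c:
        raise ValueError(
            f"ledger horizons differ: {years_f} vs {years_c}"
        )
    cum_f = ledger_fixed.grand_total()
    cum_c = ledger_continuous.grand_total()
    report = {
        "years": years_f,
        "annual_total_fixed": {y: ledger_fixed.annual_total(y) for y in years_f},
        "annual_total_continuous": {
            y: ledger_continuous.annual_total(y) for y in years_f
        },
        "annual_difference": {
            y: ledger_continuous.annual_total(y) - ledger_fixed.annual_total(y)
            for y in years_f
        },
        "cumulative_fixed": cum_f,
        "cumulative_continuous": cum_c,
        "savings_total": cum_c - cum_f,
        "savings_percent": (100.0 * (cum_c - cum_f) / cum_c) if cum_c else 0.0,
        "by_line": {},
    }
    for line in LEDGER_LINES:
        f = ledger_fixed.line_total(line)
        c = ledger_continuous.line_total(line)
        report["by_line"][line] = {
            "fixed": f,
            "continuous": c,
            "savings": c - f,
            "savings_percent": (100.0 * (c - f) / c) if c else 0.0,
        }
    return report
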