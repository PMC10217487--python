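"""A complete runnable configuration and the high-level pipeline runs.

``ModelContext`` bundles parameters, registry, both scenario policies,
the incidence series, the monitoring schedule and behavioural options.
The pipeline is: a warm-up over 2010-2019 accumulating incident cohorts
into the prevalent population (both scenarios share the warm-up policy
rules), then a 2020-2025 projection per scenario with cost accrual.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .costing import CostLedger, CostModel, MonitoringSchedule, compare_scenarios
from .engine import CohortEngine, ModelOptions, RunResult, StateVector
from .params import BaselineParameters, TimeGrid
from .policy import CONTINUOUS, FIXED, AllocationPolicy, default_policy
from .registry import Registry, default_registry


@dataclass
class ModelContext:
    params: BaselineParameters
    registry: Registry
    policies: dict[str, AllocationPolicy]
    incidence: dict[int, float]
    schedule: MonitoringSchedule = field(default_factory=MonitoringSchedule)
    options: ModelOptions = field(default_factory=ModelOptions)
    warmup_years: tuple[int, int] = (2010, 2019)
    projection_years: tuple[int, int] = (2020, 2025)
    #: drug-cost scaling by regimen name (sensitivity analysis)
    drug_cost_multipliers: dict[str, float] = field(default_factory=dict)

    def policy(self, scenario: str) -> AllocationPolicy:
        try:
            return self.policies[scenario]
        except KeyError:
            raise ValueError(f"no policy for scenario {scenario!r}") from None

    @property
    def warmup_grid(self) -> TimeGrid:
        return TimeGrid(*self.warmup_years)

    @property
    def projection_grid(self) -> TimeGrid:
        return TimeGrid(*self.projection_years)

    def copy(self) -> "ModelContext":
        return copy.deepcopy(self)

    def engine(self, scenario: str) -> CohortEngine:
        return CohortEngine(
            self.params, self.registry, self.policy(scenario), self.options
        )

    def cost_model(self) -> CostModel:
        return CostModel(
            self.registry,
            self.params,
            self.schedule,
            self.options,
            self.drug_cost_multipliers,
        )


@dataclass
class ScenarioResult:
    scenario: str
    warmup_trace: pd.DataFrame
    trace: pd.DataFrame
    ledger: CostLedger
    sv_start: StateVector   # prevalent population entering the projection
    sv_final: StateVector


def run_warmup(ctx: ModelContext, scenario: str = FIXED) -> RunResult:
    """Build the prevalent population by accumulating incident cohorts
    over the warm-up years (policies agree across scenarios there)."""
    grid = ctx.warmup_grid
    missing = [y for y in grid.years if y not in ctx.incidence]
    if missing:
        raise ValueError(f"incidence series missing warm-up years {missing}")
    engine = ctx.engine(scenario)
    return engine.run(grid, ctx.incidence)


def run_projection(
    ctx: ModelContext,
    sv0: Optional[StateVector],
    scenario: str,
    record_cycles: bool = False,
) -> RunResult:
    """Project prevalence and costs over the projection horizon."""
    grid = ctx.projection_grid
    missing = [y for y in grid.years if y not in ctx.incidence]
    if missing:
        raise ValueError(f"incidence series missing projection years {missing}")
    engine = ctx.engine(scenario)
    return engine.run(
        grid,
        ctx.incidence,
        sv0=sv0,
        cost_model=ctx.cost_model(),
        record_cycles=record_cycles,
    )


def run_scenario(ctx: ModelContext, scenario: str,
                 record_cycles: bool = False) -> ScenarioResult:
    warm = run_warmup(ctx, scenario)
    proj = run_projection(ctx, warm.sv, scenario, record_cycles=record_cycles)
    return ScenarioResult(
        scenario=scenario,
        warmup_trace=warm.trace,
        trace=proj.trace,
        ledger=proj.ledger,
        sv_start=warm.sv,
        sv_final=proj.sv,
    )


def run_both_scenarios(ctx: ModelContext) -> tuple[
    ScenarioResult, ScenarioResult, dict
]:
    """Run fixed and continuous scenarios (sharing one warm-up, since
    warm-up rules are identical) and build the difference report."""
    warm = run_warmup(ctx, FIXED)
    fixed = run_projection(ctx, warm.sv, FIXED)
    cont = run_projection(ctx, warm.sv, CONTINUOUS)
    res_f = ScenarioResult(FIXED, warm.trace, fixed.trace, fixed.ledger,
                           warm.sv, fixed.sv)
    res_c = ScenarioResult(CONTINUOUS, warm.trace, cont.trace, cont.ledger,
                           warm.sv, cont.sv)
    report = compare_scenarios(res_f.ledger, res_c.ledger)
    return res_f, res_c, report


def default_context(
    incidence: Optional[Mapping[int, float]] = None,
    params: Optional[BaselineParameters] = None,
) -> ModelContext:
    """The shipped default configuration (synthetic incidence defaults
    live in :mod:`cllburden.synthetic`; importing here would cycle)."""
    from .synthetic import default_incidence

    return ModelContext(
        params=params or BaselineParameters(),
        registry=default_registry(),
        policies={FIXED: default_policy(FIXED),
                  CONTINUOUS: default_policy(CONTINUOUS)},
        incidence=dict(incidence) if incidence is not None
        else default_incidence(),
    )
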