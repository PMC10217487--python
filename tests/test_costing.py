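"""Cost accrual, annual aggregation and the scenario comparison."""

import numpy as np
import pytest
from _toys import toy_context

from cllburden.context import run_projection
from cllburden.costing import (
    CostLedger,
    CostModel,
    MonitoringSchedule,
    aggregate_annual,
    compare_scenarios,
)
from cllburden.params import TimeGrid
from cllburden.policy import FIXED
from cllburden.registry import FIRST


def test_panel_cost_is_sum_of_four_panels(default_ctx):
    cm = default_ctx.cost_model()
    assert cm.panel_cost == pytest.approx(18.08 + 13.32 + 21.15 + 14.74)
    assert cm.panel_cost == pytest.approx(67.29)


def test_hundred_gclb_starters_accrue_first_cycle_drug_cost(default_ctx):
    engine = default_ctx.engine(FIXED)
    cm = default_ctx.cost_model()
    sv = engine.empty_state()
    j = engine.r1_names.index("GClb")
    sv.l1[0, j, 0] = 100.0
    sv.entrants = 100.0
    init1 = np.zeros_like(sv.l1[:, :, 0])
    init1[0, j] = 100.0
    from cllburden.engine import Flows

    flows = Flows(init1=init1, init2=np.zeros_like(sv.l2[:, :, 0]),
                  pall_entries=0.0, deaths=0.0, entrants=100.0)
    inc = cm.accrue_cycle(sv, flows)
    assert inc[("first", "drug")] == pytest.approx(100 * 16_497.0)
    # consultation charged once per initiation
    assert inc[("first", "monitoring")] == pytest.approx(
        100 * (67.29 + (4 / (365.25 / 28)) * 38.05 + 157.0)
    )


def test_empty_state_accrues_nothing(default_ctx):
    engine = default_ctx.engine(FIXED)
    cm = default_ctx.cost_model()
    sv = engine.empty_state()
    from cllburden.engine import Flows

    flows = Flows(init1=np.zeros_like(sv.l1[:, :, 0]),
                  init2=np.zeros_like(sv.l2[:, :, 0]),
                  pall_entries=0.0, deaths=0.0, entrants=0.0)
    assert cm.accrue_cycle(sv, flows) == {}


class TestAggregateAnnual:
    def test_single_increment_lands_in_start_year(self):
        grid = TimeGrid(2020, 2021)
        ledger = aggregate_annual([(0, {("first", "drug"): 1.0})], grid)
        assert ledger.annual_total(2020) == 1.0

    def test_calendar_rule_first_fourteen_cycles_are_2020(self):
        grid = TimeGrid(2020, 2021)
        incs = [(k, {("first", "drug"): 1.0}) for k in range(15)]
        ledger = aggregate_annual(incs, grid)
        assert ledger.annual_total(2020) == 14.0  # cycles 0..13 (day 364)
        assert ledger.annual_total(2021) == 1.0

    def test_empty_run_gives_zero_ledger(self):
        ledger = aggregate_annual([], TimeGrid(2020, 2020))
        assert ledger.grand_total() == 0.0
        assert ledger.cells == {}


class TestCompareScenarios:
    @staticmethod
    def _ledger(values):
        ledger = CostLedger()
        for y, v in values.items():
            ledger.add(y, "first", "drug", v)
        return ledger

    def test_identical_ledgers_zero_difference(self):
        a = self._ledger({2020: 10.0, 2021: 20.0})
        b = self._ledger({2020: 10.0, 2021: 20.0})
        rep = compare_scenarios(a, b)
        assert rep["savings_total"] == 0.0
        assert rep["savings_percent"] == 0.0

    def test_percent_definition(self):
        fixed = self._ledger({2020: 94.0})
        cont = self._ledger({2020: 100.0})
        rep = compare_scenarios(fixed, cont)
        assert rep["savings_total"] == pytest.approx(6.0)
        assert rep["savings_percent"] == pytest.approx(6.0)

    def test_horizon_mismatch_rejected(self):
        with pytest.raises(ValueError, match="horizons"):
            compare_scenarios(self._ledger({2020: 1.0}),
                              self._ledger({2021: 1.0}))


def test_ledger_linearity_in_unit_costs():
    """Scaling every unit cost (and drug schedules) by c scales every
    ledger cell by exactly c — occupancy trajectories are cost-free."""
    ctx = toy_context(p_prog1=0.02, p_prog2=0.02, p_os=0.05,
                      cost1=100.0, cost2=40.0,
                      ae_profile1={"neutropenia": 0.3})
    base = run_projection(ctx, None, FIXED).ledger
    scaled_ctx = ctx.copy()
    scaled_ctx.params.unit_costs = {
        k: 3.0 * v for k, v in ctx.params.unit_costs.items()
    }
    scaled_ctx.params = scaled_ctx.params.copy(
        palliative_care_cost=3.0 * ctx.params.palliative_care_cost
    )
    scaled_ctx.drug_cost_multipliers = {"T1": 3.0, "T2": 3.0}
    scaled = run_projection(scaled_ctx, None, FIXED).ledger
    assert set(scaled.cells) == set(base.cells)
    for key, v in base.cells.items():
        assert scaled.cells[key] == pytest.approx(3.0 * v, rel=1e-12)


def test_continuous_drug_cost_matches_geometric_closed_form():
    """Per-entrant drug cost for a continuous regimen with per-cycle
    cost d and total exit probability q equals d/q (geometric
    time-on-treatment)."""
    d, p_bg, p_prog, p_disc = 1000.0, 0.05, 0.08, 0.02
    q = 1.0 - (1.0 - p_bg) * (1.0 - p_prog) * (1.0 - p_disc)
    years = (2020, 2029)
    incidence = {y: 0.0 for y in range(2020, 2030)}
    incidence[2020] = 1000.0
    ctx = toy_context(
        p_prog1=p_prog, cost1=d, years=years, incidence=incidence,
        p_ww_at_diagnosis=0.0,
        p_ww_to_tx_per_cycle=0.0,
        p_background_death_per_cycle=p_bg,
        p_discontinue_1L_per_cycle=p_disc,
        p_discontinue_2L_per_cycle=0.0,
    )
    res = run_projection(ctx, None, FIXED)
    drug = sum(v for (y, ln, cat), v in res.ledger.cells.items()
               if ln == "first" and cat == "drug")
    assert drug / 1000.0 == pytest.approx(d / q, rel=1e-6)


def test_per_cycle_ae_basis_scales_with_duration():
    profile = {"neutropenia": 0.3}
    ctx = toy_context(p_prog1=0.02, ae_profile1=profile)
    per_course = run_projection(ctx, None, FIXED).ledger
    ctx2 = ctx.copy()
    ctx2.options.ae_cost_basis = "per_cycle"
    per_cycle = run_projection(ctx2, None, FIXED).ledger
    ae = lambda led: sum(v for (y, ln, cat), v in led.cells.items()
                         if cat == "ae")
    assert ae(per_cycle) > ae(per_course)


def test_monitoring_schedule_round_trip(tmp_path):
    sch = MonitoringSchedule(panels_per_cycle_ww=0.25)
    path = tmp_path / "schedule.yaml"
    sch.save(path)
    assert MonitoringSchedule.load(path) == sch
    with pytest.raises(ValueError, match="nurse_minutes_per_infusion"):
        MonitoringSchedule(nurse_minutes_per_infusion=-1).validate()
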