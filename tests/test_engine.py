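"""Cohort engine: sequential within-cycle risks, conservation, runs."""

import numpy as np
import pytest
from _toys import ALL_RISKS_OFF, toy_context

from cllburden.context import run_projection, run_scenario, run_warmup
from cllburden.policy import CONTINUOUS, FIXED
from cllburden.states import STRATA


def test_step_applies_sequential_risks_to_watchful_waiting():
    """1000 in WW with background death 0.695%/cycle and WW->treatment
    1.65%/cycle: death first (6.95), then initiation among survivors
    (0.0165 x 993.05 = 16.385), remainder stays in WW."""
    ctx = toy_context(
        p_background_death_per_cycle=0.00695,
        p_ww_to_tx_per_cycle=0.0165,
        p_discontinue_1L_per_cycle=0.0,
        p_discontinue_2L_per_cycle=0.0,
    )
    engine = ctx.engine(FIXED)
    sv = engine.empty_state()
    sv.ww[0] = 1000.0
    sv.entrants = 1000.0
    flows = engine.step(sv, 2020)
    assert flows.deaths == pytest.approx(6.95, abs=1e-9)
    assert sv.l1.sum() == pytest.approx(0.0165 * 993.05, abs=1e-9)
    assert sv.ww.sum() == pytest.approx(993.05 - 0.0165 * 993.05, abs=1e-9)
    sv.check_conservation()


def test_step_identity_when_all_probabilities_zero():
    ctx = toy_context(**ALL_RISKS_OFF)
    engine = ctx.engine(FIXED)
    sv = engine.empty_state()
    sv.ww[2] = 50.0
    sv.l1[1, 0, 3] = 20.0
    sv.pall[0, 0] = 5.0
    sv.entrants = 75.0
    before_l1 = sv.l1.copy()
    engine.step(sv, 2020)
    assert sv.ww[2] == 50.0
    assert sv.pall[0, 0] == 5.0
    # tunnel advances but the mass is untouched
    assert sv.l1.sum() == pytest.approx(20.0)
    assert sv.l1[1, 0, 4] == pytest.approx(before_l1[1, 0, 3])
    assert sv.dead == 0.0


def test_certain_background_death_absorbs_at_risk_mass():
    ctx = toy_context(p_background_death_per_cycle=1.0)
    engine = ctx.engine(FIXED)
    sv = engine.empty_state()
    sv.ww[0] = 10.0
    sv.l1[0, 0, 2] = 7.0
    sv.l2[0, 0, 1] = 3.0
    sv.entrants = 20.0
    engine.step(sv, 2020)
    assert sv.total_alive == pytest.approx(0.0, abs=1e-12)
    assert sv.dead == pytest.approx(20.0)


def test_mass_conserved_over_full_default_horizon(default_ctx):
    """Warm-up plus projection is 210 cycles; the engine checks the
    total-mass identity to 1e-9 (relative) every cycle and the final
    balance holds."""
    res = run_scenario(default_ctx, FIXED)
    n_cycles = (default_ctx.warmup_grid.n_cycles
                + default_ctx.projection_grid.n_cycles)
    assert n_cycles >= 200
    sv = res.sv_final
    assert abs(sv.total - sv.entrants) <= 1e-9 * sv.entrants


def test_constant_incidence_no_exits_accumulates_exactly():
    ctx = toy_context(**ALL_RISKS_OFF)
    res = run_projection(ctx, None, FIXED)
    assert res.trace["prevalence"].tolist() == pytest.approx(
        [1000.0, 2000.0, 3000.0]
    )
    assert res.trace["ww"].iloc[-1] == pytest.approx(3000.0 * 0.85)


def test_zero_incidence_prevalence_never_increases(default_ctx):
    warm = run_warmup(default_ctx)
    ctx = default_ctx.copy()
    ctx.incidence = {y: 0.0 for y in ctx.projection_grid.years}
    res = run_projection(ctx, warm.sv, FIXED)
    prev = res.trace["prevalence"].to_numpy()
    assert (np.diff(prev) <= 0).all()


def test_baseline_prevalence_strictly_increases(both_results):
    res_f, res_c, _ = both_results
    for res in (res_f, res_c):
        assert (np.diff(res.trace["prevalence"].to_numpy()) > 0).all()


def test_identical_policies_give_identical_traces_and_ledgers():
    ctx = toy_context(p_prog1=0.02, p_prog2=0.03, p_os=0.05,
                      cost1=100.0, cost2=50.0)
    res_f = run_projection(ctx, None, FIXED)
    res_c = run_projection(ctx, None, CONTINUOUS)
    assert res_f.trace.equals(res_c.trace)
    assert res_f.ledger.cells == res_c.ledger.cells


def test_missing_incidence_year_is_an_input_error(default_ctx):
    ctx = default_ctx.copy()
    del ctx.incidence[2015]
    with pytest.raises(ValueError, match="2015"):
        run_warmup(ctx)


def test_fixed_course_mass_moves_off_drug():
    """A 6-cycle course: after the course every survivor sits in the
    off-drug pool, still progressing at the trial PFS rate."""
    ctx = toy_context(duration_class="cit_course", max_cycles=6,
                      p_prog1=0.01, cost1=100.0,
                      p_ww_at_diagnosis=0.0, **ALL_RISKS_OFF)
    res = run_projection(ctx, None, FIXED)
    sv = res.sv
    assert sv.l1.sum() < sv.first_line  # someone has completed
    # on-drug mass only occupies tunnel positions 0..5
    assert sv.l1[:, :, 6:].sum() == 0.0
    # and drug cost stops after 6 cycles: per-entrant drug cost can only
    # fall short of the full-course cost (progression), never exceed it
    drug = sum(v for (y, ln, cat), v in res.ledger.cells.items()
               if ln == "first" and cat == "drug")
    assert drug <= 600.0 * sv.entrants + 1e-6


def test_cycle_records_export(default_ctx):
    ctx = default_ctx.copy()
    ctx.projection_years = (2020, 2020)
    warm = run_warmup(ctx)
    res = run_projection(ctx, warm.sv, FIXED, record_cycles=True)
    df = res.cycle_records
    assert set(df.columns) == {"cycle", "year", "state", "stratum",
                               "regimen", "cycles_on_treatment", "count"}
    assert (df["count"] > 0).all()
    total = df[df.cycle == df.cycle.max()]["count"].sum()
    assert total == pytest.approx(res.trace["prevalence"].iloc[-1])
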