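"""Individual-level Monte-Carlo simulator mirroring the cohort rules.

Used as an independent oracle: each simulated patient advances
cycle-by-cycle drawing Bernoulli events with exactly the probabilities
and within-cycle event order of the cohort engine (background death,
then initiation/progression, then discontinuation, palliative death
from the last second-line regimen's OS; movers enter the new state at
tunnel 0 and accrue that state's cycle-1 costs in the transition
cycle).  Patient-level aggregates divided by n are then unbiased
estimates of the cohort fractions, with binomial / sample standard
errors for every observable.

Randomness layout: one PCG64 stream seeded by the master seed, drawn as
fixed-size per-patient blocks (4 entry draws + 4 draws per cycle) in
fixed 50,000-patient chunks, so patient i's draws do not depend on the
total cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .context import ModelContext
from .params import TimeGrid, stratum_probabilities
from .registry import (
    FIRST,
    SECOND,
    drug_cost_for_cycle,
    expected_ae_cost,
    infusions_for_cycle,
)
from .states import STRATA

CHUNK_SIZE = 50_000
ENTRY_DRAWS = 4
CYCLE_DRAWS = 4

# state codes
WW, L1, L2, PALL, DEAD = 0, 1, 2, 3, 4
STATE_LABELS = {WW: "ww", L1: "first_line", L2: "second_line",
                PALL: "palliative", DEAD: "dead"}
_LINES = ("first", "second", "other")
_CATS = ("drug", "monitoring", "administration", "ae", "palliative")
_LI = {ln: i for i, ln in enumerate(_LINES)}
_CI = {c: i for i, c in enumerate(_CATS)}


@dataclass
class MicrosimResult:
    n: int
    seed: int
    scenario: str
    total_entrant_mass: float
    #: columns: year, state, mean (fraction of patients), se
    occupancy: pd.DataFrame
    #: columns: line, category, mean (CAD per patient), se
    costs: pd.DataFrame
    total_cost_mean: float
    total_cost_se: float
    patients: Optional[pd.DataFrame] = None

    def occupancy_lookup(self, year: int, state: str) -> tuple[float, float]:
        row = self.occupancy[(self.occupancy.year == year)
                             & (self.occupancy.state == state)]
        return float(row["mean"].iloc[0]), float(row["se"].iloc[0])

    def cost_lookup(self, line: str, category: str) -> tuple[float, float]:
        row = self.costs[(self.costs.line == line)
                         & (self.costs.category == category)]
        if row.empty:
            return 0.0, 0.0
        return float(row["mean"].iloc[0]), float(row["se"].iloc[0])


class _Compiled:
    """Probability/cost lookups built directly from the configuration
    (shares, trial summaries, schedules) without touching the cohort
    engine's compiled matrices."""

    def __init__(self, ctx: ModelContext, scenario: str, grid: TimeGrid):
        params = ctx.params
        params.validate()
        if ctx.options.discontinue_destination != "off_drug":
            raise NotImplementedError(
                "the micro-simulation oracle validates the default "
                "off-drug discontinuation handling only"
            )
        policy = ctx.policy(scenario)
        reg = ctx.registry
        cd = float(params.cycle_days)
        T_tun = ctx.options.tunnel_cap
        self.grid = grid
        self.years = grid.years

        self.r1 = reg.names(FIRST)
        self.r2 = reg.names(SECOND)
        S, R1, R2 = len(STRATA), len(self.r1), len(self.r2)

        self.p_bg = params.p_background_death_per_cycle
        self.p_wt = params.p_ww_to_tx_per_cycle
        self.p_d1 = params.p_discontinue_1L_per_cycle
        self.p_d2 = params.p_discontinue_2L_per_cycle
        self.p_ww = params.p_ww_at_diagnosis

        self.prog1 = np.zeros((S, R1))
        self.prog2 = np.zeros((S, R2))
        self.osd = np.zeros((S, R2))
        for i, s in enumerate(STRATA):
            for j, n in enumerate(self.r1):
                self.prog1[i, j] = reg.get(FIRST, n).efficacy_pfs.per_cycle_prob(s, cd)
            for j, n in enumerate(self.r2):
                r = reg.get(SECOND, n)
                self.prog2[i, j] = r.efficacy_pfs.per_cycle_prob(s, cd)
                self.osd[i, j] = r.efficacy_os.per_cycle_prob(s, cd)

        mult = ctx.drug_cost_multipliers

        def _cost_arrays(names, line):
            R = len(names)
            drug = np.zeros((R, T_tun))
            infus = np.zeros((R, T_tun))
            on = np.zeros((R, T_tun), dtype=bool)
            disc = np.zeros((R, T_tun), dtype=bool)
            ae = np.zeros(R)
            for j, name in enumerate(names):
                r = reg.get(line, name)
                m = mult.get(name, 1.0)
                for t in range(T_tun):
                    drug[j, t] = m * drug_cost_for_cycle(r, t + 1)
                    infus[j, t] = infusions_for_cycle(r, t + 1)
                drug[j, 0] += m * r.ramp_up_cost
                limit = T_tun if r.max_cycles is None else min(r.max_cycles, T_tun)
                on[j, :limit] = True
                if r.duration_class in ("continuous_ott", "fixed_ott"):
                    disc[j, :limit] = True
                ae[j] = expected_ae_cost(r, params.unit_costs)
            return drug, infus, on, disc, ae

        self.drug1, self.infus1, self.on1, self.discm1, self.ae1 = \
            _cost_arrays(self.r1, FIRST)
        self.drug2, self.infus2, self.on2, self.discm2, self.ae2 = \
            _cost_arrays(self.r2, SECOND)
        self.t_cap = T_tun - 1

        sch = ctx.schedule
        uc = params.unit_costs
        from .params import FULL_LAB_PANEL

        self.panel = sum(uc[k] for k in FULL_LAB_PANEL)
        self.panel_on = self.panel * sch.panels_per_cycle_on_treatment
        self.panel_off = self.panel * sch.panels_per_cycle_ww
        self.admin_inf = (uc["infusion_administration"]
                          + sch.nurse_minutes_per_infusion * uc["nurse_wage_per_min"])
        self.pharm = sch.pharmacist_minutes_per_cycle * uc["pharmacist_wage_per_min"]
        self.partial = (sch.partial_assessments_per_year
                        / (365.25 / params.cycle_days)) * uc["partial_assessment"]
        self.consult = sch.consults_per_initiation * uc["consult_hematology"]
        self.pall_cost = params.palliative_care_cost
        self.per_course_ae = ctx.options.ae_cost_basis == "per_course"

        # entry machinery
        inc = np.array([float(ctx.incidence.get(y, 0.0)) for y in self.years])
        if inc.sum() <= 0:
            raise ValueError("incidence over the grid must be positive")
        self.total_entrants = float(inc.sum())
        self.cum_year = np.cumsum(inc) / inc.sum()
        self.cycles_by_year = [np.array(grid.cycles_in_year(y)) for y in self.years]
        self.year_end_cycle = np.array([c[-1] for c in self.cycles_by_year])
        self.strata_cum = np.cumsum(stratum_probabilities(params))

        # cumulative share tables per (year index, stratum)
        def _cum_shares(line, names):
            idx = {n: j for j, n in enumerate(names)}
            out = np.zeros((len(self.years), S, len(names)))
            for yi, y in enumerate(self.years):
                for si, s in enumerate(STRATA):
                    for name, w in policy.shares(y, line, s).items():
                        out[yi, si, idx[name]] = w
            return np.cumsum(out, axis=2)

        self.cum_sh1 = _cum_shares(FIRST, self.r1)
        self.cum_sh2 = _cum_shares(SECOND, self.r2)


def _pick(cum_rows: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF choice per row: smallest j with cum[j] > u."""
    return (cum_rows < u[:, None]).sum(axis=1)


def simulate_cohort(
    n: int,
    seed: int,
    ctx: ModelContext,
    scenario: str = "fixed",
    grid: Optional[TimeGrid] = None,
    collect_patients: bool = False,
) -> MicrosimResult:
    """Simulate ``n`` independent patients through the pathway."""
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = grid or ctx.projection_grid
    c = _Compiled(ctx, scenario, grid)
    T = grid.n_cycles
    n_years = len(c.years)
    yi_of_cycle = np.array([c.years.index(grid.year_of_cycle(k))
                            for k in range(T)])

    rng = np.random.default_rng(seed)
    occ_counts = np.zeros((n_years, 5))
    cost_sum = np.zeros((3, 5))
    cost_sq = np.zeros((3, 5))
    total_sum = 0.0
    total_sq = 0.0
    patient_rows = [] if collect_patients else None

    done = 0
    while done < n:
        m = min(CHUNK_SIZE, n - done)
        U = rng.random((CHUNK_SIZE, ENTRY_DRAWS + T * CYCLE_DRAWS))[:m]
        occ, costs = _run_chunk(c, grid, T, yi_of_cycle, U, patient_rows)
        occ_counts += occ
        tot = costs.sum(axis=(1, 2))
        cost_sum += costs.sum(axis=0)
        cost_sq += (costs**2).sum(axis=0)
        total_sum += tot.sum()
        total_sq += (tot**2).sum()
        done += m

    occ_rows = []
    for yi, y in enumerate(c.years):
        for code, label in STATE_LABELS.items():
            p = occ_counts[yi, code] / n
            se = float(np.sqrt(max(p * (1.0 - p), 0.0) / n))
            occ_rows.append({"year": y, "state": label, "mean": p, "se": se})
    cost_rows = []
    for ln, li in _LI.items():
        for cat, ci in _CI.items():
            mean = cost_sum[li, ci] / n
            var = max(cost_sq[li, ci] / n - mean**2, 0.0)
            cost_rows.append({"line": ln, "category": cat, "mean": mean,
                              "se": float(np.sqrt(var / n))})
    tmean = total_sum / n
    tvar = max(total_sq / n - tmean**2, 0.0)
    return MicrosimResult(
        n=n,
        seed=seed,
        scenario=scenario,
        total_entrant_mass=c.total_entrants,
        occupancy=pd.DataFrame(occ_rows),
        costs=pd.DataFrame(cost_rows),
        total_cost_mean=tmean,
        total_cost_se=float(np.sqrt(tvar / n)),
        patients=pd.DataFrame(patient_rows) if collect_patients else None,
    )


def _run_chunk(c: _Compiled, grid: TimeGrid, T: int, yi_of_cycle, U,
               patient_rows) -> tuple[np.ndarray, np.ndarray]:
    m = U.shape[0]
    # entry assignment from the 4 leading draws
    u_year, u_strat, u_state, u_reg = U[:, 0], U[:, 1], U[:, 2], U[:, 3]
    year_idx = (c.cum_year < u_year[:, None]).sum(axis=1)
    # reuse the year draw's within-band remainder for the cycle choice
    lo = np.concatenate(([0.0], c.cum_year))[year_idx]
    band = c.cum_year[year_idx] - lo
    frac = np.where(band > 0, (u_year - lo) / np.where(band > 0, band, 1.0), 0.0)
    entry_cycle = np.empty(m, dtype=np.int64)
    for yi in range(len(c.years)):
        sel = year_idx == yi
        cyc = c.cycles_by_year[yi]
        entry_cycle[sel] = cyc[
            np.minimum((frac[sel] * len(cyc)).astype(np.int64), len(cyc) - 1)
        ]
    sidx = (c.strata_cum < u_strat[:, None]).sum(axis=1)
    direct = u_state >= c.p_ww
    entry_reg = np.full(m, -1, dtype=np.int64)
    for yi in range(len(c.years)):
        sel = direct & (year_idx == yi)
        if sel.any():
            entry_reg[sel] = _pick(c.cum_sh1[yi][sidx[sel]], u_reg[sel])

    state = np.full(m, -1, dtype=np.int8)  # -1 = not yet entered
    reg = np.full(m, -1, dtype=np.int64)
    od = np.zeros(m, dtype=bool)  # currently accruing drug cost
    tun = np.zeros(m, dtype=np.int64)
    pall_reg = np.full(m, -1, dtype=np.int64)
    costs = np.zeros((m, 3, 5))
    occ = np.zeros((len(c.years), 5))
    death_cycle = np.full(m, -1, dtype=np.int64)

    for k in range(T):
        yi = yi_of_cycle[k]
        base = ENTRY_DRAWS + k * CYCLE_DRAWS
        uD = U[:, base]
        uT = U[:, base + 1]
        uS = U[:, base + 2]
        uC = U[:, base + 3]

        active = state >= 0
        prev_state = state.copy()
        prev_reg = reg.copy()
        init1 = np.zeros(m, dtype=bool)
        init2 = np.zeros(m, dtype=bool)
        pall_entry = np.zeros(m, dtype=bool)
        switched = np.zeros(m, dtype=bool)

        # watchful waiting: background death, then initiation
        mask = active & (prev_state == WW)
        die = mask & (uD < c.p_bg)
        state[die] = DEAD
        start = mask & ~die & (uT < c.p_wt)
        if start.any():
            state[start] = L1
            reg[start] = _pick(c.cum_sh1[yi][sidx[start]], uC[start])
            tun[start] = 0
            od[start] = True
            switched[start] = True
            init1[start] = True

        # first line: death, progression, then OTT discontinuation
        mask = active & (prev_state == L1)
        die = mask & (uD < c.p_bg)
        state[die] = DEAD
        rest = mask & ~die
        if rest.any():
            pp = np.zeros(m)
            pp[rest] = c.prog1[sidx[rest], prev_reg[rest]]
            prog = rest & (uT < pp)
            if prog.any():
                state[prog] = L2
                reg[prog] = _pick(c.cum_sh2[yi][sidx[prog]], uC[prog])
                tun[prog] = 0
                od[prog] = True
                switched[prog] = True
                init2[prog] = True
            eligible = np.zeros(m, dtype=bool)
            eligible[rest] = c.discm1[prev_reg[rest],
                                      np.minimum(tun[rest], c.t_cap)]
            disc = rest & ~prog & od & eligible & (uS < c.p_d1)
            od[disc] = False  # drug stops; state and PFS risk continue

        # second line: death, progression -> palliative, discontinuation
        mask = active & (prev_state == L2)
        die = mask & (uD < c.p_bg)
        state[die] = DEAD
        rest = mask & ~die
        if rest.any():
            pp = np.zeros(m)
            pp[rest] = c.prog2[sidx[rest], prev_reg[rest]]
            prog = rest & (uT < pp)
            if prog.any():
                state[prog] = PALL
                pall_reg[prog] = prev_reg[prog]
                switched[prog] = True
                pall_entry[prog] = True
            eligible = np.zeros(m, dtype=bool)
            eligible[rest] = c.discm2[prev_reg[rest],
                                      np.minimum(tun[rest], c.t_cap)]
            disc = rest & ~prog & od & eligible & (uS < c.p_d2)
            od[disc] = False

        # palliative: OS-derived death
        mask = active & (prev_state == PALL)
        if mask.any():
            po = np.zeros(m)
            po[mask] = c.osd[sidx[mask], pall_reg[mask]]
            die = mask & (uD < po)
            state[die] = DEAD

        death_cycle[(state == DEAD) & (death_cycle < 0)] = k

        # advance the tunnel for stayers
        stay = active & ~switched & (state == prev_state) & \
            ((state == L1) | (state == L2))
        tun[stay] += 1

        # incident entrants arrive at the end of the cycle
        newly = entry_cycle == k
        if newly.any():
            ww_new = newly & ~direct
            state[ww_new] = WW
            d_new = newly & direct
            state[d_new] = L1
            reg[d_new] = entry_reg[d_new]
            tun[d_new] = 0
            od[d_new] = True
            init1[d_new] = True

        # accrual on the post-transition population
        tt = np.minimum(tun, c.t_cap)
        for code, li, drug, infus, on, ae in (
            (L1, _LI["first"], c.drug1, c.infus1, c.on1, c.ae1),
            (L2, _LI["second"], c.drug2, c.infus2, c.on2, c.ae2),
        ):
            sel = state == code
            if not sel.any():
                continue
            r, t = reg[sel], tt[sel]
            on_sel = on[r, t] & od[sel]
            costs[sel, li, _CI["drug"]] += drug[r, t] * on_sel
            costs[sel, li, _CI["administration"]] += (
                infus[r, t] * c.admin_inf + on_sel * c.pharm
            ) * on_sel
            costs[sel, li, _CI["monitoring"]] += (
                np.where(on_sel, c.panel_on, c.panel_off) + c.partial
            )
            if not c.per_course_ae:
                costs[sel, li, _CI["ae"]] += on_sel * ae[r]
        for flag, li, names_ae in ((init1, _LI["first"], c.ae1),
                                   (init2, _LI["second"], c.ae2)):
            if flag.any():
                costs[flag, li, _CI["monitoring"]] += c.consult
                if c.per_course_ae:
                    costs[flag, li, _CI["ae"]] += names_ae[reg[flag]]
        ww_sel = state == WW
        costs[ww_sel, _LI["other"], _CI["monitoring"]] += c.panel_off + c.partial
        costs[pall_entry, _LI["other"], _CI["palliative"]] += c.pall_cost

        if k == c.year_end_cycle[yi]:
            present = state >= 0
            for code in range(5):
                occ[yi, code] += int(((state == code) & present).sum())

    if patient_rows is not None:
        for i in range(m):
            patient_rows.append({
                "entry_cycle": int(entry_cycle[i]),
                "stratum": STRATA[sidx[i]].key,
                "entered_on_treatment": bool(direct[i]),
                "final_state": STATE_LABELS[int(state[i])] if state[i] >= 0
                else "not_entered",
                "death_cycle": int(death_cycle[i]),
                "total_cost": float(costs[i].sum()),
            })
    return occ, costs
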