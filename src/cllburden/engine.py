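"""Deterministic cohort engine over 28-day cycles.

The state vector holds expected person-counts indexed by health state,
stratum, regimen and cycles-on-treatment (a tunnel dimension so that
cycle-indexed drug costs and fixed durations can be applied), with
separate off-drug pools per line and regimen for patients who finished
or discontinued therapy but have not progressed.  Within a cycle, risks
are applied sequentially per occupied cell:

1. background death (watchful waiting, first line, responding relapse);
2. WW -> first-line initiation, regimen assigned by the year's policy;
3. progression at the regimen's PFS-derived probability, on or off drug
   (first line -> second-line assignment; second line -> palliative);
4. OTT discontinuation (0.70%/1.40% per cycle in first/second line)
   moves on-drug mass to the line's off-drug pool by default — drug
   cost stops, the trial PFS keeps driving progression — or routes it
   like progression under the ``next_line`` option;
5. palliative -> death at the OS-derived probability of the last
   second-line regimen;
6. cycles-on-treatment advance for on-drug stayers; mass completing a
   finite course moves to the off-drug pool (costs stop, trial efficacy
   — which spans post-treatment follow-up — is retained).

Incident patients enter at the end of their entry cycle (85% watchful
waiting, 15% straight to first line) and face their first transition
risks in the following cycle.  Everything is an expectation: the engine
draws no random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .params import BaselineParameters, TimeGrid, stratum_probabilities
from .policy import AllocationPolicy
from .registry import FIRST, SECOND, Registry, RegistryError
from .states import STRATA

#: relative mass-conservation tolerance checked every cycle
CONSERVATION_RTOL = 1e-9


class EngineError(RuntimeError):
    pass


@dataclass
class ModelOptions:
    """Behavioural switches the published description leaves open."""

    #: where OTT discontinuers go: "off_drug" (stay in the line with
    #: drug-cost accrual stopped, progressing at the trial PFS rate) or
    #: "next_line" (first line -> second-line assignment, second line ->
    #: palliative, i.e. discontinuation treated as line exit)
    discontinue_destination: str = "off_drug"
    #: "per_course" charges the expected AE cost once at initiation;
    #: "per_cycle" charges it every on-drug cycle (inflates with duration)
    ae_cost_basis: str = "per_course"
    #: tunnel length; continuous-therapy cells pool at the cap (must
    #: exceed the longest finite course)
    tunnel_cap: int = 40

    def validate(self) -> None:
        if self.discontinue_destination not in ("off_drug", "next_line"):
            raise ValueError(
                f"discontinue_destination must be 'off_drug' or 'next_line', "
                f"got {self.discontinue_destination!r}"
            )
        if self.ae_cost_basis not in ("per_course", "per_cycle"):
            raise ValueError("ae_cost_basis must be 'per_course' or 'per_cycle'")
        if self.tunnel_cap < 28:
            raise ValueError("tunnel_cap must cover the longest finite course")


@dataclass
class StateVector:
    """Expected person-counts by cell plus cumulative deaths/entrants.

    ``l1``/``l2`` are on-treatment tunnels (stratum x regimen x
    cycles-on-treatment); ``l1_off``/``l2_off`` hold course completers
    and discontinuers still in the line; ``pall`` is keyed by the
    second-line regimen whose OS drives palliative mortality.
    """

    ww: np.ndarray      # (S,)
    l1: np.ndarray      # (S, R1, T)
    l1_off: np.ndarray  # (S, R1)
    l2: np.ndarray      # (S, R2, T)
    l2_off: np.ndarray  # (S, R2)
    pall: np.ndarray    # (S, R2)
    dead: float = 0.0
    entrants: float = 0.0

    @classmethod
    def empty(cls, n_strata: int, n_r1: int, n_r2: int, tunnel: int) -> "StateVector":
        return cls(
            ww=np.zeros(n_strata),
            l1=np.zeros((n_strata, n_r1, tunnel)),
            l1_off=np.zeros((n_strata, n_r1)),
            l2=np.zeros((n_strata, n_r2, tunnel)),
            l2_off=np.zeros((n_strata, n_r2)),
            pall=np.zeros((n_strata, n_r2)),
        )

    def copy(self) -> "StateVector":
        return StateVector(
            self.ww.copy(), self.l1.copy(), self.l1_off.copy(),
            self.l2.copy(), self.l2_off.copy(), self.pall.copy(),
            self.dead, self.entrants,
        )

    @property
    def first_line(self) -> float:
        return float(self.l1.sum() + self.l1_off.sum())

    @property
    def second_line(self) -> float:
        return float(self.l2.sum() + self.l2_off.sum())

    @property
    def on_drug(self) -> float:
        return float(self.l1.sum() + self.l2.sum())

    @property
    def total_alive(self) -> float:
        return float(self.ww.sum()) + self.first_line + self.second_line \
            + float(self.pall.sum())

    @property
    def total(self) -> float:
        return self.total_alive + self.dead

    def check_conservation(self, rtol: float = CONSERVATION_RTOL) -> None:
        gap = abs(self.total - self.entrants)
        if gap > rtol * max(1.0, self.entrants):
            raise EngineError(
                f"mass not conserved: |alive + dead - entrants| = {gap:.3e} "
                f"for {self.entrants:.6f} entrants"
            )
        for a in (self.ww, self.l1, self.l1_off, self.l2, self.l2_off, self.pall):
            if (a < -1e-12).any():
                raise EngineError("negative occupancy encountered")


@dataclass
class Flows:
    """Within-cycle mass flows needed by the cost accountant."""

    init1: np.ndarray       # (S, R1) mass starting a first-line regimen
    init2: np.ndarray       # (S, R2) mass starting a second-line regimen
    pall_entries: float     # mass entering the palliative state
    deaths: float
    entrants: float


@dataclass
class RunResult:
    trace: pd.DataFrame           # indexed by calendar year
    sv: StateVector
    ledger: Optional[object] = None      # CostLedger when costing enabled
    cycle_records: Optional[pd.DataFrame] = None


def _shift_tunnel(a: np.ndarray) -> None:
    """Advance cycles-on-treatment in place, pooling at the cap."""
    tail = a[..., -1].copy()
    a[..., 1:] = a[..., :-1]
    a[..., 0] = 0.0
    a[..., -1] += tail


class CohortEngine:
    """Compiled transition machinery for one policy and parameter set."""

    def __init__(
        self,
        params: BaselineParameters,
        registry: Registry,
        policy: AllocationPolicy,
        options: Optional[ModelOptions] = None,
    ):
        params.validate()
        self.params = params
        self.registry = registry
        self.policy = policy
        self.options = options or ModelOptions()
        self.options.validate()

        self.strata = STRATA
        self.r1_names = registry.names(FIRST)
        self.r2_names = registry.names(SECOND)
        S, R1, R2 = len(self.strata), len(self.r1_names), len(self.r2_names)
        T = self.options.tunnel_cap

        self.stratum_probs = stratum_probabilities(params)

        cd = float(params.cycle_days)
        self.prog1 = np.zeros((S, R1))
        for j, name in enumerate(self.r1_names):
            reg = registry.get(FIRST, name)
            for i, s in enumerate(self.strata):
                self.prog1[i, j] = reg.efficacy_pfs.per_cycle_prob(s, cd)
        self.prog2 = np.zeros((S, R2))
        self.os_death = np.zeros((S, R2))
        for j, name in enumerate(self.r2_names):
            reg = registry.get(SECOND, name)
            if reg.efficacy_os is None:
                raise RegistryError(
                    f"second-line regimen {name} needs an OS summary to "
                    "drive palliative mortality"
                )
            for i, s in enumerate(self.strata):
                self.prog2[i, j] = reg.efficacy_pfs.per_cycle_prob(s, cd)
                self.os_death[i, j] = reg.efficacy_os.per_cycle_prob(s, cd)

        def _masks(names, line):
            disc = np.zeros((len(names), T), dtype=bool)
            complete = np.zeros((len(names), T), dtype=bool)
            for j, name in enumerate(names):
                reg = registry.get(line, name)
                if reg.max_cycles is not None and reg.max_cycles < T:
                    complete[j, reg.max_cycles] = True
                limit = T if reg.max_cycles is None else min(reg.max_cycles, T)
                if reg.duration_class in ("continuous_ott", "fixed_ott"):
                    disc[j, :limit] = True
            return disc, complete

        self.disc1, self.complete1 = _masks(self.r1_names, FIRST)
        self.disc2, self.complete2 = _masks(self.r2_names, SECOND)
        self.shape = (S, R1, R2, T)
        self._share_cache: dict[tuple[int, str], np.ndarray] = {}

    # -- policy resolution --------------------------------------------
    def shares_matrix(self, year: int, line: str) -> np.ndarray:
        key = (year, line)
        if key not in self._share_cache:
            names = self.r1_names if line == FIRST else self.r2_names
            idx = {n: j for j, n in enumerate(names)}
            m = np.zeros((len(self.strata), len(names)))
            for i, s in enumerate(self.strata):
                for name, w in self.policy.shares(year, line, s).items():
                    if name not in idx:
                        raise EngineError(
                            f"policy names {name!r} which is not a {line}-line "
                            "regimen in the registry"
                        )
                    m[i, idx[name]] = w
            self._share_cache[key] = m
        return self._share_cache[key]

    def empty_state(self) -> StateVector:
        S, R1, R2, T = self.shape
        return StateVector.empty(S, R1, R2, T)

    # -- one cycle -----------------------------------------------------
    def step(self, sv: StateVector, year: int,
             incidence_per_cycle: float = 0.0) -> Flows:
        p = self.params
        pd_ = p.p_background_death_per_cycle
        shares1 = self.shares_matrix(year, FIRST)
        shares2 = self.shares_matrix(year, SECOND)
        to_next = self.options.discontinue_destination == "next_line"

        # 1. background death
        deaths = pd_ * (sv.ww.sum() + sv.l1.sum() + sv.l1_off.sum()
                        + sv.l2.sum() + sv.l2_off.sum())
        sv.ww *= 1.0 - pd_
        sv.l1 *= 1.0 - pd_
        sv.l1_off *= 1.0 - pd_
        sv.l2 *= 1.0 - pd_
        sv.l2_off *= 1.0 - pd_

        # 2. treatment initiation from watchful waiting
        started = sv.ww * p.p_ww_to_tx_per_cycle
        sv.ww = sv.ww - started
        new1 = started[:, None] * shares1

        # 3. progression, on and off drug
        out1 = sv.l1 * self.prog1[:, :, None]
        sv.l1 -= out1
        out1_off = sv.l1_off * self.prog1
        sv.l1_off -= out1_off
        to_second = out1.sum(axis=(1, 2)) + out1_off.sum(axis=1)
        out2 = sv.l2 * self.prog2[:, :, None]
        sv.l2 -= out2
        out2_off = sv.l2_off * self.prog2
        sv.l2_off -= out2_off
        pall_in = out2.sum(axis=2) + out2_off  # (S, R2)

        # 4. OTT discontinuation (survivors of progression, on drug)
        disc_out1 = sv.l1 * self.disc1[None] * p.p_discontinue_1L_per_cycle
        sv.l1 -= disc_out1
        disc_out2 = sv.l2 * self.disc2[None] * p.p_discontinue_2L_per_cycle
        sv.l2 -= disc_out2
        if to_next:
            to_second = to_second + disc_out1.sum(axis=(1, 2))
            pall_in = pall_in + disc_out2.sum(axis=2)
        else:
            sv.l1_off += disc_out1.sum(axis=2)
            sv.l2_off += disc_out2.sum(axis=2)

        # 5. palliative death (occupants at cycle start; entrants arrive below)
        pall_deaths = sv.pall * self.os_death
        sv.pall -= pall_deaths
        deaths += pall_deaths.sum()

        # 6. advance tunnels; completed finite courses move off drug;
        #    this cycle's movers land at tunnel position 0
        _shift_tunnel(sv.l1)
        _shift_tunnel(sv.l2)
        done1 = sv.l1 * self.complete1[None]
        sv.l1 -= done1
        sv.l1_off += done1.sum(axis=2)
        done2 = sv.l2 * self.complete2[None]
        sv.l2 -= done2
        sv.l2_off += done2.sum(axis=2)
        new2 = to_second[:, None] * shares2
        sv.l1[:, :, 0] += new1
        sv.l2[:, :, 0] += new2
        sv.pall += pall_in

        # incident entrants arrive at the end of the cycle
        init1 = new1
        if incidence_per_cycle > 0.0:
            entry = incidence_per_cycle * self.stratum_probs
            sv.ww += entry * p.p_ww_at_diagnosis
            direct = (entry * (1.0 - p.p_ww_at_diagnosis))[:, None] * shares1
            sv.l1[:, :, 0] += direct
            init1 = new1 + direct

        sv.dead += deaths
        sv.entrants += incidence_per_cycle
        return Flows(
            init1=init1,
            init2=new2,
            pall_entries=float(pall_in.sum()),
            deaths=float(deaths),
            entrants=float(incidence_per_cycle),
        )

    # -- multi-year runs -----------------------------------------------
    def run(
        self,
        grid: TimeGrid,
        incidence: Mapping[int, float],
        sv0: Optional[StateVector] = None,
        cost_model=None,
        record_cycles: bool = False,
    ) -> RunResult:
        """Evolve the cohort across ``grid``, adding ``incidence[year]``
        entrants spread evenly over each year's cycles."""
        sv = sv0.copy() if sv0 is not None else self.empty_state()
        ledger = cost_model.new_ledger() if cost_model is not None else None

        per_cycle_inc = {}
        last_cycle_of_year = {}
        for y in grid.years:
            cycles = grid.cycles_in_year(y)
            per_cycle_inc[y] = float(incidence.get(y, 0.0)) / len(cycles)
            last_cycle_of_year[y] = cycles[-1]

        rows = []
        cyc_rows = [] if record_cycles else None
        deaths_y = 0.0
        entrants_y = 0.0
        for k in range(grid.n_cycles):
            year = grid.year_of_cycle(k)
            flows = self.step(sv, year, per_cycle_inc[year])
            sv.check_conservation()
            deaths_y += flows.deaths
            entrants_y += flows.entrants
            if cost_model is not None:
                cost_model.accrue(sv, flows, ledger, year)
            if record_cycles:
                cyc_rows.extend(self._cycle_records(sv, k, year))
            if k == last_cycle_of_year[year]:
                rows.append(self._annual_row(sv, year, deaths_y, entrants_y))
                deaths_y = 0.0
                entrants_y = 0.0

        trace = pd.DataFrame(rows).set_index("year")
        cyc = pd.DataFrame(cyc_rows) if record_cycles else None
        return RunResult(trace=trace, sv=sv, ledger=ledger, cycle_records=cyc)

    def _annual_row(self, sv: StateVector, year: int,
                    deaths: float, entrants: float) -> dict:
        return {
            "year": year,
            "prevalence": sv.total_alive,
            "ww": float(sv.ww.sum()),
            "first_line": sv.first_line,
            "second_line": sv.second_line,
            "palliative": float(sv.pall.sum()),
            "on_drug": sv.on_drug,
            "deaths": deaths,
            "entrants": entrants,
            "dead_cum": sv.dead,
        }

    def _cycle_records(self, sv: StateVector, cycle: int, year: int) -> list[dict]:
        rows = []

        def row(state, stratum, regimen, tunnel, count):
            return {"cycle": cycle, "year": year, "state": state,
                    "stratum": stratum, "regimen": regimen,
                    "cycles_on_treatment": tunnel, "count": float(count)}

        for i, s in enumerate(self.strata):
            if sv.ww[i] > 0:
                rows.append(row("ww", s.key, "", -1, sv.ww[i]))
            for arrs, offs, names, label in (
                (sv.l1, sv.l1_off, self.r1_names, "first_line"),
                (sv.l2, sv.l2_off, self.r2_names, "second_line"),
            ):
                for j, name in enumerate(names):
                    for t in np.nonzero(arrs[i, j] > 0)[0]:
                        rows.append(row(label, s.key, name, int(t), arrs[i, j, t]))
                    if offs[i, j] > 0:
                        rows.append(row(label + "_off_drug", s.key, name, -1,
                                        offs[i, j]))
            ptot = float(sv.pall[i].sum())
            if ptot > 0:
                rows.append(row("palliative", s.key, "", -1, ptot))
        return rows
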