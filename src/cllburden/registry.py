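"""Treatment regimens: efficacy, adverse events, cost and administration.

Each regimen carries the published trial PFS (and, in second line, OS)
summary, grade 3/4 adverse-event incidences per treatment course, a
cycle-indexed drug-cost schedule in 2020 CAD, an infusion schedule, and
a duration class:

* ``cit_course``     -- chemoimmunotherapy, a fixed 6-cycle course;
* ``continuous_ott`` -- oral targeted therapy until progression or
  discontinuation (unbounded constant-cost tail);
* ``fixed_ott``      -- venetoclax-based fixed-duration therapy
  (VO 13 cycles ~ 12 months, VR 26 cycles ~ 24 months plus a ramp-up
  charge); drug cost stops at completion but the trial PFS, which spans
  post-treatment follow-up, keeps driving progression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import yaml

from .states import StratumPredicate
from .survival import EfficacySummary

FIRST = "first"
SECOND = "second"
LINES = (FIRST, SECOND)

DURATION_CLASSES = ("cit_course", "continuous_ott", "fixed_ott")

AE_NAMES = (
    "anemia",
    "neutropenia",
    "febrile_neutropenia",
    "thrombocytopenia",
    "infection",
    "atrial_fibrillation",
)


class RegistryError(ValueError):
    pass


@dataclass(frozen=True)
class RegimenSpec:
    name: str
    line: str  # "first" | "second"
    duration_class: str
    #: (start_cycle, end_cycle_or_None, CAD per cycle), 1-based inclusive
    cost_schedule: tuple[tuple[int, Optional[int], float], ...]
    efficacy_pfs: EfficacySummary
    efficacy_os: Optional[EfficacySummary] = None
    ae_profile: dict[str, float] = field(default_factory=dict)
    #: (start_cycle, end_cycle_or_None, infusions per cycle)
    infusions: tuple[tuple[int, Optional[int], float], ...] = ()
    max_cycles: Optional[int] = None  # None = unbounded (continuous)
    ramp_up_cost: float = 0.0
    oral_only: bool = False

    def __post_init__(self) -> None:
        if self.line not in LINES:
            raise RegistryError(f"{self.name}: unknown line {self.line!r}")
        if self.duration_class not in DURATION_CLASSES:
            raise RegistryError(
                f"{self.name}: unknown duration class {self.duration_class!r}"
            )
        if self.duration_class == "continuous_ott":
            if self.max_cycles is not None:
                raise RegistryError(f"{self.name}: continuous OTT is unbounded")
        elif self.max_cycles is None or self.max_cycles < 1:
            raise RegistryError(f"{self.name}: finite regimen needs max_cycles >= 1")
        for name, rate in self.ae_profile.items():
            if name not in AE_NAMES:
                raise RegistryError(f"{self.name}: unknown adverse event {name!r}")
            if not (0.0 <= rate <= 1.0):
                raise RegistryError(f"{self.name}: AE rate for {name} not in [0, 1]")
        for start, end, cost in self.cost_schedule:
            if cost < 0:
                raise RegistryError(f"{self.name}: negative drug cost")
            if start < 1 or (end is not None and end < start):
                raise RegistryError(f"{self.name}: bad cycle range ({start}, {end})")
        # schedule must cover cycles 1..max_cycles without gaps
        horizon = self.max_cycles or max(
            (s for s, _, _ in self.cost_schedule), default=1
        )
        for c in range(1, horizon + 1):
            if not any(
                s <= c and (e is None or c <= e) for s, e, _ in self.cost_schedule
            ):
                raise RegistryError(
                    f"{self.name}: cost schedule has a gap at cycle {c}"
                )


def _lookup(schedule, cycle_index: int) -> float:
    for start, end, value in schedule:
        if start <= cycle_index and (end is None or cycle_index <= end):
            return value
    return 0.0


def drug_cost_for_cycle(regimen: RegimenSpec, cycle_index: int) -> float:
    """Scheduled drug cost (CAD) for 1-based on-treatment ``cycle_index``;
    0 beyond ``max_cycles`` for finite regimens."""
    if cycle_index < 1:
        raise ValueError(f"cycle_index must be >= 1, got {cycle_index}")
    if regimen.max_cycles is not None and cycle_index > regimen.max_cycles:
        return 0.0
    return _lookup(regimen.cost_schedule, cycle_index)


def infusions_for_cycle(regimen: RegimenSpec, cycle_index: int) -> float:
    if cycle_index < 1:
        raise ValueError(f"cycle_index must be >= 1, got {cycle_index}")
    if regimen.max_cycles is not None and cycle_index > regimen.max_cycles:
        return 0.0
    return _lookup(regimen.infusions, cycle_index)


def course_drug_cost(regimen: RegimenSpec) -> float:
    """Total drug cost of a complete finite course (ramp-up included)."""
    if regimen.max_cycles is None:
        raise RegistryError(
            f"{regimen.name} is continuous; accrue per cycle instead of "
            "summing an unbounded schedule"
        )
    return regimen.ramp_up_cost + sum(
        drug_cost_for_cycle(regimen, c) for c in range(1, regimen.max_cycles + 1)
    )


def expected_ae_cost(regimen: RegimenSpec, unit_costs: dict[str, float]) -> float:
    """Expected grade 3/4 adverse-event management cost per treatment
    course: sum of incidence x unit cost, charged once at initiation."""
    total = 0.0
    for name in sorted(regimen.ae_profile):  # fixed order: bit-stable sums
        rate = regimen.ae_profile[name]
        if name not in unit_costs:
            raise RegistryError(f"no unit cost configured for adverse event {name!r}")
        total += rate * unit_costs[name]
    return total


class Registry:
    """Keyed collection of :class:`RegimenSpec`, unique per (line, name)."""

    def __init__(self, regimens: list[RegimenSpec]):
        self._by_key: dict[tuple[str, str], RegimenSpec] = {}
        for r in regimens:
            key = (r.line, r.name)
            if key in self._by_key:
                raise RegistryError(f"duplicate regimen {key}")
            self._by_key[key] = r

    def get(self, line: str, name: str) -> RegimenSpec:
        try:
            return self._by_key[(line, name)]
        except KeyError:
            raise RegistryError(f"no regimen {name!r} in {line} line") from None

    def has(self, line: str, name: str) -> bool:
        return (line, name) in self._by_key

    def names(self, line: str) -> list[str]:
        return [n for (ln, n) in self._by_key if ln == line]

    def regimens(self, line: Optional[str] = None) -> list[RegimenSpec]:
        return [r for r in self._by_key.values() if line is None or r.line == line]

    def __len__(self) -> int:
        return len(self._by_key)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        out = []
        for r in self._by_key.values():
            d = {
                "name": r.name,
                "line": r.line,
                "duration_class": r.duration_class,
                "cost_schedule": [
                    [int(s), None if e is None else int(e), float(c)]
                    for s, e, c in r.cost_schedule
                ],
                "efficacy_pfs": r.efficacy_pfs.to_dict(),
                "ae_profile": {k: float(v) for k, v in r.ae_profile.items()},
                "oral_only": r.oral_only,
            }
            if r.efficacy_os is not None:
                d["efficacy_os"] = r.efficacy_os.to_dict()
            if r.infusions:
                d["infusions"] = [
                    [int(s), None if e is None else int(e), float(v)]
                    for s, e, v in r.infusions
                ]
            if r.max_cycles is not None:
                d["max_cycles"] = int(r.max_cycles)
            if r.ramp_up_cost:
                d["ramp_up_cost"] = float(r.ramp_up_cost)
            out.append(d)
        return {"regimens": out}

    @classmethod
    def from_dict(cls, d: dict) -> "Registry":
        regs = []
        for rd in d["regimens"]:
            regs.append(
                RegimenSpec(
                    name=rd["name"],
                    line=rd["line"],
                    duration_class=rd["duration_class"],
                    cost_schedule=tuple(
                        (int(s), None if e is None else int(e), float(c))
                        for s, e, c in rd["cost_schedule"]
                    ),
                    efficacy_pfs=EfficacySummary.from_dict(rd["efficacy_pfs"]),
                    efficacy_os=(
                        EfficacySummary.from_dict(rd["efficacy_os"])
                        if "efficacy_os" in rd
                        else None
                    ),
                    ae_profile=dict(rd.get("ae_profile", {})),
                    infusions=tuple(
                        (int(s), None if e is None else int(e), float(v))
                        for s, e, v in rd.get("infusions", ())
                    ),
                    max_cycles=rd.get("max_cycles"),
                    ramp_up_cost=float(rd.get("ramp_up_cost", 0.0)),
                    oral_only=bool(rd.get("oral_only", False)),
                )
            )
        return cls(regs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "Registry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _p(**kw) -> StratumPredicate:
    from .states import AgeGroup

    if "age_group" in kw and isinstance(kw["age_group"], str):
        kw["age_group"] = AgeGroup(kw["age_group"])
    return StratumPredicate(**kw)


def default_registry() -> Registry:
    """The 16 modelled regimens with their published parameters."""
    E = EfficacySummary
    first = [
        RegimenSpec(
            "GClb", FIRST, "cit_course",
            cost_schedule=((1, 1, 16497.0), (2, 6, 5541.0)),
            efficacy_pfs=E.median(29.8),
            ae_profile={"anemia": 0.04, "neutropenia": 0.33,
                        "thrombocytopenia": 0.10, "infection": 0.12},
            infusions=((1, 1, 3.0), (2, 6, 1.0)),
            max_cycles=6,
        ),
        RegimenSpec(
            "FCR", FIRST, "cit_course",
            cost_schedule=((1, 1, 3067.0), (2, 6, 3769.0)),
            efficacy_pfs=E.landmark(
                0.43, 5.0,
                overrides=(
                    (_p(ighv_mutated=True), E.landmark(0.67, 5.0)),
                    (_p(ighv_mutated=False), E.landmark(0.33, 5.0)),
                    (_p(age_group="under_65"), E.landmark(0.48, 5.0)),
                ),
            ),
            ae_profile={"anemia": 0.06, "neutropenia": 0.30,
                        "thrombocytopenia": 0.09, "infection": 0.24},
            infusions=((1, 6, 1.0),),
            max_cycles=6,
        ),
        RegimenSpec(
            "FR", FIRST, "cit_course",
            cost_schedule=((1, 1, 3194.0), (2, 6, 3896.0)),
            efficacy_pfs=E.median(42.0),
            ae_profile={"anemia": 0.40, "neutropenia": 0.76,
                        "thrombocytopenia": 0.20, "infection": 0.20},
            infusions=((1, 6, 1.0),),
            max_cycles=6,
        ),
        RegimenSpec(
            "F", FIRST, "cit_course",
            cost_schedule=((1, 6, 1089.0),),
            efficacy_pfs=E.median(19.0),
            ae_profile={"anemia": 0.15, "neutropenia": 0.12,
                        "thrombocytopenia": 0.15, "infection": 0.80},
            infusions=((1, 6, 1.0),),
            max_cycles=6,
        ),
        RegimenSpec(
            "BR", FIRST, "cit_course",
            cost_schedule=((1, 1, 6357.0), (2, 6, 7059.0)),
            efficacy_pfs=E.median(43.0),
            ae_profile={"anemia": 0.31, "neutropenia": 0.31,
                        "thrombocytopenia": 0.35, "infection": 0.12},
            infusions=((1, 6, 2.0),),
            max_cycles=6,
        ),
        RegimenSpec(
            "Clb", FIRST, "cit_course",
            cost_schedule=((1, 1, 264.30), (2, 6, 176.20)),
            efficacy_pfs=E.median(15.0),
            ae_profile={"anemia": 0.27, "neutropenia": 0.12,
                        "thrombocytopenia": 0.20, "infection": 0.04},
            max_cycles=6,
            oral_only=True,
        ),
        RegimenSpec(
            "ibrutinib", FIRST, "continuous_ott",
            cost_schedule=((1, None, 8198.0),),
            efficacy_pfs=E.landmark(
                0.70, 5.0,
                overrides=(
                    (_p(del17p=True), E.landmark(0.56, 5.0)),
                    (_p(ighv_mutated=True), E.landmark(0.81, 5.0)),
                    (_p(ighv_mutated=False), E.landmark(0.67, 5.0)),
                ),
            ),
            ae_profile={"anemia": 0.06, "neutropenia": 0.10,
                        "thrombocytopenia": 0.02, "infection": 0.06,
                        "atrial_fibrillation": 0.06},
            oral_only=True,
        ),
        RegimenSpec(
            "ACAL", FIRST, "continuous_ott",
            cost_schedule=((1, None, 7615.0),),
            efficacy_pfs=E.landmark(0.87, 2.0),
            ae_profile={"anemia": 0.07, "neutropenia": 0.10,
                        "thrombocytopenia": 0.05, "infection": 0.05},
            oral_only=True,
        ),
        RegimenSpec(
            "VO", FIRST, "fixed_ott",
            cost_schedule=((1, 1, 16532.0), (2, 2, 9153.0),
                           (3, 6, 13318.0), (7, 13, 7840.0)),
            efficacy_pfs=E.landmark(
                0.82, 3.0,
                overrides=(
                    (_p(del17p=True), E.landmark(0.49, 3.0)),
                    (_p(ighv_mutated=True), E.landmark(0.87, 3.0)),
                    (_p(ighv_mutated=False), E.landmark(0.81, 3.0)),
                ),
            ),
            ae_profile={"anemia": 0.08, "neutropenia": 0.53,
                        "febrile_neutropenia": 0.05,
                        "thrombocytopenia": 0.14, "infection": 0.18},
            infusions=((1, 1, 3.0), (2, 6, 1.0)),
            max_cycles=13,
        ),
    ]
    second = [
        RegimenSpec(
            "F", SECOND, "cit_course",
            cost_schedule=((1, 6, 1089.0),),
            efficacy_pfs=E.median(14.8),
            efficacy_os=E.median(41.0),
            ae_profile={"anemia": 0.80, "neutropenia": 0.17,
                        "thrombocytopenia": 0.60, "infection": 0.15},
            infusions=((1, 6, 1.0),),
            max_cycles=6,
        ),
        RegimenSpec(
            "FCR", SECOND, "cit_course",
            cost_schedule=((1, 1, 3067.0), (2, 6, 3769.0)),
            efficacy_pfs=E.median(28.0),
            efficacy_os=E.median(42.0),
            ae_profile={"anemia": 0.24, "neutropenia": 0.81,
                        "thrombocytopenia": 0.34, "infection": 0.16},
            infusions=((1, 6, 1.0),),
            max_cycles=6,
        ),
        RegimenSpec(
            "ibrutinib", SECOND, "continuous_ott",
            cost_schedule=((1, None, 8198.0),),
            efficacy_pfs=E.median(
                44.1,
                overrides=(
                    (_p(del17p=True), E.median(40.6)),
                    (_p(ighv_mutated=True), E.median(48.4)),
                    (_p(ighv_mutated=False), E.median(49.7)),
                ),
            ),
            efficacy_os=E.median(
                67.7, overrides=((_p(del17p=True), E.median(61.8)),)
            ),
            ae_profile={"anemia": 0.0, "neutropenia": 0.18,
                        "thrombocytopenia": 0.10, "infection": 0.51,
                        "atrial_fibrillation": 0.06},
            oral_only=True,
        ),
        RegimenSpec(
            "BR", SECOND, "cit_course",
            cost_schedule=((1, 1, 6357.0), (2, 6, 7059.0)),
            efficacy_pfs=E.landmark(0.17, 2.0),
            efficacy_os=E.landmark(0.62, 5.0),
            ae_profile={"anemia": 0.14, "neutropenia": 0.39,
                        "thrombocytopenia": 0.10, "infection": 0.22},
            infusions=((1, 6, 2.0),),
            max_cycles=6,
        ),
        RegimenSpec(
            "ACAL", SECOND, "continuous_ott",
            cost_schedule=((1, None, 7615.0),),
            efficacy_pfs=E.landmark(0.88, 1.0),
            efficacy_os=E.landmark(0.94, 1.0),
            ae_profile={"anemia": 0.07, "neutropenia": 0.14,
                        "febrile_neutropenia": 0.02,
                        "thrombocytopenia": 0.02, "infection": 0.01,
                        "atrial_fibrillation": 0.02},
            oral_only=True,
        ),
        RegimenSpec(
            "venetoclax", SECOND, "continuous_ott",
            cost_schedule=((1, 1, 1813.0), (2, None, 7840.0)),
            efficacy_pfs=E.median(
                24.7, overrides=((_p(del17p=True), E.landmark(0.54, 2.0)),)
            ),
            efficacy_os=E.landmark(
                0.91, 1.0, overrides=((_p(del17p=True), E.landmark(0.73, 2.0)),)
            ),
            ae_profile={"anemia": 0.29, "neutropenia": 0.51,
                        "febrile_neutropenia": 0.13,
                        "thrombocytopenia": 0.29, "infection": 0.11},
            oral_only=True,
        ),
        RegimenSpec(
            "VR", SECOND, "fixed_ott",
            cost_schedule=((1, 1, 9945.0), (2, 6, 10647.0), (7, 26, 7840.0)),
            efficacy_pfs=E.median(
                53.6,
                overrides=(
                    (_p(del17p=True), E.median(45.3)),
                    (_p(del17p=False), E.median(56.6)),
                ),
            ),
            efficacy_os=E.landmark(0.82, 5.0),
            ae_profile={"anemia": 0.11, "neutropenia": 0.58,
                        "febrile_neutropenia": 0.04,
                        "thrombocytopenia": 0.06, "infection": 0.18},
            infusions=((1, 6, 1.0),),
            max_cycles=26,
            ramp_up_cost=3773.0,
        ),
    ]
    return Registry(first + second)
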