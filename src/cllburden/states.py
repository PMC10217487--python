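"""Health states and patient strata.

The disease pathway is a forward-only chain

    watchful waiting -> first-line -> relapsed/refractory -> palliative -> dead

with death reachable from every alive state.  Patients are stratified at
model entry by age group, fitness, del(17p)/TP53 status and (for
non-del(17p) patients) IGHV mutation status; the stratum never changes.
del(17p) patients are not further split by IGHV because treatment choice
branches on del(17p) first, so there are 18 strata:
3 age groups x fit/unfit x (del17p | IGHV-mutated | IGHV-unmutated).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional


class HealthState(Enum):
    WATCHFUL_WAITING = "watchful_waiting"
    FIRST_LINE = "first_line"
    RELAPSED_REFRACTORY = "relapsed_refractory"
    PALLIATIVE = "palliative"
    DEAD = "dead"


#: forward-only ordering; transitions never target an earlier state
STATE_ORDER = (
    HealthState.WATCHFUL_WAITING,
    HealthState.FIRST_LINE,
    HealthState.RELAPSED_REFRACTORY,
    HealthState.PALLIATIVE,
    HealthState.DEAD,
)


class AgeGroup(str, Enum):
    UNDER_65 = "under_65"
    FROM_65_TO_70 = "65_70"
    OVER_70 = "over_70"


AGE_GROUPS = (AgeGroup.UNDER_65, AgeGroup.FROM_65_TO_70, AgeGroup.OVER_70)


@dataclass(frozen=True)
class Stratum:
    """Fixed patient characteristics assigned at model entry.

    ``ighv_mutated`` is ``None`` for del(17p) patients: they are not
    split by IGHV status (del(17p) dominates treatment choice).
    """

    age_group: AgeGroup
    fit: bool
    del17p: bool
    ighv_mutated: Optional[bool]

    def __post_init__(self) -> None:
        if self.del17p and self.ighv_mutated is not None:
            raise ValueError("del(17p) strata are not split by IGHV status")
        if not self.del17p and self.ighv_mutated is None:
            raise ValueError("non-del(17p) strata require an IGHV status")

    @property
    def key(self) -> str:
        if self.del17p:
            mark = "del17p"
        else:
            mark = "ighv_mut" if self.ighv_mutated else "ighv_unmut"
        return f"{self.age_group.value}/{'fit' if self.fit else 'unfit'}/{mark}"


def enumerate_strata() -> tuple[Stratum, ...]:
    """All 18 strata in a fixed, documented order (age, fitness, marker)."""
    out = []
    for age in AGE_GROUPS:
        for fit in (True, False):
            out.append(Stratum(age, fit, True, None))
            out.append(Stratum(age, fit, False, True))
            out.append(Stratum(age, fit, False, False))
    return tuple(out)


STRATA = enumerate_strata()
STRATUM_INDEX = {s: i for i, s in enumerate(STRATA)}


@dataclass(frozen=True)
class StratumPredicate:
    """Partial match on stratum fields; ``None`` fields are wildcards.

    A predicate constraining ``ighv_mutated`` never matches a del(17p)
    stratum (whose IGHV status is undefined).
    """

    age_group: Optional[AgeGroup] = None
    fit: Optional[bool] = None
    del17p: Optional[bool] = None
    ighv_mutated: Optional[bool] = None

    def matches(self, s: Stratum) -> bool:
        if self.age_group is not None and s.age_group != self.age_group:
            return False
        if self.fit is not None and s.fit != self.fit:
            return False
        if self.del17p is not None and s.del17p != self.del17p:
            return False
        if self.ighv_mutated is not None:
            if s.ighv_mutated is None or s.ighv_mutated != self.ighv_mutated:
                return False
        return True

    def to_dict(self) -> dict:
        d = {}
        if self.age_group is not None:
            d["age_group"] = self.age_group.value
        if self.fit is not None:
            d["fit"] = self.fit
        if self.del17p is not None:
            d["del17p"] = self.del17p
        if self.ighv_mutated is not None:
            d["ighv_mutated"] = self.ighv_mutated
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StratumPredicate":
        age = d.get("age_group")
        return cls(
            age_group=AgeGroup(age) if age is not None else None,
            fit=d.get("fit"),
            del17p=d.get("del17p"),
            ighv_mutated=d.get("ighv_mutated"),
        )


ANY_STRATUM = StratumPredicate()
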