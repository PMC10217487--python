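"""Time-varying treatment-allocation policies.

A policy is an ordered rule list mapping (calendar year, treatment line,
stratum) to regimen shares; the first matching rule wins.  The shipped
defaults reconstruct the Canadian reimbursement timeline — CIT before
2015, ibrutinib entering second line in 2015 and first-line high-risk
use in 2016-2018, acalabrutinib from 2019, VR from 2020, VO from 2021 —
with deterministic stratum-to-regimen assignment (the published mix
percentages are not recoverable, so the mix is configuration).  The two
scenarios share the 2010-2019 warm-up rules and differ from 2020-2021
onward: the *fixed* scenario routes the OTT-eligible share to
venetoclax-based fixed-duration regimens (VO first line, VR second),
the *continuous* scenario keeps it on ibrutinib/acalabrutinib.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import yaml

from .params import TimeGrid
from .registry import FIRST, LINES, SECOND, Registry
from .states import STRATA, Stratum, StratumPredicate

FIXED = "fixed"
CONTINUOUS = "continuous"
SCENARIOS = (FIXED, CONTINUOUS)

#: first year each regimen may be assigned, by (line, name); unlisted
#: regimens are available from the start of the horizon
AVAILABILITY: dict[tuple[str, str], int] = {
    (SECOND, "ibrutinib"): 2015,
    (FIRST, "ibrutinib"): 2016,
    (FIRST, "ACAL"): 2019,
    (SECOND, "ACAL"): 2019,
    (SECOND, "venetoclax"): 2016,
    (SECOND, "VR"): 2020,
    (FIRST, "VO"): 2021,
    (FIRST, "GClb"): 2015,
}


class PolicyError(ValueError):
    pass


@dataclass(frozen=True)
class PolicyRule:
    years: tuple[int, int]  # inclusive calendar-year span
    line: str
    predicate: StratumPredicate
    shares: dict[str, float]

    def applies(self, year: int, line: str, stratum: Stratum) -> bool:
        return (
            self.years[0] <= year <= self.years[1]
            and self.line == line
            and self.predicate.matches(stratum)
        )

    def to_dict(self) -> dict:
        return {
            "years": [int(self.years[0]), int(self.years[1])],
            "line": self.line,
            "predicate": self.predicate.to_dict(),
            "shares": {k: float(v) for k, v in self.shares.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolicyRule":
        return cls(
            years=(int(d["years"][0]), int(d["years"][1])),
            line=d["line"],
            predicate=StratumPredicate.from_dict(d.get("predicate", {})),
            shares=dict(d["shares"]),
        )


@dataclass
class AllocationPolicy:
    scenario: str
    rules: list[PolicyRule] = field(default_factory=list)

    def shares(self, year: int, line: str, stratum: Stratum) -> dict[str, float]:
        """Regimen shares for a patient starting ``line`` in ``year``."""
        for rule in self.rules:
            if rule.applies(year, line, stratum):
                total = sum(rule.shares.values())
                if abs(total - 1.0) > 1e-9:
                    raise PolicyError(
                        f"shares for ({year}, {line}, {stratum.key}) sum to "
                        f"{total:.6f}, not 1"
                    )
                return dict(rule.shares)
        raise PolicyError(
            f"no allocation rule matches ({year}, {line}, {stratum.key})"
        )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {"scenario": self.scenario,
                "rules": [r.to_dict() for r in self.rules]}

    @classmethod
    def from_dict(cls, d: dict) -> "AllocationPolicy":
        return cls(
            scenario=d["scenario"],
            rules=[PolicyRule.from_dict(r) for r in d["rules"]],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "AllocationPolicy":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def validate_policy(
    policy: AllocationPolicy,
    registry: Registry,
    grid: TimeGrid,
    strata: Optional[tuple[Stratum, ...]] = None,
) -> list[str]:
    """Check the full (year x line x stratum) grid; returns violations
    (empty list iff the policy is valid over the horizon)."""
    violations: list[str] = []
    strata = strata or STRATA
    for year in grid.years:
        for line in LINES:
            for s in strata:
                try:
                    shares = policy.shares(year, line, s)
                except PolicyError as exc:
                    violations.append(str(exc))
                    continue
                for name, w in shares.items():
                    if w < 0:
                        violations.append(
                            f"negative share for {name} at ({year}, {line}, {s.key})"
                        )
                    if not registry.has(line, name):
                        violations.append(
                            f"regimen {name!r} not in registry for {line} line "
                            f"(rule at year {year})"
                        )
                        continue
                    avail = AVAILABILITY.get((line, name))
                    if avail is not None and year < avail and w > 0:
                        violations.append(
                            f"{name} assigned in {line} line in {year}, before "
                            f"its {avail} availability"
                        )
    # deduplicate, preserving order
    seen: set[str] = set()
    out = []
    for v in violations:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def _r(y0, y1, line, shares, **pred) -> PolicyRule:
    from .states import AgeGroup

    if "age_group" in pred and isinstance(pred["age_group"], str):
        pred["age_group"] = AgeGroup(pred["age_group"])
    return PolicyRule((y0, y1), line, StratumPredicate(**pred), shares)


def _warmup_rules() -> list[PolicyRule]:
    """2010-2019 treatment algorithm, shared by both scenarios."""
    return [
        # first line: del(17p) — CIT-resistant; chlorambucil until
        # ibrutinib's first-line high-risk entry
        _r(2010, 2016, FIRST, {"Clb": 1.0}, del17p=True),
        _r(2017, 2019, FIRST, {"ibrutinib": 1.0}, del17p=True),
        # young fit IGHV-unmutated move to ibrutinib as of 2018
        _r(2018, 2019, FIRST, {"ibrutinib": 1.0}, fit=True, ighv_mutated=False),
        _r(2010, 2019, FIRST, {"FCR": 1.0}, fit=True, age_group="under_65"),
        _r(2010, 2019, FIRST, {"BR": 1.0}, fit=True),
        _r(2010, 2014, FIRST, {"Clb": 1.0}),
        _r(2015, 2019, FIRST, {"GClb": 1.0}),
        # second line: CIT until ibrutinib's 2015 relapsed entry
        _r(2010, 2014, SECOND, {"FCR": 1.0}, fit=True),
        _r(2010, 2014, SECOND, {"BR": 1.0}),
        _r(2015, 2019, SECOND, {"ibrutinib": 1.0}),
    ]


def _continuous_projection_rules() -> list[PolicyRule]:
    """2020-2025, continuous-OTT scenario: ibrutinib expands to all
    IGHV-unmutated first-line patients from 2021."""
    return [
        _r(2020, 2025, FIRST, {"ibrutinib": 1.0}, del17p=True),
        _r(2020, 2020, FIRST, {"ibrutinib": 1.0}, fit=True, ighv_mutated=False),
        _r(2021, 2025, FIRST, {"ibrutinib": 1.0}, ighv_mutated=False),
        _r(2020, 2025, FIRST, {"FCR": 1.0}, fit=True, age_group="under_65"),
        _r(2020, 2025, FIRST, {"BR": 1.0}, fit=True),
        _r(2020, 2025, FIRST, {"GClb": 1.0}),
        _r(2020, 2025, SECOND, {"venetoclax": 1.0}, del17p=True),
        _r(2020, 2025, SECOND, {"ibrutinib": 0.8, "ACAL": 0.2}),
    ]


def _fixed_projection_rules() -> list[PolicyRule]:
    """2020-2025, fixed-OTT scenario: the IGHV-unmutated first-line
    share that the continuous scenario gives to ibrutinib moves to VO
    once VO is reimbursed (late 2021), and the relapsed ibrutinib share
    moves to VR (reimbursed 2020).  del(17p) patients stay on BTK
    inhibition in both scenarios."""
    return [
        _r(2020, 2025, FIRST, {"ibrutinib": 1.0}, del17p=True),
        # 2020: VO not yet available — same first-line mix as continuous
        _r(2020, 2020, FIRST, {"ibrutinib": 1.0}, fit=True, ighv_mutated=False),
        _r(2021, 2025, FIRST, {"VO": 1.0}, ighv_mutated=False),
        _r(2020, 2025, FIRST, {"FCR": 1.0}, fit=True, age_group="under_65"),
        _r(2020, 2025, FIRST, {"BR": 1.0}, fit=True),
        _r(2020, 2025, FIRST, {"GClb": 1.0}),
        _r(2020, 2025, SECOND, {"venetoclax": 1.0}, del17p=True),
        # VR reimbursement lands during 2020; modelled uptake from 2021,
        # so the two scenarios' 2020 rules — and 2020 costs — coincide
        _r(2020, 2020, SECOND, {"ibrutinib": 0.8, "ACAL": 0.2}),
        _r(2021, 2025, SECOND, {"VR": 0.8, "ACAL": 0.2}),
    ]


def default_policy(scenario: str) -> AllocationPolicy:
    """Shipped 2010-2025 policy for ``scenario`` ("fixed"/"continuous").

    Reconstructed from the reimbursement timeline, not a verbatim copy
    of any published mix.
    """
    if scenario not in SCENARIOS:
        raise PolicyError(f"unknown scenario {scenario!r}; expected {SCENARIOS}")
    rules = _warmup_rules()
    if scenario == CONTINUOUS:
        rules += _continuous_projection_rules()
    else:
        rules += _fixed_projection_rules()
    return AllocationPolicy(scenario=scenario, rules=rules)
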