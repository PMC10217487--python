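"""Conversion of published survival summaries to per-cycle probabilities.

Trials report PFS/OS as medians (months) or landmark survival fractions
(e.g. 5-year PFS 70%).  Under a constant-hazard (exponential) assumption
the per-28-day-cycle event probability follows in closed form:

    from a median m (months):    p = 1 - 0.5 ** (cycle_days / (m * 30.4375))
    from survival S(t) at t yrs: p = 1 - S ** (cycle_days / (t * 365.25))

A month is 365.25/12 = 30.4375 days, consistent with the 365.25-day year
used by the cycle grid.  :class:`EfficacySummary` wraps one summary with
optional stratum-specific overrides (del(17p) first, then IGHV, then
age), mirroring how trial subgroup results are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .params import DAYS_PER_MONTH, DAYS_PER_YEAR
from .states import Stratum, StratumPredicate


def per_cycle_prob_from_median(
    median_months: float,
    cycle_days: float = 28.0,
    days_per_month: float = DAYS_PER_MONTH,
) -> float:
    """Per-cycle event probability from a median time-to-event in months."""
    if median_months <= 0:
        raise ValueError(f"median_months must be positive, got {median_months!r}")
    return 1.0 - 0.5 ** (cycle_days / (median_months * days_per_month))


def per_cycle_prob_from_landmark(
    fraction: float, t_years: float, cycle_days: float = 28.0
) -> float:
    """Per-cycle event probability from event-free survival ``fraction``
    observed at ``t_years``."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"landmark fraction must be in (0, 1], got {fraction!r}")
    if t_years <= 0:
        raise ValueError(f"t_years must be positive, got {t_years!r}")
    return 1.0 - fraction ** (cycle_days / (t_years * DAYS_PER_YEAR))


def annual_prob_to_cycle(p_annual: float, cycle_days: float = 28.0) -> float:
    """Convert an annual event probability to the per-cycle equivalent."""
    if not (0.0 <= p_annual <= 1.0):
        raise ValueError(f"p_annual must be in [0, 1], got {p_annual!r}")
    return 1.0 - (1.0 - p_annual) ** (cycle_days / DAYS_PER_YEAR)


@dataclass(frozen=True)
class EfficacySummary:
    """One published PFS or OS summary, with subgroup overrides.

    ``overrides`` are consulted in order before the pooled summary;
    list them del(17p) first, then IGHV status, then age/fitness.
    """

    kind: str  # "median_months" | "landmark"
    median_months: Optional[float] = None
    landmark_fraction: Optional[float] = None
    landmark_years: Optional[float] = None
    overrides: tuple[tuple[StratumPredicate, "EfficacySummary"], ...] = field(
        default_factory=tuple
    )

    def __post_init__(self) -> None:
        if self.kind == "median_months":
            if self.median_months is None or self.median_months <= 0:
                raise ValueError("median_months must be positive")
        elif self.kind == "landmark":
            if self.landmark_fraction is None or not (
                0.0 < self.landmark_fraction <= 1.0
            ):
                raise ValueError("landmark_fraction must be in (0, 1]")
            if self.landmark_years is None or self.landmark_years <= 0:
                raise ValueError("landmark_years must be positive")
        else:
            raise ValueError(f"unknown summary kind {self.kind!r}")

    @classmethod
    def median(cls, months: float, overrides=()) -> "EfficacySummary":
        return cls("median_months", median_months=months,
                   overrides=tuple(overrides))

    @classmethod
    def landmark(cls, fraction: float, years: float, overrides=()) -> "EfficacySummary":
        return cls("landmark", landmark_fraction=fraction,
                   landmark_years=years, overrides=tuple(overrides))

    def resolve(self, stratum: Optional[Stratum]) -> "EfficacySummary":
        """The summary applying to ``stratum`` (pooled if none matches)."""
        if stratum is not None:
            for pred, summ in self.overrides:
                if pred.matches(stratum):
                    return summ.resolve(stratum)
        return self

    def per_cycle_prob(
        self, stratum: Optional[Stratum] = None, cycle_days: float = 28.0
    ) -> float:
        s = self.resolve(stratum)
        if s.kind == "median_months":
            return per_cycle_prob_from_median(s.median_months, cycle_days)
        return per_cycle_prob_from_landmark(
            s.landmark_fraction, s.landmark_years, cycle_days
        )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        if self.kind == "median_months":
            d["median_months"] = float(self.median_months)
        else:
            d["landmark_fraction"] = float(self.landmark_fraction)
            d["landmark_years"] = float(self.landmark_years)
        if self.overrides:
            d["overrides"] = [
                {"when": pred.to_dict(), **summ.to_dict()}
                for pred, summ in self.overrides
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EfficacySummary":
        overrides = tuple(
            (StratumPredicate.from_dict(o["when"]),
             cls.from_dict({k: v for k, v in o.items() if k != "when"}))
            for o in d.get("overrides", ())
        )
        if d["kind"] == "median_months":
            return cls.median(d["median_months"], overrides)
        return cls.landmark(d["landmark_fraction"], d["landmark_years"], overrides)
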