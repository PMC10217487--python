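"""Minimal single-regimen configurations used by several test modules."""

from cllburden.context import ModelContext
from cllburden.params import BaselineParameters
from cllburden.policy import CONTINUOUS, FIXED, AllocationPolicy, PolicyRule
from cllburden.registry import FIRST, SECOND, RegimenSpec, Registry
from cllburden.states import ANY_STRATUM
from cllburden.survival import EfficacySummary


def exact_cycle_prob(p: float) -> EfficacySummary:
    """A landmark summary whose per-cycle probability is exactly ``p``
    (event-free fraction 1-p observed over one 28-day cycle)."""
    if p <= 0.0:
        return EfficacySummary.landmark(1.0, 1.0)
    return EfficacySummary.landmark(1.0 - p, 28.0 / 365.25)


def toy_context(
    p_prog1: float = 0.0,
    p_prog2: float = 0.0,
    p_os: float = 0.0,
    cost1: float = 0.0,
    cost2: float = 0.0,
    duration_class: str = "continuous_ott",
    max_cycles=None,
    ae_profile1=None,
    years=(2020, 2022),
    incidence=None,
    **param_changes,
) -> ModelContext:
    """One regimen per line, one rule per line, flat incidence."""
    r1 = RegimenSpec(
        "T1", FIRST, duration_class,
        cost_schedule=((1, None, cost1),),
        efficacy_pfs=exact_cycle_prob(p_prog1),
        ae_profile=ae_profile1 or {},
        max_cycles=max_cycles,
        oral_only=True,
    )
    r2 = RegimenSpec(
        "T2", SECOND, "continuous_ott",
        cost_schedule=((1, None, cost2),),
        efficacy_pfs=exact_cycle_prob(p_prog2),
        efficacy_os=exact_cycle_prob(p_os),
        oral_only=True,
    )
    rules = [
        PolicyRule(years, FIRST, ANY_STRATUM, {"T1": 1.0}),
        PolicyRule(years, SECOND, ANY_STRATUM, {"T2": 1.0}),
    ]
    if incidence is None:
        incidence = {y: 1000.0 for y in range(years[0], years[1] + 1)}
    return ModelContext(
        params=BaselineParameters().copy(**param_changes),
        registry=Registry([r1, r2]),
        policies={FIXED: AllocationPolicy(FIXED, list(rules)),
                  CONTINUOUS: AllocationPolicy(CONTINUOUS, list(rules))},
        incidence=dict(incidence),
        warmup_years=(years[0], years[0]),
        projection_years=years,
    )


ALL_RISKS_OFF = dict(
    p_background_death_per_cycle=0.0,
    p_ww_to_tx_per_cycle=0.0,
    p_discontinue_1L_per_cycle=0.0,
    p_discontinue_2L_per_cycle=0.0,
)
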