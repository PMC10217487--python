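"""Treatment-allocation policies and their validation."""

import pytest

from cllburden.params import TimeGrid
from cllburden.policy import (
    AVAILABILITY,
    CONTINUOUS,
    FIXED,
    AllocationPolicy,
    PolicyError,
    PolicyRule,
    default_policy,
    validate_policy,
)
from cllburden.registry import FIRST, SECOND
from cllburden.states import ANY_STRATUM, STRATA, AgeGroup, Stratum, StratumPredicate

UNFIT_UNMUTATED = Stratum(AgeGroup.OVER_70, False, False, False)
DEL17P = Stratum(AgeGroup.UNDER_65, True, True, None)


def test_degenerate_policy_returns_single_regimen():
    pol = AllocationPolicy(FIXED, [PolicyRule((2020, 2025), FIRST,
                                              ANY_STRATUM, {"GClb": 1.0})])
    assert pol.shares(2022, FIRST, UNFIT_UNMUTATED) == {"GClb": 1.0}


def test_shares_not_summing_to_one_rejected():
    pol = AllocationPolicy(FIXED, [PolicyRule((2020, 2025), FIRST,
                                              ANY_STRATUM,
                                              {"A": 0.5, "B": 0.4})])
    with pytest.raises(PolicyError, match="sum"):
        pol.shares(2022, FIRST, UNFIT_UNMUTATED)


def test_unmatched_cell_names_year_line_stratum():
    pol = AllocationPolicy(FIXED, [])
    with pytest.raises(PolicyError) as err:
        pol.shares(2022, SECOND, DEL17P)
    assert "2022" in str(err.value) and "second" in str(err.value)


def test_default_fixed_policy_gives_vo_to_unfit_unmutated_2022():
    shares = default_policy(FIXED).shares(2022, FIRST, UNFIT_UNMUTATED)
    assert shares.get("VO", 0.0) > 0.0


def test_shipped_default_policies_validate_cleanly(registry):
    grid = TimeGrid(2010, 2025)
    for scenario in (FIXED, CONTINUOUS):
        assert validate_policy(default_policy(scenario), registry, grid) == []


def test_premature_regimen_flagged(registry):
    pol = AllocationPolicy(FIXED, [
        PolicyRule((2019, 2025), FIRST, ANY_STRATUM, {"VO": 1.0}),
        PolicyRule((2019, 2025), SECOND, ANY_STRATUM, {"ibrutinib": 1.0}),
    ])
    violations = validate_policy(pol, registry, TimeGrid(2019, 2025))
    assert any("before" in v and "VO" in v for v in violations)
    assert AVAILABILITY[(FIRST, "VO")] == 2021


def test_coverage_gap_reported_not_raised(registry):
    pol = AllocationPolicy(FIXED, [
        PolicyRule((2020, 2025), FIRST, StratumPredicate(del17p=False),
                   {"GClb": 1.0}),
        PolicyRule((2020, 2025), SECOND, ANY_STRATUM, {"ibrutinib": 1.0}),
    ])
    violations = validate_policy(pol, registry, TimeGrid(2020, 2021))
    assert any("no allocation rule" in v for v in violations)


def test_unknown_regimen_flagged(registry):
    pol = AllocationPolicy(FIXED, [
        PolicyRule((2020, 2021), FIRST, ANY_STRATUM, {"VENE": 1.0}),
        PolicyRule((2020, 2021), SECOND, ANY_STRATUM, {"ibrutinib": 1.0}),
    ])
    violations = validate_policy(pol, registry, TimeGrid(2020, 2021))
    assert any("VENE" in v and "not in registry" in v for v in violations)


def test_warmup_rules_identical_between_scenarios():
    """Pre-2020 (and, with VR uptake modelled from 2021, all-2020)
    allocations agree between the two shipped scenarios."""
    fixed, cont = default_policy(FIXED), default_policy(CONTINUOUS)
    for year in range(2010, 2021):
        for line in (FIRST, SECOND):
            for s in STRATA:
                assert fixed.shares(year, line, s) == cont.shares(year, line, s)


def test_scenarios_diverge_only_in_ott_substitution():
    """From 2021 the fixed scenario moves the continuous-OTT share to
    VO (first line, IGHV-unmutated) and VR (second line); everything
    else is unchanged."""
    fixed, cont = default_policy(FIXED), default_policy(CONTINUOUS)
    for year in range(2021, 2026):
        for s in STRATA:
            sf = fixed.shares(year, FIRST, s)
            sc = cont.shares(year, FIRST, s)
            if sf != sc:
                assert "VO" in sf and "ibrutinib" in sc
            sf2 = fixed.shares(year, SECOND, s)
            sc2 = cont.shares(year, SECOND, s)
            if sf2 != sc2:
                assert "VR" in sf2 and "ibrutinib" in sc2


def test_policy_round_trip(tmp_path):
    pol = default_policy(FIXED)
    path = tmp_path / "policy.yaml"
    pol.save(path)
    assert AllocationPolicy.load(path).to_dict() == pol.to_dict()
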