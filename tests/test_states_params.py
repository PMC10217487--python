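"""Strata, baseline parameters and the entry distribution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cllburden.params import (
    BaselineParameters,
    ParameterError,
    TimeGrid,
    build_entry_distribution,
    stratum_probabilities,
)
from cllburden.states import (
    STRATA,
    AgeGroup,
    HealthState,
    Stratum,
    StratumPredicate,
    enumerate_strata,
)


def test_eighteen_strata_del17p_not_split_by_ighv():
    strata = enumerate_strata()
    assert len(strata) == 18
    assert all(s.ighv_mutated is None for s in strata if s.del17p)
    assert all(s.ighv_mutated is not None for s in strata if not s.del17p)


def test_stratum_construction_rejects_inconsistent_ighv():
    with pytest.raises(ValueError):
        Stratum(AgeGroup.UNDER_65, True, True, True)
    with pytest.raises(ValueError):
        Stratum(AgeGroup.UNDER_65, True, False, None)


def test_predicate_on_ighv_never_matches_del17p_strata():
    pred = StratumPredicate(ighv_mutated=False)
    del17p = Stratum(AgeGroup.OVER_70, False, True, None)
    assert not pred.matches(del17p)
    assert pred.matches(Stratum(AgeGroup.OVER_70, False, False, False))


def test_entry_distribution_defaults(params):
    dist = build_entry_distribution(params)
    assert math.isclose(sum(dist.values()), 1.0, abs_tol=1e-12)
    ww_mass = sum(v for (s, h), v in dist.items()
                  if h is HealthState.WATCHFUL_WAITING)
    assert ww_mass == pytest.approx(0.85, abs=1e-12)
    assert sum(v for (s, h), v in dist.items()
               if h is HealthState.FIRST_LINE) == pytest.approx(0.15, abs=1e-12)
    over70 = sum(v for (s, h), v in dist.items()
                 if s.age_group is AgeGroup.OVER_70)
    assert over70 == pytest.approx(0.5191, abs=1e-12)


def test_entry_distribution_boundary_all_watchful_waiting(params):
    dist = build_entry_distribution(params.copy(p_ww_at_diagnosis=1.0))
    assert all(v == 0.0 for (s, h), v in dist.items()
               if h is HealthState.FIRST_LINE)


def test_fit_marginal_among_young_is_exact(params):
    probs = stratum_probabilities(params)
    young = [i for i, s in enumerate(STRATA)
             if s.age_group is AgeGroup.UNDER_65]
    young_fit = [i for i in young if STRATA[i].fit]
    assert probs[young_fit].sum() / probs[young].sum() == pytest.approx(
        params.fitness_by_age[0], abs=1e-12
    )


def test_invalid_probability_names_offending_field(params):
    bad = params.copy(p_ww_at_diagnosis=1.5)
    with pytest.raises(ParameterError, match="p_ww_at_diagnosis"):
        bad.validate()
    with pytest.raises(ParameterError, match="prevalence_del17p"):
        params.copy(prevalence_del17p=-0.1).validate()


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    p_ww=st.floats(0.0, 1.0),
    del17p=st.floats(0.0, 1.0),
    ighv=st.floats(0.0, 1.0),
    a1=st.floats(0.01, 1.0),
    a2=st.floats(0.01, 1.0),
    a3=st.floats(0.01, 1.0),
    f=st.tuples(*[st.floats(0.0, 1.0)] * 3),
)
def test_entry_distribution_sums_to_one_for_any_valid_params(
    p_ww, del17p, ighv, a1, a2, a3, f
):
    total = a1 + a2 + a3
    params = BaselineParameters(
        p_ww_at_diagnosis=p_ww,
        prevalence_del17p=del17p,
        p_ighv_mutated=ighv,
        age_distribution=(a1 / total, a2 / total, a3 / total),
        fitness_by_age=f,
    )
    dist = build_entry_distribution(params)
    assert math.isclose(sum(dist.values()), 1.0, abs_tol=1e-12)


def test_parameter_roundtrip_and_omitted_keys_get_defaults(tmp_path, params):
    path = tmp_path / "params.yaml"
    params.save(path)
    assert BaselineParameters.load(path).to_dict() == params.to_dict()
    sparse = BaselineParameters.from_dict({"p_ww_at_diagnosis": 0.9})
    assert sparse.p_ww_to_tx_per_cycle == 0.0165
    assert sparse.p_ww_at_diagnosis == 0.9


class TestTimeGrid:
    def test_cycle_to_year_assignment(self):
        grid = TimeGrid(2020, 2025)
        assert grid.year_of_cycle(0) == 2020
        assert grid.year_of_cycle(13) == 2020  # day 364 < 365.25
        assert grid.year_of_cycle(14) == 2021
        assert grid.n_cycles == 79
        assert grid.year_of_cycle(grid.n_cycles - 1) == 2025

    def test_every_cycle_in_exactly_one_year(self):
        grid = TimeGrid(2010, 2019)
        seen = sorted(c for y in grid.years for c in grid.cycles_in_year(y))
        assert seen == list(range(grid.n_cycles))
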