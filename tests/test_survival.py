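"""Survival-summary to per-cycle probability conversions."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cllburden.params import DAYS_PER_MONTH, DAYS_PER_YEAR
from cllburden.states import AgeGroup, Stratum, StratumPredicate
from cllburden.survival import (
    EfficacySummary,
    annual_prob_to_cycle,
    per_cycle_prob_from_landmark,
    per_cycle_prob_from_median,
)


@pytest.mark.parametrize(
    "median,expected",
    [
        (29.8, 0.02117),     # 1 - 0.5 ** (28 / 907.0375)
        (57.6, 0.01101),     # 4.8 years; the calibrated 1.65% is used
                             # instead for WW -> treatment, this is the
                             # raw exponential conversion
    ],
)
def test_median_conversion_closed_form(median, expected):
    assert per_cycle_prob_from_median(median) == pytest.approx(expected, abs=5e-6)


def test_median_of_one_cycle_gives_half():
    one_cycle_months = 28.0 / DAYS_PER_MONTH
    assert per_cycle_prob_from_median(one_cycle_months) == pytest.approx(
        0.5, abs=1e-12
    )


@pytest.mark.parametrize(
    "fraction,years,expected",
    [
        (0.70, 5.0, 0.00545),
        (0.82, 3.0, 0.00506),
        (1.0, 7.0, 0.0),
    ],
)
def test_landmark_conversion_closed_form(fraction, years, expected):
    assert per_cycle_prob_from_landmark(fraction, years) == pytest.approx(
        expected, abs=5e-6
    )


@pytest.mark.parametrize(
    "p_annual,expected",
    [(0.0, 0.0), (1.0, 1.0), (0.5, 0.05175)],
)
def test_annual_to_cycle(p_annual, expected):
    assert annual_prob_to_cycle(p_annual) == pytest.approx(expected, abs=5e-6)


@pytest.mark.parametrize(
    "call",
    [
        lambda: per_cycle_prob_from_median(0.0),
        lambda: per_cycle_prob_from_median(-3.0),
        lambda: per_cycle_prob_from_landmark(0.0, 5.0),
        lambda: per_cycle_prob_from_landmark(0.5, 0.0),
        lambda: annual_prob_to_cycle(1.2),
    ],
)
def test_domain_errors(call):
    with pytest.raises(ValueError):
        call()


@settings(max_examples=200, deadline=None, derandomize=True)
@given(median=st.floats(0.5, 600.0))
def test_median_round_trip_survival_is_half(median):
    p = per_cycle_prob_from_median(median)
    n_cycles = median * DAYS_PER_MONTH / 28.0
    assert (1.0 - p) ** n_cycles == pytest.approx(0.5, abs=1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(fraction=st.floats(0.01, 1.0), years=st.floats(0.25, 20.0))
def test_landmark_round_trip_reproduces_fraction(fraction, years):
    p = per_cycle_prob_from_landmark(fraction, years)
    n_cycles = years * DAYS_PER_YEAR / 28.0
    assert (1.0 - p) ** n_cycles == pytest.approx(fraction, abs=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(m1=st.floats(1.0, 300.0), m2=st.floats(1.0, 300.0))
def test_probability_strictly_decreases_in_median(m1, m2):
    if m1 == m2:
        return
    lo, hi = sorted((m1, m2))
    assert per_cycle_prob_from_median(hi) < per_cycle_prob_from_median(lo)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(f1=st.floats(0.05, 0.999), f2=st.floats(0.05, 0.999))
def test_probability_strictly_increases_in_event_fraction(f1, f2):
    if f1 == f2:
        return
    lo, hi = sorted((f1, f2))
    assert per_cycle_prob_from_landmark(lo, 5.0) > per_cycle_prob_from_landmark(hi, 5.0)


class TestEfficacyOverrides:
    def test_stratum_specific_summary_takes_precedence(self):
        summ = EfficacySummary.landmark(
            0.70, 5.0,
            overrides=(
                (StratumPredicate(del17p=True), EfficacySummary.landmark(0.56, 5.0)),
                (StratumPredicate(ighv_mutated=True),
                 EfficacySummary.landmark(0.81, 5.0)),
            ),
        )
        del17p = Stratum(AgeGroup.UNDER_65, True, True, None)
        mutated = Stratum(AgeGroup.UNDER_65, True, False, True)
        assert summ.resolve(del17p).landmark_fraction == 0.56
        assert summ.resolve(mutated).landmark_fraction == 0.81
        assert summ.resolve(None).landmark_fraction == 0.70

    def test_serialization_round_trip(self):
        summ = EfficacySummary.median(
            44.1, overrides=((StratumPredicate(del17p=True),
                              EfficacySummary.median(40.6)),)
        )
        assert EfficacySummary.from_dict(summ.to_dict()) == summ
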