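"""Treatment registry: completeness, cost schedules, adverse events."""

import pytest

from cllburden.registry import (
    FIRST,
    SECOND,
    RegimenSpec,
    Registry,
    RegistryError,
    course_drug_cost,
    default_registry,
    drug_cost_for_cycle,
    expected_ae_cost,
)
from cllburden.survival import EfficacySummary


def test_all_sixteen_regimens_present(registry):
    assert sorted(registry.names(FIRST)) == sorted(
        ["GClb", "FCR", "FR", "F", "BR", "Clb", "ibrutinib", "ACAL", "VO"]
    )
    assert sorted(registry.names(SECOND)) == sorted(
        ["F", "FCR", "ibrutinib", "BR", "ACAL", "venetoclax", "VR"]
    )
    assert len(registry) == 16


def test_duration_classes(registry):
    assert registry.get(FIRST, "ibrutinib").duration_class == "continuous_ott"
    assert registry.get(FIRST, "VO").duration_class == "fixed_ott"
    assert registry.get(FIRST, "VO").max_cycles == 13
    assert registry.get(SECOND, "VR").max_cycles == 26
    assert registry.get(SECOND, "venetoclax").max_cycles is None
    for name in ("GClb", "FCR", "FR", "F", "BR", "Clb"):
        assert registry.get(FIRST, name).max_cycles == 6


@pytest.mark.parametrize(
    "line,name,cycle,expected",
    [
        (FIRST, "GClb", 1, 16497.0),
        (FIRST, "GClb", 6, 5541.0),
        (FIRST, "GClb", 7, 0.0),          # beyond the 6-cycle course
        (FIRST, "VO", 14, 0.0),           # beyond the 13-cycle fixed course
        (FIRST, "ibrutinib", 999, 8198.0),  # continuous tail
        (SECOND, "venetoclax", 1, 1813.0),
        (SECOND, "venetoclax", 500, 7840.0),
    ],
)
def test_drug_cost_for_cycle(registry, line, name, cycle, expected):
    assert drug_cost_for_cycle(registry.get(line, name), cycle) == expected


def test_drug_cost_rejects_nonpositive_cycle(registry):
    with pytest.raises(ValueError):
        drug_cost_for_cycle(registry.get(FIRST, "GClb"), 0)


def test_course_costs(registry):
    assert course_drug_cost(registry.get(FIRST, "GClb")) == pytest.approx(44_202.0)
    assert course_drug_cost(registry.get(FIRST, "VO")) == pytest.approx(133_837.0)
    with pytest.raises(RegistryError, match="per cycle"):
        course_drug_cost(registry.get(FIRST, "ibrutinib"))


def test_course_cost_includes_vr_ramp_up(registry):
    vr = registry.get(SECOND, "VR")
    expected = 3773.0 + 9945.0 + 5 * 10_647.0 + 20 * 7840.0
    assert course_drug_cost(vr) == pytest.approx(expected)


def test_expected_ae_cost_first_line_ibrutinib(registry, params):
    reg = registry.get(FIRST, "ibrutinib")
    assert expected_ae_cost(reg, params.unit_costs) == pytest.approx(301.38, abs=0.01)


def test_expected_ae_cost_edge_cases(params):
    empty = RegimenSpec(
        "toy", FIRST, "continuous_ott",
        cost_schedule=((1, None, 0.0),),
        efficacy_pfs=EfficacySummary.median(30.0),
    )
    assert expected_ae_cost(empty, params.unit_costs) == 0.0
    febrile = RegimenSpec(
        "toy2", FIRST, "continuous_ott",
        cost_schedule=((1, None, 0.0),),
        efficacy_pfs=EfficacySummary.median(30.0),
        ae_profile={"febrile_neutropenia": 1.0},
    )
    assert expected_ae_cost(febrile, params.unit_costs) == pytest.approx(10_918.0)
    with pytest.raises(RegistryError, match="unit cost"):
        expected_ae_cost(febrile, {})


def test_schedule_gap_rejected():
    with pytest.raises(RegistryError, match="gap"):
        RegimenSpec(
            "gappy", FIRST, "cit_course",
            cost_schedule=((1, 2, 100.0), (4, 6, 100.0)),
            efficacy_pfs=EfficacySummary.median(30.0),
            max_cycles=6,
        )


def test_continuous_regimen_rejects_max_cycles():
    with pytest.raises(RegistryError, match="unbounded"):
        RegimenSpec(
            "bad", FIRST, "continuous_ott",
            cost_schedule=((1, None, 1.0),),
            efficacy_pfs=EfficacySummary.median(30.0),
            max_cycles=10,
        )


def test_registry_round_trips_bit_identically(registry, tmp_path):
    path = tmp_path / "registry.yaml"
    registry.save(path)
    loaded = Registry.load(path)
    assert loaded.to_dict() == registry.to_dict()
    # and the reloaded registry reproduces every efficacy number exactly
    for r in registry.regimens():
        r2 = loaded.get(r.line, r.name)
        assert r2.efficacy_pfs == r.efficacy_pfs
        assert r2.efficacy_os == r.efficacy_os
        assert r2.cost_schedule == r.cost_schedule
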