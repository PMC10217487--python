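"""Synthetic stand-ins for external inputs the published model consumed.

The original analysis used national statistics (annual incident CLL
case counts), real-world calibration targets and clinic-level treatment
mixes that are not printed anywhere; this module emulates them with
controlled statistical structure so the whole pipeline runs and can be
tested offline:

* an incidence series with geometric annual growth and optional
  multiplicative lognormal noise (unit median, chosen coefficient of
  variation);
* calibration targets generated from the model's own warm-up
  observables at known "true" parameters, optionally noised — the basis
  of parameter-recovery experiments;
* complete runnable configuration bundles (parameters, registry, both
  policies, incidence, monitoring schedule, targets) written to and
  read from plain-text files;
* a set of deliberately small configurations used to cross-validate the
  cohort engine against the individual-level simulator.

The default incidence (1800 cases in 2010 growing 2%/year, noise-free)
was fixed once so that the default bundle's prevalent 2020 population
is near the originally reported 15,512; see scripts/tune_incidence.py
for the provenance of these constants.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .calibrate import CalibrationTarget, observable_from_trace
from .context import ModelContext, default_context, run_warmup
from .costing import MonitoringSchedule
from .engine import ModelOptions
from .params import BaselineParameters
from .policy import CONTINUOUS, FIXED, AllocationPolicy, PolicyRule, default_policy
from .registry import FIRST, SECOND, Registry, default_registry
from .states import ANY_STRATUM

DEFAULT_BASE_INCIDENCE = 2000.0  # cases in 2010
DEFAULT_ANNUAL_GROWTH = 0.02


def generate_incidence(
    base_count: float,
    annual_growth: float,
    years: Sequence[int],
    seed: Optional[int] = None,
    noise_cv: float = 0.0,
) -> dict[int, float]:
    """Incident case counts: ``base_count * (1 + growth)^(y - y0)``
    times lognormal noise with unit median and CV ``noise_cv``."""
    years = list(years)
    if not years:
        raise ValueError("year range must be non-empty")
    if base_count <= 0:
        raise ValueError("base_count must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    y0 = years[0]
    trend = {y: base_count * (1.0 + annual_growth) ** (y - y0) for y in years}
    if noise_cv == 0.0:
        return trend
    sigma = math.sqrt(math.log(1.0 + noise_cv**2))
    rng = np.random.default_rng(seed)
    noise = np.exp(rng.normal(0.0, sigma, size=len(years)))
    return {y: trend[y] * float(z) for y, z in zip(years, noise)}


def default_incidence() -> dict[int, float]:
    return generate_incidence(
        DEFAULT_BASE_INCIDENCE, DEFAULT_ANNUAL_GROWTH, range(2010, 2026)
    )


def generate_calibration_targets(
    ctx: ModelContext,
    target_spec: Sequence[tuple[str, int, float]] = (
        ("prevalence_at_year", 2019, 1.0),
        ("on_drug_share_at_year", 2019, 1.0),
    ),
    seed: Optional[int] = None,
    noise_cv: float = 0.0,
) -> list[CalibrationTarget]:
    """Targets equal to the model's own warm-up observables at the
    context's (true) parameters, optionally with multiplicative noise.

    With ``noise_cv = 0`` calibration at these targets has an exact
    zero-residual solution at the generating parameters, which is what
    parameter-recovery experiments need.
    """
    trace = run_warmup(ctx).trace
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0
    out = []
    for observable, year, weight in target_spec:
        value = observable_from_trace(trace, observable, year)
        if sigma > 0:
            value *= float(np.exp(rng.normal(0.0, sigma)))
        out.append(CalibrationTarget(observable, year, value, weight))
    return out


# ---------------------------------------------------------------------
# configuration bundles

_BUNDLE_FILES = (
    "params.yaml", "registry.yaml", "policy_fixed.yaml",
    "policy_continuous.yaml", "incidence.csv", "schedule.yaml", "meta.yaml",
)


def write_bundle(ctx: ModelContext, out_dir,
                 targets: Optional[Sequence[CalibrationTarget]] = None) -> list[str]:
    """Serialize a complete runnable configuration; returns file names."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ctx.params.save(out / "params.yaml")
    ctx.registry.save(out / "registry.yaml")
    ctx.policy(FIXED).save(out / "policy_fixed.yaml")
    ctx.policy(CONTINUOUS).save(out / "policy_continuous.yaml")
    with open(out / "incidence.csv", "w") as fh:
        fh.write("year,count\n")
        for y in sorted(ctx.incidence):
            fh.write(f"{y},{ctx.incidence[y]!r}\n")
    ctx.schedule.save(out / "schedule.yaml")
    meta = {
        "warmup_years": list(ctx.warmup_years),
        "projection_years": list(ctx.projection_years),
        "options": {
            "discontinue_destination": ctx.options.discontinue_destination,
            "ae_cost_basis": ctx.options.ae_cost_basis,
            "tunnel_cap": int(ctx.options.tunnel_cap),
        },
        "drug_cost_multipliers": {
            k: float(v) for k, v in ctx.drug_cost_multipliers.items()
        },
    }
    with open(out / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    files = list(_BUNDLE_FILES)
    if targets is not None:
        with open(out / "targets.yaml", "w") as fh:
            yaml.safe_dump([t.to_dict() for t in targets], fh, sort_keys=True)
        files.append("targets.yaml")
    return files


def read_bundle(bundle_dir) -> ModelContext:
    d = Path(bundle_dir)
    params = BaselineParameters.load(d / "params.yaml")
    registry = Registry.load(d / "registry.yaml")
    policies = {
        FIXED: AllocationPolicy.load(d / "policy_fixed.yaml"),
        CONTINUOUS: AllocationPolicy.load(d / "policy_continuous.yaml"),
    }
    incidence: dict[int, float] = {}
    with open(d / "incidence.csv") as fh:
        next(fh)
        for line in fh:
            y, c = line.strip().split(",")
            incidence[int(y)] = float(c)
    schedule = MonitoringSchedule.load(d / "schedule.yaml")
    with open(d / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    return ModelContext(
        params=params,
        registry=registry,
        policies=policies,
        incidence=incidence,
        schedule=schedule,
        options=ModelOptions(**meta.get("options", {})),
        warmup_years=tuple(meta["warmup_years"]),
        projection_years=tuple(meta["projection_years"]),
        drug_cost_multipliers=dict(meta.get("drug_cost_multipliers", {})),
    )


def read_targets(bundle_dir) -> list[CalibrationTarget]:
    with open(Path(bundle_dir) / "targets.yaml") as fh:
        return [CalibrationTarget.from_dict(d) for d in yaml.safe_load(fh)]


def make_bundle(seed: Optional[int], out_dir, noise_cv: float = 0.0) -> ModelContext:
    """Generate and write the default configuration bundle."""
    incidence = generate_incidence(
        DEFAULT_BASE_INCIDENCE, DEFAULT_ANNUAL_GROWTH, range(2010, 2026),
        seed=seed, noise_cv=noise_cv,
    )
    ctx = default_context(incidence=incidence)
    targets = generate_calibration_targets(ctx)
    write_bundle(ctx, out_dir, targets=targets)
    return ctx


# ---------------------------------------------------------------------
# small cross-validation configurations


def _single_policy(shares1: dict, shares2: dict, years: tuple[int, int]):
    rules = [
        PolicyRule(years, FIRST, ANY_STRATUM, shares1),
        PolicyRule(years, SECOND, ANY_STRATUM, shares2),
    ]
    return {FIXED: AllocationPolicy(FIXED, list(rules)),
            CONTINUOUS: AllocationPolicy(CONTINUOUS, list(rules))}


def small_validation_contexts() -> dict[str, ModelContext]:
    """Five deliberately small configurations (one or two regimens per
    line, few strata, short horizon, no warm-up) used to cross-validate
    the cohort engine against the micro-simulation oracle."""
    registry = default_registry()
    years = (2020, 2022)
    incidence = {2020: 1000.0, 2021: 1000.0, 2022: 1000.0}

    def ctx(shares1, shares2, **param_changes):
        params = BaselineParameters().copy(**param_changes)
        return ModelContext(
            params=params,
            registry=registry,
            policies=_single_policy(shares1, shares2, years),
            incidence=dict(incidence),
            warmup_years=(2019, 2019),
            projection_years=years,
        )

    one_stratum = dict(
        prevalence_del17p=0.0, p_ighv_mutated=1.0,
        age_distribution=(1.0, 0.0, 0.0), fitness_by_age=(1.0, 0.0, 0.0),
    )
    two_strata = dict(
        prevalence_del17p=0.0, p_ighv_mutated=0.5,
        age_distribution=(1.0, 0.0, 0.0), fitness_by_age=(1.0, 0.0, 0.0),
    )
    return {
        "continuous_ott": ctx(
            {"ibrutinib": 1.0}, {"venetoclax": 1.0}, **one_stratum
        ),
        "fixed_first_line": ctx(
            {"VO": 1.0}, {"FCR": 1.0}, **one_stratum
        ),
        "cit_then_ott": ctx(
            {"GClb": 1.0}, {"ibrutinib": 1.0}, **two_strata
        ),
        "mixed_shares": ctx(
            {"FCR": 0.5, "ibrutinib": 0.5}, {"ibrutinib": 1.0}, **two_strata
        ),
        "fast_progression": ctx(
            {"Clb": 1.0}, {"F": 1.0},
            p_ww_at_diagnosis=0.5, p_ww_to_tx_per_cycle=0.05, **one_stratum
        ),
    }
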