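"""One-way sensitivity analysis (tornado table).

Each designated parameter is varied to 75% and 125% of its baseline,
all others held fixed, and the outcome — by default the cumulative
2020-2025 total-cost difference, fixed minus continuous scenario — is
recomputed with two scenario-pair runs per bound.  Probabilities are
clipped to [0, 1] with a logged warning.  PFS/OS summaries and the
calibrated probabilities (WW-to-treatment, discontinuation, background
death) are excluded from the default parameter list because they were
set by calibration, not measured independently.
"""

from __future__ import annotations

import logging
from typing import Callable, Optional, Sequence

import pandas as pd

from .context import ModelContext, run_both_scenarios

log = logging.getLogger(__name__)

#: probability-type scalar parameters eligible for OWSA
_PROB_SCALARS = ("p_ww_at_diagnosis", "prevalence_del17p", "p_ighv_mutated")
_COST_SCALARS = ("palliative_care_cost",)

#: calibrated quantities never varied here
EXCLUDED_PARAMETERS = (
    "p_ww_to_tx_per_cycle",
    "p_discontinue_1L_per_cycle",
    "p_discontinue_2L_per_cycle",
    "p_background_death_per_cycle",
)


def default_owsa_parameters(ctx: ModelContext) -> list[str]:
    """All baseline costs and non-calibrated probabilities, plus one
    drug-cost scale per regimen."""
    names = list(_PROB_SCALARS) + list(_COST_SCALARS)
    names += [f"unit_cost.{k}" for k in sorted(ctx.params.unit_costs)]
    regimen_names = sorted({r.name for r in ctx.registry.regimens()})
    names += [f"drug_cost.{n}" for n in regimen_names]
    return names


def baseline_value(ctx: ModelContext, name: str) -> float:
    if name.startswith("unit_cost."):
        return float(ctx.params.unit_costs[name.split(".", 1)[1]])
    if name.startswith("drug_cost."):
        return float(ctx.drug_cost_multipliers.get(name.split(".", 1)[1], 1.0))
    if name in _PROB_SCALARS + _COST_SCALARS:
        return float(getattr(ctx.params, name))
    raise KeyError(f"unknown sensitivity parameter {name!r}")


def perturb(ctx: ModelContext, name: str, factor: float) -> ModelContext:
    """A deep-copied context with ``name`` scaled by ``factor``."""
    out = ctx.copy()
    if name.startswith("unit_cost."):
        key = name.split(".", 1)[1]
        out.params.unit_costs[key] *= factor
        return out
    if name.startswith("drug_cost."):
        key = name.split(".", 1)[1]
        base = out.drug_cost_multipliers.get(key, 1.0)
        out.drug_cost_multipliers[key] = base * factor
        return out
    value = getattr(out.params, name) * factor
    if name in _PROB_SCALARS and value > 1.0:
        log.warning("%s clipped to 1.0 (was %.4f after scaling)", name, value)
        value = 1.0
    out.params = out.params.copy(**{name: value})
    return out


def scenario_cost_difference(ctx: ModelContext) -> float:
    """Cumulative total cost, fixed minus continuous scenario (CAD)."""
    _, _, report = run_both_scenarios(ctx)
    return float(report["cumulative_fixed"] - report["cumulative_continuous"])


def run_owsa(
    param_list: Optional[Sequence[str]],
    ctx: ModelContext,
    outcome: Callable[[ModelContext], float] = scenario_cost_difference,
    rel_range: float = 0.25,
) -> pd.DataFrame:
    """Tornado table: one row per parameter, sorted by descending bar
    width, ties broken alphabetically.  A failed evaluation flags the
    row (``error`` column) and the run continues."""
    names = list(param_list) if param_list is not None \
        else default_owsa_parameters(ctx)
    base_outcome = outcome(ctx)
    rows = []
    for name in names:
        base_value = baseline_value(ctx, name)
        row = {
            "parameter": name,
            "low_value": base_value * (1.0 - rel_range),
            "high_value": base_value * (1.0 + rel_range),
            "baseline_outcome": base_outcome,
            "outcome_low": float("nan"),
            "outcome_high": float("nan"),
            "width": float("nan"),
            "error": "",
        }
        try:
            row["outcome_low"] = outcome(perturb(ctx, name, 1.0 - rel_range))
            row["outcome_high"] = outcome(perturb(ctx, name, 1.0 + rel_range))
            row["width"] = abs(row["outcome_high"] - row["outcome_low"])
        except Exception as exc:  # noqa: BLE001 — flagged, not fatal
            row["error"] = f"{type(exc).__name__}: {exc}"
            log.warning("sensitivity run failed for %s: %s", name, exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["width", "parameter"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return df


def plot_tornado(table: pd.DataFrame, path) -> None:
    """Optional convenience figure; the CSV is the artifact."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = table.dropna(subset=["width"]).head(15).iloc[::-1]
    base = shown["baseline_outcome"].iloc[0] if len(shown) else 0.0
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(shown) + 1.5))
    for i, (_, row) in enumerate(shown.iterrows()):
        lo = min(row["outcome_low"], row["outcome_high"])
        hi = max(row["outcome_low"], row["outcome_high"])
        ax.barh(i, hi - lo, left=lo, color="#4878b0")
    ax.axvline(base, color="k", lw=1)
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels(shown["parameter"])
    ax.set_xlabel("cumulative cost difference, fixed - continuous (CAD)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
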